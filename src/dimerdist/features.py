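"""Assembly of the (S, S, 186) model input tensor.

Channel layout (fixed and recorded on every FeatureStack):

====== ======================= ==========================================
index  name                    content
====== ======================= ==========================================
0      distance                intra-chain Cb-Cb distances, raw Angstrom;
                               for heterodimers the two monomer maps sit
                               in the diagonal blocks, zeros elsewhere
1      plm                     pseudo-likelihood coupling scores
                               (CCMpred-style), symmetric
2-145  attention_0..143        MSA-transformer-style row attention maps,
                               passed through unmodified
146-185 pssm_0..39             tiled PSSM: out[i, j] = concat(row_i, row_j)
====== ======================= ==========================================

Distances are used raw (no binning or scaling); normalization is the
network's job via its RCIN blocks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .structio import MonomerStructure, PositionSpecificScoringMatrix

N_ATTENTION = 144
N_PSSM = 40
N_CHANNELS = 1 + 1 + N_ATTENTION + N_PSSM
assert N_CHANNELS == 186

CHANNEL_LAYOUT = (
    ["distance", "plm"]
    + [f"attention_{k}" for k in range(N_ATTENTION)]
    + [f"pssm_{k}" for k in range(N_PSSM)]
)


@dataclasses.dataclass
class IntraChainDistanceMap:
    values: np.ndarray  # (L, L) Cb-Cb distances, Angstrom

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance map must be square")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance map must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance map diagonal must be zero")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class CoevolutionFeatures:
    plm_scores: np.ndarray  # (S, S), symmetric
    attention_maps: np.ndarray  # (S, S, 144)

    def __post_init__(self):
        plm = np.asarray(self.plm_scores, dtype=float)
        att = np.asarray(self.attention_maps, dtype=float)
        if plm.ndim != 2 or plm.shape[0] != plm.shape[1]:
            raise ValueError("plm_scores must be square")
        if not np.allclose(plm, plm.T):
            raise ValueError("plm_scores must be symmetric")
        if att.shape != (plm.shape[0], plm.shape[1], N_ATTENTION):
            raise ValueError(f"attention stack must be (S, S, {N_ATTENTION})")
        if not (np.isfinite(plm).all() and np.isfinite(att).all()):
            raise ValueError("co-evolution features must be finite")
        self.plm_scores, self.attention_maps = plm, att


@dataclasses.dataclass
class FeatureStack:
    tensor: np.ndarray  # (S, S, 186)
    dimer_kind: str  # "homodimer" | "heterodimer"
    lengths: tuple  # (L1, L2); L1 == L2 == L for homodimers
    channel_layout: tuple = tuple(CHANNEL_LAYOUT)

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=np.float32)
        if t.ndim != 3 or t.shape[2] != N_CHANNELS:
            raise ValueError(f"feature tensor must be (S, S, {N_CHANNELS})")
        l1, l2 = self.lengths
        side = l1 if self.dimer_kind == "homodimer" else l1 + l2
        if self.dimer_kind == "homodimer" and l1 != l2:
            raise ValueError("homodimer requires L1 == L2")
        if t.shape[0] != side or t.shape[1] != side:
            raise ValueError("tensor side must match lengths")
        if self.dimer_kind == "heterodimer":
            dist = t[:, :, 0]
            if np.any(dist[:l1, l1:]) or np.any(dist[l1:, :l1]):
                raise ValueError(
                    "heterodimer distance channel must be zero off the diagonal blocks"
                )
        self.tensor = t

    @property
    def side(self) -> int:
        return self.tensor.shape[0]


def compute_cb_distance_map(structure: MonomerStructure) -> IntraChainDistanceMap:
    """Cb-Cb Euclidean distances (Ca for glycine or Cb-less residues)."""
    coords = np.array([r.reference_coord() for r in structure.residues])
    if len(coords) == 1:
        return IntraChainDistanceMap(values=np.zeros((1, 1)))
    return IntraChainDistanceMap(values=squareform(pdist(coords)))


def cross_chain_cb_distances(
    structure_a: MonomerStructure, structure_b: MonomerStructure
) -> np.ndarray:
    """(L1, L2) Cb-Cb distances between two chains (ground-truth helper)."""
    ca = np.array([r.reference_coord() for r in structure_a.residues])
    cb = np.array([r.reference_coord() for r in structure_b.residues])
    return cdist(ca, cb)


def assemble_dimer_distance_channel(
    map_a: IntraChainDistanceMap, map_b: IntraChainDistanceMap | None = None
) -> np.ndarray:
    """Place monomer distance maps into the dimer grid.

    Homodimer (map_b None): the L x L map unchanged. Heterodimer: map_a in
    the top-left block, map_b in the bottom-right, zeros in the inter-chain
    blocks.
    """
    if map_b is None:
        return map_a.values.copy()
    l1, l2 = len(map_a), len(map_b)
    out = np.zeros((l1 + l2, l1 + l2))
    out[:l1, :l1] = map_a.values
    out[l1:, l1:] = map_b.values
    return out


def tile_pssm(
    pssm_a: PositionSpecificScoringMatrix,
    pssm_b: PositionSpecificScoringMatrix | None = None,
) -> np.ndarray:
    """Cross-concatenate PSSM rows: out[i, j] = concat(row_i, row_j).

    For heterodimers the two L x 20 profiles are vertically concatenated
    first, giving an (L1+L2, 20) profile over the dimer grid.
    """
    profile = pssm_a.scores
    if pssm_b is not None:
        profile = np.vstack([pssm_a.scores, pssm_b.scores])
    s = profile.shape[0]
    out = np.empty((s, s, N_PSSM))
    out[:, :, :20] = profile[:, None, :]
    out[:, :, 20:] = profile[None, :, :]
    return out


def stack_features(
    dist_channel: np.ndarray,
    coevo: CoevolutionFeatures,
    pssm_tile: np.ndarray,
    dimer_kind: str = "homodimer",
    lengths: tuple | None = None,
) -> FeatureStack:
    """Concatenate [distance, plm, attention x144, pssm x40] into the stack."""
    dist = np.asarray(dist_channel, dtype=float)
    side = dist.shape[0]
    for name, arr, want in (
        ("distance channel", dist, (side, side)),
        ("plm scores", coevo.plm_scores, (side, side)),
        ("attention maps", coevo.attention_maps, (side, side, N_ATTENTION)),
        ("pssm tile", pssm_tile, (side, side, N_PSSM)),
    ):
        if arr.shape != want:
            raise ValueError(f"feature length mismatch: {name} is {arr.shape}, want {want}")
    tensor = np.concatenate(
        [
            dist[:, :, None],
            coevo.plm_scores[:, :, None],
            coevo.attention_maps,
            pssm_tile,
        ],
        axis=2,
    )
    if lengths is None:
        lengths = (side, side)  # homodimer default
    return FeatureStack(tensor=tensor, dimer_kind=dimer_kind, lengths=tuple(lengths))


def save_feature_stack(path, stack: FeatureStack):
    from .structio import save_tensors

    save_tensors(
        path,
        {"tensor": stack.tensor},
        {
            "dimer_kind": stack.dimer_kind,
            "lengths": list(stack.lengths),
            "channel_layout": list(stack.channel_layout),
        },
    )


def load_feature_stack(path) -> FeatureStack:
    from .structio import load_tensors

    arrays, meta = load_tensors(path)
    return FeatureStack(
        tensor=arrays["tensor"],
        dimer_kind=meta["dimer_kind"],
        lengths=tuple(meta["lengths"]),
    )
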