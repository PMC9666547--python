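"""From raw distogram outputs to final ranked contact predictions.

The inference conventions mirror the published protocol: predictions made
from two alternative MSAs are averaged distogram-wise; for heterodimers
the network is run on both chain orders (AB and BA) and the inter-chain
block of the BA map is transposed onto the AB frame before averaging;
contact probabilities are the summed mass of all distance bins below the
8-Angstrom heavy-atom contact threshold; and a prediction's confidence is
the mean probability of its top-L/5 contacts, which tracks realized
precision.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn.model import DistogramPrediction
from .structio import RankedContactList
from .train import BIN_HIGH, DistanceBinning

DEFAULT_CONTACT_THRESHOLD = 8.0


@dataclasses.dataclass
class ContactScoreMap:
    scores: np.ndarray  # (L1, L2) contact probabilities
    threshold: float = DEFAULT_CONTACT_THRESHOLD
    dimer_kind: str = "heterodimer"

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2:
            raise ValueError("score map must be 2D")
        if (s < -1e-5).any() or (s > 1 + 1e-5).any():
            raise ValueError("contact probabilities must lie in [0, 1]")
        self.scores = np.clip(s, 0.0, 1.0)

    @property
    def shape(self):
        return self.scores.shape


def average_ensemble(preds: list) -> DistogramPrediction:
    """Elementwise mean of distogram predictions (e.g., the two-MSA ensemble).

    A convex combination of per-cell distributions is itself a distribution,
    so no renormalization is needed.
    """
    if not preds:
        raise ValueError("nothing to average")
    shapes = {p.heavy_atom_probs.shape for p in preds}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across ensemble members: {shapes}")
    return DistogramPrediction(
        heavy_atom_probs=np.mean([p.heavy_atom_probs for p in preds], axis=0),
        cb_probs=np.mean([p.cb_probs for p in preds], axis=0),
        lengths=preds[0].lengths,
        dimer_kind=preds[0].dimer_kind,
    )


def interchain_block(volume: np.ndarray, l1: int, l2: int) -> np.ndarray:
    """Top-right (chain A x chain B) block of a dimer-grid volume."""
    return volume[:l1, l1 : l1 + l2]


def average_two_orders(
    pred_ab: DistogramPrediction, pred_ba: DistogramPrediction, l1: int, l2: int
) -> dict:
    """Average the AB inter-chain block with the transposed BA block.

    Returns per-head (l1, l2, bins) inter-chain distograms in the AB frame.
    The BA run's top-right block is (l2, l1); its spatial transpose aligns
    residue i of chain A with residue j of chain B.
    """
    if pred_ab.side != l1 + l2 or pred_ba.side != l1 + l2:
        raise ValueError("prediction sides inconsistent with (l1, l2)")
    out = {}
    for head in ("heavy_atom_probs", "cb_probs"):
        block_ab = interchain_block(getattr(pred_ab, head), l1, l2)
        block_ba = interchain_block(getattr(pred_ba, head), l2, l1)
        out[head] = 0.5 * (block_ab + block_ba.transpose(1, 0, 2))
    return out


def contact_probability(
    distogram: np.ndarray, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> np.ndarray:
    """Probability mass below ``threshold`` per cell.

    Bins entirely below the threshold contribute fully; a bin straddling a
    non-boundary threshold contributes the linear fraction of its width
    below it. 8 A lands exactly on a bin edge, so the default is the clean
    sum of bins 0..12.
    """
    if not (0.0 < threshold <= BIN_HIGH):
        raise ValueError(f"threshold must lie in (0, {BIN_HIGH}]")
    arr = np.asarray(distogram, dtype=float)
    binning = DistanceBinning()
    uppers = binning.bin_upper_edges()
    lowers = np.concatenate([[0.0], uppers[:-1]])
    widths = uppers - lowers
    frac = np.clip((threshold - lowers) / widths, 0.0, 1.0)
    frac[~np.isfinite(widths)] = 0.0  # the open [22, inf) tail never counts
    return arr @ frac


def contact_map_from_distogram(
    pred: DistogramPrediction,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    symmetrize_output: bool = True,
) -> ContactScoreMap:
    """Heavy-atom-head contact probabilities for the inter-chain grid.

    Homodimer: the full L x L output grid is inter-chain; with
    ``symmetrize_output`` the map is averaged with its transpose, making
    the index swap an exact symmetry. Heterodimer: the top-right L1 x L2
    block of the dimer grid.
    """
    l1, l2 = pred.lengths
    if pred.dimer_kind == "homodimer":
        scores = contact_probability(pred.heavy_atom_probs, threshold)
        if symmetrize_output:
            scores = 0.5 * (scores + scores.T)
    else:
        block = interchain_block(pred.heavy_atom_probs, l1, l2)
        scores = contact_probability(block, threshold)
    return ContactScoreMap(scores=scores, threshold=threshold, dimer_kind=pred.dimer_kind)


def rank_contacts(
    scores: ContactScoreMap, dedupe_symmetric: bool = True
) -> RankedContactList:
    """Descending-score contact list, 1-based indices, ties lexicographic.

    For homodimers with ``dedupe_symmetric``, the (i, j) / (j, i) mirror
    pair collapses to one entry with i <= j carrying the larger score.
    """
    s = scores.scores
    n1, n2 = s.shape
    entries = []
    if scores.dimer_kind == "homodimer" and dedupe_symmetric:
        for i in range(n1):
            for j in range(i, n2):
                entries.append((i + 1, j + 1, float(max(s[i, j], s[j, i]))))
    else:
        for i in range(n1):
            for j in range(n2):
                entries.append((i + 1, j + 1, float(s[i, j])))
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return RankedContactList(entries=entries)


def top_k_size(length: int, divisor: float) -> int:
    """floor(L / divisor), clamped to at least one prediction."""
    return max(1, int(length // divisor))


def confidence_score(ranked: RankedContactList, monomer_length: int) -> float:
    """Mean probability of the top floor(L/5) entries (min 1)."""
    if len(ranked) == 0:
        raise ValueError("empty contact list")
    k = min(top_k_size(monomer_length, 5), len(ranked))
    return float(np.mean([p for _, _, p in ranked.entries[:k]]))
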