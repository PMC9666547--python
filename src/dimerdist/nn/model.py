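"""The inter-chain distogram network.

Input: an (S, S, 186) feature stack (S = L for homodimers, L1 + L2 for
heterodimers). The stack is projected by a 3x3 convolution, compressed by
a Maxout stage (conv to ``groups x filters`` channels, then max within
consecutive groups), passed through a trunk of attention-powered residual
blocks, and classified per cell into 42 distance bins by two independent
softmax heads: one trained on minimum-heavy-atom distances, one on Cb-Cb
distances.

Conv-layer counting convention (exposed so the published "156 convolutional
layers" figure is a checkable quantity): the input projection conv, the
Maxout stage's conv, the two convs of every residual block, and the two
head convs are counted; 1x1 RCIN fusion convs, SE bottleneck weights and
spatial-gate convs are auxiliary and excluded. With B residual blocks the
tally is 4 + 2B, so the 156-layer default uses 76 blocks.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Conv2d, Maxout, Module, ResidualBlock

N_INPUT_CHANNELS = 186
N_BINS = 42


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    total_conv_layers counts convs per the module convention above and must
    satisfy ``(total_conv_layers - 4) % 2 == 0`` with at least one block.
    """

    total_conv_layers: int = 156
    filters: int = 64
    bins: int = N_BINS
    maxout_groups: int = 2
    se_reduction: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.total_conv_layers < 6:
            raise ValueError("total_conv_layers must be >= 6 (one residual block)")
        if (self.total_conv_layers - 4) % 2:
            raise ValueError(
                "total_conv_layers must be 4 + 2*blocks under the counting rule"
            )
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if self.bins != N_BINS:
            warnings.warn(
                f"bins={self.bins} departs from the 42-bin discretization; "
                "published bin edges no longer apply",
                stacklevel=2,
            )

    @property
    def n_blocks(self) -> int:
        return (self.total_conv_layers - 4) // 2


class DistogramNetwork(Module):
    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, g = config.filters, config.maxout_groups
        self.conv_in = Conv2d(N_INPUT_CHANNELS, f, 3, rng, role="input")
        self.maxout_conv = Conv2d(f, f * g, 3, rng, role="maxout")
        self.maxout = Maxout(g)
        self.blocks = [
            ResidualBlock(f, config.se_reduction, rng) for _ in range(config.n_blocks)
        ]
        self.head_heavy = Conv2d(f, config.bins, 3, rng, role="head")
        self.head_cb = Conv2d(f, config.bins, 3, rng, role="head")

    # -- introspection ----------------------------------------------------

    def counted_conv_layers(self):
        """Counted (role, filters) pairs in forward order."""
        layers = [("input", self.conv_in), ("maxout", self.maxout_conv)]
        for i, blk in enumerate(self.blocks):
            layers.append((f"block{i}.conv1", blk.conv1))
            layers.append((f"block{i}.conv2", blk.conv2))
        layers += [("head_heavy", self.head_heavy), ("head_cb", self.head_cb)]
        return [(name, conv.filters) for name, conv in layers if conv.counted]

    @property
    def conv_layer_count(self) -> int:
        return len(self.counted_conv_layers())

    def trunk_filter_counts(self):
        """Output filters of every residual-block conv."""
        return [f for name, f in self.counted_conv_layers() if name.startswith("block")]

    # -- forward ----------------------------------------------------------

    def forward_logits(self, x) -> tuple[Tensor, Tensor]:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 3 or x.shape[-1] != N_INPUT_CHANNELS:
            raise ValueError(
                f"feature shape mismatch: expected (S, S, {N_INPUT_CHANNELS}), "
                f"got {x.shape}"
            )
        h = self.conv_in(x)
        h = self.maxout(self.maxout_conv(h))
        for blk in self.blocks:
            h = blk(h)
        return self.head_heavy(h), self.head_cb(h)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        logits_heavy, logits_cb = self.forward_logits(x)
        return ag.softmax(logits_heavy), ag.softmax(logits_cb)

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            arr = state[name]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {name}: shape {arr.shape} != {p.data.shape}")
            p.data = np.asarray(arr, dtype=np.float32)

    def save(self, path):
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
            ),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "DistogramNetwork":
        with np.load(path) as archive:
            cfg = NetworkConfig(**json.loads(bytes(archive["__config__"]).decode()))
            model = cls(cfg)
            model.load_state_dict(
                {k: archive[k] for k in archive.files if k != "__config__"}
            )
        return model


def build_network(config: NetworkConfig | None = None) -> DistogramNetwork:
    """Construct the network; deterministic given ``config.seed``."""
    return DistogramNetwork(config or NetworkConfig())


def config_from_yaml(path) -> NetworkConfig:
    """Load a NetworkConfig from a YAML mapping (unknown keys rejected)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(NetworkConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return NetworkConfig(**raw)


@dataclasses.dataclass
class DistogramPrediction:
    """Two per-cell probability volumes over the 42 distance bins."""

    heavy_atom_probs: np.ndarray  # (S, S, bins)
    cb_probs: np.ndarray  # (S, S, bins)
    lengths: tuple  # (L1, L2); L1 == L2 == L for homodimers
    dimer_kind: str = "homodimer"

    def __post_init__(self):
        for name in ("heavy_atom_probs", "cb_probs"):
            vol = np.asarray(getattr(self, name), dtype=np.float32)
            if vol.ndim != 3:
                raise ValueError(f"{name} must be (S, S, bins)")
            if (vol < -1e-6).any() or (vol > 1 + 1e-6).any():
                raise ValueError(f"{name} probabilities outside [0, 1]")
            sums = vol.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-5):
                raise ValueError(f"{name} cells must each sum to 1")
            setattr(self, name, vol)
        if self.heavy_atom_probs.shape != self.cb_probs.shape:
            raise ValueError("the two heads must share a shape")

    @property
    def side(self) -> int:
        return self.heavy_atom_probs.shape[0]


def forward(model: DistogramNetwork, stack) -> DistogramPrediction:
    """Inference pass on a FeatureStack: two per-cell softmax volumes."""
    tensor = stack.tensor if hasattr(stack, "tensor") else np.asarray(stack)
    with ag.no_grad():
        probs_heavy, probs_cb = model.forward(tensor)
    lengths = getattr(stack, "lengths", (tensor.shape[0], tensor.shape[0]))
    kind = getattr(stack, "dimer_kind", "homodimer")
    return DistogramPrediction(
        heavy_atom_probs=probs_heavy.data,
        cb_probs=probs_cb.data,
        lengths=tuple(lengths),
        dimer_kind=kind,
    )
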