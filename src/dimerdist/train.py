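"""Distance discretization, inter-chain loss masking, and the training loop.

Distances are classified into 42 half-open bins: [0, 2), forty uniform
0.5-Angstrom bins covering [2, 22), and [22, inf). Only inter-chain cells
contribute to the cross-entropy loss; for a heterodimer these are the two
off-diagonal L1 x L2 blocks of the output grid, while for a homodimer the
whole L x L grid is inter-chain by construction.

The optimizer schedule is two-phase: an adaptive-moment (Adam) phase at
1e-3 for 30 epochs for fast convergence, then plain SGD from 1e-4 with a
ten-fold reduction every 20 epochs for the remaining 50. Batch size is 1,
which also sidesteps padding of variable-size dimers.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .nn import autograd as ag
from .nn.model import DistogramNetwork, DistogramPrediction
from .nn.optim import SGD, Adam

BIN_LOW = 2.0
BIN_HIGH = 22.0
BIN_WIDTH = 0.5
N_BINS = 42


@dataclasses.dataclass(frozen=True)
class DistanceBinning:
    """The 42-bin discretization; ``edges`` are the interior boundaries."""

    low: float = BIN_LOW
    high: float = BIN_HIGH
    width: float = BIN_WIDTH

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.low, self.high + self.width / 2, self.width)

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1  # 42

    def bin_upper_edges(self) -> np.ndarray:
        """Upper edge of each bin; the last bin is unbounded (inf)."""
        return np.concatenate([self.edges, [np.inf]])


def discretize_distance(d) -> np.ndarray | int:
    """Map distances (Angstrom) to bin indices 0..41 (half-open [lo, hi))."""
    arr = np.asarray(d, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("invalid distance")
    bins = np.where(
        arr < BIN_LOW,
        0,
        np.where(
            arr >= BIN_HIGH,
            N_BINS - 1,
            1 + np.floor((arr - BIN_LOW) / BIN_WIDTH),
        ),
    ).astype(int)
    return int(bins) if np.isscalar(d) or np.ndim(d) == 0 else bins


def bin_midpoint(index) -> np.ndarray | float:
    """Representative distance per bin (tail bins clamp to their finite edge)."""
    idx = np.asarray(index)
    mid = np.where(
        idx == 0,
        1.0,
        np.where(idx == N_BINS - 1, BIN_HIGH, BIN_LOW + (idx - 0.5) * BIN_WIDTH),
    )
    return float(mid) if np.ndim(index) == 0 else mid


@dataclasses.dataclass
class LossMask:
    mask: np.ndarray  # boolean; True cells contribute to the loss

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())


def build_interchain_mask(l1: int, l2: int | None = None) -> LossMask:
    """All-true L x L for a homodimer; off-diagonal blocks for a heterodimer."""
    if l2 is None:
        return LossMask(mask=np.ones((l1, l1), dtype=bool))
    side = l1 + l2
    mask = np.zeros((side, side), dtype=bool)
    mask[:l1, l1:] = True
    mask[l1:, :l1] = True
    return LossMask(mask=mask)


def masked_cross_entropy(
    pred: DistogramPrediction,
    true_heavy_bins: np.ndarray,
    true_cb_bins: np.ndarray,
    mask: LossMask,
) -> float:
    """Mean -log p[true bin] over masked cells, summed over the two heads."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty loss support")
    ii, jj = np.nonzero(m)
    total = 0.0
    for probs, bins in (
        (pred.heavy_atom_probs, true_heavy_bins),
        (pred.cb_probs, true_cb_bins),
    ):
        picked = probs[ii, jj, np.asarray(bins)[ii, jj]]
        total += float(-np.log(np.maximum(picked, 1e-30)).mean())
    return total


@dataclasses.dataclass(frozen=True)
class TrainingSchedule:
    """Two-phase schedule: Adam then step-decayed SGD, batch size 1."""

    phase1_epochs: int = 30
    phase1_lr: float = 1e-3
    phase2_epochs: int = 50
    phase2_lr: float = 1e-4
    phase2_decay: float = 0.1
    phase2_decay_every: int = 20
    batch_size: int = 1

    @property
    def total_epochs(self) -> int:
        return self.phase1_epochs + self.phase2_epochs


def lr_at_epoch(schedule: TrainingSchedule, epoch: int) -> tuple[str, float]:
    """(optimizer kind, learning rate) for a 0-based epoch."""
    if epoch < 0 or epoch >= schedule.total_epochs:
        raise ValueError("schedule exhausted")
    if epoch < schedule.phase1_epochs:
        return "adam", schedule.phase1_lr
    steps = (epoch - schedule.phase1_epochs) // schedule.phase2_decay_every
    return "sgd", schedule.phase2_lr * schedule.phase2_decay**steps


@dataclasses.dataclass
class TrainingExample:
    stack: object  # FeatureStack
    heavy_bins: np.ndarray  # (S, S) int labels
    cb_bins: np.ndarray  # (S, S) int labels
    mask: LossMask


def save_example(path, example: TrainingExample):
    from .structio import save_tensors

    save_tensors(
        path,
        {
            "tensor": example.stack.tensor,
            "heavy_bins": example.heavy_bins,
            "cb_bins": example.cb_bins,
            "mask": example.mask.mask,
        },
        {
            "dimer_kind": example.stack.dimer_kind,
            "lengths": list(example.stack.lengths),
        },
    )


def load_example(path) -> TrainingExample:
    from .features import FeatureStack
    from .structio import load_tensors

    arrays, meta = load_tensors(path)
    stack = FeatureStack(
        tensor=arrays["tensor"],
        dimer_kind=meta["dimer_kind"],
        lengths=tuple(meta["lengths"]),
    )
    return TrainingExample(
        stack=stack,
        heavy_bins=arrays["heavy_bins"],
        cb_bins=arrays["cb_bins"],
        mask=LossMask(mask=arrays["mask"]),
    )


def _example_loss(model: DistogramNetwork, ex: TrainingExample):
    logits_heavy, logits_cb = model.forward_logits(ex.stack.tensor)
    loss = ag.masked_softmax_cross_entropy(logits_heavy, ex.heavy_bins, ex.mask.mask)
    loss = loss + ag.masked_softmax_cross_entropy(logits_cb, ex.cb_bins, ex.mask.mask)
    return loss


def train_loop(
    model: DistogramNetwork,
    dataset: list,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    epochs: int | None = None,
    checkpoint_dir=None,
    verbose: bool = False,
) -> list:
    """Batch-size-1 training over ``dataset`` (TrainingExample list).

    Deterministic given ``seed`` (example order is reshuffled per epoch from
    a seeded generator). Returns the per-epoch mean loss trace; aborts with
    a diagnostic if the loss diverges to NaN. ``epochs`` truncates the
    schedule for desk-scale runs; optimizer kind and learning rate still
    follow ``lr_at_epoch``.
    """
    schedule = schedule or TrainingSchedule()
    n_epochs = schedule.total_epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    params = list(model.parameters())
    optimizer = None
    current = (None, None)
    trace = []
    for epoch in range(n_epochs):
        kind, lr = lr_at_epoch(schedule, epoch)
        if (kind, lr) != current:
            optimizer = Adam(params, lr=lr) if kind == "adam" else SGD(params, lr=lr)
            current = (kind, lr)
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for idx in order:
            optimizer.zero_grad()
            loss = _example_loss(model, dataset[idx])
            value = float(loss.data)
            if math.isnan(value) or math.isinf(value):
                raise FloatingPointError(
                    f"divergent loss ({value}) at epoch {epoch}, example {idx}"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += value
        trace.append(epoch_loss / max(len(dataset), 1))
        if verbose:
            print(f"epoch {epoch:3d}  {kind}  lr={lr:.1e}  loss={trace[-1]:.4f}")
        if checkpoint_dir is not None:
            from pathlib import Path

            path = Path(checkpoint_dir)
            path.mkdir(parents=True, exist_ok=True)
            model.save(path / f"epoch_{epoch:03d}.npz")
    return trace
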