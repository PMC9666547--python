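"""Ground-truth contact extraction and evaluation statistics.

A pair of inter-chain residues is a true contact when the minimum distance
over all heavy-atom pairs is strictly below 8 Angstrom. Reported metrics:
precision of the top 5 / 10 / L/10 / L/5 / L/2 / L predictions, accuracy
order (permil rank of the first correct prediction over the dimer's
residue count; lower is better), accuracy rate (percent of dimers with a
correct prediction in the top 10), and the rank-based ROC AUC over all
inter-chain pairs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .infer import ContactScoreMap, top_k_size
from .structio import MonomerStructure, RankedContactList

CONTACT_THRESHOLD = 8.0

PRECISION_KEYS = ("top5", "top10", "L/10", "L/5", "L/2", "L")


@dataclasses.dataclass
class ContactGroundTruth:
    min_heavy_distances: np.ndarray  # (L1, L2) Angstrom
    threshold: float = CONTACT_THRESHOLD

    def __post_init__(self):
        d = np.asarray(self.min_heavy_distances, dtype=float)
        if d.ndim != 2 or (d <= 0).any():
            raise ValueError("distances must be a positive (L1, L2) matrix")
        self.min_heavy_distances = d

    @property
    def contacts(self) -> np.ndarray:
        return self.min_heavy_distances < self.threshold

    @property
    def n_true_contacts(self) -> int:
        return int(self.contacts.sum())

    def is_contact(self, i: int, j: int) -> bool:
        """1-based residue indices, chain A then chain B."""
        return bool(self.contacts[i - 1, j - 1])


@dataclasses.dataclass
class EvaluationReport:
    precision_at: dict  # PRECISION_KEYS -> fraction
    accuracy_order_permil: float  # NaN when no prediction is correct
    auc: float
    n_true_contacts: int
    confidence: float | None = None


def true_contacts(
    structure_a: MonomerStructure,
    structure_b: MonomerStructure,
    threshold: float = CONTACT_THRESHOLD,
) -> ContactGroundTruth:
    """Minimum heavy-atom pair distance per residue pair; contact iff < threshold."""
    coords = [r.heavy_coords() for r in structure_b.residues]
    dmat = np.empty((len(structure_a), len(structure_b)))
    for i, res_a in enumerate(structure_a.residues):
        ca = res_a.heavy_coords()
        for j, cb in enumerate(coords):
            dmat[i, j] = cdist(ca, cb).min()
    return ContactGroundTruth(min_heavy_distances=dmat, threshold=threshold)


def precision_at_k(
    ranked: RankedContactList, truth: ContactGroundTruth, k: int
) -> float:
    """Fraction of the top-k predictions that are true contacts (k clipped)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top = ranked.entries[: min(k, len(ranked))]
    if not top:
        return 0.0
    return sum(truth.is_contact(i, j) for i, j, _ in top) / len(top)


def accuracy_order(
    ranked: RankedContactList, truth: ContactGroundTruth, total_dimer_residues: int
) -> float:
    """Permil rank of the first correct prediction over L1 + L2.

    Returns NaN when no prediction is correct; set-level means exclude
    such dimers (their count is reported separately).
    """
    if total_dimer_residues < 1:
        raise ValueError("total_dimer_residues must be >= 1")
    for rank, (i, j, _) in enumerate(ranked.entries, start=1):
        if truth.is_contact(i, j):
            return 1000.0 * rank / total_dimer_residues
    return math.nan


def accuracy_rate(per_dimer: list) -> float:
    """Percent of dimers with >= 1 correct prediction among their top 10."""
    if not per_dimer:
        raise ValueError("need at least one dimer")
    hits = sum(
        any(truth.is_contact(i, j) for i, j, _ in ranked.entries[:10])
        for ranked, truth in per_dimer
    )
    return 100.0 * hits / len(per_dimer)


def contact_auc(scores: ContactScoreMap, truth: ContactGroundTruth) -> float:
    """Rank-based ROC AUC (Mann-Whitney; ties count half) over all pairs."""
    y = truth.contacts.ravel()
    if y.all() or not y.any():
        raise ValueError("undefined AUC: truth needs positives and negatives")
    return float(roc_auc_score(y, scores.scores.ravel()))


def _dedupe_truth(truth: ContactGroundTruth) -> ContactGroundTruth:
    """Fold a homodimer truth matrix onto i <= j (min distance of mirrors)."""
    d = np.minimum(truth.min_heavy_distances, truth.min_heavy_distances.T)
    return ContactGroundTruth(min_heavy_distances=d, threshold=truth.threshold)


def evaluate_dimer(
    ranked: RankedContactList,
    truth: ContactGroundTruth,
    scores: ContactScoreMap,
    monomer_length: int,
    total_dimer_residues: int,
    deduped_homodimer: bool = False,
) -> EvaluationReport:
    """Full per-dimer report. ``monomer_length`` is L for homodimers or the
    shorter chain Ls for heterodimers; ``deduped_homodimer`` folds the truth
    to i <= j so it matches a mirror-deduplicated ranking."""
    truth_for_list = _dedupe_truth(truth) if deduped_homodimer else truth
    precision = {}
    for key in PRECISION_KEYS:
        if key == "top5":
            k = 5
        elif key == "top10":
            k = 10
        else:
            k = top_k_size(monomer_length, float(key.split("/")[1]) if "/" in key else 1)
        precision[key] = precision_at_k(ranked, truth_for_list, k)
    return EvaluationReport(
        precision_at=precision,
        accuracy_order_permil=accuracy_order(ranked, truth_for_list, total_dimer_residues),
        auc=contact_auc(scores, truth),
        n_true_contacts=truth.n_true_contacts,
    )
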