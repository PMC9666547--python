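"""Heterodimer MSA pairing and alignment-depth (Neff) diagnostics.

Two pairing strategies are provided, mirroring the two stages of the
co-evolution feature pipeline: organism-taxonomy matching (FoldDock-style,
used when building training alignments) and per-species best-identity
matching (EvComplex2-style, used at prediction time). With a single
candidate per species the two coincide; they differ only in how multiple
candidate rows within one species are resolved, and both resolve by the
highest sequence identity to the query, ties to the earlier row.

Sequence identity is computed over query-aligned columns with gaps counted
as mismatches. Neff down-weights each row by the size of its 80%-identity
neighbourhood, the community convention for MSA depth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structio import MsaRow, MultipleSequenceAlignment


@dataclasses.dataclass
class PairedMSA:
    rows: list  # MsaRow, width L1 + L2; row 0 is the concatenated query
    provenance: list  # (row index in MSA A, row index in MSA B) per row
    pairing_method: str  # "taxonomy" | "identity"

    def __len__(self) -> int:
        return len(self.rows)

    def to_alignment(self) -> MultipleSequenceAlignment:
        return MultipleSequenceAlignment(rows=list(self.rows))


def sequence_identity(seq: str, ref: str) -> float:
    """Fraction of identical non-gap-in-ref columns; gaps in seq mismatch."""
    cols = [(a, b) for a, b in zip(seq, ref) if b != "-"]
    if not cols:
        return 0.0
    return sum(a == b for a, b in cols) / len(cols)


def _best_rows_per_tag(msa: MultipleSequenceAlignment) -> dict:
    """tag -> (row index, identity) of the highest-identity row; first wins ties."""
    best = {}
    for i, row in enumerate(msa.rows[1:], start=1):
        if row.organism_tag is None:
            continue
        ident = sequence_identity(row.sequence, msa.query)
        tag = row.organism_tag
        if tag not in best or ident > best[tag][1]:
            best[tag] = (i, ident)
    return best


def _pair(
    msa_a: MultipleSequenceAlignment,
    msa_b: MultipleSequenceAlignment,
    method: str,
) -> PairedMSA:
    best_a = _best_rows_per_tag(msa_a)
    best_b = _best_rows_per_tag(msa_b)
    rows = [
        MsaRow(sequence=msa_a.query + msa_b.query, source_id="query_pair")
    ]
    provenance = [(0, 0)]
    shared = sorted(set(best_a) & set(best_b))
    for tag in shared:
        ia, ib = best_a[tag][0], best_b[tag][0]
        rows.append(
            MsaRow(
                sequence=msa_a.rows[ia].sequence + msa_b.rows[ib].sequence,
                source_id=f"{msa_a.rows[ia].source_id}|{msa_b.rows[ib].source_id}",
                organism_tag=tag,
            )
        )
        provenance.append((ia, ib))
    return PairedMSA(rows=rows, provenance=provenance, pairing_method=method)


def pair_by_taxonomy(
    msa_a: MultipleSequenceAlignment, msa_b: MultipleSequenceAlignment
) -> PairedMSA:
    """One concatenated row per organism tag present in both alignments.

    Within a tag the row most identical to its query is chosen on each side.
    Untagged rows never pair; no shared tags leaves only the query pair.
    """
    return _pair(msa_a, msa_b, "taxonomy")


def pair_by_top_identity(
    msa_a: MultipleSequenceAlignment, msa_b: MultipleSequenceAlignment
) -> PairedMSA:
    """Per species, concatenate the single best-identity row from each side."""
    return _pair(msa_a, msa_b, "identity")


def write_provenance(paired: PairedMSA) -> str:
    """Tab-separated sidecar mapping paired rows to their source rows."""
    lines = ["row\tsource_a\tsource_b\tmethod"]
    for k, (ia, ib) in enumerate(paired.provenance):
        lines.append(f"{k}\t{ia}\t{ib}\t{paired.pairing_method}")
    return "\n".join(lines) + "\n"


def compute_neff(
    msa: MultipleSequenceAlignment, identity_threshold: float = 0.8
) -> float:
    """Effective sequence count: sum over rows of 1 / (cluster size), where a
    row's cluster is every row within ``identity_threshold`` pairwise identity.

    Pairwise identity here is the fraction of matching characters over the
    columns where the query is not a gap (gap-residue pairs mismatch).
    """
    cols = [k for k, c in enumerate(msa.query) if c != "-"]
    seqs = [[row.sequence[k] for k in cols] for row in msa.rows]
    n = len(seqs)
    if n == 1:
        return 1.0
    mat = np.array([[ord(c) for c in s] for s in seqs], dtype=np.int16)
    ident = (mat[:, None, :] == mat[None, :, :]).mean(axis=2)
    cluster_sizes = (ident >= identity_threshold).sum(axis=1)
    return float((1.0 / cluster_sizes).sum())
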