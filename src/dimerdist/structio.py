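"""Readers and writers for the formats the pipeline touches.

PDB monomer structures (via Bio.PDB), A3M/FASTA alignments, PSI-BLAST
ASCII PSSMs, ranked contact lists in a CASP-RR-like layout, and a named
tensor archive for precomputed co-evolution features.

Serialized indices are 1-based (PDB / CASP convention); in-memory arrays
are 0-based, with the conversion confined to this module. Residues are
indexed by order of appearance in the chain, so structures with gaps in
author numbering still map onto a dense 0..L-1 axis.
"""

from __future__ import annotations

import dataclasses
import io
import json
import re
import warnings

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

# PSI-BLAST PSSM column order
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Residue:
    index: int  # 1-based, dense, by order of appearance
    amino_acid: str  # one-letter code
    atoms: dict  # atom name -> (3,) float array, heavy atoms only
    author_id: str = ""  # original PDB resseq+icode, for provenance

    def heavy_coords(self) -> np.ndarray:
        return np.array(list(self.atoms.values()), dtype=float)

    def reference_coord(self) -> np.ndarray:
        """Cb coordinate, falling back to Ca (glycine convention)."""
        if "CB" in self.atoms:
            return self.atoms["CB"]
        if "CA" in self.atoms:
            return self.atoms["CA"]
        raise ValueError(f"no reference atom for residue {self.index}")


@dataclasses.dataclass
class MonomerStructure:
    chain_id: str
    residues: list

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty structure")
        indices = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("residue indices must be strictly increasing")
        if any(not r.atoms for r in self.residues):
            raise ValueError("every residue needs at least one heavy atom")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)


@dataclasses.dataclass
class MsaRow:
    sequence: str
    source_id: str = ""
    organism_tag: str | None = None


@dataclasses.dataclass
class MultipleSequenceAlignment:
    rows: list

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        widths = {len(r.sequence) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("ragged alignment")

    @property
    def query(self) -> str:
        return self.rows[0].sequence

    @property
    def ncol(self) -> int:
        return len(self.rows[0].sequence)

    def __len__(self) -> int:
        return len(self.rows)


@dataclasses.dataclass
class PositionSpecificScoringMatrix:
    scores: np.ndarray  # (L, 20) log-odds in PSSM_ALPHABET order

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM must be L x 20")
        if not np.isfinite(self.scores).all():
            raise ValueError("PSSM contains non-finite values")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclasses.dataclass
class RankedContactList:
    entries: list  # (residue_i, residue_j, probability), 1-based indices

    def __post_init__(self):
        probs = [p for _, _, p in self.entries]
        if any(b > a for a, b in zip(probs, probs[1:])):
            raise ValueError("entries must be sorted by non-increasing probability")
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must be within [0, 1]")

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------


def _pick_altloc(atom):
    """Resolve a possibly disordered atom: highest occupancy, first wins ties."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    best = children[0]
    for child in children[1:]:
        if (child.get_occupancy() or 0.0) > (best.get_occupancy() or 0.0):
            best = child
    return best


def read_structure(pdb_text: str, chain_id: str) -> MonomerStructure:
    """Parse one chain from PDB text into a MonomerStructure.

    Hydrogens (and deuterium) are dropped; altlocs resolve to the highest
    occupancy; HETATM residues (waters, ligands) are skipped; residues are
    re-indexed densely in order of appearance, insertion codes included.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sparse toy records
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("x", io.StringIO(pdb_text))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain not found: {chain_id!r}")
    residues = []
    for res in model[chain_id]:
        hetflag, resseq, icode = res.get_id()
        if hetflag.strip():
            continue
        atoms = {}
        for atom in res.get_unpacked_list():
            atom = _pick_altloc(atom)
            element = (atom.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            if atom.get_name() not in atoms:  # first altloc occurrence wins
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        if atoms:
            residues.append(
                Residue(
                    index=len(residues) + 1,
                    amino_acid=seq1(res.get_resname()),
                    atoms=atoms,
                    author_id=f"{resseq}{icode.strip()}",
                )
            )
    if not residues:
        raise ValueError("empty structure")
    return MonomerStructure(chain_id=chain_id, residues=residues)


def write_structure(structure: MonomerStructure) -> str:
    """Serialize a MonomerStructure as minimal PDB ATOM records."""
    from Bio.SeqUtils import seq3

    lines = []
    serial = 0
    for res in structure.residues:
        resname = seq3(res.amino_acid).upper()
        for name, xyz in res.atoms.items():
            serial += 1
            element = name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} "
                f"{structure.chain_id:1s}{res.index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# A3M / FASTA alignments
# ---------------------------------------------------------------------------

_OX_RE = re.compile(r"\bOX=(\d+)")
_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


def _organism_tag(header: str) -> str | None:
    m = _OX_RE.search(header)
    if m:
        return m.group(1)
    m = _BRACKET_RE.search(header)
    if m:
        return m.group(1).strip()
    return None


def read_msa(a3m_text: str) -> MultipleSequenceAlignment:
    """Parse A3M/FASTA text; the first sequence is the query.

    Lowercase letters and '.' mark insertion states relative to the query
    and are removed (A3M convention). Organism tags are taken from a
    UniProt ``OX=`` field or a trailing bracketed binomial when present.
    """
    rows = []
    header, chunks = None, []

    def flush():
        if header is None and not chunks:
            return
        seq = "".join(chunks)
        seq = "".join(c for c in seq if not (c.islower() or c == "."))
        rows.append(
            MsaRow(
                sequence=seq,
                source_id=(header or "").split()[0] if header else "",
                organism_tag=_organism_tag(header or ""),
            )
        )

    for line in a3m_text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            header, chunks = line[1:], []
        else:
            chunks.append(line)
    flush()
    if not rows:
        raise ValueError("empty alignment")
    return MultipleSequenceAlignment(rows=rows)


def write_msa(msa: MultipleSequenceAlignment) -> str:
    out = []
    for i, row in enumerate(msa.rows):
        header = row.source_id or f"seq{i}"
        if row.organism_tag and "OX=" not in header:
            header += f" OX={row.organism_tag}"
        out.append(f">{header}\n{row.sequence}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PSI-BLAST PSSM
# ---------------------------------------------------------------------------


def read_pssm(psiblast_text: str) -> PositionSpecificScoringMatrix:
    """Parse a PSI-BLAST ASCII PSSM (position, residue, 20 log-odds columns).

    Trailing weighted-percentage and information-content columns, when
    present, are ignored.
    """
    rows = []
    for line in psiblast_text.splitlines():
        tokens = line.split()
        if len(tokens) < 22:
            continue
        if not tokens[0].isdigit():
            continue
        if len(tokens[1]) != 1 or not tokens[1].isalpha():
            continue
        try:
            rows.append([float(t) for t in tokens[2:22]])
        except ValueError:
            raise ValueError("malformed PSSM") from None
    if not rows:
        raise ValueError("malformed PSSM")
    return PositionSpecificScoringMatrix(scores=np.array(rows))


def write_pssm(pssm: PositionSpecificScoringMatrix, sequence: str | None = None) -> str:
    header = "    " + "   ".join(PSSM_ALPHABET)
    lines = ["", header]
    for i, row in enumerate(pssm.scores):
        aa = sequence[i] if sequence else "X"
        lines.append(f"{i + 1:5d} {aa} " + " ".join(f"{int(round(v)):3d}" for v in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ranked contact lists (CASP-RR-like)
# ---------------------------------------------------------------------------

_RR_HEADER = "PFRMAT RR"


def write_contact_list(contacts: RankedContactList) -> str:
    """Serialize as 'i j 0 8 prob' lines, descending probability."""
    lines = [_RR_HEADER]
    for i, j, p in contacts.entries:
        lines.append(f"{i} {j} 0 8 {p:.6f}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_contact_list(text: str) -> RankedContactList:
    entries = []
    for line in text.splitlines():
        tokens = line.split()
        if len(tokens) == 5 and tokens[0].isdigit():
            entries.append((int(tokens[0]), int(tokens[1]), float(tokens[4])))
    return RankedContactList(entries=entries)


# ---------------------------------------------------------------------------
# tensor archives
# ---------------------------------------------------------------------------


def save_tensors(path, arrays: dict, metadata: dict | None = None):
    """Named-array archive with a JSON metadata record (shapes self-describe)."""
    meta = json.dumps(metadata or {})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_tensors(path) -> tuple[dict, dict]:
    with np.load(path) as archive:
        meta = (
            json.loads(bytes(archive["__meta__"]).decode())
            if "__meta__" in archive.files
            else {}
        )
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    return arrays, meta
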