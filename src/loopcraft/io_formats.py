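"""Readers and writers for the external formats the tool consumes and emits.

FASTA, aligned FASTA and Clustal go through Biopython; the plate CSV goes
through pandas.  PDB B-factor extraction uses Bio.PDB with the altloc /
HETATM / insertion-code policy enforced on top.  No science lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ResidueLookupError

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
#: residues legal on read; generators reject X
AA_READ = AA20 | {"X"}
NT4 = set("ACGT")

__all__ = [
    "AA20",
    "ProteinRecord",
    "AlignmentRecord",
    "ResidueBFactors",
    "read_fasta",
    "write_fasta",
    "read_nt_fasta",
    "read_alignment",
    "write_alignment",
    "read_pdb_bfactors",
    "read_screening_csv",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an explicit residue-numbering origin.

    ``numbering_offset`` is the residue number of the first sequence
    character (1 for a full-length chain), so positions quoted in the
    field's usual 1-based convention (e.g. G236, F278) resolve without
    bookkeeping at call sites.
    """

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_READ
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)}"
            )
        if self.numbering_offset < 1:
            raise FormatError(f"record {self.id!r}: numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first_residue(self) -> int:
        return self.numbering_offset

    @property
    def last_residue(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    def index_of(self, residue_number: int) -> int:
        """0-based string index of a 1-based residue number."""
        i = residue_number - self.numbering_offset
        if not 0 <= i < len(self.sequence):
            raise ResidueLookupError(
                f"residue {residue_number} outside {self.id!r} "
                f"({self.first_residue}..{self.last_residue})"
            )
        return i

    def residue_at(self, residue_number: int) -> str:
        return self.sequence[self.index_of(residue_number)]


@dataclass(frozen=True)
class AlignmentRecord:
    """A gapped multiple sequence alignment ('-' is the only gap character)."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            ragged = [rid for rid, s in self.records if len(s) != len(self.records[0][1])]
            raise FormatError(f"ragged alignment rows: {ragged}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise ResidueLookupError(
            f"id {record_id!r} not in alignment (rows: {self.ids})"
        )

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.records)


@dataclass
class ResidueBFactors:
    """Per-residue, per-atom crystallographic B-factors for one chain."""

    chain_id: str
    residues: dict[int, list[tuple[str, float]]] = field(default_factory=dict)

    def atoms(self, residue_number: int) -> list[tuple[str, float]]:
        if residue_number not in self.residues:
            raise ResidueLookupError(
                f"residue {residue_number} not in chain {self.chain_id!r}"
            )
        return self.residues[residue_number]


# ---------------------------------------------------------------------------
# FASTA


def _clean(seq: str, record_id: str, alphabet: set[str]) -> str:
    s = "".join(seq.split()).upper()
    if not s:
        raise FormatError(f"record {record_id!r}: empty sequence")
    bad = set(s) - alphabet
    if bad:
        raise FormatError(
            f"record {record_id!r}: illegal characters {sorted(bad)}"
        )
    return s


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; sequences are uppercased and whitespace-stripped."""
    records = [
        ProteinRecord(id=r.id, sequence=_clean(str(r.seq), r.id, AA_READ))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_nt_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read nucleotide FASTA as (id, sequence) pairs (A/C/G/T only)."""
    out = [
        (r.id, _clean(str(r.seq), r.id, NT4)) for r in SeqIO.parse(str(path), "fasta")
    ]
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(path: str | Path, records: Iterable[ProteinRecord | tuple[str, str]]) -> None:
    seqrecs = []
    for r in records:
        if isinstance(r, ProteinRecord):
            rid, seq = r.id, r.sequence
        else:
            rid, seq = r
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignments


def read_alignment(path: str | Path, dialect: str = "fasta") -> AlignmentRecord:
    """Read an MSA in aligned-FASTA or Clustal format.

    Gap characters ('.', '-') are normalised to '-'.  Ragged rows raise a
    :class:`FormatError` naming the offending row.
    """
    if dialect not in {"fasta", "clustal"}:
        raise ValueError(f"dialect must be 'fasta' or 'clustal', got {dialect!r}")
    try:
        msa = AlignIO.read(str(path), dialect)
    except ValueError as exc:  # Biopython's ragged/ill-formed message
        raise FormatError(f"{path}: {exc}") from exc
    rows = tuple(
        (r.id, str(r.seq).upper().replace(".", "-")) for r in msa
    )
    return AlignmentRecord(records=rows)


def write_alignment(path: str | Path, alignment: AlignmentRecord, dialect: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment

    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment.records
    )
    AlignIO.write(msa, str(path), dialect)


# ---------------------------------------------------------------------------
# PDB B-factors


def read_pdb_bfactors(path: str | Path, chain: str) -> ResidueBFactors:
    """Extract per-atom B-factors for one chain from a PDB file.

    HETATM records are excluded.  For altloc'd atoms the highest-occupancy
    location is kept (ties: first encountered).  Residues with insertion
    codes are rejected — the numbering convention here is plain integers.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id for c in model}
    if chain not in chains:
        raise ResidueLookupError(
            f"chain {chain!r} not found; available chains: {sorted(chains)}"
        )
    out = ResidueBFactors(chain_id=chain)
    for residue in model[chain]:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue  # water / ligand
        if icode.strip():
            raise FormatError(
                f"residue {resseq}{icode.strip()} in chain {chain!r}: "
                "insertion codes are not supported"
            )
        atoms: list[tuple[str, float]] = []
        for atom in residue:
            if atom.is_disordered():
                best = max(
                    atom.disordered_get_list(),
                    key=lambda a: (a.get_occupancy() or 0.0),
                )
                atoms.append((best.get_name(), float(best.get_bfactor())))
            else:
                atoms.append((atom.get_name(), float(atom.get_bfactor())))
        for name, b in atoms:
            if not (b >= 0.0):
                raise FormatError(
                    f"residue {resseq} atom {name}: B-factor {b} is not finite/non-negative"
                )
        if atoms:
            out.residues[resseq] = atoms
    return out


# ---------------------------------------------------------------------------
# Screening plate CSV

_ALLOWED_ROLES = ("variant", "wildtype", "empty_vector")
_REQUIRED_COLS = {"well", "sample_role", "analyte", "peak_area"}


def read_screening_csv(path: str | Path, internal_standard: str = "biphenyl"):
    """Read a long-format plate table (one row per well x analyte).

    Every well must carry a row for the internal-standard analyte.  Returns
    a :class:`loopcraft.screening.ScreeningTable`; calibration and reaction
    parameters are attached by the caller.
    """
    from .screening import ScreeningTable, Well

    df = pd.read_csv(path, dtype={"well": str})
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad_roles = set(df["sample_role"].unique()) - set(_ALLOWED_ROLES)
    if bad_roles:
        raise FormatError(
            f"{path}: illegal sample_role values {sorted(bad_roles)}; "
            f"allowed: {list(_ALLOWED_ROLES)}"
        )
    wells: list[Well] = []
    for well_id, grp in df.groupby("well", sort=False):
        roles = grp["sample_role"].unique()
        if len(roles) != 1:
            raise FormatError(f"{path}: well {well_id} has conflicting roles {list(roles)}")
        areas = dict(zip(grp["analyte"], grp["peak_area"].astype(float)))
        if internal_standard not in areas:
            raise FormatError(
                f"{path}: well {well_id} lacks internal-standard analyte "
                f"{internal_standard!r}"
            )
        name = None
        if "variant_name" in grp.columns:
            vals = grp["variant_name"].dropna().unique()
            if len(vals) == 1:
                name = str(vals[0])
        wells.append(Well(well_id=str(well_id), role=str(roles[0]), variant_name=name, areas=areas))
    if not wells:
        raise FormatError(f"{path}: no wells found")
    return ScreeningTable(wells=wells, internal_standard=internal_standard)
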