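"""The variant data model: single edits on a protein and their systematic names.

Names follow the den Dunnen & Antonarakis protein conventions as used in
the loop-engineering literature, without the strict-HGVS "p." prefix:

* substitution        ``F282A``
* single deletion     ``A283del``
* multi deletion      ``F282_L284del``
* insertion           ``Q286_A287insGSGSG`` (anchored between two residues)

Positions always refer to the unmodified reference; libraries are sets of
single independent edits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from Bio.Seq import Seq

from .errors import DesignError, ValidationError
from .io_formats import AA20, ProteinRecord

__all__ = [
    "Variant",
    "VariantLibrary",
    "substitution",
    "deletion",
    "insertion",
    "name_variant",
    "parse_variant_name",
    "apply_variant",
    "apply_variant_cds",
    "cds_edit",
    "translate_cds",
    "PREFERRED_CODONS_ECOLI",
]

Kind = Literal["substitution", "deletion", "insertion"]

#: Most-frequent codon per amino acid in highly expressed E. coli genes
#: (class II); used to encode inserted/substituted residues.
PREFERRED_CODONS_ECOLI: dict[str, str] = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATC",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}


@dataclass(frozen=True)
class Variant:
    """A single substitution, deletion or insertion on a reference protein.

    * substitution: ``start == end``, ``ref`` the wild-type residue,
      ``alt`` the new residue.
    * deletion: residues ``start..end`` (1-based inclusive) removed;
      ``ref`` holds the deleted residues.
    * insertion: ``start`` is the left anchor, ``end == start + 1`` the
      right anchor, ``alt`` the inserted residue string.
    """

    kind: Kind
    start: int
    end: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.start != self.end or len(self.ref) != 1 or len(self.alt) != 1:
                raise ValidationError(f"malformed substitution: {self!r}")
        elif self.kind == "deletion":
            if self.start > self.end or len(self.ref) != self.end - self.start + 1:
                raise ValidationError(f"malformed deletion: {self!r}")
        elif self.kind == "insertion":
            if self.end != self.start + 1 or not self.alt:
                raise ValidationError(f"malformed insertion: {self!r}")
        else:
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        for residues in (self.ref, self.alt):
            bad = set(residues) - AA20
            if bad:
                raise ValidationError(
                    f"{self!r}: illegal residues {sorted(bad)}"
                )

    @property
    def name(self) -> str:
        return name_variant(self)

    def validate(self, reference: ProteinRecord) -> None:
        """Check the stated reference residues against the actual sequence."""
        if self.kind == "substitution":
            found = reference.residue_at(self.start)
            if found != self.ref:
                raise ValidationError(
                    f"{self.name}: expected {self.ref} at {self.start}, "
                    f"reference has {found}"
                )
        elif self.kind == "deletion":
            for pos, want in zip(range(self.start, self.end + 1), self.ref):
                found = reference.residue_at(pos)
                if found != want:
                    raise ValidationError(
                        f"{self.name}: expected {want} at {pos}, reference has {found}"
                    )
        else:  # insertion: both anchors must exist
            if self.kind == "insertion" and len(self.ref) == 2:
                for pos, want in ((self.start, self.ref[0]), (self.end, self.ref[1])):
                    found = reference.residue_at(pos)
                    if found != want:
                        raise ValidationError(
                            f"{self.name}: expected {want} at {pos}, "
                            f"reference has {found}"
                        )
            else:
                reference.index_of(self.start)
                reference.index_of(self.end)


def substitution(reference: ProteinRecord, position: int, alt: str) -> Variant:
    ref = reference.residue_at(position)
    v = Variant("substitution", position, position, ref=ref, alt=alt)
    if ref == alt:
        raise ValidationError(f"{v.name}: substitution equals wild type")
    return v


def deletion(reference: ProteinRecord, start: int, end: int) -> Variant:
    ref = "".join(reference.residue_at(p) for p in range(start, end + 1))
    return Variant("deletion", start, end, ref=ref)


def insertion(reference: ProteinRecord, after: int, inserted: str) -> Variant:
    """Insertion anchored between residue ``after`` and ``after + 1``.

    Terminal insertions are rejected: the naming grammar needs two
    framing residues.
    """
    if after >= reference.last_residue:
        raise ValidationError(
            f"insertion after {after}: no right anchor within the reference"
        )
    ref = reference.residue_at(after) + reference.residue_at(after + 1)
    return Variant("insertion", after, after + 1, ref=ref, alt=inserted)


# ---------------------------------------------------------------------------
# Naming


def name_variant(variant: Variant) -> str:
    v = variant
    if v.kind == "substitution":
        return f"{v.ref}{v.start}{v.alt}"
    if v.kind == "deletion":
        if v.start == v.end:
            return f"{v.ref}{v.start}del"
        return f"{v.ref[0]}{v.start}_{v.ref[-1]}{v.end}del"
    # insertion; ref carries the two anchor residues when constructed
    left = v.ref[0] if len(v.ref) == 2 else "?"
    right = v.ref[1] if len(v.ref) == 2 else "?"
    return f"{left}{v.start}_{right}{v.end}ins{v.alt}"


_AA = "[ACDEFGHIKLMNPQRSTVWY]"
_RE_SUB = re.compile(rf"^({_AA})(\d+)({_AA})$")
_RE_DEL1 = re.compile(rf"^({_AA})(\d+)del$")
_RE_DELN = re.compile(rf"^({_AA})(\d+)_({_AA})(\d+)del$")
_RE_INS = re.compile(rf"^({_AA})(\d+)_({_AA})(\d+)ins({_AA}+)$")


def parse_variant_name(name: str, reference: ProteinRecord) -> Variant:
    """Parse a systematic variant name and validate it against the reference.

    Round-trips with :func:`name_variant`.  An optional strict-HGVS "p."
    prefix is accepted and stripped.
    """
    raw = name
    if name.startswith("p."):
        name = name[2:]
    if m := _RE_INS.match(name):
        l_aa, l_pos, r_aa, r_pos, ins = m.groups()
        if int(r_pos) != int(l_pos) + 1:
            raise ValidationError(
                f"{raw}: insertion anchors must be adjacent "
                f"({l_pos} and {r_pos} are not)"
            )
        v = Variant("insertion", int(l_pos), int(r_pos), ref=l_aa + r_aa, alt=ins)
    elif m := _RE_DELN.match(name):
        s_aa, s_pos, e_aa, e_pos, = m.groups()
        start, end = int(s_pos), int(e_pos)
        if start >= end:
            raise ValidationError(f"{raw}: deletion start must precede end")
        ref = "".join(reference.residue_at(p) for p in range(start, end + 1))
        if ref[0] != s_aa or ref[-1] != e_aa:
            raise ValidationError(
                f"{raw}: expected {reference.residue_at(start)}{start} and "
                f"{reference.residue_at(end)}{end}, found {s_aa}/{e_aa}"
            )
        v = Variant("deletion", start, end, ref=ref)
    elif m := _RE_DEL1.match(name):
        aa, pos = m.groups()
        v = Variant("deletion", int(pos), int(pos), ref=aa)
    elif m := _RE_SUB.match(name):
        ref, pos, alt = m.groups()
        if ref == alt:
            raise ValidationError(f"{raw}: substitution equals wild type")
        v = Variant("substitution", int(pos), int(pos), ref=ref, alt=alt)
    else:
        raise ValidationError(f"{raw}: does not match any variant-name grammar")
    v.validate(reference)
    return v


# ---------------------------------------------------------------------------
# Applying edits


def apply_variant(reference: ProteinRecord, variant: Variant) -> str:
    """Return the mutated protein sequence (plain string)."""
    variant.validate(reference)
    seq = reference.sequence
    if variant.kind == "substitution":
        i = reference.index_of(variant.start)
        return seq[:i] + variant.alt + seq[i + 1 :]
    if variant.kind == "deletion":
        i = reference.index_of(variant.start)
        j = reference.index_of(variant.end)
        return seq[:i] + seq[j + 1 :]
    i = reference.index_of(variant.start)
    return seq[: i + 1] + variant.alt + seq[i + 1 :]


def translate_cds(cds: str, codon_table: str | int = "Standard") -> str:
    """Translate a CDS (drops one trailing stop if present)."""
    if len(cds) % 3:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate(table=codon_table))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValidationError("internal stop codon in CDS")
    return prot


def _check_cds_matches(cds: str, reference: ProteinRecord, codon_table: str | int) -> str:
    prot = translate_cds(cds, codon_table)
    if prot != reference.sequence:
        for k, (a, b) in enumerate(zip(prot, reference.sequence)):
            if a != b:
                raise ValidationError(
                    f"CDS/protein mismatch at codon {k + reference.numbering_offset}: "
                    f"CDS encodes {a}, reference has {b}"
                )
        raise ValidationError(
            f"CDS encodes {len(prot)} residues, reference has {len(reference.sequence)}"
        )
    return prot


@dataclass(frozen=True)
class CdsEdit:
    """A codon-level edit: replace ``cds[start:start+len(deleted)]`` with
    ``inserted`` (both on the coding strand, 0-based)."""

    start: int
    deleted: str
    inserted: str

    @property
    def size(self) -> int:
        """Edit size as replaced + inserted nucleotides."""
        return len(self.deleted) + len(self.inserted)

    def apply(self, cds: str) -> str:
        return cds[: self.start] + self.inserted + cds[self.start + len(self.deleted) :]


def cds_edit(
    cds: str,
    reference: ProteinRecord,
    variant: Variant,
    codon_table: str | int = "Standard",
    codon_choice: dict[str, str] | None = None,
) -> CdsEdit:
    """Codon-level realisation of a protein variant on its CDS.

    New residues are encoded with the organism-preferred codon from
    ``codon_choice`` (default: highly-expressed E. coli genes).  The CDS
    must translate exactly to the reference protein (a trailing stop codon
    is allowed).
    """
    variant.validate(reference)
    _check_cds_matches(cds, reference, codon_table)
    codons = codon_choice or PREFERRED_CODONS_ECOLI
    off = reference.numbering_offset
    if variant.kind == "substitution":
        i = 3 * (variant.start - off)
        return CdsEdit(start=i, deleted=cds[i : i + 3], inserted=codons[variant.alt])
    if variant.kind == "deletion":
        i = 3 * (variant.start - off)
        j = 3 * (variant.end - off + 1)
        return CdsEdit(start=i, deleted=cds[i:j], inserted="")
    i = 3 * (variant.start - off + 1)  # after the left anchor codon
    return CdsEdit(start=i, deleted="", inserted="".join(codons[a] for a in variant.alt))


def apply_variant_cds(
    cds: str,
    reference: ProteinRecord,
    variant: Variant,
    codon_table: str | int = "Standard",
    codon_choice: dict[str, str] | None = None,
) -> str:
    """Mutated CDS whose translation equals ``apply_variant`` of the protein."""
    return cds_edit(cds, reference, variant, codon_table, codon_choice).apply(cds)


# ---------------------------------------------------------------------------
# Libraries


@dataclass
class VariantLibrary:
    """An ordered collection of variants from one generator run."""

    generator: str
    reference_id: str
    variants: list[Variant] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    skipped: int = 0  # positions skipped because the edit would equal wild type

    def __post_init__(self) -> None:
        names = [v.name for v in self.variants]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DesignError(
                f"{self.generator}: duplicate variant names {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variants]

    def to_dataframe(self, reference: ProteinRecord | None = None) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            row = {
                "name": v.name,
                "kind": v.kind,
                "start": v.start,
                "end": v.end,
                "inserted_seq": v.alt if v.kind == "insertion" else "",
            }
            if reference is not None:
                row["protein_seq"] = apply_variant(reference, v)
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["name", "kind", "start", "end", "inserted_seq"]
            + (["protein_seq"] if reference is not None else []),
        )

    def write_tsv(self, path: str | Path, reference: ProteinRecord | None = None) -> None:
        self.to_dataframe(reference).to_csv(path, sep="\t", index=False)

    def write_fasta(self, path: str | Path, reference: ProteinRecord) -> None:
        from .io_formats import write_fasta

        write_fasta(path, ((v.name, apply_variant(reference, v)) for v in self.variants))


def validate_library(library: VariantLibrary, reference: ProteinRecord) -> None:
    for v in library:
        v.validate(reference)
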