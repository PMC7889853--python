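"""Variant-library generators for active-site-loop engineering.

Five strategies, each returning a :class:`~loopcraft.variant_model.VariantLibrary`
of single independent edits on a reference protein:

* :func:`alanine_scan` — every loop residue to Ala (wild-type Ala to Gly);
* NNK site-saturation sizing (:func:`nnk_coverage`, :func:`clones_for_coverage`,
  :func:`nnk_saturation`) — 32-codon degenerate saturation and the
  clones-vs-coverage arithmetic behind "92 colonies for almost 95%";
* :func:`consensus_library` — substitutions (and deletions) toward the
  homolog consensus at well-conserved loop columns;
* :func:`fillup_insertions` — stepwise insertion of the residues longer
  homolog loops carry at the reference's alignment gaps;
* :func:`nested_deletions` — 1/3/7-residue deletion series centred on
  chosen loop residues;
* :func:`lili_library` — Linker In Loop Insertion: 2-6 residue G/GS/PA/GP
  linker repeats inserted after hot-spot positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DesignError
from .hotspots import ConservationProfile, LoopRegion, _reference_column_map, conservation_profile
from .io_formats import AlignmentRecord, ProteinRecord
from .variant_model import (
    Variant,
    VariantLibrary,
    deletion,
    insertion,
    substitution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LINKER_SETS",
    "LinkerSet",
    "SaturationDesign",
    "alanine_scan",
    "nnk_coverage",
    "amino_acid_coverage",
    "clones_for_coverage",
    "nnk_saturation",
    "consensus_library",
    "fillup_insertions",
    "nested_deletions",
    "lili_library",
]


@dataclass(frozen=True)
class LinkerSet:
    """A protein-linker repeat unit; a linker of length L is the first L
    characters of the unit repeated."""

    name: str
    unit: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.unit) <= 2:
            raise DesignError(f"linker unit {self.unit!r} must have length 1 or 2")

    def linker(self, length: int) -> str:
        if length < 1:
            raise DesignError(f"linker length must be >= 1, got {length}")
        reps = -(-length // len(self.unit))
        return (self.unit * reps)[:length]


#: The four linker chemistries used for loop insertion: flexible G and GS,
#: stiff non-helical PA, polar unstructured GP.
LINKER_SETS: tuple[LinkerSet, ...] = (
    LinkerSet("G", "G"),
    LinkerSet("GS", "GS"),
    LinkerSet("PA", "PA"),
    LinkerSet("GP", "GP"),
)


# ---------------------------------------------------------------------------
# Alanine scan


def alanine_scan(reference: ProteinRecord, regions: Sequence[LoopRegion]) -> VariantLibrary:
    """One substitution per region residue: X->A, wild-type A->G.

    Library size always equals the summed region length.
    """
    variants: list[Variant] = []
    for region in regions:
        for pos in region.residues:
            wt = reference.residue_at(pos)
            variants.append(substitution(reference, pos, "G" if wt == "A" else "A"))
    variants.sort(key=lambda v: v.start)
    return VariantLibrary(
        generator="alanine_scan",
        reference_id=reference.id,
        variants=variants,
        params={"regions": [(r.name, r.start, r.end) for r in regions]},
    )


# ---------------------------------------------------------------------------
# NNK saturation sizing


def nnk_coverage(V: int, N: int) -> float:
    """Expected fraction of V equiprobable codons seen at least once in N clones.

    1 - (1 - 1/V)^N; with the NNK scheme V = 32, so 92 clones give ~0.946
    ("almost 95%").
    """
    if V < 1:
        raise ValueError(f"V must be >= 1, got {V}")
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    return 1.0 - (1.0 - 1.0 / V) ** N


def amino_acid_coverage(N: int) -> float:
    """Expected fraction of the 20 amino acids seen at least once among N
    NNK clones (codon multiplicities 3/2/1 per residue make this much
    higher than codon-level coverage at the same N)."""
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    multiplicity = {3: 8, 2: 9, 1: 3}  # NNK codons per aa: 8 aa x3, 9 aa x2, 3 aa x1
    total = 0.0
    for m, n_aa in multiplicity.items():
        total += n_aa * (1.0 - (1.0 - m / 32.0) ** N)
    return total / 20.0


def clones_for_coverage(V: int, target: float) -> int:
    """Smallest N with nnk_coverage(V, N) >= target (exact inverse)."""
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    if V == 1:
        return 1
    n = max(0, math.ceil(math.log(1.0 - target) / math.log(1.0 - 1.0 / V)))
    while nnk_coverage(V, n) < target:  # guard float edge cases
        n += 1
    while n > 0 and nnk_coverage(V, n - 1) >= target:
        n -= 1
    return n


@dataclass(frozen=True)
class SaturationDesign:
    """Sizing record for one NNK-saturated position."""

    position: int
    wt_residue: str
    scheme: str = "NNK"
    codons: int = 32
    amino_acids: int = 20
    stop_codons: int = 1
    clones: int = 92

    @property
    def codon_coverage(self) -> float:
        return nnk_coverage(self.codons, self.clones)

    @property
    def aa_coverage(self) -> float:
        return amino_acid_coverage(self.clones)


def nnk_saturation(
    reference: ProteinRecord,
    positions: Iterable[int],
    clones: int | None = None,
    target_coverage: float | None = None,
    scheme: str = "NNK",
) -> list[SaturationDesign]:
    """Per-position NNK (or NNS; also 32 codons) saturation designs.

    Give either ``clones`` directly or a ``target_coverage`` from which the
    clone count is sized; default is 92 clones (~94.6% codon coverage).
    """
    if scheme not in {"NNK", "NNS"}:
        raise DesignError(f"unsupported degenerate scheme {scheme!r}")
    if clones is not None and target_coverage is not None:
        raise DesignError("give clones or target_coverage, not both")
    if clones is None:
        clones = 92 if target_coverage is None else clones_for_coverage(32, target_coverage)
    return [
        SaturationDesign(
            position=p, wt_residue=reference.residue_at(p), scheme=scheme, clones=clones
        )
        for p in sorted(positions)
    ]


def simulate_nnk_sampling(V: int, N: int, reps: int, rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of nnk_coverage: mean fraction of distinct
    codons among N uniform draws from V, over ``reps`` replicates.  Kept
    as an independent cross-check of the closed form."""
    draws = rng.integers(0, V, size=(reps, N))
    distinct = np.array([np.unique(row).size for row in draws])
    return float(distinct.mean() / V)


# ---------------------------------------------------------------------------
# Consensus library


def consensus_library(
    alignment: AlignmentRecord,
    reference_id: str,
    regions: Sequence[LoopRegion],
    cons_thr: float = 0.8,
    profile: ConservationProfile | None = None,
    numbering_offset: int = 1,
) -> VariantLibrary:
    """Substitutions/deletions toward the homolog consensus in loop regions.

    For each region column conserved at >= ``cons_thr``: if the reference
    residue differs from the consensus, substitute to consensus; where the
    reference carries a residue but >= ``cons_thr`` of homologs have a gap,
    delete that residue.  Positions already matching consensus are skipped
    (and counted), so no emitted variant equals wild type.
    """
    if profile is None:
        profile = conservation_profile(alignment)
    row = alignment.row(reference_id)
    reference = ProteinRecord(
        id=reference_id, sequence=row.replace("-", ""), numbering_offset=numbering_offset
    )
    col_for_res = {r: j for j, r in _reference_column_map(alignment, reference_id, numbering_offset)}
    n_rows = len(alignment.records)

    variants: list[Variant] = []
    seen: set[str] = set()
    skipped = 0
    wanted = {pos for region in regions for pos in region.residues}
    for pos in sorted(wanted):
        j = col_for_res.get(pos)
        if j is None:
            continue
        col = profile.columns[j]
        # homolog gap fraction excludes the reference row itself
        others = [alignment.records[k][1][j] for k in range(n_rows) if alignment.records[k][0] != reference_id]
        gap_frac_others = others.count("-") / len(others)
        if gap_frac_others >= cons_thr:
            v = deletion(reference, pos, pos)
        elif col.score >= cons_thr and col.consensus not in ("-", reference.residue_at(pos)):
            v = substitution(reference, pos, col.consensus)
        else:
            skipped += 1
            continue
        if v.name in seen:
            continue
        seen.add(v.name)
        variants.append(v)
    logger.info("consensus_library: %d variants, %d positions skipped", len(variants), skipped)
    return VariantLibrary(
        generator="consensus_library",
        reference_id=reference_id,
        variants=variants,
        params={"cons_thr": cons_thr, "regions": [(r.name, r.start, r.end) for r in regions]},
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Fill-up insertions


def _region_column_block(
    alignment: AlignmentRecord, reference_id: str, region: LoopRegion, offset: int
) -> tuple[int, int]:
    """Alignment-column span [first, last] covered by a reference region."""
    col_for_res = {r: j for j, r in _reference_column_map(alignment, reference_id, offset)}
    try:
        return col_for_res[region.start], col_for_res[region.end]
    except KeyError as exc:
        raise DesignError(
            f"region {region.name} ({region.start}-{region.end}) outside the "
            f"reference row {reference_id!r}"
        ) from exc


def fillup_insertions(
    alignment: AlignmentRecord,
    reference_id: str,
    region: LoopRegion,
    n_donors: int = 2,
    step: int = 2,
    numbering_offset: int = 1,
) -> VariantLibrary:
    """Stepwise "fill-up" of a short loop with residues from longer homolog loops.

    Within the region's alignment block, the ``n_donors`` homolog rows with
    the most non-gap residues are selected.  For each donor, the residues it
    carries at columns where the reference is gapped are collected in column
    order and inserted stepwise — lengths ``step, 2*step, ...`` up to the
    full complement (plus a final full-length variant when the total is not
    a multiple of ``step``) — anchored at the reference residue immediately
    left of the donor's first gap-column residue.
    """
    if step < 1:
        raise DesignError(f"step must be >= 1, got {step}")
    row = alignment.row(reference_id)
    reference = ProteinRecord(
        id=reference_id, sequence=row.replace("-", ""), numbering_offset=numbering_offset
    )
    c0, c1 = _region_column_block(alignment, reference_id, region, numbering_offset)
    gap_cols = [j for j in range(c0, c1 + 1) if row[j] == "-"]
    variants: list[Variant] = []
    seen: set[str] = set()
    if not gap_cols:
        logger.warning(
            "fillup_insertions: reference has no gap columns in %s; empty library",
            region.name,
        )
        return VariantLibrary(
            generator="fillup_insertions",
            reference_id=reference_id,
            variants=[],
            params={"region": (region.name, region.start, region.end), "step": step},
        )

    donors = [
        (rid, seq)
        for rid, seq in alignment.records
        if rid != reference_id
    ]
    donors.sort(
        key=lambda item: (-sum(1 for j in range(c0, c1 + 1) if item[1][j] != "-"), item[0])
    )
    # residue number of the reference residue at/left of each column
    res_left: dict[int, int] = {}
    resnum = numbering_offset - 1
    for j, c in enumerate(row):
        if c != "-":
            resnum += 1
        res_left[j] = resnum

    for rid, seq in donors[:n_donors]:
        donor_cols = [j for j in gap_cols if seq[j] != "-"]
        if not donor_cols:
            continue
        missing = "".join(seq[j] for j in donor_cols)
        anchor = res_left[donor_cols[0]]
        if anchor < reference.first_residue:
            raise DesignError(
                f"fillup_insertions: donor {rid!r} fill starts before the first "
                "reference residue; no left anchor"
            )
        lengths = list(range(step, len(missing) + 1, step))
        if not lengths or lengths[-1] != len(missing):
            lengths.append(len(missing))
        for L in lengths:
            v = insertion(reference, anchor, missing[:L])
            if v.name not in seen:
                seen.add(v.name)
                variants.append(v)
    return VariantLibrary(
        generator="fillup_insertions",
        reference_id=reference_id,
        variants=variants,
        params={
            "region": (region.name, region.start, region.end),
            "n_donors": n_donors,
            "step": step,
        },
    )


# ---------------------------------------------------------------------------
# Nested deletions


def nested_deletions(
    reference: ProteinRecord,
    centers: Sequence[int],
    half_widths: Sequence[int] = (0, 1, 3),
) -> VariantLibrary:
    """Deletion series centred on chosen residues.

    For each center c and half-width h, residues [c-h, c+h] are removed —
    the default half-widths (0, 1, 3) give the 1/3/7-residue series in
    which each step removes the two neighbours of the previous deletion.
    """
    variants: list[Variant] = []
    for c in centers:
        for h in sorted(half_widths):
            start, end = c - h, c + h
            if start < reference.first_residue or end > reference.last_residue:
                raise DesignError(
                    f"nested_deletions: window [{start}, {end}] around center {c} "
                    "is out of bounds"
                )
            variants.append(deletion(reference, start, end))
    return VariantLibrary(
        generator="nested_deletions",
        reference_id=reference.id,
        variants=variants,
        params={"centers": list(centers), "half_widths": sorted(half_widths)},
    )


# ---------------------------------------------------------------------------
# LILI


def lili_library(
    reference: ProteinRecord,
    sites: Sequence[int],
    linker_sets: Sequence[LinkerSet] = LINKER_SETS,
    min_len: int = 2,
    max_len: int = 6,
) -> VariantLibrary:
    """Linker In Loop Insertion: linker repeats inserted after hot-spot sites.

    Each site x linker set x length in [min_len, max_len] yields one
    insertion of the first L characters of the repeated unit; defaults
    (4 sets, lengths 2..6) give 20 variants per site.  Same-name duplicates
    across sets (e.g. "G" and "GS" both give "G" at L=1) are dropped.
    """
    if min_len < 1 or max_len < min_len:
        raise DesignError(f"bad linker length range [{min_len}, {max_len}]")
    variants: list[Variant] = []
    seen: set[str] = set()
    for site in sites:
        for lset in linker_sets:
            for L in range(min_len, max_len + 1):
                v = insertion(reference, site, lset.linker(L))
                if v.name not in seen:
                    seen.add(v.name)
                    variants.append(v)
    return VariantLibrary(
        generator="lili_library",
        reference_id=reference.id,
        variants=variants,
        params={
            "sites": list(sites),
            "linker_sets": [s.name for s in linker_sets],
            "min_len": min_len,
            "max_len": max_len,
        },
    )
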