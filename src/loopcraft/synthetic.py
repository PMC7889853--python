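"""Seeded synthetic fixtures: every input the tool consumes, generated in code.

The generators emulate the structure of the real inputs — a homolog family
whose variable-length loops sit between fully alignable conserved motifs, a
CDS consistent with the protein, a minimal PDB file with loop-elevated
B-factors, and an internal-standard plate with multiplicative area noise —
without claiming any evolutionary or crystallographic realism.  Everything
is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hotspots import LoopRegion
from .io_formats import AlignmentRecord, ProteinRecord
from .screening import ScreeningTable, Well
from .variant_model import VariantLibrary

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "LoopFixture",
    "FixtureSpec",
    "PlateSpec",
    "make_cdo_like_reference",
    "CDO_LOOP1",
    "CDO_LOOP2",
    "make_homolog_family",
    "make_cds",
    "make_structure_pdb",
    "make_plate",
    "write_demo_workspace",
]


# ---------------------------------------------------------------------------
# Synthetic reference with the study's anchor residues


#: Anchor residues of the dioxygenase alpha-subunit loops engineered in the
#: field (iron-coordinating H240, loop centres, LILI sites and their right
#: anchors).  The filler between anchors is seeded-random: this reference is
#: SYNTHETIC, not the real alpha-subunit sequence.
_ANCHORS: dict[int, str] = {
    236: "G", 240: "H", 251: "E", 257: "V", 260: "P", 264: "N",
    278: "F", 279: "N", 280: "D", 281: "D", 282: "F", 283: "A",
    284: "L", 286: "Q", 287: "A", 288: "I", 289: "M", 290: "G",
}

CDO_LOOP1 = LoopRegion("loop1", 236, 264)
CDO_LOOP2 = LoopRegion("loop2", 278, 290)


def make_cdo_like_reference(length: int = 460, seed: int = 1329) -> ProteinRecord:
    """A synthetic dioxygenase-like reference (default length 460).

    Carries the canonical loop anchor residues (G236, H240, E251, V257,
    P260, N264, F278-G290 as published) at their 1-based positions; all
    other positions are seeded-random filler.  A stand-in for the real
    alpha-subunit, sufficient for every position-arithmetic operation.
    """
    rng = np.random.default_rng(seed)
    residues = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=length)]
    for pos, aa in _ANCHORS.items():
        residues[pos - 1] = aa
    return ProteinRecord(id="CDO_alpha_synthetic", sequence="".join(residues))


# ---------------------------------------------------------------------------
# Homolog family


@dataclass(frozen=True)
class LoopFixture:
    """One variable loop: where it sits on the reference and how homologs vary."""

    start: int  # first loop residue (1-based, on the reference)
    length: int  # reference loop length
    spread: int = 6  # max extra residues a homolog's loop may carry
    substitution_rate: float = 1.0  # chance a homolog loop residue differs from ref

    @property
    def region(self) -> LoopRegion:
        return LoopRegion(f"loop_{self.start}", self.start, self.start + self.length - 1)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic homolog family."""

    seed: int
    protein_length: int = 460
    loops: tuple[LoopFixture, ...] = (LoopFixture(236, 29), LoopFixture(278, 13))
    n_homologs: int = 16
    flank_conservation: float = 1.0  # conserved framing motifs, per the family
    #: loop positions where all homologs share a residue differing from the
    #: reference (drives the consensus-substitution rule)
    consensus_mismatch_positions: tuple[int, ...] = ()
    #: loop positions where homologs are gapped while the reference is not
    #: (drives the consensus-deletion rule)
    consensus_gap_positions: tuple[int, ...] = ()


def make_homolog_family(
    spec: FixtureSpec, reference: ProteinRecord | None = None
) -> tuple[ProteinRecord, AlignmentRecord, list[LoopRegion]]:
    """Build (reference, alignment, ground-truth loop regions).

    Outside the loops every homolog matches the reference with probability
    ``flank_conservation``.  Inside a loop, homolog residues are resampled
    at ``substitution_rate`` and each homolog carries 0..spread extra
    residues, left-aligned in a gap block opened at the loop midpoint, so
    the reference's gap columns sit inside the loop and the conserved
    flanks stay alignable without running an aligner.
    """
    rng = np.random.default_rng(spec.seed)
    if reference is None:
        residues = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=spec.protein_length)]
        reference = ProteinRecord(id="ref", sequence="".join(residues))
    regions = [lf.region for lf in spec.loops]
    for lf, region in zip(spec.loops, regions):
        if region.end > reference.last_residue:
            raise ValueError(f"loop at {lf.start} extends past the reference")

    loop_of: dict[int, LoopFixture] = {}
    for lf in spec.loops:
        for pos in lf.region.residues:
            loop_of[pos] = lf
    mismatch = set(spec.consensus_mismatch_positions)
    gapped = set(spec.consensus_gap_positions)
    # one shared "family" residue per consensus-mismatch position
    family_res = {}
    for pos in sorted(mismatch):
        wt = reference.residue_at(pos)
        choices = [a for a in AA_ALPHABET if a != wt]
        family_res[pos] = choices[rng.integers(0, len(choices))]

    # column layout: every reference residue is a column; each loop opens a
    # gap block of `spread` columns at its midpoint
    columns: list[tuple[str, int | None, LoopFixture | None]] = []  # (type, resnum, loop)
    pos = reference.first_residue
    while pos <= reference.last_residue:
        lf = loop_of.get(pos)
        columns.append(("res", pos, lf))
        if lf is not None and pos == lf.start + lf.length // 2 - 1 and lf.spread > 0:
            for _ in range(lf.spread):
                columns.append(("gap", None, lf))
        pos += 1

    ref_row = "".join("-" if t == "gap" else reference.residue_at(p) for t, p, _ in columns)

    rows: list[tuple[str, str]] = [(reference.id, ref_row)]
    for h in range(spec.n_homologs):
        extra = {lf: int(rng.integers(0, lf.spread + 1)) for lf in spec.loops}
        filled: dict[LoopFixture, int] = {lf: 0 for lf in spec.loops}
        out = []
        for t, p, lf in columns:
            if t == "gap":
                assert lf is not None
                if filled[lf] < extra[lf]:
                    out.append(AA_ALPHABET[rng.integers(0, 20)])
                    filled[lf] += 1
                else:
                    out.append("-")
                continue
            wt = reference.residue_at(p)
            if lf is None:  # conserved frame
                if rng.random() < spec.flank_conservation:
                    out.append(wt)
                else:
                    others = [a for a in AA_ALPHABET if a != wt]
                    out.append(others[rng.integers(0, 19)])
            elif p in gapped:
                out.append("-")
            elif p in mismatch:
                out.append(family_res[p])
            elif rng.random() < lf.substitution_rate:
                others = [a for a in AA_ALPHABET if a != wt]
                out.append(others[rng.integers(0, 19)])
            else:
                out.append(wt)
        rows.append((f"homolog_{h:02d}", "".join(out)))

    return reference, AlignmentRecord(records=tuple(rows)), regions


# ---------------------------------------------------------------------------
# CDS


def make_cds(reference: ProteinRecord, seed: int, codon_table: str = "Standard") -> str:
    """A CDS translating exactly to the reference, with a TAA stop appended.

    Synonymous codons are chosen uniformly at random (seeded) from the
    codon table, so the CDS is not codon-optimised — deliberately, to keep
    primer-annealing sequence complexity realistic.
    """
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_name[codon_table]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    rng = np.random.default_rng(seed)
    codons = [
        by_aa[aa][rng.integers(0, len(by_aa[aa]))] for aa in reference.sequence
    ]
    return "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# Structure with synthetic B-factors


def make_structure_pdb(
    reference: ProteinRecord,
    loops: list[LoopRegion],
    seed: int,
    chain: str = "A",
    base_b: float = 18.0,
    loop_b: float = 38.0,
    b_sd: float = 3.0,
) -> str:
    """Minimal PDB text: backbone atoms N/CA/C/O on a synthetic trace, with
    B-factors elevated inside the loops.  Coordinates are a placeholder
    helix-free trace; only B-factors carry signal."""
    rng = np.random.default_rng(seed)
    in_loop = {p for lp in loops for p in lp.residues}
    three = {  # enough of the 20 for a synthetic record
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    lines = []
    serial = 1
    for pos in range(reference.first_residue, reference.last_residue + 1):
        aa = three[reference.residue_at(pos)]
        center = loop_b if pos in in_loop else base_b
        for k, name in enumerate(("N", "CA", "C", "O")):
            b = max(2.0, rng.normal(center, b_sd))
            x = 3.8 * pos + 0.4 * k
            # strict PDB columns: name 13-16, altLoc 17, resName 18-20,
            # chainID 22, resSeq 23-26, iCode 27
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {aa:3s} {chain}{pos:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{b:6.2f}          "
                f"{name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Screening plate


@dataclass(frozen=True)
class PlateSpec:
    """Layout and noise model of a synthetic 96-well screening plate.

    Defaults mirror the standard saturation-screen layout: 92 variant wells,
    three wild-type wells and one empty-vector well on a 96-deep-well plate,
    1 mM internal standard, 20 mM substrate, ~5% multiplicative area noise.
    """

    n_variant_wells: int = 92
    n_wildtype: int = 3
    n_empty_vector: int = 1
    noise_cv: float = 0.05
    is_concentration: float = 1.0  # mM
    substrate_initial: float = 20.0  # mM
    product_analytes: tuple[str, ...] = ("product_a", "product_b", "product_c")
    conc_range: tuple[float, float] = (0.0, 6.0)  # mM per product, variant wells
    wt_conc_range: tuple[float, float] = (0.2, 1.0)  # mM per product, wild type
    response_factors: tuple[float, ...] = (1.0, 1.2, 0.8)
    internal_standard: str = "biphenyl"


def _well_ids(n: int) -> list[str]:
    return [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)][:n]


def make_plate(
    pspec: PlateSpec, library: VariantLibrary | list[str], seed: int
) -> tuple[ScreeningTable, pd.DataFrame]:
    """Simulate a plate and return (table, truth sheet).

    Per-well true product concentrations are drawn from the spec's ranges
    (empty vector: zero).  Areas follow the internal-standard model
    ``area_i = conc_i / [IS] * rf_i * area_IS`` with mean-one lognormal
    noise of the requested CV on every analyte area.  The truth sheet holds
    the drawn concentrations and formation; analysis code never reads it.
    """
    rng = np.random.default_rng(seed)
    names = list(library.names if isinstance(library, VariantLibrary) else library)
    if not names:
        raise ValueError("library has no variants to plate")
    n_total = pspec.n_variant_wells + pspec.n_wildtype + pspec.n_empty_vector
    ids = _well_ids(n_total)
    sigma = float(np.sqrt(np.log(1.0 + pspec.noise_cv**2)))

    def noise() -> float:
        if pspec.noise_cv == 0:
            return 1.0
        return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))

    rf = dict(zip(pspec.product_analytes, pspec.response_factors))
    wells: list[Well] = []
    truth_rows = []
    k = 0
    for i in range(n_total):
        if i < pspec.n_variant_wells:
            role, vname = "variant", names[i % len(names)]
            lo, hi = pspec.conc_range
        elif i < pspec.n_variant_wells + pspec.n_wildtype:
            role, vname = "wildtype", None
            lo, hi = pspec.wt_conc_range
        else:
            role, vname = "empty_vector", None
            lo = hi = 0.0
        conc = {a: float(rng.uniform(lo, hi)) for a in pspec.product_analytes}
        area_is = float(rng.uniform(8e4, 1.2e5))
        areas = {pspec.internal_standard: area_is}
        for a in pspec.product_analytes:
            areas[a] = conc[a] / pspec.is_concentration * rf[a] * area_is * noise()
        wells.append(Well(well_id=ids[i], role=role, variant_name=vname, areas=areas))
        truth_rows.append(
            {
                "well": ids[i],
                "role": role,
                "variant": vname or "",
                **{f"true_conc_{a}_mM": conc[a] for a in pspec.product_analytes},
                "true_formation_pct": 100.0 * sum(conc.values()) / pspec.substrate_initial,
            }
        )
        k += 1
    table = ScreeningTable(
        wells=wells,
        internal_standard=pspec.internal_standard,
        is_concentration=pspec.is_concentration,
        substrate_initial=pspec.substrate_initial,
        product_analytes=pspec.product_analytes,
        calibration=rf,
    )
    return table, pd.DataFrame(truth_rows)


def write_plate_csv(path: str | Path, table: ScreeningTable) -> None:
    rows = []
    for w in table.wells:
        for analyte, area in w.areas.items():
            rows.append(
                {
                    "well": w.well_id,
                    "sample_role": w.role,
                    "variant_name": w.variant_name or "",
                    "analyte": analyte,
                    "peak_area": area,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Demo workspace


def write_demo_workspace(outdir: str | Path, seed: int) -> dict[str, Path]:
    """Write a complete, self-consistent demo input set and return the paths."""
    from .io_formats import write_alignment, write_fasta
    from .library_design import lili_library

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = make_cdo_like_reference(seed=seed)
    # engineered consensus mismatches sit on the first loop residues so the
    # low-conservation runs stay contiguous for find-loops demos
    spec = FixtureSpec(
        seed=seed,
        consensus_mismatch_positions=(236, 278),
    )
    reference, alignment, regions = make_homolog_family(spec, reference=reference)
    cds = make_cds(reference, seed=seed + 1)
    pdb_text = make_structure_pdb(reference, regions, seed=seed + 2)
    library = lili_library(reference, sites=[257, 278, 286])
    table, truth = make_plate(PlateSpec(), library, seed=seed + 3)

    paths = {
        "reference": outdir / "reference.fasta",
        "alignment": outdir / "family_alignment.fasta",
        "cds": outdir / "cds.fasta",
        "structure": outdir / "structure_synthetic.pdb",
        "plate": outdir / "plate.csv",
        "truth": outdir / "plate_truth.csv",
    }
    write_fasta(paths["reference"], [reference])
    write_alignment(paths["alignment"], alignment)
    write_fasta(paths["cds"], [(f"{reference.id}_cds", cds)])
    paths["structure"].write_text(pdb_text)
    write_plate_csv(paths["plate"], table)
    truth.to_csv(paths["truth"], index=False)
    return paths
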