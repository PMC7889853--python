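"""Loop hot-spot discovery: MSA conservation profiling and B-factor flexibility.

Active-site loops in Rieske oxygenase alpha-subunits are poorly conserved
stretches framed by highly conserved motifs, and they are the most mobile
parts of the crystal structure.  This module scores both signals: a
per-column conservation profile over a homolog alignment, and per-residue
backbone B-factor statistics from a structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ResidueLookupError
from .io_formats import AA20, AlignmentRecord, ResidueBFactors

#: conventional protein backbone atoms
BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "BACKBONE_ATOMS",
    "LoopRegion",
    "ColumnScore",
    "ConservationProfile",
    "LoopCandidate",
    "conservation_profile",
    "find_loop_candidates",
    "backbone_bfactor",
    "region_bfactor_stats",
    "write_candidates_tsv",
]


@dataclass(frozen=True)
class LoopRegion:
    """A named 1-based inclusive residue interval on a reference protein."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class ColumnScore:
    score: float
    gap_fraction: float
    consensus: str  # '-' when the column is all gaps


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation of an MSA.

    score = 1 - H/H_max with H the Shannon entropy of the amino-acid
    distribution among non-gap symbols and H_max = ln(20); 1 means fully
    conserved, 0 means uniform over the 20-letter alphabet.  Gaps are
    excluded from the entropy and reported separately as gap_fraction —
    in loop regions the homologs' indels are the signal, not noise.
    """

    columns: tuple[ColumnScore, ...]

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def scores(self) -> np.ndarray:
        return np.array([c.score for c in self.columns])

    @property
    def gap_fractions(self) -> np.ndarray:
        return np.array([c.gap_fraction for c in self.columns])


@dataclass(frozen=True)
class LoopCandidate:
    """A low-conservation run framed by conserved motifs, in reference coords."""

    region: LoopRegion
    mean_score: float
    left_flank: LoopRegion
    right_flank: LoopRegion
    mean_bfactor: float | None = None
    max_bfactor: float | None = None


_HMAX = math.log(20.0)


def conservation_profile(alignment: AlignmentRecord) -> ConservationProfile:
    """Score each alignment column.

    Entropy is computed over the 20 standard amino acids among non-gap,
    non-X symbols; all-gap columns get score 0 and consensus '-'.
    Consensus ties break alphabetically for determinism.
    """
    cols = []
    n_rows = len(alignment.records)
    for j in range(alignment.length):
        col = alignment.column(j)
        residues = [c for c in col if c in AA20]
        gap_fraction = col.count("-") / n_rows
        if not residues:
            cols.append(ColumnScore(score=0.0, gap_fraction=gap_fraction, consensus="-"))
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        n = len(residues)
        h = -sum((k / n) * math.log(k / n) for k in counts.values())
        score = max(0.0, 1.0 - h / _HMAX)
        consensus = min(sorted(counts), key=lambda a: (-counts[a], a))
        cols.append(ColumnScore(score=score, gap_fraction=gap_fraction, consensus=consensus))
    return ConservationProfile(columns=tuple(cols))


def _reference_column_map(alignment: AlignmentRecord, reference_id: str, offset: int = 1) -> list[tuple[int, int]]:
    """(alignment column, reference residue number) for each non-gap reference column."""
    row = alignment.row(reference_id)
    out = []
    resnum = offset
    for j, c in enumerate(row):
        if c != "-":
            out.append((j, resnum))
            resnum += 1
    return out


def find_loop_candidates(
    profile: ConservationProfile,
    alignment: AlignmentRecord,
    reference_id: str,
    low_thr: float = 0.4,
    high_thr: float = 0.8,
    min_loop_len: int = 4,
    min_flank_len: int = 4,
    numbering_offset: int = 1,
) -> list[LoopCandidate]:
    """Find low-conservation runs framed on both sides by conserved motifs.

    The scan runs over the subsequence of columns where the reference has a
    residue (columns where the reference is gapped are skipped): maximal
    runs of >= ``min_loop_len`` consecutive reference-mapped columns with
    score < ``low_thr``, immediately preceded and followed by
    >= ``min_flank_len`` consecutive reference-mapped columns with score
    >= ``high_thr``.  Results are reported in reference residue numbers,
    sorted by start; runs touching the alignment edge have no flank and are
    not reported.
    """
    colmap = _reference_column_map(alignment, reference_id, numbering_offset)
    scores = [profile.columns[j].score for j, _ in colmap]
    resnums = [r for _, r in colmap]
    n = len(scores)

    def high_run_left(i: int) -> int:
        """Length of the consecutive high-score run ending at index i (inclusive)."""
        k = 0
        while i - k >= 0 and scores[i - k] >= high_thr:
            k += 1
        return k

    def high_run_right(i: int) -> int:
        k = 0
        while i + k < n and scores[i + k] >= high_thr:
            k += 1
        return k

    candidates: list[LoopCandidate] = []
    i = 0
    while i < n:
        if scores[i] < low_thr:
            j = i
            while j + 1 < n and scores[j + 1] < low_thr:
                j += 1
            run_len = j - i + 1
            if run_len >= min_loop_len and i > 0 and j < n - 1:
                lf = high_run_left(i - 1)
                rf = high_run_right(j + 1)
                if lf >= min_flank_len and rf >= min_flank_len:
                    k = len(candidates) + 1
                    region = LoopRegion(f"loop{k}", resnums[i], resnums[j])
                    candidates.append(
                        LoopCandidate(
                            region=region,
                            mean_score=float(np.mean(scores[i : j + 1])),
                            left_flank=LoopRegion(
                                f"loop{k}_left_flank", resnums[i - lf], resnums[i - 1]
                            ),
                            right_flank=LoopRegion(
                                f"loop{k}_right_flank", resnums[j + 1], resnums[j + rf]
                            ),
                        )
                    )
            i = j + 1
        else:
            i += 1
    return candidates


def backbone_bfactor(bfactors: ResidueBFactors, residue_number: int) -> float:
    """Mean B-factor (A^2) over the backbone atoms {N, CA, C, O} present."""
    atoms = bfactors.atoms(residue_number)
    vals = [b for name, b in atoms if name in BACKBONE_ATOMS]
    if not vals:
        raise ResidueLookupError(
            f"residue {residue_number} in chain {bfactors.chain_id!r} "
            "has no backbone atoms"
        )
    return float(np.mean(vals))


def region_bfactor_stats(
    bfactors: ResidueBFactors, region: LoopRegion, pooled: bool = False
) -> tuple[float, float, int]:
    """(mean, max, argmax residue) of backbone B-factors over a region.

    By default the mean averages the per-residue backbone means; with
    ``pooled=True`` all backbone atoms of the region are pooled into a
    single mean instead.  Max and its residue always use per-residue means.
    """
    missing = [r for r in region.residues if r not in bfactors.residues]
    if missing:
        raise ResidueLookupError(
            f"region {region.name}: residues missing from chain "
            f"{bfactors.chain_id!r}: {missing}"
        )
    per_res = {r: backbone_bfactor(bfactors, r) for r in region.residues}
    if pooled:
        pool = [
            b
            for r in region.residues
            for name, b in bfactors.atoms(r)
            if name in BACKBONE_ATOMS
        ]
        mean = float(np.mean(pool))
    else:
        mean = float(np.mean(list(per_res.values())))
    argmax = max(per_res, key=lambda r: (per_res[r], -r))
    return mean, per_res[argmax], argmax


def write_candidates_tsv(
    path: str | Path,
    candidates: Sequence[LoopCandidate],
    bed: bool = False,
) -> None:
    """Export candidates as TSV; 1-based inclusive by default, BED-style
    (0-based half-open) behind the ``bed`` flag."""
    import pandas as pd

    rows = []
    for c in candidates:
        start, end = c.region.start, c.region.end
        if bed:
            start, end = start - 1, end
        rows.append(
            {
                "name": c.region.name,
                "start": start,
                "end": end,
                "mean_score": round(c.mean_score, 4),
                "mean_B": None if c.mean_bfactor is None else round(c.mean_bfactor, 2),
                "max_B": None if c.max_bfactor is None else round(c.max_bfactor, 2),
            }
        )
    pd.DataFrame(
        rows, columns=["name", "start", "end", "mean_score", "mean_B", "max_B"]
    ).to_csv(path, sep="\t", index=False)
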