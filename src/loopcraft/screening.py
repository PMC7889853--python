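"""Reduction of variant-screening plate data to catalytic read-outs.

Wells are whole-cell biotransformations extracted with an internal-standard
(IS) spiked solvent; integrated peak areas are the input.  The module turns
them into product concentrations, product formation (% of initial
substrate), product distribution (% of total product), enantiomeric and
diastereomeric excess, and wild-type-relative fold changes for hit calling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LoopcraftError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Well",
    "ScreeningTable",
    "WellResult",
    "quantify",
    "enantiomeric_excess",
    "diastereomeric_excess",
    "call_hits",
    "summarize_library",
]

ROLES = ("variant", "wildtype", "empty_vector")


@dataclass
class Well:
    well_id: str
    role: str
    variant_name: str | None
    areas: dict[str, float]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"well {self.well_id}: role {self.role!r} not in {list(ROLES)}"
            )


@dataclass
class ScreeningTable:
    """A plate (or vial series) of IS-normalised peak areas plus layout.

    ``calibration`` maps analyte -> response factor (area per concentration
    unit, relative to the IS); when omitted it defaults to 1.0 for every
    analyte with a loud warning, i.e. area ratios are read as concentration
    ratios directly.
    """

    wells: list[Well]
    internal_standard: str = "biphenyl"
    is_concentration: float = 1.0  # mM in the extract
    substrate_initial: float = 10.0  # mM
    product_analytes: tuple[str, ...] = ()
    calibration: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.wells:
            a = w.areas.get(self.internal_standard)
            if a is None or not a > 0:
                raise ValidationError(
                    f"well {w.well_id}: internal standard {self.internal_standard!r} "
                    "missing or non-positive"
                )
        for analyte, rf in self.calibration.items():
            if not rf > 0:
                raise ValidationError(f"response factor for {analyte!r} must be > 0")
        if not self.product_analytes:
            inferred = sorted(
                {a for w in self.wells for a in w.areas} - {self.internal_standard}
            )
            self.product_analytes = tuple(inferred)

    def response_factor(self, analyte: str) -> float:
        if analyte in self.calibration:
            return self.calibration[analyte]
        warnings.warn(
            f"no response factor for {analyte!r}: assuming 1.0 "
            "(area ratio == concentration ratio)",
            stacklevel=2,
        )
        return 1.0


@dataclass
class WellResult:
    well_id: str
    role: str
    variant_name: str | None
    concentrations: dict[str, float]  # mM per product analyte
    formation: float  # % of initial substrate
    distribution: dict[str, float]  # % of total product; empty if none formed
    ee: float | None = None
    ee_major: str | None = None
    de: float | None = None
    de_major: str | None = None
    fold_change: float | None = None


def quantify(table: ScreeningTable) -> list[WellResult]:
    """IS-normalised quantification of every well.

    conc_i = (area_i / area_IS) / rf_i * [IS]; product formation is the
    summed product concentration over the initial substrate concentration
    (clipped at 100% with a warning); the distribution normalises each
    product to the total.  Wells without any product get formation 0 and an
    empty distribution.
    """
    results = []
    for w in table.wells:
        a_is = w.areas[table.internal_standard]
        conc = {}
        for analyte in table.product_analytes:
            area = w.areas.get(analyte, 0.0)
            if area < 0:
                raise ValidationError(f"well {w.well_id}: negative area for {analyte!r}")
            conc[analyte] = (area / a_is) / table.response_factor(analyte) * table.is_concentration
        total = sum(conc.values())
        formation = 100.0 * total / table.substrate_initial
        if formation > 100.0:
            warnings.warn(
                f"well {w.well_id}: product formation {formation:.1f}% exceeds "
                "100%; clipping", stacklevel=2,
            )
            formation = 100.0
        distribution = (
            {a: 100.0 * c / total for a, c in conc.items()} if total > 0 else {}
        )
        results.append(
            WellResult(
                well_id=w.well_id,
                role=w.role,
                variant_name=w.variant_name,
                concentrations=conc,
                formation=formation,
                distribution=distribution,
            )
        )
    return results


def _excess(area_a: float, area_b: float, label_a: str, label_b: str) -> tuple[float, str]:
    if area_a < 0 or area_b < 0:
        raise ValidationError("peak areas must be >= 0")
    total = area_a + area_b
    if total == 0:
        raise LoopcraftError("both stereoisomer areas are zero; excess undefined")
    excess = 100.0 * abs(area_a - area_b) / total
    if area_a == area_b:
        return 0.0, "racemic"
    return excess, (label_a if area_a > area_b else label_b)


def enantiomeric_excess(
    area_a: float, area_b: float, label_a: str = "R", label_b: str = "S"
) -> tuple[float, str]:
    """ee% = |a - b| / (a + b) x 100 with the major-enantiomer label."""
    return _excess(area_a, area_b, label_a, label_b)


def diastereomeric_excess(
    area_a: float, area_b: float, label_a: str, label_b: str
) -> tuple[float, str]:
    """de%: the same statistic over a diastereomer peak pair."""
    return _excess(area_a, area_b, label_a, label_b)


def stereo_fraction(area_major: float, area_minor: float) -> float:
    """Alternative convention: the major isomer's share of the pair, in %.

    Some reports quote "X% (R)-product" as a fraction rather than an
    excess; offered for comparison, never used by default.
    """
    if area_major + area_minor == 0:
        raise LoopcraftError("both stereoisomer areas are zero")
    return 100.0 * area_major / (area_major + area_minor)


def call_hits(
    results: list[WellResult],
    metric: str = "formation",
    fold_thr: float = 2.0,
) -> pd.DataFrame:
    """Blank-correct, normalise to the wild-type mean, and rank.

    ``metric`` is "formation" or "product_share:<analyte>" (the analyte's
    percentage of total product).  The empty-vector well acts as blank: its
    metric is subtracted from every well (floored at 0) before fold changes
    are computed against the wild-type mean.  A zero wild-type mean flags
    fold changes as infinite; those rank first.
    """

    def metric_of(r: WellResult) -> float:
        if metric == "formation":
            return r.formation
        if metric.startswith("product_share:"):
            analyte = metric.split(":", 1)[1]
            return r.distribution.get(analyte, 0.0)
        raise ValueError(f"unknown metric {metric!r}")

    wt = [metric_of(r) for r in results if r.role == "wildtype"]
    if not wt:
        raise ValidationError("no wildtype wells; cannot compute fold changes")
    blanks = [metric_of(r) for r in results if r.role == "empty_vector"]
    blank = float(np.mean(blanks)) if blanks else 0.0
    wt_mean = max(0.0, float(np.mean(wt)) - blank)

    rows = []
    for r in results:
        if r.role != "variant":
            continue
        value = max(0.0, metric_of(r) - blank)
        if wt_mean > 0:
            fold = value / wt_mean
        else:
            fold = math.inf if value > 0 else 0.0
        r.fold_change = fold
        rows.append(
            {
                "well": r.well_id,
                "variant": r.variant_name or r.well_id,
                "metric": value,
                "fold_change": fold,
                "hit": fold >= fold_thr,
            }
        )
    df = pd.DataFrame(rows, columns=["well", "variant", "metric", "fold_change", "hit"])
    # rank: infinite fold first, then descending fold, ties by variant name
    df = df.sort_values(
        by=["fold_change", "variant"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def summarize_library(results: list[WellResult]) -> pd.DataFrame:
    """Replicate aggregation by variant name: n, mean +/- sd formation,
    mean distribution per analyte, mean fold change."""
    groups: dict[str, list[WellResult]] = {}
    for r in results:
        if r.role != "variant":
            continue
        key = r.variant_name or r.well_id
        groups.setdefault(key, []).append(r)
    analytes = sorted({a for r in results for a in r.concentrations})
    rows = []
    for name, rs in sorted(groups.items()):
        row: dict[str, object] = {
            "variant": name,
            "n": len(rs),
            "formation_mean": float(np.mean([r.formation for r in rs])),
            "formation_sd": float(np.std([r.formation for r in rs], ddof=1)) if len(rs) > 1 else 0.0,
        }
        for a in analytes:
            shares = [r.distribution.get(a, 0.0) for r in rs if r.distribution]
            row[f"share_{a}"] = float(np.mean(shares)) if shares else 0.0
        folds = [r.fold_change for r in rs if r.fold_change is not None]
        row["fold_change"] = float(np.mean(folds)) if folds else None
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_csv(path: str | Path, results: list[WellResult]) -> None:
    analytes = sorted({a for r in results for a in r.concentrations})
    rows = []
    for r in results:
        row = {
            "well": r.well_id,
            "role": r.role,
            "variant": r.variant_name or "",
            "formation_pct": r.formation,
        }
        for a in analytes:
            row[f"conc_{a}_mM"] = r.concentrations.get(a, 0.0)
            row[f"share_{a}_pct"] = r.distribution.get(a, "")
        if r.ee is not None:
            row["ee_pct"], row["ee_major"] = r.ee, r.ee_major
        if r.de is not None:
            row["de_pct"], row["de_major"] = r.de, r.de_major
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
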