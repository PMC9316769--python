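"""Peak-area → concentration → content conversion and batch summaries.

Peak areas are inverted through the calibration line to µg/mL, then
scaled to mg per g of dry herb through the sample preparation record
(powder mass, extract volume, dilution). Batch tables follow the
"<site>/<Month>" id convention (e.g. S2/July); summaries report per
batch totals and rank harvest periods within each site.

Concentrations outside the calibration range are flagged, never
dropped: silently nulling near-range analytes would corrupt totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validation import CalibrationCurve

__all__ = ["SamplePrep", "ContentRecord", "area_to_concentration",
           "concentration_to_content", "batch_summary", "parse_batch_id"]

_MONTH_ORDER = {m: i for i, m in enumerate(
    ["January", "February", "March", "April", "May", "June", "July",
     "August", "September", "October", "November", "December"])}


@dataclass(frozen=True)
class SamplePrep:
    """Extraction bookkeeping for content calculation."""

    mass_g: float
    extract_volume_ml: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("powder mass must be positive")
        if self.extract_volume_ml <= 0:
            raise ValueError("extract volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass
class ContentRecord:
    """Replicate contents of one analyte in one batch."""

    batch: str
    analyte: str
    contents_mg_g: np.ndarray

    def __post_init__(self) -> None:
        self.contents_mg_g = np.asarray(self.contents_mg_g, dtype=float).ravel()
        if np.any(self.contents_mg_g < 0):
            raise ValueError("contents must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.contents_mg_g.mean())

    @property
    def sd(self) -> float:
        n = self.contents_mg_g.size
        return float(self.contents_mg_g.std(ddof=1)) if n > 1 else 0.0


def area_to_concentration(area, curve: CalibrationCurve):
    """Invert the calibration line: C = (area − intercept) / slope.

    Returns (concentration µg/mL, in_range flag); both vectorized.
    """
    if curve.slope == 0:
        raise ValueError("zero slope")
    c = (np.asarray(area, dtype=float) - curve.intercept) / curve.slope
    flag = curve.in_range(c)
    if np.ndim(area) == 0:
        return float(c), bool(flag)
    return c, flag


def concentration_to_content(concentration_ug_ml, prep: SamplePrep):
    """Content in mg per g dry powder.

    content = C[µg/mL] · V[mL] · dilution / mass[g] / 1000
    (the 1000 converts µg to mg).
    """
    c = np.asarray(concentration_ug_ml, dtype=float)
    out = c * prep.extract_volume_ml * prep.dilution_factor / prep.mass_g / 1000.0
    return float(out) if np.ndim(concentration_ug_ml) == 0 else out


def parse_batch_id(batch: str) -> tuple[str, str]:
    """Split "<site>/<Month>" ids; raises on any other shape."""
    parts = batch.split("/")
    if len(parts) != 2 or not parts[0] or parts[1] not in _MONTH_ORDER:
        raise ValueError(
            f"batch id {batch!r} does not follow the '<site>/<Month>' convention; "
            "supply an explicit site/period mapping"
        )
    return parts[0], parts[1]


def batch_summary(records: list[ContentRecord]) -> dict:
    """Aggregate content records into per-batch and per-period tables.

    Returns a dict with
      ``per_batch``  — batch × analyte mean (mg/g) plus a total column,
      ``per_period`` — site × period totals with the best period flagged.
    Duplicate (batch, analyte) pairs are rejected.
    """
    if not records:
        raise ValueError("no records")
    seen = set()
    for r in records:
        key = (r.batch, r.analyte)
        if key in seen:
            raise ValueError(f"duplicated batch/analyte pair {key}")
        seen.add(key)

    df = pd.DataFrame(
        [{"batch": r.batch, "analyte": r.analyte, "mean": r.mean, "sd": r.sd}
         for r in records]
    )
    wide = df.pivot(index="batch", columns="analyte", values="mean")
    totals = wide.sum(axis=1)
    per_batch = wide.assign(total_mg_g=totals)

    rows = []
    for batch, total in totals.items():
        site, month = parse_batch_id(str(batch))
        rows.append({"site": site, "period": month, "total_mg_g": float(total)})
    per_period = pd.DataFrame(rows)
    per_period["month_order"] = per_period["period"].map(_MONTH_ORDER)
    per_period = (per_period.sort_values(["site", "month_order"])
                  .drop(columns="month_order").reset_index(drop=True))
    best = per_period.loc[per_period.groupby("site")["total_mg_g"].idxmax()]
    per_period["is_best_period"] = per_period.index.isin(best.index)
    return {"per_batch": per_batch, "per_period": per_period}
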