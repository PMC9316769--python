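"""Analytical-method validation statistics.

Calibration linearity (unweighted OLS of peak area on concentration),
detection/quantification limits scaled from baseline noise over the
calibration slope, replicate precision as relative standard deviation,
and spike recovery. Defaults follow ICH conventions (LOD = 3.3 σ/S,
LOQ = 10 σ/S); the multipliers are explicit parameters because
laboratories differ in which convention they report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CalibrationCurve", "ValidationReport", "fit_calibration",
           "lod_loq", "rsd", "recovery", "recovery_summary"]


@dataclass
class CalibrationCurve:
    """Linear calibration: peak area = slope · concentration + intercept."""

    analyte: str
    slope: float              # area per (µg/mL)
    intercept: float          # area
    r2: float
    range_low: float          # µg/mL
    range_high: float         # µg/mL
    lod: float | None = None  # µg/mL
    loq: float | None = None  # µg/mL

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError(f"analyte {self.analyte!r}: zero calibration slope")
        if self.range_low > self.range_high:  # normalize to (low, high)
            self.range_low, self.range_high = self.range_high, self.range_low
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValueError(f"analyte {self.analyte!r}: LOD exceeds LOQ")

    def area(self, concentration) -> np.ndarray | float:
        """Forward prediction of peak area."""
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def in_range(self, concentration) -> np.ndarray | bool:
        c = np.asarray(concentration, dtype=float)
        return (c >= self.range_low) & (c <= self.range_high)


def fit_calibration(concentrations, areas, analyte: str = "",
                    weights: str | None = None) -> CalibrationCurve:
    """Fit a straight calibration line by least squares.

    Parameters
    ----------
    concentrations, areas : array-like
        Paired standards, ≥ 3 distinct concentration levels.
    analyte : str
        Label carried onto the curve.
    weights : None or "1/x"
        Optional inverse-concentration weighting; unweighted by default.
    """
    c = np.asarray(concentrations, dtype=float).ravel()
    a = np.asarray(areas, dtype=float).ravel()
    if c.size != a.size:
        raise ValueError("concentration/area length mismatch")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if weights is None:
        res = stats.linregress(c, a)
        slope, intercept, r = res.slope, res.intercept, res.rvalue
        r2 = r * r
    elif weights == "1/x":
        if np.any(c <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / c
        W = np.diag(w)
        M = np.column_stack([np.ones_like(c), c])
        beta = np.linalg.solve(M.T @ W @ M, M.T @ W @ a)
        intercept, slope = beta
        fitted = M @ beta
        ybar = np.average(a, weights=w)
        r2 = 1.0 - np.sum(w * (a - fitted) ** 2) / np.sum(w * (a - ybar) ** 2)
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    return CalibrationCurve(
        analyte=analyte, slope=float(slope), intercept=float(intercept),
        r2=float(r2), range_low=float(c.min()), range_high=float(c.max()),
    )


def lod_loq(curve: CalibrationCurve, noise_sd: float,
            k_lod: float = 3.3, k_loq: float = 10.0) -> tuple[float, float]:
    """Detection and quantification limits from noise over slope.

    LOD = k_lod · σ / |slope|, LOQ = k_loq · σ / |slope| with σ the
    peak-area noise standard deviation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0 < k_lod <= k_loq):
        raise ValueError("require 0 < k_lod <= k_loq")
    if curve.slope == 0:
        raise ValueError("zero slope")
    s = abs(curve.slope)
    return k_lod * noise_sd / s, k_loq * noise_sd / s


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 · s / mean (n−1 sd)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean: RSD undefined")
    return 100.0 * v.std(ddof=1) / m


def recovery(original_amount: float, added_amount: float,
             found_amount: float) -> float:
    """Spike recovery in percent: 100 · (found − original) / added."""
    if added_amount <= 0:
        raise ValueError("added amount must be positive")
    return 100.0 * (found_amount - original_amount) / added_amount


def recovery_summary(table: pd.DataFrame) -> dict:
    """Aggregate a spike-recovery experiment (typically 3 levels × 3 reps).

    ``table`` needs columns original, added, found; returns the mean
    recovery %, its RSD %, n, and the per-row recoveries.
    """
    need = {"original", "added", "found"}
    if not need.issubset(table.columns):
        raise ValueError(f"recovery table must have columns {sorted(need)}")
    recs = np.array([
        recovery(row.original, row.added, row.found)
        for row in table.itertuples()
    ])
    return {
        "mean_recovery_pct": float(recs.mean()),
        "rsd_pct": float(rsd(recs)),
        "n": int(recs.size),
        "recoveries_pct": recs,
    }


@dataclass
class ValidationReport:
    """Per-analyte validation summary in the usual report layout."""

    analyte: str
    curve: CalibrationCurve
    precision_rsd: float | None = None
    repeatability_rsd: float | None = None
    stability_rsd: float | None = None
    recovery_mean: float | None = None
    recovery_rsd: float | None = None
    recovery_n: int | None = None

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "slope": self.curve.slope,
            "intercept": self.curve.intercept,
            "r2": self.curve.r2,
            "range_ug_ml": [self.curve.range_low, self.curve.range_high],
            "lod_ug_ml": self.curve.lod,
            "loq_ug_ml": self.curve.loq,
            "precision_rsd_pct": self.precision_rsd,
            "repeatability_rsd_pct": self.repeatability_rsd,
            "stability_rsd_pct": self.stability_rsd,
            "recovery_mean_pct": self.recovery_mean,
            "recovery_rsd_pct": self.recovery_rsd,
            "recovery_n": self.recovery_n,
        }
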