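"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study's data-producing steps:

* designed-experiment responses drawn from a stated quadratic surface
  plus additive homoscedastic Gaussian noise, for parameter-recovery
  and optimization exercises;
* calibration standards on a known line plus area noise;
* variable-wavelength chromatograms — sums of Gaussian peaks whose
  height is rescaled by a per-peak response factor when the detector
  wavelength switches between retention-time segments — together with
  baseline-subtracted trapezoidal peak integration.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import DesignMatrix
from .rsm import model_matrix

__all__ = ["SurfaceTruth", "WavelengthSchedule", "GaussianPeak",
           "SimChromatogram", "DEFAULT_SCHEDULE", "simulate_bbd_responses",
           "simulate_chromatogram", "integrate_peaks", "simulate_calibration"]


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground-truth quadratic surface for response simulation.

    ``coef`` is the 10-vector on the coded scale in model-matrix order
    [β0, β1, β2, β3, β12, β13, β23, β11, β22, β33].
    """

    coef: tuple
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_bbd_responses(design: DesignMatrix, truth: SurfaceTruth,
                           seed: int) -> pd.DataFrame:
    """Draw one response per run: quadratic(β, x) + N(0, noise_sd)."""
    coef = np.asarray(truth.coef, dtype=float)
    M = model_matrix(design.coded)
    if M.shape[1] != coef.size:
        raise ValueError(f"truth has {coef.size} coefficients for a "
                         f"{M.shape[1]}-column model")
    rng = np.random.default_rng(seed)
    y = M @ coef + rng.normal(0.0, truth.noise_sd, size=design.n_runs)
    return pd.DataFrame({"run_id": design.run_ids, "response": y})


# ---------------------------------------------------------------------------
# chromatogram simulation

@dataclass(frozen=True)
class WavelengthSchedule:
    """Contiguous detector-wavelength segments over the run."""

    segments: tuple  # of (t_start_min, t_end_min, wavelength_nm)

    def __post_init__(self) -> None:
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("empty schedule")
        if segs[0][0] != 0.0:
            raise ValueError("schedule must start at t=0")
        for (a0, a1, _), (b0, b1, _) in zip(segs, segs[1:]):
            if a1 != b0:
                raise ValueError("segments must be contiguous and non-overlapping")
        for t0, t1, _ in segs:
            if t1 <= t0:
                raise ValueError("each segment needs t_end > t_start")

    @property
    def run_end(self) -> float:
        return self.segments[-1][1]

    def wavelength_at(self, t) -> np.ndarray:
        """Active wavelength per time point (boundary belongs to the
        later segment; the run end to the last)."""
        t = np.asarray(t, dtype=float)
        wl = np.empty_like(t)
        for t0, t1, w in self.segments:
            wl[(t >= t0) & (t < t1)] = w
        wl[t >= self.run_end] = self.segments[-1][2]
        return wl


# detector segment table used throughout the worked examples:
# six wavelength windows over a 28-minute gradient run
DEFAULT_SCHEDULE = WavelengthSchedule(segments=(
    (0.0, 7.3, 348.0),
    (7.3, 9.0, 284.0),
    (9.0, 13.0, 330.0),
    (13.0, 23.3, 270.0),
    (23.3, 24.7, 250.0),
    (24.7, 28.0, 280.0),
))


@dataclass(frozen=True)
class GaussianPeak:
    """One chromatographic peak with wavelength-dependent response.

    ``height`` applies at the detection wavelength ``ref_wavelength``;
    at any other wavelength the height is height · response_factors[wl]
    (default factor 1.0 when a wavelength is not listed).
    """

    rt_min: float
    height: float
    sigma_min: float
    ref_wavelength: float | None = None
    response_factors: dict = field(default_factory=dict)

    def height_at(self, wavelength: float) -> float:
        if self.ref_wavelength is None or wavelength == self.ref_wavelength:
            return self.height
        return self.height * float(self.response_factors.get(wavelength, 1.0))


@dataclass
class SimChromatogram:
    """Simulated detector trace plus the peak ground truth."""

    time_min: np.ndarray
    signal: np.ndarray
    peaks: list[GaussianPeak]
    schedule: WavelengthSchedule

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time_min, "signal": self.signal})


def simulate_chromatogram(peaks: list[GaussianPeak],
                          schedule: WavelengthSchedule = DEFAULT_SCHEDULE,
                          baseline_sd: float = 0.0,
                          step_min: float = 0.01,
                          seed: int = 0) -> SimChromatogram:
    """Render Gaussian peaks onto a uniform time grid.

    The active wavelength (hence each peak's effective height) switches
    exactly at the segment boundaries; baseline noise is additive
    Gaussian; the signal is clipped at zero as a detector would.
    """
    run_end = schedule.run_end
    for p in peaks:
        if not 0.0 <= p.rt_min <= run_end:
            raise ValueError(f"peak at {p.rt_min} min outside run window "
                             f"[0, {run_end}]")
    n = int(round(run_end / step_min)) + 1
    t = np.linspace(0.0, run_end, n)
    wl = schedule.wavelength_at(t)
    signal = np.zeros_like(t)
    for p in peaks:
        h = np.zeros_like(t)
        for w in np.unique(wl):
            h[wl == w] = p.height_at(w)
        signal += h * np.exp(-0.5 * ((t - p.rt_min) / p.sigma_min) ** 2)
    if baseline_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, baseline_sd, size=n)
    signal = np.clip(signal, 0.0, None)
    return SimChromatogram(time_min=t, signal=signal, peaks=list(peaks),
                           schedule=schedule)


def integrate_peaks(chrom: SimChromatogram,
                    windows: list[tuple[float, float]]) -> np.ndarray:
    """Baseline-subtracted trapezoidal area per integration window.

    The baseline under each window is the straight line between the
    signal at the window endpoints. Windows must be disjoint and lie
    on the time grid span.
    """
    t, y = chrom.time_min, chrom.signal
    wins = sorted((float(a), float(b)) for a, b in windows)
    for (a0, b0), (a1, b1) in zip(wins, wins[1:]):
        if a1 < b0:
            raise ValueError("integration windows overlap")
    areas = []
    for lo, hi in windows:
        if lo >= hi:
            raise ValueError("window needs t_lo < t_hi")
        if lo < t[0] or hi > t[-1]:
            raise ValueError("window outside the time grid")
        mask = (t >= lo) & (t <= hi)
        tw, yw = t[mask], y[mask]
        baseline = np.interp(tw, [tw[0], tw[-1]], [yw[0], yw[-1]])
        areas.append(float(np.trapezoid(yw - baseline, tw)))
    return np.array(areas)


def simulate_calibration(slope: float, intercept: float, concentrations,
                         noise_sd: float, seed: int) -> pd.DataFrame:
    """Standards on a known line: area = slope·C + intercept + N(0, σ)."""
    c = np.asarray(concentrations, dtype=float).ravel()
    if c.size < 3:
        raise ValueError("need at least 3 concentrations")
    rng = np.random.default_rng(seed)
    areas = slope * c + intercept + rng.normal(0.0, noise_sd, size=c.size)
    return pd.DataFrame({"concentration_ug_ml": c, "peak_area": areas})
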