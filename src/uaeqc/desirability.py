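"""Overall-desirability (OD) aggregation of multiple quality indices.

Each measured index Y_i is normalized to a desirability d_i in [0, 1]
by the linear (Hassan) transform

    larger-better:  d_i = (Y_i − Y_min) / (Y_max − Y_min)
    smaller-better: d_i = (Y_max − Y_i) / (Y_max − Y_min)

with Y_min/Y_max the extremes observed over the runs of the experiment
(or user-supplied fixed bounds). The overall desirability of a run is
the unweighted geometric mean OD = (d_1 d_2 … d_n)^(1/n), so a run
that is worst on any single index scores OD = 0 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesirabilitySpec", "DesirabilityResult", "compute_desirability",
           "single_factor_profile"]

_DIRECTIONS = ("larger_better", "smaller_better")


@dataclass(frozen=True)
class DesirabilitySpec:
    """Directions (and optional fixed bounds) for each quality index."""

    index_names: tuple[str, ...]
    directions: tuple[str, ...]
    bounds: dict = field(default_factory=dict)  # name -> (Ymin, Ymax)

    def __post_init__(self) -> None:
        if len(self.index_names) != len(self.directions):
            raise ValueError("one direction required per index")
        for d in self.directions:
            if d not in _DIRECTIONS:
                raise ValueError(f"direction must be one of {_DIRECTIONS}, got {d!r}")
        for name, (lo, hi) in self.bounds.items():
            if name not in self.index_names:
                raise ValueError(f"bounds given for unknown index {name!r}")
            if not hi > lo:
                raise ValueError(f"index {name!r}: Ymax must exceed Ymin")

    @classmethod
    def all_larger_better(cls, index_names) -> "DesirabilitySpec":
        names = tuple(index_names)
        return cls(names, ("larger_better",) * len(names))


@dataclass
class DesirabilityResult:
    """Per-run desirabilities and their geometric-mean OD."""

    di: pd.DataFrame          # runs × indices, each in [0, 1]
    od: pd.Series             # per-run overall desirability
    ymin: pd.Series
    ymax: pd.Series
    values: pd.DataFrame      # the measured index values

    @property
    def n_indices(self) -> int:
        return self.di.shape[1]


def _as_frame(values, index_names=None) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        return values.astype(float)
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    names = index_names or [f"index_{j + 1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=list(names))


def compute_desirability(values, spec: DesirabilitySpec) -> DesirabilityResult:
    """Normalize an index table to desirabilities and per-run OD values.

    Parameters
    ----------
    values : DataFrame or array-like, shape (n_runs, n_indices)
        Measured index values, one column per index in ``spec`` order.
    spec : DesirabilitySpec
        Direction (and optional fixed bounds) per index.

    Returns
    -------
    DesirabilityResult
        d_i per run and index, and OD = geometric mean across indices.
    """
    table = _as_frame(values, spec.index_names)
    if list(table.columns) != list(spec.index_names):
        table = table[list(spec.index_names)]
    if len(table) < 2:
        raise ValueError("need at least 2 runs to scale desirabilities")
    if table.isna().any().any():
        raise ValueError("missing index values")

    di = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    ymin = pd.Series(index=table.columns, dtype=float)
    ymax = pd.Series(index=table.columns, dtype=float)
    for name, direction in zip(spec.index_names, spec.directions):
        col = table[name].to_numpy()
        if name in spec.bounds:
            lo, hi = spec.bounds[name]
            if ((col < lo) | (col > hi)).any():
                warnings.warn(
                    f"index {name!r}: values outside fixed bounds ({lo}, {hi}) "
                    "clamped to [0, 1]",
                    stacklevel=2,
                )
        else:
            lo, hi = float(col.min()), float(col.max())
            if hi == lo:
                raise ValueError(
                    f"index {name!r} is constant; supply fixed bounds to scale it"
                )
        d = (col - lo) / (hi - lo)
        if direction == "smaller_better":
            d = 1.0 - d
        di[name] = np.clip(d, 0.0, 1.0)
        ymin[name], ymax[name] = lo, hi

    # geometric mean; exact 0 whenever any d_i is 0 (no epsilon floor)
    od = di.prod(axis=1) ** (1.0 / di.shape[1])
    od[(di == 0).any(axis=1)] = 0.0
    return DesirabilityResult(di=di, od=od, ymin=ymin, ymax=ymax, values=table)


def single_factor_profile(levels, values, spec: DesirabilitySpec):
    """OD profile of a one-factor-at-a-time experiment.

    Bounds are taken over the levels of this experiment only. Returns
    a DataFrame of (level, OD) rows plus the level with the highest OD.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2:
        raise ValueError("need at least 2 levels")
    res = compute_desirability(values, spec)
    if len(res.od) != levels.size:
        raise ValueError("one value row required per level")
    profile = pd.DataFrame({"level": levels, "od": res.od.to_numpy()})
    best = float(levels[int(np.argmax(profile["od"].to_numpy()))])
    return profile, best
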