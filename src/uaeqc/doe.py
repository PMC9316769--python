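"""Box–Behnken designs and coded/actual factor-level conversion.

A three-factor Box–Behnken design (BBD) places runs at the midpoints of
the edges of the factor cube — every pair of factors at the −1/+1
levels with the third factor held at its centre — plus replicated
centre points. For k = 3 this gives 12 edge runs; with the customary
5 centre replicates the design has 17 runs. Coded levels −1/0/+1 map
linearly onto the actual low/centre/high settings of each factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FactorSpec", "DesignMatrix", "generate_bbd", "code_levels", "decode_levels"]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its coded-level anchors.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"methanol"``.
    unit : str
        Physical unit, e.g. ``"%"`` or ``"mL/g"``.
    low, center, high : float
        Actual settings mapped to coded −1, 0 and +1.
    """

    name: str
    unit: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        for v in (self.low, self.center, self.high):
            if not np.isfinite(v):
                raise ValueError(f"factor {self.name!r}: non-finite level {v!r}")
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})"
            )
        mid = 0.5 * (self.low + self.high)
        scale = max(abs(self.high), abs(self.low), 1.0)
        if abs(self.center - mid) > 1e-9 * scale:
            warnings.warn(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"of (low, high) = ({self.low}, {self.high}); coded levels will be "
                "asymmetric",
                stacklevel=3,
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual):
        """Map actual level(s) to the coded scale."""
        hr = self.half_range
        if hr == 0:
            raise ValueError(f"factor {self.name!r}: zero half-range")
        return (np.asarray(actual, dtype=float) - self.center) / hr

    def decode(self, coded):
        """Map coded level(s) back to actual units."""
        return self.center + self.half_range * np.asarray(coded, dtype=float)


@dataclass
class DesignMatrix:
    """A designed experiment: coded rows plus factor metadata.

    ``coded`` holds integer −1/0/+1 entries for generated designs so
    that orthogonality and replicate identification are exact.
    """

    factors: list[FactorSpec]
    coded: np.ndarray  # shape (n_runs, k)
    run_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coded = np.atleast_2d(np.asarray(self.coded))
        if self.run_ids is None:
            self.run_ids = np.arange(1, len(self.coded) + 1)
        if self.coded.shape[1] != len(self.factors):
            raise ValueError(
                f"coded matrix has {self.coded.shape[1]} columns for "
                f"{len(self.factors)} factors"
            )

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def actual(self) -> np.ndarray:
        """Actual-unit levels, decoded through each FactorSpec."""
        return np.column_stack(
            [f.decode(self.coded[:, j]) for j, f in enumerate(self.factors)]
        )

    def center_mask(self) -> np.ndarray:
        """True for runs with every coded level exactly zero."""
        return np.all(self.coded == 0, axis=1)

    def to_frame(self, include_coded: bool = True) -> pd.DataFrame:
        cols = {"run_id": self.run_ids}
        act = self.actual
        for j, f in enumerate(self.factors):
            cols[f.name] = act[:, j]
        if include_coded:
            for j, f in enumerate(self.factors):
                cols[f"coded_{f.name}"] = self.coded[:, j]
        return pd.DataFrame(cols)


# canonical edge-block order: factor pairs (0,1),(0,2),(1,2); within each
# pair signs (−,−),(+,−),(−,+),(+,+); centre replicates appended last
_PAIRS = ((0, 1), (0, 2), (1, 2))
_SIGNS = ((-1, -1), (1, -1), (-1, 1), (1, 1))


def generate_bbd(factors: list[FactorSpec], n_center: int = 5) -> DesignMatrix:
    """Generate a three-factor Box–Behnken design.

    Parameters
    ----------
    factors : list of FactorSpec
        Exactly three factors (only k = 3 is supported).
    n_center : int
        Number of centre replicates (≥ 1); 5 gives the classical
        17-run design.

    Returns
    -------
    DesignMatrix
        ``12 + n_center`` runs in a fixed canonical order: edge blocks
        for factor pairs (1,2), (1,3), (2,3), signs (−,−), (+,−),
        (−,+), (+,+) within each block, centre runs last.
    """
    if len(factors) != 3:
        raise ValueError(
            f"generate_bbd supports exactly 3 factors, got {len(factors)}; "
            "other sizes are not implemented"
        )
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")
    rows = []
    for i, j in _PAIRS:
        for si, sj in _SIGNS:
            row = [0, 0, 0]
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend([[0, 0, 0]] * n_center)
    return DesignMatrix(factors=list(factors), coded=np.array(rows, dtype=int))


def code_levels(actual: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Convert actual-unit levels to the coded scale, column per factor."""
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    if actual.shape[1] != len(factors):
        raise ValueError(
            f"{actual.shape[1]} columns for {len(factors)} factors"
        )
    return np.column_stack([f.code(actual[:, j]) for j, f in enumerate(factors)])


def decode_levels(coded: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Inverse of :func:`code_levels`."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    if coded.shape[1] != len(factors):
        raise ValueError(f"{coded.shape[1]} columns for {len(factors)} factors")
    return np.column_stack([f.decode(coded[:, j]) for j, f in enumerate(factors)])
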