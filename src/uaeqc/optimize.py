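"""Bounded maximization of a fitted quadratic response surface.

The fitted surface is maximized over the coded design cube (box
constraints, default [−1, 1]^k) by multi-start L-BFGS-B from all 3^k
lattice points of {−1, 0, 1}^k, with a deterministic shrinking-grid
coordinate refinement as a fallback. Optima on a cube face are flagged
per factor — a boundary optimum means the best setting may lie outside
the experimental region, which the design alone cannot resolve.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .rsm import QuadraticModel

__all__ = ["OptimumResult", "maximize_surface", "round_to_practice"]

_GTOL = 1e-10
_XTOL = 1e-8


@dataclass
class OptimumResult:
    """Constrained maximizer of a quadratic surface."""

    coded: np.ndarray             # x* on the coded scale
    actual: np.ndarray            # X* in factor units
    predicted: float              # model value at x*
    at_boundary: np.ndarray       # per-factor bool: |x_i*| at a bound
    stationary_type: str          # maximum | saddle | minimum (of the quadratic form)
    factor_names: list[str]
    factor_units: list[str]

    def to_dict(self) -> dict:
        return {
            "coded": [float(v) for v in self.coded],
            "actual": {
                n: {"value": float(x), "unit": u}
                for n, x, u in zip(self.factor_names, self.actual, self.factor_units)
            },
            "predicted": float(self.predicted),
            "at_boundary": [bool(b) for b in self.at_boundary],
            "stationary_type": self.stationary_type,
        }


def _classify(A: np.ndarray) -> str:
    eig = np.linalg.eigvalsh(A)
    if np.all(eig < 0):
        return "maximum"
    if np.all(eig > 0):
        return "minimum"
    return "saddle"


def _coordinate_refine(fun, x0, lo, hi, sweeps: int = 60) -> np.ndarray:
    """Deterministic shrinking-grid search along one coordinate at a time."""
    x = x0.copy()
    span = (hi - lo).astype(float)
    for sweep in range(sweeps):
        width = span * 0.5 ** (sweep // x.size)
        i = sweep % x.size
        grid = np.clip(np.linspace(x[i] - width[i], x[i] + width[i], 101), lo[i], hi[i])
        vals = np.array([fun(np.r_[x[:i], g, x[i + 1:]]) for g in grid])
        x[i] = grid[int(np.argmax(vals))]
    return x


def maximize_surface(model: QuadraticModel, bounds=None) -> OptimumResult:
    """Maximize the fitted surface over a coded box.

    Parameters
    ----------
    model : QuadraticModel
    bounds : sequence of (lo, hi) per factor, coded scale
        Defaults to [−1, 1]^k — the design cube. Required when the
        quadratic form is not negative definite (otherwise the maximum
        is unbounded).

    Notes
    -----
    Deterministic: multi-starts are a fixed lattice and ties are broken
    by the coded-lexicographically smallest point.
    """
    k = model.k
    A, b = model.quadratic_form()
    stype = _classify(A)
    if bounds is None:
        if stype != "maximum":
            raise ValueError(
                "quadratic form is not negative definite; the unconstrained "
                "maximum is unbounded — supply bounds"
            )
        bounds = [(-1.0, 1.0)] * k
    lo = np.array([bb[0] for bb in bounds], dtype=float)
    hi = np.array([bb[1] for bb in bounds], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("each bound must satisfy lo < hi")

    coef = model.coef

    def value(x: np.ndarray) -> float:
        return float(coef[0] + b @ x + x @ A @ x)

    def neg(x: np.ndarray) -> float:
        return -value(x)

    def neg_grad(x: np.ndarray) -> np.ndarray:
        return -(b + 2.0 * A @ x)

    candidates: list[np.ndarray] = []
    # closed-form interior stationary point, when it is a maximum
    if stype == "maximum":
        xs = np.linalg.solve(-2.0 * A, b)
        if np.all(xs >= lo - 1e-12) and np.all(xs <= hi + 1e-12):
            candidates.append(np.clip(xs, lo, hi))
    for start in itertools.product((-1.0, 0.0, 1.0), repeat=k):
        x0 = np.clip(np.asarray(start), lo, hi)
        res = minimize(neg, x0, jac=neg_grad, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options={"gtol": _GTOL, "ftol": 1e-14})
        candidates.append(np.clip(res.x, lo, hi))
    candidates.append(_coordinate_refine(value, np.clip(np.zeros(k), lo, hi), lo, hi))

    vals = np.array([value(x) for x in candidates])
    best_val = vals.max()
    # lexicographic tie-break among near-ties for reproducibility
    near = [x for x, v in zip(candidates, vals) if v >= best_val - _XTOL]
    best = min(near, key=lambda x: tuple(np.round(x / _XTOL) * _XTOL))

    actual = np.array([f.decode(best[j]) for j, f in enumerate(model.factors)])
    at_bound = (best <= lo + 1e-9) | (best >= hi - 1e-9)
    return OptimumResult(
        coded=best,
        actual=actual,
        predicted=value(best),
        at_boundary=at_bound,
        stationary_type=stype,
        factor_names=[f.name for f in model.factors],
        factor_units=[f.unit for f in model.factors],
    )


def _snap(x: float, quantum: float) -> float:
    # round-half-away-from-zero on the quotient so e.g. 62.5 → 65 at quantum 5
    q = x / quantum
    return quantum * math.floor(q + 0.5) if q >= 0 else -quantum * math.floor(-q + 0.5)


def round_to_practice(opt: OptimumResult, model: QuadraticModel,
                      rounding: dict) -> OptimumResult:
    """Snap actual optimum levels to operator-friendly increments.

    Parameters
    ----------
    opt : OptimumResult
    model : QuadraticModel
        The model to re-predict at the snapped point.
    rounding : dict
        factor name → quantum in actual units (e.g. ``{"methanol": 5,
        "time": 5}``); factors absent from the dict are left as-is.

    Returns
    -------
    OptimumResult at the snapped point, response re-predicted.
    """
    actual = opt.actual.copy().astype(float)
    for j, name in enumerate(opt.factor_names):
        if name in rounding and rounding[name]:
            actual[j] = _snap(actual[j], float(rounding[name]))
    coded = np.array([f.code(actual[j]) for j, f in enumerate(model.factors)])
    if np.any(np.abs(coded) > 1.0 + 1e-9):
        raise ValueError("snapped point lies outside the coded design cube")
    pred = float(model.predict(coded))
    return OptimumResult(
        coded=coded,
        actual=actual,
        predicted=pred,
        at_boundary=np.abs(coded) >= 1.0 - 1e-9,
        stationary_type=opt.stationary_type,
        factor_names=list(opt.factor_names),
        factor_units=list(opt.factor_units),
    )
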