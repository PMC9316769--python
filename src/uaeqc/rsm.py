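"""Second-order response-surface fitting and ANOVA with lack-of-fit.

The model, on coded variables x_i in [−1, 1],

    Y = β0 + Σ β_i x_i + Σ β_ii x_i² + Σ_{i<j} β_ij x_i x_j

is fitted by ordinary least squares on the 10-column model matrix
[1, x1, x2, x3, x1x2, x1x3, x2x3, x1², x2², x3²] (k = 3). The ANOVA
reports partial (drop-one) sums of squares per term, the model F
against the residual mean square, and — when the design carries
replicated runs — the lack-of-fit / pure-error split of the residual,
with the lack-of-fit F taken against the pure-error mean square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .doe import DesignMatrix, FactorSpec, code_levels

__all__ = ["QuadraticModel", "AnovaTable", "fit_quadratic", "anova",
           "surface_grid", "model_matrix", "term_names"]


def term_names(factor_names: list[str]) -> list[str]:
    """Model-matrix column labels after the intercept."""
    k = len(factor_names)
    names = list(factor_names)
    names += [
        f"{factor_names[i]}:{factor_names[j]}"
        for i in range(k) for j in range(i + 1, k)
    ]
    names += [f"{n}^2" for n in factor_names]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Full quadratic model matrix [1, linear, interactions, squares]."""
    X = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Fitted second-order polynomial on the coded scale."""

    beta0: float
    beta_linear: np.ndarray        # (k,)
    beta_inter: np.ndarray         # (k(k−1)/2,), pairs in (i<j) order
    beta_quad: np.ndarray          # (k,)
    factors: list[FactorSpec]

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def coef(self) -> np.ndarray:
        """Coefficients in model-matrix column order."""
        return np.concatenate(
            [[self.beta0], self.beta_linear, self.beta_inter, self.beta_quad]
        )

    @property
    def term_labels(self) -> list[str]:
        return term_names([f.name for f in self.factors])

    def quadratic_form(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, b) with predict(x) = β0 + bᵀx + xᵀAx; A symmetric."""
        k = self.k
        A = np.diag(self.beta_quad.astype(float))
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                A[i, j] = A[j, i] = 0.5 * self.beta_inter[idx]
                idx += 1
        return A, self.beta_linear.astype(float)

    def predict(self, point, coded: bool = True) -> np.ndarray | float:
        """Evaluate the surface at one or many points.

        Parameters
        ----------
        point : array-like, shape (k,) or (m, k)
        coded : bool
            If False, ``point`` is in actual units and is coded through
            the stored FactorSpecs first.
        """
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        if pts.shape[1] != self.k:
            raise ValueError(f"expected {self.k} coordinates, got {pts.shape[1]}")
        if not coded:
            pts = code_levels(pts, self.factors)
        if np.any(np.abs(pts) > 1.5):
            warnings.warn("prediction point well outside the coded design range",
                          stacklevel=2)
        out = model_matrix(pts) @ self.coef
        return float(out[0]) if np.ndim(point) == 1 else out

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta_linear": list(map(float, self.beta_linear)),
            "beta_inter": list(map(float, self.beta_inter)),
            "beta_quad": list(map(float, self.beta_quad)),
            "factors": [
                {"name": f.name, "unit": f.unit, "low": f.low,
                 "center": f.center, "high": f.high}
                for f in self.factors
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        return cls(
            beta0=float(d["beta0"]),
            beta_linear=np.asarray(d["beta_linear"], dtype=float),
            beta_inter=np.asarray(d["beta_inter"], dtype=float),
            beta_quad=np.asarray(d["beta_quad"], dtype=float),
            factors=[FactorSpec(**f) for f in d["factors"]],
        )


def fit_quadratic(design: DesignMatrix, response) -> QuadraticModel:
    """Least-squares fit of the full quadratic to a designed experiment."""
    y = np.asarray(response, dtype=float).ravel()
    if len(y) != design.n_runs:
        raise ValueError(f"{len(y)} responses for {design.n_runs} runs")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")
    k = design.k
    p = 1 + 2 * k + k * (k - 1) // 2
    if design.n_runs < p:
        raise ValueError(f"need at least {p} runs to fit {p} parameters")
    M = model_matrix(design.coded)
    if np.linalg.matrix_rank(M) < p:
        raise np.linalg.LinAlgError("rank-deficient model matrix")
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    n_inter = k * (k - 1) // 2
    return QuadraticModel(
        beta0=float(beta[0]),
        beta_linear=beta[1:1 + k],
        beta_inter=beta[1 + k:1 + k + n_inter],
        beta_quad=beta[1 + k + n_inter:],
        factors=list(design.factors),
    )


@dataclass
class AnovaTable:
    """Decomposition of a fitted response-surface model (Design-Expert style)."""

    table: pd.DataFrame   # index: source; columns: ss, df, ms, F, p
    r2: float
    r2_adj: float

    def formatted(self) -> pd.DataFrame:
        """Rounded view matching the usual report precision."""
        out = self.table.copy()
        out["ss"] = out["ss"].round(4)
        out["ms"] = out["ms"].round(4)
        out["F"] = out["F"].round(2)
        out["p"] = out["p"].round(4)
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index(names="source")


def _sse(M: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    r = y - M @ beta
    return float(r @ r)


def anova(model: QuadraticModel, design: DesignMatrix, response) -> AnovaTable:
    """Full ANOVA of a fitted quadratic: per-term partial SS, model F,
    lack-of-fit / pure-error split, R² and adjusted R².

    Pure error is pooled over groups of runs with identical coded rows
    (the centre replicates in a BBD); if the design has no replicated
    runs the lack-of-fit rows are omitted with a warning.
    """
    y = np.asarray(response, dtype=float).ravel()
    M = model_matrix(design.coded)
    n, p = M.shape
    sse = _sse(M, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssm = sst - sse
    df_model, df_resid = p - 1, n - p
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ms_model, ms_resid = ssm / df_model, sse / df_resid

    rows: list[dict] = []

    def add(source, ss, df, ms=None, F=None, pval=None):
        rows.append({"source": source, "ss": ss, "df": df,
                     "ms": ms if ms is not None else np.nan,
                     "F": F if F is not None else np.nan,
                     "p": pval if pval is not None else np.nan})

    add("model", ssm, df_model, ms_model, ms_model / ms_resid,
        stats.f.sf(ms_model / ms_resid, df_model, df_resid))

    # partial (drop-one) SS per term against the full-model residual MS
    labels = model.term_labels
    for j, label in enumerate(labels, start=1):
        ss_term = _sse(np.delete(M, j, axis=1), y) - sse
        F = ss_term / ms_resid
        add(label, ss_term, 1, ss_term, F, stats.f.sf(F, 1, df_resid))

    add("residual", sse, df_resid, ms_resid)

    # replicate groups by exact equality of coded rows
    _, inv, counts = np.unique(design.coded, axis=0,
                               return_inverse=True, return_counts=True)
    rep_groups = np.flatnonzero(counts > 1)
    if rep_groups.size:
        ss_pe = 0.0
        df_pe = 0
        for g in rep_groups:
            yg = y[inv == g]
            ss_pe += float(np.sum((yg - yg.mean()) ** 2))
            df_pe += len(yg) - 1
        ss_lof = sse - ss_pe
        df_lof = df_resid - df_pe
        if df_lof > 0 and df_pe > 0:
            ms_lof, ms_pe = ss_lof / df_lof, ss_pe / df_pe
            if ms_pe > 0:
                F_lof = ms_lof / ms_pe
                add("lack_of_fit", ss_lof, df_lof, ms_lof, F_lof,
                    stats.f.sf(F_lof, df_lof, df_pe))
            else:  # exact replicates (noiseless data): F undefined
                add("lack_of_fit", ss_lof, df_lof, ms_lof)
            add("pure_error", ss_pe, df_pe, ms_pe)
    else:
        warnings.warn("no replicated runs: lack-of-fit decomposition skipped",
                      stacklevel=2)

    add("corrected_total", sst, n - 1)

    table = pd.DataFrame(rows).set_index("source")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (sse / df_resid) / (sst / (n - 1))
    return AnovaTable(table=table, r2=r2, r2_adj=r2_adj)


def surface_grid(model: QuadraticModel, factor_i: int, factor_j: int,
                 fixed_levels=None, resolution: int = 41):
    """Predicted-response grid over coded [−1, 1]² for two free factors.

    Remaining factors sit at ``fixed_levels`` (default 0, the centre).
    Returns (xi, xj, Z) with Z[a, b] the prediction at
    (xi[a], xj[b]) — ready for contour or 3-D surface plotting.
    """
    k = model.k
    if factor_i == factor_j:
        raise ValueError("need two distinct factors")
    for f in (factor_i, factor_j):
        if not 0 <= f < k:
            raise IndexError(f"factor index {f} out of range for k={k}")
    base = np.zeros(k) if fixed_levels is None else np.asarray(fixed_levels, float)
    if base.shape != (k,):
        raise ValueError(f"fixed_levels must have length {k}")
    xi = np.linspace(-1.0, 1.0, resolution)
    xj = np.linspace(-1.0, 1.0, resolution)
    pts = np.tile(base, (resolution * resolution, 1))
    gi, gj = np.meshgrid(xi, xj, indexing="ij")
    pts[:, factor_i] = gi.ravel()
    pts[:, factor_j] = gj.ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = np.asarray(model.predict(pts)).reshape(resolution, resolution)
    return xi, xj, Z
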