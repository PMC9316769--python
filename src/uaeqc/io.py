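"""Delimited-table IO, run configuration and pipeline orchestration.

Tables are UTF-8 comma-delimited text with a header row and '.'
decimal separator. ``read_table`` validates a declared schema and
reports (rather than silently drops) rows with unparseable cells.
``run_pipeline`` chains the stages of the extraction-optimization
workflow: desirability → quadratic fit → ANOVA → constrained
optimization, with optional rounding of the optimum to practical
increments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .desirability import DesirabilitySpec, compute_desirability
from .doe import DesignMatrix, FactorSpec
from .optimize import maximize_surface, round_to_practice
from .rsm import anova, fit_quadratic

logger = logging.getLogger("uaeqc")

__all__ = ["SchemaError", "read_table", "write_table", "RunConfig",
           "run_pipeline", "load_config"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path, schema: dict) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a delimited table.

    Parameters
    ----------
    path : path-like
    schema : dict
        column name → "numeric" | "text".

    Returns
    -------
    (table, rejections)
        ``table`` holds the rows that parsed cleanly; ``rejections``
        is a list of human-readable messages, one per dropped row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file; expected columns "
                          f"{sorted(schema)}") from None
    missing = sorted(c for c in schema if c not in df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    rejections: list[str] = []
    bad = np.zeros(len(df), dtype=bool)
    for col, kind in schema.items():
        if kind == "numeric":
            parsed = pd.to_numeric(df[col], errors="coerce")
            for i in np.flatnonzero(parsed.isna() & df[col].notna()):
                rejections.append(
                    f"{path.name} row {i + 2}: non-numeric value "
                    f"{df[col].iloc[i]!r} in column {col!r}"
                )
            bad |= parsed.isna().to_numpy()
            df[col] = parsed
        elif kind != "text":
            raise ValueError(f"unknown schema kind {kind!r}")
    for msg in rejections:
        logger.warning(msg)
    return df.loc[~bad].reset_index(drop=True), rejections


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV preserving numeric values to full precision."""
    df.to_csv(path, index=False, float_format="%.12g")


@dataclass
class RunConfig:
    """Validated configuration for the end-to-end pipeline."""

    design_path: Path
    response_path: Path | None
    factors: list[FactorSpec]
    directions: dict = field(default_factory=dict)  # index name -> direction
    response_column: str | None = None              # use a ready-made OD column
    bounds: tuple = (-1.0, 1.0)
    rounding: dict = field(default_factory=dict)
    seed: int = 20220710
    out_dir: Path = Path("results")

    def validate(self) -> None:
        if not Path(self.design_path).exists():
            raise FileNotFoundError(f"design table not found: {self.design_path}")
        if self.response_path is not None and not Path(self.response_path).exists():
            raise FileNotFoundError(
                f"response table not found: {self.response_path}")
        if self.response_path is None and self.response_column is None:
            raise ValueError("config needs a response table or a response column")
        if len(self.factors) != 3:
            raise ValueError("pipeline expects exactly 3 factors")


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    factors = [FactorSpec(**f) for f in raw["factors"]]

    def _resolve(p):
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    return RunConfig(
        design_path=_resolve(raw["design"]),
        response_path=_resolve(raw.get("responses")),
        factors=factors,
        directions=raw.get("directions", {}),
        response_column=raw.get("response_column"),
        bounds=tuple(raw.get("bounds", (-1.0, 1.0))),
        rounding=raw.get("rounding", {}),
        seed=int(raw.get("seed", 20220710)),
        out_dir=_resolve(raw.get("out_dir", "results")),
    )


def _design_from_table(df: pd.DataFrame, factors: list[FactorSpec]) -> DesignMatrix:
    coded_cols = [f"coded_{f.name}" for f in factors]
    if all(c in df.columns for c in coded_cols):
        coded = df[coded_cols].to_numpy(dtype=float)
        if np.allclose(coded, np.round(coded)):
            coded = coded.astype(int)
    else:
        actual = df[[f.name for f in factors]].to_numpy(dtype=float)
        coded = np.column_stack(
            [f.code(actual[:, j]) for j, f in enumerate(factors)])
    run_ids = (df["run_id"].to_numpy() if "run_id" in df.columns else None)
    return DesignMatrix(factors=factors, coded=coded, run_ids=run_ids)


def run_pipeline(config: RunConfig) -> dict:
    """Execute desirability → fit → ANOVA → optimize and write reports.

    Returns the report bundle as a dict; the same content is written
    under ``config.out_dir`` as JSON/CSV plus a plain-text summary.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    schema = {"run_id": "numeric"}
    schema.update({f.name: "numeric" for f in config.factors})
    design_df, _ = read_table(config.design_path, schema)
    design = _design_from_table(design_df, config.factors)

    if config.response_column is not None:
        source = design_df if config.response_path is None else read_table(
            config.response_path, {config.response_column: "numeric"})[0]
        od = source[config.response_column].to_numpy(dtype=float)
        od_result = None
    else:
        resp_df, _ = read_table(config.response_path, {"run_id": "numeric"})
        index_cols = [c for c in resp_df.columns if c != "run_id"]
        directions = tuple(
            config.directions.get(c, "larger_better") for c in index_cols)
        spec = DesirabilitySpec(tuple(index_cols), directions)
        od_result = compute_desirability(
            resp_df[index_cols].astype(float), spec)
        od = od_result.od.to_numpy()

    logger.info("fitting quadratic surface to %d runs", design.n_runs)
    model = fit_quadratic(design, od)
    table = anova(model, design, od)
    opt = maximize_surface(
        model, bounds=[tuple(config.bounds)] * design.k)
    rounded = (round_to_practice(opt, model, config.rounding)
               if config.rounding else None)

    report = {
        "model": model.to_dict(),
        "r2": table.r2,
        "r2_adj": table.r2_adj,
        "anova": table.to_frame().to_dict(orient="records"),
        "optimum": opt.to_dict(),
        "optimum_rounded": rounded.to_dict() if rounded else None,
        "seed": config.seed,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, allow_nan=True, default=float) + "\n")
    write_table(table.to_frame(), out / "anova.csv")
    if od_result is not None:
        od_frame = od_result.di.assign(od=od_result.od)
        write_table(od_frame, out / "desirability.csv")

    mf = table.table.loc["model"]
    lines = [
        f"runs: {design.n_runs}",
        f"model F = {mf['F']:.2f} (p = {mf['p']:.4g}), "
        f"R2 = {table.r2:.4f}, adj R2 = {table.r2_adj:.4f}",
        "optimum (coded): "
        + ", ".join(f"{v:.4f}" for v in opt.coded),
        "optimum (actual): "
        + ", ".join(
            f"{n} = {x:.2f} {u}" for n, x, u in
            zip(opt.factor_names, opt.actual, opt.factor_units)),
        f"predicted response at optimum: {opt.predicted:.4f}",
    ]
    if rounded:
        lines.append(
            "rounded optimum: "
            + ", ".join(f"{n} = {x:g} {u}" for n, x, u in
                        zip(rounded.factor_names, rounded.actual,
                            rounded.factor_units))
            + f"; predicted {rounded.predicted:.4f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
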