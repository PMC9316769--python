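"""Packaged reference tables from the worked extraction-optimization study.

These small CSVs carry the published experiment: the three-factor
level schedule, the 17-run Box–Behnken design with its overall-
desirability responses, the per-analyte calibration/validation
properties of the eleven marker compounds, and the batch content
table (24 batches × 11 analytes, mean ± sd over triplicate
injections).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .doe import DesignMatrix, FactorSpec

__all__ = ["load_factor_levels", "load_factors", "load_bbd_design",
           "load_calibration_properties", "load_batch_contents"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("uaeqc.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_factor_levels() -> pd.DataFrame:
    """Factor level schedule: name, unit, low/center/high."""
    return _read("factor_levels.csv")


def load_factors() -> list[FactorSpec]:
    """The three extraction factors as FactorSpec objects."""
    return [FactorSpec(**row) for row in load_factor_levels().to_dict("records")]


def load_bbd_design(with_response: bool = True):
    """The published 17-run design.

    Returns (DesignMatrix, od Series) or just the DesignMatrix when
    ``with_response`` is False.
    """
    df = _read("bbd_design_od.csv")
    factors = load_factors()
    coded = df[[f"coded_{f.name}" for f in factors]].to_numpy(dtype=int)
    design = DesignMatrix(factors=factors, coded=coded,
                          run_ids=df["run_id"].to_numpy())
    if with_response:
        return design, df["od"]
    return design


def load_calibration_properties() -> pd.DataFrame:
    """Published per-analyte calibration and validation figures."""
    return _read("calibration_properties.csv")


def load_batch_contents() -> pd.DataFrame:
    """Per-batch, per-analyte contents in mg/g (mean and sd, n = 3)."""
    return _read("batch_contents.csv")
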