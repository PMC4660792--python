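"""Evaluation statistics for hydration free energy predictions.

Includes the bundled transcription of the published 21-molecule IHB
benchmark (experimental vs. calculated dG_hyd with and without the IHB
atom types), used by the regression tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SolvContactError

MODES = ("with_ihb", "no_ihb")


@dataclass(frozen=True)
class PredictionRecord:
    """One experimental/calculated pair (kcal/mol)."""

    name: str
    dg_exp: float
    dg_calc: float
    mode: str = "with_ihb"

    def __post_init__(self):
        if self.mode not in MODES:
            raise SolvContactError(f"unknown mode {self.mode!r}")

    @property
    def error(self) -> float:
        """Unsigned error |dG_exp - dG_calc|."""
        return abs(self.dg_exp - self.dg_calc)

    @property
    def signed_error(self) -> float:
        return self.dg_exp - self.dg_calc


def unsigned_error(dg_exp: float, dg_calc: float) -> float:
    """|dG_exp - dG_calc| in kcal/mol."""
    if not (math.isfinite(dg_exp) and math.isfinite(dg_calc)):
        raise SolvContactError("non-finite energies")
    return abs(dg_exp - dg_calc)


def _signed_errors(records: Sequence[PredictionRecord]) -> np.ndarray:
    if not records:
        raise SolvContactError("empty record list")
    return np.array([r.signed_error for r in records])


def rmse(records: Sequence[PredictionRecord]) -> float:
    """Root mean square error (kcal/mol)."""
    e = _signed_errors(records)
    return float(np.sqrt(np.mean(e ** 2)))


def aue(records: Sequence[PredictionRecord]) -> float:
    """Average unsigned error (kcal/mol)."""
    return float(np.abs(_signed_errors(records)).mean())


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise SolvContactError("need two equal-length vectors of >= 3 values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise SolvContactError("degenerate (zero-variance) input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def load_ihb_benchmark() -> pd.DataFrame:
    """The bundled 21-compound IHB benchmark table.

    Columns: compound, subset, dg_exp, dg_calc_no_ihb, error_no_ihb,
    dg_calc_ihb, error_ihb (energies in kcal/mol).
    """
    with resources.files("solvcontact.data").joinpath(
            "table2_ihb_molecules.csv").open() as fh:
        return pd.read_csv(fh)


def benchmark_records(mode: str = "with_ihb") -> list[PredictionRecord]:
    """The benchmark as PredictionRecords for one evaluation mode."""
    if mode not in MODES:
        raise SolvContactError(f"unknown mode {mode!r}")
    df = load_ihb_benchmark()
    col = "dg_calc_ihb" if mode == "with_ihb" else "dg_calc_no_ihb"
    return [PredictionRecord(str(row.compound), row.dg_exp, getattr(row, col), mode)
            for row in df.itertuples(index=False)]


def evaluate(records: Sequence[PredictionRecord]) -> dict[str, float]:
    """RMSE, AUE and R^2 for a set of predictions."""
    out = {"n": float(len(records)), "rmse": rmse(records), "aue": aue(records)}
    if len(records) >= 3:
        out["r_squared"] = r_squared([r.dg_exp for r in records],
                                     [r.dg_calc for r in records])
    return out
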