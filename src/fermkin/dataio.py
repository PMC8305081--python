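"""Tabular containers and CSV I/O for fermentation data.

Two table shapes are supported:

* a replicated fermentation time course (sampling time in hours against
  per-time mean / SD / replicate count for pH, titratable acidity,
  glucose and plate counts), and
* a three-factor inoculum design table (2^3 corners plus an optional
  center point, with mean / SD / n per response).

CSV convention: comma separated, ``.`` decimal, UTF-8, one header row.
Each summarised variable occupies three columns named ``<var>_mean``,
``<var>_sd`` and ``<var>_n``; a missing ``<var>_n`` column defaults to
triplicate readings (n = 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, SchemaError

__all__ = [
    "Replicated",
    "FermentationTimeSeries",
    "FactorialDesignTable",
    "TitrationRecord",
    "load_timeseries_csv",
    "load_design_csv",
    "write_timeseries_csv",
    "write_design_csv",
    "builtin_fixture",
    "TIMESERIES_VARIABLES",
    "DESIGN_RESPONSES",
]

#: canonical variable names of a slurry fermentation time course
TIMESERIES_VARIABLES = ("pH", "tta_pct", "glucose_pct", "lab_log10cfu", "tvc_log10cfu")

#: canonical response names of the inoculum design table
DESIGN_RESPONSES = ("pH", "tta_pct", "viscosity_mPas")

#: variables constrained to be non-negative (concentrations)
_NONNEGATIVE_VARS = frozenset({"tta_pct", "glucose_pct", "viscosity_mPas"})

_DEFAULT_N = 3


@dataclass(eq=False)
class Replicated:
    """Per-observation summary of replicated measurements: mean, SD, n."""

    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (self.mean.shape == self.sd.shape == self.n.shape):
            raise SchemaError("mean, sd and n must have identical shapes")
        if np.any(self.sd < 0):
            raise DataValidationError("standard deviations must be >= 0")
        if np.any(self.n < 1):
            raise DataValidationError("replicate counts must be >= 1")

    def __len__(self):
        return self.mean.size


@dataclass(eq=False)
class FermentationTimeSeries:
    """Replicated multi-variable time course of one fermentation batch."""

    time_h: np.ndarray
    variables: Dict[str, Replicated]
    batch_label: str = ""

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.size == 0:
            raise SchemaError("time_h must be a non-empty 1-D sequence")
        diffs = np.diff(self.time_h)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise DataValidationError(
                f"sampling times must be strictly increasing; row {i + 1} "
                f"(t={self.time_h[i + 1]:g} h) repeats or precedes row {i} "
                f"(t={self.time_h[i]:g} h)"
            )
        for name, rep in self.variables.items():
            if len(rep) != self.time_h.size:
                raise SchemaError(
                    f"variable {name!r} has {len(rep)} values for "
                    f"{self.time_h.size} time points"
                )
            if name in _NONNEGATIVE_VARS and np.any(rep.mean < 0):
                raise DataValidationError(f"variable {name!r} must be >= 0")

    @property
    def n_times(self) -> int:
        return self.time_h.size

    def means(self, variable: str) -> np.ndarray:
        return self.variables[variable].mean

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.time_h}
        for name, rep in self.variables.items():
            data[f"{name}_mean"] = rep.mean
            data[f"{name}_sd"] = rep.sd
            data[f"{name}_n"] = rep.n
        return pd.DataFrame(data)


@dataclass(eq=False)
class FactorialDesignTable:
    """Inoculum levels (three factors) against replicated response summaries."""

    levels: np.ndarray  # (n_runs, 3) factor concentrations, % w/w
    responses: Dict[str, Replicated]
    factor_names: Tuple[str, str, str] = ("x1", "x2", "x3")

    def __post_init__(self):
        self.levels = np.atleast_2d(np.asarray(self.levels, dtype=float))
        if self.levels.shape[1] != 3:
            raise SchemaError("exactly three factor columns are required")
        if np.any(self.levels <= 0):
            raise DataValidationError("all inoculum levels must be > 0")
        if len(tuple(self.factor_names)) != 3:
            raise SchemaError("exactly three factor names are required")
        self.factor_names = tuple(self.factor_names)
        for name, rep in self.responses.items():
            if len(rep) != self.n_runs:
                raise SchemaError(
                    f"response {name!r} has {len(rep)} values for {self.n_runs} runs"
                )
            if name in _NONNEGATIVE_VARS and np.any(rep.mean < 0):
                raise DataValidationError(f"response {name!r} must be >= 0")

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    def means(self, response: str) -> np.ndarray:
        return self.responses[response].mean

    def to_frame(self) -> pd.DataFrame:
        data = {
            "x1": self.levels[:, 0],
            "x2": self.levels[:, 1],
            "x3": self.levels[:, 2],
        }
        for name, rep in self.responses.items():
            data[f"{name}_mean"] = rep.mean
            data[f"{name}_sd"] = rep.sd
            data[f"{name}_n"] = rep.n
        return pd.DataFrame(data)


@dataclass(frozen=True)
class TitrationRecord:
    """One NaOH titration of a fermenting sample.

    ``lactic_equivalent_mg`` is the milligram-equivalent factor of lactic
    acid (90.08 mg per milliequivalent for 0.1 M NaOH titrations).
    """

    naoh_ml: float
    naoh_molarity: float = 0.1
    sample_ml: float = 10.0
    lactic_equivalent_mg: float = 90.08

    def __post_init__(self):
        if self.naoh_ml < 0:
            raise DataValidationError("titrant volume must be >= 0 mL")
        for name in ("naoh_molarity", "sample_ml", "lactic_equivalent_mg"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"{name} must be > 0")


def _extract_replicated(df: pd.DataFrame, label: str) -> Dict[str, Replicated]:
    """Collect <var>_mean/_sd/_n triplets from a parsed frame."""
    out: Dict[str, Replicated] = {}
    for col in df.columns:
        if not col.endswith("_mean"):
            continue
        var = col[: -len("_mean")]
        sd_col = f"{var}_sd"
        if sd_col not in df.columns:
            raise SchemaError(f"{label}: column {sd_col!r} missing for {col!r}")
        n_col = f"{var}_n"
        n = df[n_col].to_numpy() if n_col in df.columns else np.full(len(df), _DEFAULT_N)
        mean = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        sd = pd.to_numeric(df[sd_col], errors="raise").to_numpy(dtype=float)
        out[var] = Replicated(mean=mean, sd=sd, n=n)
    if not out:
        raise SchemaError(f"{label}: no <var>_mean columns found")
    return out


def load_timeseries_csv(path: Union[str, Path]) -> FermentationTimeSeries:
    """Read a fermentation time course from CSV and validate it.

    Rows are sorted by time before validation, so only genuinely
    duplicated sampling times are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise SchemaError(f"{path.name}: required column 'time_h' missing")
    df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
    times = pd.to_numeric(df["time_h"], errors="raise").to_numpy(dtype=float)
    variables = _extract_replicated(df, path.name)
    return FermentationTimeSeries(time_h=times, variables=variables, batch_label=path.stem)


def load_design_csv(path: Union[str, Path]) -> FactorialDesignTable:
    """Read a three-factor inoculum design table from CSV and validate it."""
    path = Path(path)
    df = pd.read_csv(path)
    factor_cols = [
        c
        for c in df.columns
        if not (c.endswith("_mean") or c.endswith("_sd") or c.endswith("_n"))
    ]
    if len(factor_cols) < 3:
        raise SchemaError(
            f"{path.name}: expected three factor columns, found {factor_cols!r}"
        )
    factor_cols = factor_cols[:3]
    levels = df[factor_cols].apply(pd.to_numeric, axis=0).to_numpy(dtype=float)
    responses = _extract_replicated(df, path.name)
    return FactorialDesignTable(
        levels=levels, responses=responses, factor_names=tuple(factor_cols)
    )


def write_timeseries_csv(series: FermentationTimeSeries, path: Union[str, Path]) -> None:
    series.to_frame().to_csv(path, index=False)


def write_design_csv(design: FactorialDesignTable, path: Union[str, Path]) -> None:
    design.to_frame().to_csv(path, index=False)


_FIXTURE_FILES = {
    "table1": "table1_slurry_timeseries.csv",
    "table6": "table6_inoculum_design.csv",
}


def builtin_fixture(name: str):
    """Return a bundled reference table by short name.

    ``"table1"`` is the 36-h pearl-millet slurry fermentation time course
    (13 sampling times at 3-h intervals, five variables, triplicate
    readings); ``"table6"`` is the starter-culture inoculum design table
    (2^3 corners at 0.05 / 0.10 % w/w plus the 0.075 % center, three
    responses, triplicate readings).
    """
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        ) from None
    ref = resources.files("fermkin.data").joinpath(fname)
    with resources.as_file(ref) as p:
        if name == "table1":
            ts = load_timeseries_csv(p)
            ts.batch_label = "pearl-millet slurry, 37 C natural fermentation"
            return ts
        return load_design_csv(p)
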