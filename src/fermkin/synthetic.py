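"""Seeded synthetic-data generators with known ground truth.

Both experimental table shapes are emulated by forward-evaluating the
fitted models and adding i.i.d. Gaussian replicate noise, then storing
the per-cell mean / SD / n exactly as a bench notebook would.  Defaults
mirror the reference fermentation study: a 36-h time course sampled
every 3 h in triplicate, and a 2^3 inoculum design at 0.05/0.10 % w/w
with a 0.075 % center point, with replicate noise at the magnitude of
the published cell SDs.

The generators let parameter-recovery and pipeline tests run with no
external data: fit a generated table and compare against the truth in
the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .dataio import (
    _NONNEGATIVE_VARS,
    FactorialDesignTable,
    FermentationTimeSeries,
    Replicated,
)
from .factorial import ModelSpec, build_design_matrix
from .growth import GompertzParams, eval_gompertz
from .kinetics import eval_exponential

__all__ = [
    "TimeSeriesSimConfig",
    "DesignSimConfig",
    "synth_timeseries",
    "synth_design",
    "DEFAULT_EXPONENTIAL_TRUTH",
    "DEFAULT_GOMPERTZ_TRUTH",
    "DEFAULT_QUADRATIC_TRUTH",
    "DEFAULT_DESIGN_TRUTH",
]

#: exponential (a, b, c) truths for the acid variables, from the
#: reference pH/TTA fits
DEFAULT_EXPONENTIAL_TRUTH: Dict[str, Tuple[float, float, float]] = {
    "pH": (3.382, -3.188, 0.071),
    "tta_pct": (0.663, 0.575, 0.042),
}

#: Gompertz truths for the count variables.  The TVC set is the
#: published fit; the LAB set is a self-consistent curve matching the
#: observed ~1.1-log rise and ~3.9-h apparent lag (the published LAB
#: rise parameter is not internally consistent with its own data).
DEFAULT_GOMPERTZ_TRUTH: Dict[str, GompertzParams] = {
    "lab_log10cfu": GompertzParams(K=6.97, A=1.05, mu_max=0.20, lag=3.9),
    "tvc_log10cfu": GompertzParams(K=6.911, A=0.790, mu_max=0.202, lag=0.0),
}

#: quadratic (c0, c1, c2) truth for glucose release
DEFAULT_QUADRATIC_TRUTH: Tuple[float, float, float] = (0.584, 0.107, -0.002)

#: replicate noise SD per variable, at the magnitude of the published
#: per-cell SDs
_DEFAULT_NOISE_SD: Dict[str, float] = {
    "pH": 0.09,
    "tta_pct": 0.02,
    "glucose_pct": 0.06,
    "lab_log10cfu": 0.50,
    "tvc_log10cfu": 0.20,
}

#: factorial-model coefficient truths per response (natural units), from
#: the reference starter-culture fits; viscosity carries the three-way term
DEFAULT_DESIGN_TRUTH: Dict[str, Dict[str, float]] = {
    "pH": {
        "intercept": 3.44, "x1": 1.28, "x2": 4.41, "x3": -2.73,
        "x1x2": -63.00, "x1x3": 55.00, "x2x3": -2.33,
    },
    "tta_pct": {
        "intercept": 0.686, "x1": -2.383, "x2": -1.15, "x3": 1.05,
        "x1x2": 32.0, "x1x3": -4.667, "x2x3": -12.667,
    },
    "viscosity_mPas": {
        "intercept": 34.44, "x1": -347.18, "x2": -183.45, "x3": -400.45,
        "x1x2": 1742.13, "x1x3": 4020.87, "x2x3": 2494.20,
        "x1x2x3": -13017.33,
    },
}

#: residual dispersion per response (variance scale of the reference fits)
_DEFAULT_RESIDUAL_SD: Dict[str, float] = {
    "pH": float(np.sqrt(0.027)),
    "tta_pct": float(np.sqrt(0.003)),
    "viscosity_mPas": float(np.sqrt(12.49)),
}

_DEFAULT_LEVELS = (
    (0.050, 0.050, 0.050),
    (0.050, 0.050, 0.100),
    (0.050, 0.100, 0.050),
    (0.050, 0.100, 0.100),
    (0.075, 0.075, 0.075),
    (0.100, 0.050, 0.050),
    (0.100, 0.050, 0.100),
    (0.100, 0.100, 0.050),
    (0.100, 0.100, 0.100),
)


@dataclass
class TimeSeriesSimConfig:
    """Ground truth and noise model for a synthetic fermentation batch."""

    sampling_times: Sequence[float] = tuple(range(0, 37, 3))
    exponential_truth: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXPONENTIAL_TRUTH)
    )
    gompertz_truth: Dict[str, GompertzParams] = field(
        default_factory=lambda: dict(DEFAULT_GOMPERTZ_TRUTH)
    )
    quadratic_truth: Optional[Tuple[float, float, float]] = DEFAULT_QUADRATIC_TRUTH
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_SD)
    )
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be strictly increasing")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd entries must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class DesignSimConfig:
    """Ground truth and noise model for a synthetic inoculum design."""

    levels: Sequence[Sequence[float]] = _DEFAULT_LEVELS
    coefficient_truth: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DESIGN_TRUTH.items()}
    )
    residual_sd: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RESIDUAL_SD)
    )
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ValueError("residual_sd entries must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _truth_curves(cfg: TimeSeriesSimConfig, t: np.ndarray) -> Dict[str, np.ndarray]:
    curves: Dict[str, np.ndarray] = {}
    for var, (a, b, c) in cfg.exponential_truth.items():
        curves[var] = eval_exponential(a, b, c, t)
    for var, p in cfg.gompertz_truth.items():
        curves[var] = eval_gompertz(p, t)
    if cfg.quadratic_truth is not None:
        c0, c1, c2 = cfg.quadratic_truth
        curves["glucose_pct"] = c0 + c1 * t + c2 * t * t
    return curves


def _summarise(values: np.ndarray, noise_sd: float) -> Tuple[np.ndarray, np.ndarray]:
    """Cell mean and SD (ddof=1 when replicated) over the replicate axis.

    With zero noise the replicates are identical by construction, so the
    SD column is exactly zero rather than floating-point dust.
    """
    mean = values.mean(axis=1)
    if values.shape[1] > 1 and noise_sd > 0:
        sd = values.std(axis=1, ddof=1)
    else:
        sd = np.zeros(values.shape[0])
    return mean, sd


def synth_timeseries(cfg: TimeSeriesSimConfig) -> FermentationTimeSeries:
    """Generate a replicated fermentation time course from known truth.

    Each replicate observation is the forward-model value plus i.i.d.
    Gaussian noise; the table stores per-time mean, SD and n.  Identical
    configs (including seed) give identical tables.
    """
    t = np.asarray(cfg.sampling_times, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    variables: Dict[str, Replicated] = {}
    for var, curve in _truth_curves(cfg, t).items():
        sd = cfg.noise_sd.get(var, 0.0)
        reps = curve[:, None] + rng.normal(0.0, sd, size=(t.size, cfg.n_replicates))
        if var in _NONNEGATIVE_VARS:
            reps = np.clip(reps, 0.0, None)
        mean, cell_sd = _summarise(reps, sd)
        variables[var] = Replicated(
            mean=mean, sd=cell_sd, n=np.full(t.size, cfg.n_replicates)
        )
    return FermentationTimeSeries(
        time_h=t, variables=variables, batch_label=f"synthetic seed={cfg.seed}"
    )


def synth_design(cfg: DesignSimConfig) -> FactorialDesignTable:
    """Generate a replicated inoculum design table from known truth."""
    levels = np.atleast_2d(np.asarray(cfg.levels, dtype=float))
    rng = np.random.default_rng(cfg.seed)
    responses: Dict[str, Replicated] = {}
    for resp, coeffs in cfg.coefficient_truth.items():
        spec = ModelSpec(include_three_way="x1x2x3" in coeffs)
        X = build_design_matrix(levels, spec)
        beta = np.array([coeffs[term] for term in spec.terms])
        truth = X @ beta
        sd = cfg.residual_sd.get(resp, 0.0)
        reps = truth[:, None] + rng.normal(
            0.0, sd, size=(levels.shape[0], cfg.n_replicates)
        )
        if resp in _NONNEGATIVE_VARS:
            # a rheometer cannot read below zero; truncate like the bench would
            reps = np.clip(reps, 0.0, None)
        mean, cell_sd = _summarise(reps, sd)
        responses[resp] = Replicated(
            mean=mean, sd=cell_sd, n=np.full(levels.shape[0], cfg.n_replicates)
        )
    return FactorialDesignTable(levels=levels, responses=responses)
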