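"""End-to-end analysis orchestration and the machine-readable report.

``run_all`` chains the full fermentation analysis — acid kinetics,
growth curves, plateau detection, factorial starter-culture models,
Monte Carlo propagation and a Pearson association summary — over a time
course and a design table, and returns a deterministic, JSON-ready
report keyed by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from . import __version__
from .dataio import (
    FactorialDesignTable,
    FermentationTimeSeries,
    load_design_csv,
    load_timeseries_csv,
)
from .exceptions import DegenerateVarianceError, FermkinError
from .factorial import GLMFit, ModelSpec, fit_glm
from .growth import fit_gompertz
from .kinetics import fit_exponential, fit_quadratic, plateau_time
from .montecarlo import DEFAULT_RANGES, run_monte_carlo

__all__ = ["AnalysisConfig", "PipelineStageError", "pearson_matrix", "run_all"]

log = logging.getLogger("fermkin")

#: conventional |r| bands for qualitative correlation strength
_STRENGTH_BANDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (np.inf, "very strong"),
)


class PipelineStageError(FermkinError):
    """A pipeline stage failed; carries the stage name and partial report."""

    def __init__(self, stage: str, cause: Exception, partial_report: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_report = partial_report


@dataclass
class AnalysisConfig:
    """Knobs of the full pipeline (YAML-mappable)."""

    alpha: float = 0.05
    exponential_variables: Tuple[str, ...] = ("pH", "tta_pct")
    quadratic_variables: Tuple[str, ...] = ("glucose_pct",)
    gompertz_variables: Tuple[str, ...] = ("lab_log10cfu", "tvc_log10cfu")
    plateau_variables: Tuple[str, ...] = ("pH", "tta_pct")
    glm_responses: Tuple[str, ...] = ("pH", "tta_pct", "viscosity_mPas")
    three_way_responses: Tuple[str, ...] = ("viscosity_mPas",)
    correlation_variables: Tuple[str, ...] = (
        "pH", "tta_pct", "glucose_pct", "lab_log10cfu", "tvc_log10cfu"
    )
    mc_n_cases: int = 1000
    mc_ranges: Tuple[Tuple[float, float], ...] = DEFAULT_RANGES
    seed: int = 42

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        return cfg


def strength_label(r: float) -> str:
    """Qualitative label for a correlation: magnitude band plus sign."""
    mag = abs(r)
    for bound, word in _STRENGTH_BANDS:
        if mag < bound or bound is np.inf:
            label = word
            break
    sign = "positive" if r > 0 else ("negative" if r < 0 else "zero")
    return f"{label}, {sign}"


def pearson_matrix(
    series: FermentationTimeSeries, variables: Sequence[str]
) -> Tuple[np.ndarray, Dict[str, str]]:
    """Pairwise Pearson correlations of time-point means, with labels.

    Returns the symmetric correlation matrix (unit diagonal) in the
    order of ``variables`` and a dict of qualitative strength labels
    keyed ``"var1|var2"`` for each unordered pair.
    """
    if series.n_times < 3:
        raise ValueError("need at least 3 shared time points")
    data = []
    for v in variables:
        col = series.means(v)
        if np.ptp(col) == 0.0:
            raise DegenerateVarianceError(f"variable {v!r} has zero variance")
        data.append(col)
    mat = np.corrcoef(np.vstack(data))
    mat = np.atleast_2d(mat)
    labels = {}
    for i, vi in enumerate(variables):
        for j in range(i + 1, len(variables)):
            labels[f"{vi}|{variables[j]}"] = strength_label(float(mat[i, j]))
    return mat, labels


def _round_floats(obj, ndigits=10):
    """Normalise floats for byte-stable JSON across platforms."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def _exp_fit_dict(fit) -> dict:
    return {
        "a": fit.a, "b": fit.b, "c": fit.c,
        "se_a": fit.se_a, "se_b": fit.se_b, "se_c": fit.se_c,
        "r2": fit.r2, "n_points": fit.n_points, "converged": fit.converged,
        "residuals": fit.residuals,
    }


def _glm_fit_dict(fit: GLMFit) -> dict:
    return {
        "terms": {
            term: {
                "estimate": ce.estimate, "se": ce.se,
                "ci_lower": ce.ci_lower, "ci_upper": ce.ci_upper,
                "p_value": ce.p_value,
            }
            for term, ce in fit.coefficients.items()
        },
        "scale": fit.scale,
        "n_obs": fit.n_obs,
        "dof_residual": fit.dof_residual,
        "three_way": fit.spec.include_three_way,
    }


def _sha256(path: Optional[Union[str, Path]]) -> Optional[str]:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(
    timeseries: Union[str, Path, FermentationTimeSeries],
    design: Union[str, Path, FactorialDesignTable],
    config: Optional[AnalysisConfig] = None,
) -> dict:
    """Run the full analysis and return a JSON-ready report dict.

    Accepts CSV paths or already-validated tables.  The report is
    deterministic for a given config (Monte Carlo seeds derive from
    ``config.seed``); any stage failure raises ``PipelineStageError``
    carrying the stage name and the partial report built so far.
    """
    cfg = config or AnalysisConfig()
    ts_path = d_path = None
    if not isinstance(timeseries, FermentationTimeSeries):
        ts_path, timeseries = timeseries, load_timeseries_csv(timeseries)
    if not isinstance(design, FactorialDesignTable):
        d_path, design = design, load_design_csv(design)

    report: dict = {
        "software": {"name": "fermkin", "version": __version__},
        "inputs": {
            "timeseries_sha256": _sha256(ts_path),
            "design_sha256": _sha256(d_path),
            "n_times": timeseries.n_times,
            "n_design_runs": design.n_runs,
        },
        "seeds": {"base": cfg.seed},
        "config": {
            "alpha": cfg.alpha,
            "mc_n_cases": cfg.mc_n_cases,
            "mc_ranges": [list(r) for r in cfg.mc_ranges],
        },
    }

    def stage(name):
        log.info("running stage %s", name)

        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineStageError(name, exc, report) from exc
        return wrap

    t = timeseries.time_h
    kin = {}
    for var in cfg.exponential_variables:
        fit = stage(f"kinetics:{var}")(
            lambda v=var: fit_exponential(t, timeseries.means(v))
        )
        kin[var] = {"model": "exponential", **_exp_fit_dict(fit)}
    for var in cfg.quadratic_variables:
        qf = stage(f"kinetics:{var}")(
            lambda v=var: fit_quadratic(t, timeseries.means(v))
        )
        kin[var] = {
            "model": "quadratic",
            "c0": qf.c0, "c1": qf.c1, "c2": qf.c2,
            "r2": qf.r2, "n_points": qf.n_points,
        }
    report["kinetics"] = kin

    growth = {}
    for var in cfg.gompertz_variables:
        gp = stage(f"growth:{var}")(
            lambda v=var: fit_gompertz(t, timeseries.means(v))
        )
        growth[var] = {
            "K": gp.K, "A": gp.A, "mu_max": gp.mu_max, "lag": gp.lag,
            "e_pct": gp.e_pct,
        }
    report["growth"] = growth

    report["plateau"] = {
        var: stage(f"plateau:{var}")(
            lambda v=var: plateau_time(timeseries, v, cfg.alpha)
        )
        for var in cfg.plateau_variables
    }

    glm_section = {}
    mc_section = {}
    seeder = np.random.SeedSequence(cfg.seed)
    for resp in cfg.glm_responses:
        spec = ModelSpec(include_three_way=resp in cfg.three_way_responses)
        fit = stage(f"glm:{resp}")(lambda r=resp, s=spec: fit_glm(design, r, s))
        glm_section[resp] = _glm_fit_dict(fit)
        mc_seed = int(seeder.spawn(1)[0].generate_state(1)[0] % (2**31))
        mc = stage(f"mc:{resp}")(
            lambda f=fit, s=mc_seed: run_monte_carlo(
                f, n_cases=cfg.mc_n_cases, ranges=cfg.mc_ranges, seed=s
            )
        )
        mc_section[resp] = {
            "n_cases": mc.n_cases,
            "seed": mc.seed,
            "percentiles": {str(q): v for q, v in mc.percentiles.items()},
            "correlations": mc.sensitivity,
            "contribution_pct": mc.contribution_pct,
        }
        report["seeds"][f"mc:{resp}"] = mc_seed
    report["glm"] = glm_section
    report["monte_carlo"] = mc_section

    mat, labels = stage("correlation")(
        lambda: pearson_matrix(timeseries, cfg.correlation_variables)
    )
    report["correlation"] = {
        "variables": list(cfg.correlation_variables),
        "matrix": mat,
        "labels": labels,
    }
    return _round_floats(report)


def report_to_json(report: dict) -> str:
    """Canonical JSON encoding (sorted keys); byte-identical across reruns."""
    return json.dumps(report, sort_keys=True, indent=2)
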