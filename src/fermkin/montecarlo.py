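"""Monte Carlo uncertainty propagation and factor sensitivity.

Inoculum concentrations are drawn i.i.d. uniform over per-factor ranges
(default: the experimental range 0.05-0.10 % w/w per culture), pushed
through a fitted factorial model with no residual noise added, and the
resulting response distribution is summarised by percentiles.  Factor
influence is ranked tornado-style by the correlation between each
factor's draws and the predictions (Spearman by default, Pearson as an
option), with a normalised contribution-to-variation share
contribution_i = 100 * r_i^2 / sum_j r_j^2 that sums to 100 across the
three factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .exceptions import DegenerateVarianceError
from .factorial import GLMFit, ModelSpec, build_design_matrix

__all__ = [
    "MonteCarloResult",
    "sample_uniform",
    "propagate",
    "percentile",
    "sensitivity",
    "run_monte_carlo",
    "DEFAULT_RANGES",
]

#: experimental inoculum range per culture, % w/w
DEFAULT_RANGES = ((0.05, 0.10), (0.05, 0.10), (0.05, 0.10))

DEFAULT_PERCENTILES = (1.0, 5.0, 50.0, 95.0, 99.0)


@dataclass(eq=False)
class MonteCarloResult:
    n_cases: int
    seed: int
    samples: np.ndarray          # (n, 3) factor draws
    predictions: np.ndarray      # (n,) model responses
    percentiles: Dict[float, float]
    sensitivity: Dict[str, float]       # factor -> correlation
    contribution_pct: Dict[str, float]  # factor -> share of explained variation


def sample_uniform(
    n: int,
    ranges: Sequence[Tuple[float, float]] = DEFAULT_RANGES,
    seed: int = 0,
) -> np.ndarray:
    """Reproducible i.i.d. uniform draws, one column per factor."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = tuple(ranges)
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"invalid range ({lo}, {hi}): lo > hi")
    rng = np.random.default_rng(seed)
    lo = np.array([r[0] for r in ranges])
    hi = np.array([r[1] for r in ranges])
    return rng.uniform(lo, hi, size=(n, len(ranges)))


def _coeff_vector(fit: Union[GLMFit, Dict[str, float]]) -> Tuple[np.ndarray, ModelSpec]:
    """Accept a fitted model or a plain term->estimate mapping."""
    if isinstance(fit, GLMFit):
        spec = fit.spec
        beta = np.array([fit.coefficients[t].estimate for t in spec.terms])
        return beta, spec
    est = dict(fit)
    spec = ModelSpec(include_three_way="x1x2x3" in est)
    beta = np.array([est[t] for t in spec.terms])
    return beta, spec


def propagate(fit: Union[GLMFit, Dict[str, float]], samples: np.ndarray) -> np.ndarray:
    """Model predictions for each sampled factor triple (no residual noise)."""
    beta, spec = _coeff_vector(fit)
    X = build_design_matrix(samples, spec)
    return X @ beta


def percentile(predictions: Sequence[float], q: float) -> float:
    """Linear-interpolation empirical quantile at q percent."""
    if not 0 < q < 100:
        raise ValueError("q must be inside (0, 100)")
    p = np.asarray(predictions, dtype=float)
    if p.size == 0:
        raise ValueError("predictions must be non-empty")
    return float(np.percentile(p, q))


def sensitivity(
    samples: np.ndarray,
    predictions: Sequence[float],
    factor_names: Sequence[str] = ("x1", "x2", "x3"),
    method: str = "spearman",
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Tornado correlations and normalised contribution shares per factor."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    p = np.asarray(predictions, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 cases for sensitivity")
    if np.ptp(p) == 0.0:
        raise DegenerateVarianceError(
            "predictions have zero variance; sensitivity is undefined"
        )
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    corrs = {}
    for j, name in enumerate(factor_names):
        col = samples[:, j]
        if np.ptp(col) == 0.0:
            corrs[name] = 0.0  # frozen factor cannot rank-correlate
            continue
        if method == "spearman":
            r = stats.spearmanr(col, p).statistic
        else:
            r = stats.pearsonr(col, p).statistic
        corrs[name] = float(r)
    total = sum(r * r for r in corrs.values())
    if total == 0.0:
        contrib = {name: 100.0 / len(corrs) for name in corrs}
    else:
        contrib = {name: 100.0 * r * r / total for name, r in corrs.items()}
    return corrs, contrib


def run_monte_carlo(
    fit: Union[GLMFit, Dict[str, float]],
    n_cases: int = 1000,
    ranges: Sequence[Tuple[float, float]] = DEFAULT_RANGES,
    seed: int = 0,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    method: str = "spearman",
) -> MonteCarloResult:
    """Sample, propagate and summarise in one call."""
    samples = sample_uniform(n_cases, ranges, seed)
    preds = propagate(fit, samples)
    pct = {float(q): percentile(preds, q) for q in percentiles}
    corrs, contrib = sensitivity(samples, preds, method=method)
    return MonteCarloResult(
        n_cases=n_cases,
        seed=seed,
        samples=samples,
        predictions=preds,
        percentiles=pct,
        sensitivity=corrs,
        contribution_pct=contrib,
    )
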