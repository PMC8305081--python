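"""Primary acidification and sugar kinetics.

During lactic fermentation of a cereal slurry the pH falls, and the
titratable acidity (TTA) rises, toward a plateau.  Both are described by
the three-parameter exponential

    y(t) = a - b * exp(-c * t)

where ``a`` is the horizontal asymptote, ``b = a - y(0)`` and ``c`` is
the first-order rate constant in 1/h.  For a variable decreasing toward
its asymptote from above (pH), ``b`` is negative; for one rising toward
it (TTA), ``b`` is positive.  Soluble glucose, released by amylolysis
faster than it is consumed early on, follows an empirical quadratic in
time.  Goodness of fit is reported as R^2 = 1 - RSS/CSS, the fraction of
the corrected sum of squares explained.

Plateau onset ("optimum fermentation time") is located by comparing
consecutive sampling times with Welch two-sample tests reconstructed
from the per-time mean, SD and replicate count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .dataio import FermentationTimeSeries, TitrationRecord
from .exceptions import (
    DataValidationError,
    DegenerateVarianceError,
    FitConvergenceError,
    RankDeficiencyError,
)

__all__ = [
    "ExponentialFit",
    "QuadraticFit",
    "eval_exponential",
    "fit_exponential",
    "fit_quadratic",
    "r_squared",
    "tta_percent",
    "plateau_time",
]

_N_RESTARTS = 20
_XTOL = 1e-10


@dataclass(eq=False)
class ExponentialFit:
    """Least-squares estimates of the exponential model y = a - b exp(-ct)."""

    a: float
    b: float
    c: float
    se_a: float
    se_b: float
    se_c: float
    r2: float
    n_points: int
    converged: bool
    residuals: np.ndarray  # observed - predicted, per time point

    def predict(self, t) -> np.ndarray:
        return eval_exponential(self.a, self.b, self.c, t)


@dataclass(eq=False)
class QuadraticFit:
    """OLS coefficients of y = c0 + c1 t + c2 t^2."""

    c0: float
    c1: float
    c2: float
    r2: float
    n_points: int

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c0 + self.c1 * t + self.c2 * t * t


def eval_exponential(a: float, b: float, c: float, t) -> np.ndarray:
    """Evaluate a - b * exp(-c * t)."""
    t = np.asarray(t, dtype=float)
    out = a - b * np.exp(-c * t)
    return out if out.ndim else float(out)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - RSS/CSS.

    May be negative when the model predicts worse than the observed mean.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    css = float(np.sum((o - o.mean()) ** 2))
    if css == 0.0:
        raise DegenerateVarianceError(
            "observed values are all identical; R^2 is undefined"
        )
    rss = float(np.sum((o - p) ** 2))
    return 1.0 - rss / css


def _initial_guesses(times, values, init, n_restarts):
    a0 = float(values[-1])
    b0 = a0 - float(values[0])
    guesses = []
    if init is not None:
        guesses.append(tuple(init))
    guesses.append((a0, b0, 0.1))
    # deterministic multi-start: jitter the rate constant log-uniformly
    rng = np.random.default_rng(12345)
    for _ in range(n_restarts):
        c0 = 10.0 ** rng.uniform(-3, 0.5)
        guesses.append((a0, b0, c0))
    return guesses


def fit_exponential(
    times: Sequence[float],
    values: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    init: Optional[Tuple[float, float, float]] = None,
) -> ExponentialFit:
    """Fit y = a - b exp(-ct) by (weighted) nonlinear least squares.

    Multi-start Levenberg-Marquardt/TRF with a deterministic set of
    jittered rate-constant starts; the best converged solution by RSS
    wins.  Standard errors come from the Jacobian at the optimum scaled
    by the residual variance (the usual local linearisation).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError(f"need at least 4 points to fit 3 parameters, got {t.size}")
    if t.shape != y.shape:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    if np.unique(t).size < 4:
        # ties are allowed (replicate-level fitting) but the curve still
        # needs 4 distinct times to pin down 3 parameters
        raise ValueError("need at least 4 distinct times")
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)

    def model(t, a, b, c):
        return a - b * np.exp(-c * t)

    bounds = ([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf])
    best = None  # (rss, popt, pcov)
    for p0 in _initial_guesses(t, y, init, _N_RESTARTS):
        p0 = (p0[0], p0[1], max(p0[2], 1e-6))
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=p0, sigma=sigma, bounds=bounds,
                maxfev=20000, xtol=_XTOL, ftol=_XTOL,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        rss = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or rss < best[0] * (1 - 1e-12):
            best = (rss, popt, pcov)
    if best is None:
        raise FitConvergenceError(
            "exponential fit did not converge from any start", best=None
        )
    _, popt, pcov = best
    a, b, c = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    resid = y - model(t, a, b, c)
    return ExponentialFit(
        a=a, b=b, c=c,
        se_a=float(se[0]), se_b=float(se[1]), se_c=float(se[2]),
        r2=r_squared(y, model(t, a, b, c)),
        n_points=int(t.size), converged=True, residuals=resid,
    )


def fit_quadratic(times: Sequence[float], values: Sequence[float]) -> QuadraticFit:
    """OLS fit of y = c0 + c1 t + c2 t^2."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError(f"need at least 3 points for a quadratic, got {t.size}")
    X = np.column_stack([np.ones_like(t), t, t * t])
    if np.linalg.matrix_rank(X) < 3:
        raise RankDeficiencyError(
            "quadratic design is singular (times not distinct enough)",
            collinear_terms=("t", "t^2"),
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    return QuadraticFit(
        c0=float(coef[0]), c1=float(coef[1]), c2=float(coef[2]),
        r2=r_squared(y, pred), n_points=int(t.size),
    )


def tta_percent(rec: TitrationRecord) -> float:
    """Total titratable acidity as % lactic acid from an NaOH titration.

    TTA% = (mL NaOH x molarity x 90.08 mg) / (sample mL x 1000) x 100.
    """
    return (
        rec.naoh_ml * rec.naoh_molarity * rec.lactic_equivalent_mg
        / (rec.sample_ml * 1000.0) * 100.0
    )


def _welch_p(m1, s1, n1, m2, s2, n2) -> float:
    """Two-sided Welch p-value from summary statistics.

    Degenerate replicate SDs (both zero) make the test an equality
    check: p = 1 for equal means, p = 0 otherwise.
    """
    if s1 == 0.0 and s2 == 0.0:
        return 1.0 if m1 == m2 else 0.0
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    return float(res.pvalue)


def plateau_time(
    series: FermentationTimeSeries, variable: str, alpha: float = 0.05
) -> float:
    """Earliest sampling time after which no consecutive change is significant.

    Walks the consecutive pairs of time points; each pair is compared
    with a Welch two-sample test rebuilt from the stored mean, SD and
    replicate count.  The plateau time is the earliest time t* such that
    every later consecutive comparison is non-significant at ``alpha``.
    Returns the last sampling time if the series never stabilises.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rep = series.variables[variable]
    if np.any(np.isnan(rep.sd)):
        raise DataValidationError(f"variable {variable!r} lacks SDs at some times")
    if np.any(rep.n < 2):
        raise DataValidationError(
            f"variable {variable!r} needs >= 2 replicates per time for Welch tests"
        )
    t = series.time_h
    last_sig = -1  # index i of the last significant pair (i, i+1)
    for i in range(t.size - 1):
        p = _welch_p(
            rep.mean[i], rep.sd[i], rep.n[i],
            rep.mean[i + 1], rep.sd[i + 1], rep.n[i + 1],
        )
        if p < alpha:
            last_sig = i
    return float(t[last_sig + 1]) if last_sig + 1 < t.size else float(t[-1])
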