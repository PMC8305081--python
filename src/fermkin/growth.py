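"""Modified Gompertz growth model for plate-count time courses.

Bacterial counts on the log10 scale are described by the
Zwietering-style modified Gompertz curve

    log10 N(t) = K + A * exp(-exp(mu_max * e * (lag - t) / A + 1))

with K the initial level (log10 CFU/mL), A the total rise from the
initial level to the stationary density, mu_max the maximum growth rate
(delta log10 CFU/mL per hour: the steepest tangent slope), and lag the
lag time in hours (where that tangent crosses the initial level).  The
curve runs from just above K at early times to the asymptote K + A; at
t = lag its value is exactly K + A*exp(-e).

Goodness of fit uses the mean relative deviation modulus
E% = (100/n) * sum |O - P| / O, conventional in food-engineering model
validation; E% below ~10% is usually read as an adequate fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .exceptions import DegenerateModelError, FitConvergenceError

__all__ = [
    "GompertzParams",
    "eval_gompertz",
    "mean_relative_deviation_modulus",
    "fit_gompertz",
]

_N_RESTARTS = 20


@dataclass(frozen=True)
class GompertzParams:
    """Modified-Gompertz parameter set; ``e_pct`` is filled by a fit."""

    K: float
    A: float
    mu_max: float
    lag: float
    e_pct: Optional[float] = None

    def __post_init__(self):
        if self.A < 0:
            raise DegenerateModelError("rise A must be >= 0")
        if self.mu_max < 0:
            raise DegenerateModelError("mu_max must be >= 0")
        if self.lag < 0:
            raise DegenerateModelError("lag must be >= 0")
        if self.e_pct is not None and self.e_pct < 0:
            raise DegenerateModelError("e_pct must be >= 0 when present")


def eval_gompertz(p: GompertzParams, t, allow_degenerate: bool = False):
    """Evaluate the modified Gompertz curve at time(s) t (hours)."""
    t = np.asarray(t, dtype=float)
    if p.A == 0.0:
        if not allow_degenerate:
            raise DegenerateModelError(
                "A = 0 describes a flat curve; pass allow_degenerate=True "
                "to evaluate it as the constant K"
            )
        warnings.warn("evaluating degenerate Gompertz curve (A = 0) as constant K")
        out = np.full_like(t, p.K, dtype=float)
        return out if out.ndim else float(out)
    # clip the inner exponent: anything above ~700 already evaluates to K
    inner = np.clip(p.mu_max * np.e * (p.lag - t) / p.A + 1.0, None, 700.0)
    out = p.K + p.A * np.exp(-np.exp(inner))
    return out if out.ndim else float(out)


def mean_relative_deviation_modulus(
    observed: Sequence[float], predicted: Sequence[float]
) -> float:
    """E% = (100/n) * sum |O - P| / O over paired observations."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 1:
        raise ValueError("observed and predicted must share a length >= 1")
    if np.any(o <= 0):
        raise ValueError("all observed values must be > 0 (relative deviation)")
    return float(np.mean(np.abs(o - p) / o) * 100.0)


def _default_init(t: np.ndarray, y: np.ndarray) -> GompertzParams:
    K0 = float(y[0])
    A0 = max(float(y.max() - y[0]), 1e-3)
    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    mu0 = max(float(slopes[k]), 1e-3)
    t_mid = 0.5 * (t[k] + t[k + 1])
    lag0 = max(float(t_mid - A0 / mu0), 0.0)
    return GompertzParams(K=K0, A=A0, mu_max=mu0, lag=lag0)


def fit_gompertz(
    times: Sequence[float],
    log_counts: Sequence[float],
    init: Optional[GompertzParams] = None,
) -> GompertzParams:
    """Fit the modified Gompertz curve by nonlinear least squares.

    Parameters are bounded: A > 0, mu_max >= 0, lag >= 0.  Starts from
    a secant-slope heuristic (initial level, observed rise, steepest
    secant, tangent-intercept lag) plus deterministic jittered restarts;
    the best converged solution by RSS is returned with its E% computed
    on the fitted points.  Monotone-decreasing data cannot express a
    growth curve; the fit then collapses toward the A lower bound and a
    warning is emitted alongside that boundary fit.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(log_counts, dtype=float)
    if t.size < 5:
        raise ValueError(f"need at least 5 points to fit 4 parameters, got {t.size}")
    if t.shape != y.shape:
        raise ValueError("times and log_counts must have equal length")

    def model(t, K, A, mu, lag):
        inner = np.clip(mu * np.e * (lag - t) / A + 1.0, None, 700.0)
        return K + A * np.exp(-np.exp(inner))

    p_init = init if init is not None else _default_init(t, y)
    guesses = [(p_init.K, max(p_init.A, 1e-3), max(p_init.mu_max, 1e-3), p_init.lag)]
    rng = np.random.default_rng(67890)
    for _ in range(_N_RESTARTS):
        guesses.append((
            guesses[0][0],
            guesses[0][1] * 10.0 ** rng.uniform(-0.5, 0.5),
            guesses[0][2] * 10.0 ** rng.uniform(-1.0, 1.0),
            max(guesses[0][3] + rng.uniform(-3.0, 3.0), 0.0),
        ))
    bounds = ([-np.inf, 1e-6, 0.0, 0.0], [np.inf, np.inf, np.inf, np.inf])
    best = None
    for p0 in guesses:
        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-12, ftol=1e-12,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        rss = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or rss < best[0] * (1 - 1e-12):
            best = (rss, popt)
    if best is None:
        raise FitConvergenceError("Gompertz fit did not converge from any start")
    K, A, mu, lag = (float(v) for v in best[1])
    if y[-1] < y[0] and A < 1e-3:
        warnings.warn(
            "log counts decrease overall; returning boundary fit with A near 0"
        )
    pred = model(t, K, A, mu, lag)
    e_pct = mean_relative_deviation_modulus(y, pred)
    return GompertzParams(K=K, A=A, mu_max=mu, lag=max(lag, 0.0), e_pct=e_pct)
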