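"""Factorial model for starter-culture effects on beverage responses.

A 2^3(+center) inoculum design — three lactic-acid-bacteria cultures
each dosed at two levels (% w/w) plus a center point — is analysed with
the identity-link Gaussian model

    Y = b0 + b1*X1 + b2*X2 + b3*X3 + b12*X1X2 + b13*X1X3 + b23*X2X3
        (+ b123*X1X2X3 for a saturated corner fit)

in NATURAL concentration units (not the coded -1/+1 convention), so the
interaction coefficients carry units of response per (% inoculum)^2 and
take magnitudes in the tens to thousands.  Inference is Wald: the
dispersion scale is RSS / dof, 95% CIs are estimate +/- 1.96*SE, and
p-values are two-sided normal.

The fit itself is an identity-link Gaussian GLM from statsmodels; a
plain normal-equations solve gives identical coefficients and backs the
test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .dataio import FactorialDesignTable
from .exceptions import RankDeficiencyError

__all__ = [
    "ModelSpec",
    "CoefEstimate",
    "GLMFit",
    "build_design_matrix",
    "fit_glm",
    "predict",
    "TERMS_TWO_WAY",
    "TERMS_THREE_WAY",
]

_Z95 = 1.96

TERMS_TWO_WAY = ("intercept", "x1", "x2", "x3", "x1x2", "x1x3", "x2x3")
TERMS_THREE_WAY = TERMS_TWO_WAY + ("x1x2x3",)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms the factorial model carries.

    The two-way model (intercept, mains, pairwise interactions) suits
    the acid responses; the viscosity response additionally needs the
    three-way culture interaction.
    """

    include_three_way: bool = False
    factor_names: Tuple[str, str, str] = ("x1", "x2", "x3")

    def __post_init__(self):
        if len(tuple(self.factor_names)) != 3:
            raise ValueError("exactly three factors are required")

    @property
    def terms(self) -> Tuple[str, ...]:
        return TERMS_THREE_WAY if self.include_three_way else TERMS_TWO_WAY


@dataclass(frozen=True)
class CoefEstimate:
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass(eq=False)
class GLMFit:
    """Fitted factorial model with Wald inference."""

    coefficients: Dict[str, CoefEstimate]
    scale: float  # residual dispersion, RSS / dof_residual
    n_obs: int
    dof_residual: int
    spec: ModelSpec = field(default_factory=ModelSpec)
    fitted_values: Optional[np.ndarray] = None

    @property
    def estimates(self) -> Dict[str, float]:
        return {k: v.estimate for k, v in self.coefficients.items()}


def build_design_matrix(
    levels: Sequence[Sequence[float]], spec: ModelSpec = ModelSpec()
) -> np.ndarray:
    """Regressor matrix in natural (uncoded) concentration units."""
    x = np.atleast_2d(np.asarray(levels, dtype=float))
    if x.size == 0:
        raise ValueError("levels must be non-empty")
    if x.shape[1] != 3:
        raise ValueError("each design point must have three factor levels")
    cols = [
        np.ones(x.shape[0]),
        x[:, 0], x[:, 1], x[:, 2],
        x[:, 0] * x[:, 1], x[:, 0] * x[:, 2], x[:, 1] * x[:, 2],
    ]
    if spec.include_three_way:
        cols.append(x[:, 0] * x[:, 1] * x[:, 2])
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full relative rank
        collinear = [
            terms[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} terms; "
            f"collinear terms: {collinear}",
            collinear_terms=collinear,
        )


def fit_glm(
    design: FactorialDesignTable,
    response: str,
    spec: ModelSpec = ModelSpec(),
    weights: Optional[Sequence[float]] = None,
) -> GLMFit:
    """Fit the factorial model to one response of a design table.

    By default the per-run cell means are fitted unweighted; passing the
    replicate counts as ``weights`` reproduces a balanced
    replicate-expanded fit (identical coefficients when balanced).
    ``scale`` is the residual variance RSS/dof; with zero residual
    degrees of freedom (saturated fit) it is reported as 0.
    """
    y = design.means(response)
    X = build_design_matrix(design.levels, spec)
    terms = spec.terms
    if len(np.unique(design.levels, axis=0)) < len(terms):
        raise ValueError(
            f"{len(terms)} terms requested but only "
            f"{len(np.unique(design.levels, axis=0))} distinct design points"
        )
    _check_rank(X, terms)
    freq = None
    if weights is not None:
        freq = np.asarray(weights, dtype=float)
    model = sm.GLM(y, X, family=sm.families.Gaussian(), freq_weights=freq)
    dof = int(round(model.df_resid))
    try:
        if dof <= 0:
            raise ValueError("saturated model")
        with np.errstate(invalid="ignore"):
            res = model.fit()
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite estimates")
        params, bse, pvals = res.params, res.bse, res.pvalues
        scale = float(res.scale)
        fitted = np.asarray(res.fittedvalues, dtype=float)
    except ValueError:
        # saturated or zero-residual fits break the GLM scale estimate;
        # fall back to the closed-form OLS solution
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ params
        rss = float(np.sum((y - fitted) ** 2))
        scale = rss / dof if dof > 0 else 0.0
        cov = scale * np.linalg.pinv(X.T @ X)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(bse > 0, params / np.where(bse > 0, bse, 1.0), np.inf)
            pvals = 2.0 * stats.norm.sf(np.abs(z))
            pvals = np.where(bse > 0, pvals, np.where(params == 0, 1.0, 0.0))
    coeffs = {}
    for j, term in enumerate(terms):
        est, se = float(params[j]), float(bse[j])
        coeffs[term] = CoefEstimate(
            estimate=est,
            se=se,
            ci_lower=est - _Z95 * se,
            ci_upper=est + _Z95 * se,
            p_value=float(pvals[j]),
        )
    return GLMFit(
        coefficients=coeffs,
        scale=scale,
        n_obs=int(len(y)),
        dof_residual=max(dof, 0),
        spec=spec,
        fitted_values=fitted,
    )


def predict(fit: GLMFit, x1: float, x2: float, x3: float) -> float:
    """Evaluate the fitted factorial model at one inoculum combination."""
    X = build_design_matrix([[x1, x2, x3]], fit.spec)
    beta = np.array([fit.coefficients[t].estimate for t in fit.spec.terms])
    return float((X @ beta)[0])
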