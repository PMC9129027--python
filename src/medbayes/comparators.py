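"""Classical mediation tests: Sobel, LOD drop, and 2SLS instrumental variables.

These are the frequentist comparators for the Bayesian model-selection
approach in :mod:`medbayes.core`.  All three operate on raw (unstandardized)
vectors; the Sobel test is restricted to a scalar exogenous variable because
the product of coefficient vectors has no scalar test statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("medbayes")


@dataclass(frozen=True)
class SobelResult:
    beta_a_hat: float
    beta_b_hat: float
    se_a: float
    se_b: float
    product: float
    z: float
    p: float


@dataclass(frozen=True)
class LodDropResult:
    lod_marginal: float
    lod_conditional: float
    drop: float
    scaled_drop: float  # NaN when lod_marginal == 0


@dataclass(frozen=True)
class IvResult:
    m_hat: np.ndarray
    effect: float
    se: float
    p: float


def _with_intercept(n, covariates, *extra):
    cols = [np.ones((n, 1))]
    if covariates is not None:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        cols.append(Z)
    for e in extra:
        e = np.asarray(e, float)
        cols.append(e[:, None] if e.ndim == 1 else e)
    return np.hstack(cols)


def sobel_test(y, m, x, covariates=None) -> SobelResult:
    """First-order Sobel test of the indirect effect ``beta_a * beta_b``.

    ``beta_a`` is the OLS coefficient of x in m ~ 1 (+ Z) + x and ``beta_b``
    the coefficient of m in y ~ 1 (+ Z) + x + m; the statistic is
    ``z = ab / sqrt(a^2 se_b^2 + b^2 se_a^2)`` referred to the standard
    normal.  Raises if x has more than one column: with a multivariable
    exogenous design the indirect effect is a vector and the test does not
    apply.
    """
    y = np.asarray(y, float).ravel()
    m = np.asarray(m, float).ravel()
    x = np.asarray(x, float)
    if x.ndim == 2 and x.shape[1] != 1:
        raise ValueError(
            f"Sobel test requires a single-column exogenous variable, got "
            f"{x.shape[1]} columns; use Bayesian model selection or LOD drop "
            f"for multivariable X")
    x = x.ravel()
    n = y.size

    exog_a = _with_intercept(n, covariates, x)
    exog_b = _with_intercept(n, covariates, x, m)
    if np.linalg.matrix_rank(exog_b) < exog_b.shape[1]:
        raise np.linalg.LinAlgError(
            "singular fit: x and m (or covariates) are collinear")
    fit_a = sm.OLS(m, exog_a).fit()
    fit_b = sm.OLS(y, exog_b).fit()
    a, se_a = fit_a.params[-1], fit_a.bse[-1]
    b, se_b = fit_b.params[-1], fit_b.bse[-1]
    denom = np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    z = 0.0 if denom == 0 else float(a * b / denom)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SobelResult(beta_a_hat=float(a), beta_b_hat=float(b),
                       se_a=float(se_a), se_b=float(se_b),
                       product=float(a * b), z=z, p=p)


def _rss(y, design) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def lod_score(y, X, covariates=None, adjust=None) -> float:
    """Fixed-effects LOD score of X for y: ``(N/2) log10(RSS_0 / RSS_1)``.

    The null design holds intercept and covariates (plus the mediator when
    ``adjust`` is given); the full design adds X.  Redundant columns are
    handled by the least-squares pseudo-inverse, so a constant X yields
    LOD = 0 exactly; a perfect fit returns +inf.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    null = _with_intercept(n, covariates) if adjust is None else \
        _with_intercept(n, covariates, adjust)
    full = np.hstack([null, np.asarray(X, float).reshape(n, -1)])
    rss0 = _rss(y, null)
    rss1 = _rss(y, full)
    if rss1 <= 0 or rss1 < 1e-12 * rss0:  # numerically perfect fit
        return float("inf")
    # numerical guard: nesting means rss1 <= rss0 up to roundoff
    return max(0.5 * n * np.log10(max(rss0, rss1) / rss1), 0.0)


def lod_drop(y, m, X, covariates=None) -> LodDropResult:
    """Reduction in the LOD score of X for y after conditioning on m."""
    marginal = lod_score(y, X, covariates=covariates)
    conditional = lod_score(y, X, covariates=covariates, adjust=m)
    drop = marginal - conditional
    scaled = drop / marginal if marginal > 0 else float("nan")
    return LodDropResult(lod_marginal=marginal, lod_conditional=conditional,
                         drop=drop, scaled_drop=scaled)


def iv_2sls(y, m, X, covariates=None) -> IvResult:
    """Two-stage least-squares estimate of the causal effect of m on y.

    Stage 1 regresses m on (1, Z, X) to form the genetically predicted
    mediator m_hat; stage 2 regresses y on (1, Z, m_hat).  The standard error
    uses the conventional 2SLS residuals (computed with the observed m, not
    m_hat) and the p-value refers the effect to a t distribution with N - 2
    degrees of freedom.
    """
    y = np.asarray(y, float).ravel()
    m = np.asarray(m, float).ravel()
    n = y.size
    stage1 = _with_intercept(n, covariates, X)
    b1, *_ = np.linalg.lstsq(stage1, m, rcond=None)
    m_hat = stage1 @ b1
    if np.std(m_hat - _with_intercept(n, covariates) @
              np.linalg.lstsq(_with_intercept(n, covariates), m_hat, rcond=None)[0]) == 0:
        raise ValueError("weak instrument: X explains no variance of m")
    stage2 = _with_intercept(n, covariates, m_hat)
    b2, *_ = np.linalg.lstsq(stage2, y, rcond=None)
    effect = float(b2[-1])
    # 2SLS variance: residuals from observed m at the stage-2 coefficients
    resid = y - _with_intercept(n, covariates, m) @ b2
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(stage2.T @ stage2)
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    t = effect / se if se > 0 else float("inf") * np.sign(effect)
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return IvResult(m_hat=m_hat, effect=effect, se=se, p=p)
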