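"""Exact Bayesian model selection over mediation DAGs.

The model relates an exogenous (possibly multivariable) variable X — e.g. SNP
allele dosages or founder-haplotype dosages at a QTL — a candidate mediator M,
and an outcome Y through twelve causal configurations ``theta = (a, b, c)``:
``a`` indicates the edge X→M, ``c`` the edge X→Y, and ``b`` takes three states
(0: no M–Y edge, 1: M→Y, "*": the reactive direction Y→M).

For each configuration the regression coefficients, intercepts, covariate
effects and residual variances are integrated out analytically under conjugate
normal–inverse-gamma priors, so the marginal joint likelihood of (m, y) is a
product of two zero-location multivariate Student-t densities and the
posterior over causal models is exact — no sampling is required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("medbayes")

REACTIVE = "*"

#: Default hyperparameter values: near-flat scale priors and vague
#: intercept/covariate priors, with unit prior effect-size ratios per edge.
DEFAULT_KAPPA = 0.001
DEFAULT_LAMBDA = 0.001
DEFAULT_TAU_SQ = 1000.0
DEFAULT_PHI_SQ = (1.0, 1.0, 1.0)

#: Clamp applied to probabilities before forming posterior odds, and to the
#: empirical PVE before the ratio transform.
ODDS_CLAMP = 1e-10
PVE_CLAMP = 1e-4


class DegenerateTraitError(ValueError):
    """A trait vector has no variance and cannot be standardized."""


# ---------------------------------------------------------------------------
# Causal model indicators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalModelIndicator:
    """One of the twelve edge configurations, with its canonical label."""

    theta_a: int
    theta_b: object  # 0, 1 or "*"
    theta_c: int
    label: str

    @property
    def theta(self):
        return (self.theta_a, self.theta_b, self.theta_c)

    @property
    def reactive(self) -> bool:
        return self.theta_b == REACTIVE


# Canonical theta <-> label bijection.  ML4 (complete mediation), ML5 (QTL on
# Y only), ML7 (co-local), ML8 (partial mediation) and the reactive block
# ML9-12 are anchored; the remainder follow binary counting order on
# (theta_c, theta_a, theta_b).
MODELS: tuple[CausalModelIndicator, ...] = (
    CausalModelIndicator(0, 0, 0, "ML1"),
    CausalModelIndicator(0, 1, 0, "ML2"),
    CausalModelIndicator(1, 0, 0, "ML3"),
    CausalModelIndicator(1, 1, 0, "ML4"),
    CausalModelIndicator(0, 0, 1, "ML5"),
    CausalModelIndicator(0, 1, 1, "ML6"),
    CausalModelIndicator(1, 0, 1, "ML7"),
    CausalModelIndicator(1, 1, 1, "ML8"),
    CausalModelIndicator(0, REACTIVE, 0, "ML9"),
    CausalModelIndicator(1, REACTIVE, 0, "ML10"),
    CausalModelIndicator(0, REACTIVE, 1, "ML11"),
    CausalModelIndicator(1, REACTIVE, 1, "ML12"),
)

MODEL_BY_LABEL = {m.label: m for m in MODELS}
MODEL_BY_THETA = {m.theta: m for m in MODELS}

#: Named posterior groupings.  "mediation" overlaps complete + partial and is
#: reported in addition to the disjoint groups.
GROUPS: dict[str, tuple[str, ...]] = {
    "complete": ("ML4",),
    "partial": ("ML8",),
    "colocal": ("ML7",),
    "other_non_mediation": ("ML1", "ML2", "ML3", "ML5", "ML6"),
    "reactive": ("ML9", "ML10", "ML11", "ML12"),
    "mediation": ("ML4", "ML8"),
}


def as_model(spec) -> CausalModelIndicator:
    """Coerce a label ("ML7"), a theta tuple, or an indicator to the model."""
    if isinstance(spec, CausalModelIndicator):
        return spec
    if isinstance(spec, str):
        try:
            return MODEL_BY_LABEL[spec]
        except KeyError:
            raise ValueError(f"unknown causal model label {spec!r}") from None
    key = tuple(spec)
    try:
        return MODEL_BY_THETA[key]
    except KeyError:
        raise ValueError(f"invalid edge configuration {key!r}") from None


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

def standardize_trait(v, name: str = "trait") -> np.ndarray:
    """Center and scale a trait to mean zero and unit sample variance.

    Raises :class:`DegenerateTraitError` naming the trait if the vector is
    constant (zero sample standard deviation).
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ValueError(f"{name}: need at least 2 observations to standardize")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name}: non-finite values in input")
    sd = v.std(ddof=1)
    # variation below the float resolution of the values is indistinguishable
    # from a constant vector and would only amplify rounding noise
    if not np.isfinite(sd) or sd <= 1e-13 * np.abs(v).max():
        raise DegenerateTraitError(f"{name}: constant vector cannot be standardized")
    return (v - v.mean()) / sd


def _as_2d(arr, n, name):
    if arr is None:
        return np.empty((n, 0))
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] != n:
        raise ValueError(f"{name} has {a.shape[0]} rows, expected {n}")
    return a


@dataclass
class MediationData:
    """Row-aligned outcome, mediator, exogenous design, covariates and weights.

    ``y`` and ``m`` are standardized (mean 0, sample sd 1); X and covariates
    are left on their original scale.  Rows with any missing value across the
    components are dropped jointly by :meth:`from_arrays`.
    """

    y: np.ndarray
    m: np.ndarray
    X: np.ndarray
    Z_m: np.ndarray = None
    Z_y: np.ndarray = None
    w_m: np.ndarray = None
    w_y: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.m = np.asarray(self.m, dtype=float).ravel()
        n = self.y.size
        if n < 3:
            raise ValueError(f"need at least 3 individuals, got {n}")
        if self.m.size != n:
            raise ValueError("y and m have different lengths")
        self.X = _as_2d(self.X, n, "X")
        self.Z_m = _as_2d(self.Z_m, n, "Z_m")
        self.Z_y = _as_2d(self.Z_y, n, "Z_y")
        self.w_m = np.ones(n) if self.w_m is None else np.asarray(self.w_m, float).ravel()
        self.w_y = np.ones(n) if self.w_y is None else np.asarray(self.w_y, float).ravel()
        for w, nm in ((self.w_m, "w_m"), (self.w_y, "w_y")):
            if w.size != n:
                raise ValueError(f"{nm} has wrong length")
            if not np.all(w > 0):
                raise ValueError(f"{nm} must be strictly positive")
        for a, nm in ((self.y, "y"), (self.m, "m"), (self.X, "X"),
                      (self.Z_m, "Z_m"), (self.Z_y, "Z_y")):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{nm} contains non-finite values")

    @property
    def n(self) -> int:
        return self.y.size

    @classmethod
    def from_arrays(cls, y, m, X, Z_m=None, Z_y=None, w_m=None, w_y=None,
                    standardize: bool = True) -> "MediationData":
        """Drop rows with missing values jointly, then standardize y and m."""
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        m = np.asarray(m, dtype=float).ravel()
        X = _as_2d(X, n, "X")
        Z_m = _as_2d(Z_m, n, "Z_m")
        Z_y = _as_2d(Z_y, n, "Z_y")
        w_m = np.ones(n) if w_m is None else np.asarray(w_m, float).ravel()
        w_y = np.ones(n) if w_y is None else np.asarray(w_y, float).ravel()
        ok = np.isfinite(y) & np.isfinite(m) & np.isfinite(w_m) & np.isfinite(w_y)
        ok &= np.all(np.isfinite(X), axis=1)
        ok &= np.all(np.isfinite(Z_m), axis=1) & np.all(np.isfinite(Z_y), axis=1)
        dropped = int(n - ok.sum())
        if dropped:
            logger.info("dropped %d of %d rows with missing values", dropped, n)
        y, m, X = y[ok], m[ok], X[ok]
        Z_m, Z_y, w_m, w_y = Z_m[ok], Z_y[ok], w_m[ok], w_y[ok]
        if standardize:
            y = standardize_trait(y, "y")
            m = standardize_trait(m, "m")
        return cls(y=y, m=m, X=X, Z_m=Z_m, Z_y=Z_y, w_m=w_m, w_y=w_y)

    def swapped(self) -> "MediationData":
        """Interchange the roles of y and m (with their covariates/weights)."""
        return MediationData(y=self.m, m=self.y, X=self.X, Z_m=self.Z_y,
                             Z_y=self.Z_m, w_m=self.w_y, w_y=self.w_m)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectPriorSpec:
    """Hyperparameters of the integrated-out regression parameters.

    kappa, lamb
        Shape/rate pairs (m-side, y-side) of the inverse-gamma priors on the
        residual variances; the defaults (0.001, 0.001) are near-flat.
    tau_mu_sq, tau_z_sq
        Prior variance (relative to residual variance) of the intercept and
        covariate effects; vague by default.
    phi_sq
        Per-edge (a, b, c) prior effect-size ratios: the prior variance of an
        edge coefficient is phi^2 times the residual variance.
    """

    kappa: tuple = (DEFAULT_KAPPA, DEFAULT_KAPPA)
    lamb: tuple = (DEFAULT_LAMBDA, DEFAULT_LAMBDA)
    tau_mu_sq: tuple = (DEFAULT_TAU_SQ, DEFAULT_TAU_SQ)
    tau_z_sq: tuple = (DEFAULT_TAU_SQ, DEFAULT_TAU_SQ)
    phi_sq: tuple = DEFAULT_PHI_SQ

    def __post_init__(self):
        for nm in ("kappa", "lamb", "tau_mu_sq", "tau_z_sq"):
            pair = tuple(float(x) for x in np.atleast_1d(getattr(self, nm)))
            if len(pair) == 1:
                pair = pair * 2
            if len(pair) != 2 or any(x <= 0 for x in pair):
                raise ValueError(f"{nm} must be a strictly positive pair")
            object.__setattr__(self, nm, pair)
        phi = tuple(float(x) for x in np.atleast_1d(self.phi_sq))
        if len(phi) == 1:
            phi = phi * 3
        if len(phi) != 3 or any(x < 0 for x in phi):
            raise ValueError("phi_sq must be a nonnegative triple")
        object.__setattr__(self, "phi_sq", phi)

    def with_phi(self, phi_sq) -> "EffectPriorSpec":
        return replace(self, phi_sq=tuple(phi_sq))


@dataclass(frozen=True)
class ModelPrior:
    """Nonnegative weight per causal model; normalized to sum 1 before use."""

    weights: tuple

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if len(w) != len(MODELS):
            raise ValueError(f"expected {len(MODELS)} weights, got {len(w)}")
        if any(x < 0 for x in w):
            raise ValueError("model prior weights must be nonnegative")
        if not any(x > 0 for x in w):
            raise ValueError("model prior needs at least one positive weight")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelPrior":
        return cls(tuple(float(d.get(m.label, 0.0)) for m in MODELS))

    @classmethod
    def default(cls) -> "ModelPrior":
        """Uniform over the eight models with no reverse causality (ML1-8)."""
        return cls(tuple(0.0 if m.reactive else 1.0 for m in MODELS))

    @classmethod
    def reduced(cls) -> "ModelPrior":
        """Uniform over the five non-reactive models that include edge c."""
        return cls(tuple(1.0 if (not m.reactive and m.theta_c == 1) else 0.0
                         for m in MODELS))

    @classmethod
    def expanded(cls) -> "ModelPrior":
        """Uniform over all twelve models, reactive included."""
        return cls((1.0,) * len(MODELS))

    @classmethod
    def preset(cls, name: str) -> "ModelPrior":
        try:
            return {"default": cls.default, "reduced": cls.reduced,
                    "expanded": cls.expanded}[name]()
        except KeyError:
            raise ValueError(f"unknown model prior preset {name!r}") from None

    @property
    def normalized(self) -> np.ndarray:
        w = np.asarray(self.weights)
        return w / w.sum()


# ---------------------------------------------------------------------------
# Marginal likelihood machinery
# ---------------------------------------------------------------------------

def assemble_designs(theta, data: MediationData, priors: EffectPriorSpec):
    """Concatenated design matrices and diagonal prior covariances.

    Returns ``(X_m, v_m, X_y, v_y)`` for the M- and Y-equations of a
    non-reactive configuration: the M-design is [1 | Z_m | a·X] and the
    Y-design [1 | Z_y | c·X | b·m], with blocks whose edge indicator is zero
    omitted entirely (equivalent to zero prior variance on those columns).
    """
    model = as_model(theta)
    if model.reactive:
        raise ValueError("reactive configurations are handled by the role swap "
                         "in joint_model_loglik")
    phi_a, phi_b, phi_c = priors.phi_sq
    one = np.ones((data.n, 1))

    cols_m = [one]
    v_m = [priors.tau_mu_sq[0]]
    if data.Z_m.shape[1]:
        cols_m.append(data.Z_m)
        v_m += [priors.tau_z_sq[0]] * data.Z_m.shape[1]
    if model.theta_a:
        cols_m.append(data.X)
        v_m += [phi_a] * data.X.shape[1]

    cols_y = [one]
    v_y = [priors.tau_mu_sq[1]]
    if data.Z_y.shape[1]:
        cols_y.append(data.Z_y)
        v_y += [priors.tau_z_sq[1]] * data.Z_y.shape[1]
    if model.theta_c:
        cols_y.append(data.X)
        v_y += [phi_c] * data.X.shape[1]
    if model.theta_b == 1:
        cols_y.append(data.m[:, None])
        v_y.append(phi_b)

    return (np.hstack(cols_m), np.array(v_m),
            np.hstack(cols_y), np.array(v_y))


def conditional_marginal_loglik(response, design, prior_variances, weights,
                                kappa: float, lamb: float) -> float:
    """Log marginal density of one regression equation.

    Integrating the coefficients (normal, variance sigma^2 * v_j) and the
    residual variance (inverse-gamma with shape kappa/2, rate lamb/2) out of a
    weighted Gaussian linear model yields a zero-location multivariate
    Student-t with kappa degrees of freedom and scale matrix
    (lamb/kappa) * (W^-1 + X V X').  The log density is evaluated through the
    low-rank symmetric positive-definite factorization of the capacitance
    matrix I + U'WU with U = X V^{1/2}, which is exact and remains
    well-conditioned even when X has collinear columns (e.g. haplotype
    dosages with constant row sums): W^-1 keeps the scale matrix PD.
    """
    r = np.asarray(response, dtype=float).ravel()
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite response entries")
    n = r.size
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != n or not np.all(w > 0):
        raise ValueError("weights must be strictly positive and match response")
    if kappa <= 0 or lamb <= 0:
        raise ValueError("kappa and lamb must be positive")
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    v = np.asarray(prior_variances, dtype=float).ravel()
    if X.shape[0] != n or X.shape[1] != v.size:
        raise ValueError("design, response and prior covariance dimensions disagree")
    if np.any(v < 0):
        raise ValueError("prior variances must be nonnegative")

    keep = v > 0  # zero prior variance deletes the column exactly
    U = X[:, keep] * np.sqrt(v[keep])
    p = U.shape[1]
    logdet_w_inv = -np.log(w).sum()
    wr = w * r
    quad_base = float(r @ wr)
    if p:
        A = np.eye(p) + U.T @ (w[:, None] * U)
        try:
            cf = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:  # pragma: no cover - jitter fallback
            jitter = 1e-10 * np.trace(A) / p
            logger.warning("PD factorization failed; retrying with jitter %.3e", jitter)
            cf = cho_factor(A + jitter * np.eye(p), lower=True)
        logdet = logdet_w_inv + 2.0 * np.log(np.diag(cf[0])).sum()
        z = U.T @ wr
        quad = quad_base - float(z @ cho_solve(cf, z))
    else:
        logdet = logdet_w_inv
        quad = quad_base
    quad = max(quad, 0.0)

    return float(
        gammaln((kappa + n) / 2.0) - gammaln(kappa / 2.0)
        - 0.5 * n * math.log(kappa * math.pi)
        - 0.5 * (n * math.log(lamb / kappa) + logdet)
        - 0.5 * (kappa + n) * math.log1p(quad / lamb)
    )


def _nonreactive_loglik(model, data, priors) -> float:
    X_m, v_m, X_y, v_y = assemble_designs(model, data, priors)
    ll_m = conditional_marginal_loglik(data.m, X_m, v_m, data.w_m,
                                       priors.kappa[0], priors.lamb[0])
    ll_y = conditional_marginal_loglik(data.y, X_y, v_y, data.w_y,
                                       priors.kappa[1], priors.lamb[1])
    return ll_m + ll_y


def joint_model_loglik(theta, data: MediationData,
                       priors: EffectPriorSpec = None) -> float:
    """Log marginal joint likelihood of (m, y) under one causal model.

    Non-reactive configurations factor as p(m | a-edge) * p(y | m; b,c-edges).
    Reactive configurations (theta_b = "*") swap the roles of y and m: the
    marginal equation is for y with the c-edge design, and the conditional is
    m given y with the a-edge design and y as a predictor with prior ratio
    phi_b^2 (covariates, weights and hyperparameters swap along).

    The configuration (1, *, 1) is Markov-equivalent to partial mediation
    (1, 1, 1) — the data cannot distinguish the direction of the M-Y edge once
    both X edges are present — so its likelihood is evaluated in the canonical
    factorization order and equals the partial-mediation value identically.
    """
    priors = priors or EffectPriorSpec()
    model = as_model(theta)
    if not model.reactive:
        return _nonreactive_loglik(model, data, priors)
    if model.theta == (1, REACTIVE, 1):
        return _nonreactive_loglik(MODEL_BY_THETA[(1, 1, 1)], data, priors)
    # role swap: phi stays attached to its edge (a with X->M, c with X->Y),
    # so the swapped data are scored with (phi_c, phi_b, phi_a).
    phi_a, phi_b, phi_c = priors.phi_sq
    sw = data.swapped()
    sw_priors = replace(priors, kappa=priors.kappa[::-1], lamb=priors.lamb[::-1],
                        tau_mu_sq=priors.tau_mu_sq[::-1],
                        tau_z_sq=priors.tau_z_sq[::-1],
                        phi_sq=(phi_c, phi_b, phi_a))
    target = MODEL_BY_THETA[(model.theta_c, 1, model.theta_a)]
    return _nonreactive_loglik(target, sw, sw_priors)


# ---------------------------------------------------------------------------
# Posterior over models
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Per-model log marginal likelihoods, priors and posterior probabilities."""

    labels: tuple
    log_marginal: np.ndarray
    log_prior: np.ndarray   # -inf for zero-prior models
    posterior: np.ndarray
    group_probabilities: dict = field(default_factory=dict)
    group_log_odds: dict = field(default_factory=dict)

    def probability(self, label: str) -> float:
        return float(self.posterior[self.labels.index(label)])

    def as_dict(self) -> dict:
        return {lab: float(p) for lab, p in zip(self.labels, self.posterior)}


def model_posterior(data: MediationData, priors: EffectPriorSpec = None,
                    model_prior: ModelPrior = None, log_base: float = math.e,
                    odds_clamp: float = ODDS_CLAMP) -> PosteriorResult:
    """Posterior probability of each causal model given the data.

    Normalization runs through log-sum-exp, so log-likelihood spreads of
    thousands of nats do not underflow.  Models with zero prior weight get
    posterior exactly 0 (their likelihood is still reported).
    """
    priors = priors or EffectPriorSpec()
    model_prior = model_prior or ModelPrior.default()
    prior_w = model_prior.normalized
    logml = np.array([joint_model_loglik(m, data, priors) for m in MODELS])
    with np.errstate(divide="ignore"):
        logprior = np.log(prior_w)
    logpost_un = logml + logprior
    active = prior_w > 0
    lse = logsumexp(logpost_un[active])
    posterior = np.zeros(len(MODELS))
    posterior[active] = np.exp(logpost_un[active] - lse)
    result = PosteriorResult(
        labels=tuple(m.label for m in MODELS),
        log_marginal=logml, log_prior=logprior, posterior=posterior)
    probs, odds = summarize_posterior(result, log_base=log_base,
                                      odds_clamp=odds_clamp)
    result.group_probabilities = probs
    result.group_log_odds = odds
    return result


def summarize_posterior(result: PosteriorResult, grouping: dict = None,
                        log_base: float = math.e,
                        odds_clamp: float = ODDS_CLAMP):
    """Group posterior mass and log posterior odds.

    Group probability is the sum of member posteriors; log odds are
    ``log(p / (1 - p))`` in the requested base with p clamped away from
    {0, 1} by ``odds_clamp`` (point-mass posteriors occur in simulations).
    Returns ``(probabilities, log_odds)`` dicts keyed by group name.
    """
    grouping = grouping if grouping is not None else GROUPS
    post = dict(zip(result.labels, result.posterior))
    probs, odds = {}, {}
    for name, members in grouping.items():
        try:
            p = float(sum(post[lab] for lab in members))
        except KeyError as exc:
            raise ValueError(f"unknown model label {exc} in group {name!r}") from None
        probs[name] = p
        pc = min(max(p, odds_clamp), 1.0 - odds_clamp)
        odds[name] = math.log(pc / (1.0 - pc)) / math.log(log_base)
    return probs, odds


# ---------------------------------------------------------------------------
# Empirical effect-size priors
# ---------------------------------------------------------------------------

def _pve(response, predictors) -> float:
    """Proportion of variance explained versus the intercept-only fit."""
    r = np.asarray(response, float).ravel()
    n = r.size
    resid0 = r - r.mean()
    ssr0 = float(resid0 @ resid0)
    if ssr0 <= 0:
        raise DegenerateTraitError("constant response in null fit")
    Xfull = np.column_stack([np.ones(n), np.asarray(predictors, float)])
    beta, *_ = np.linalg.lstsq(Xfull, r, rcond=None)
    resid = r - Xfull @ beta
    ssr = float(resid @ resid)
    return 1.0 - ssr / ssr0


def empirical_phi(data: MediationData, eps: float = PVE_CLAMP) -> tuple:
    """Empirical per-edge effect-size ratios from least-squares fits.

    For each edge the PVE relative to an intercept-only fit (a: m on X;
    b: y on m; c: y on X) is clamped to [eps, 1 - eps] and transformed to the
    ratio ``phi^2 = PVE / (1 - PVE)``.
    """
    pves = (_pve(data.m, data.X), _pve(data.y, data.m[:, None]),
            _pve(data.y, data.X))
    out = []
    for p in pves:
        p = min(max(p, eps), 1.0 - eps)
        out.append(p / (1.0 - p))
    return tuple(out)
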