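"""QTL trait and mediation-scenario simulator with exact effect-size scaling.

Traits are built as ``s_beta * X @ beta_raw + s_eps * eps_raw`` where the two
scaling factors are chosen so that the genetic component accounts for exactly
the requested proportion of the trait's sample variance.  On top of the
single-trait generator sit the five mediation scenarios used for
benchmarking (co-local, partial, complete and their reactive twins), plus
bi-allelic / multi-allelic / founder-haplotype genotype designs and
LD-misspecified tag variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("medbayes")

SCENARIOS = ("colocal", "partial", "complete", "reactive_partial",
             "reactive_complete", "y_only", "none")


@dataclass(frozen=True)
class GenotypeDesign:
    """Descriptor of the exogenous genetic design.

    kind
        "biallelic" (single dosage column), "multiallelic_k" (k functional
        alleles, k-1 indicator columns) or "haplotype8" (8 founder-dosage
        columns with constant row sum 2).
    n_alleles
        Number of functional alleles for "multiallelic_k".
    freqs
        Allele (or founder) frequencies; balanced by default.
    allele_of_founder
        For "haplotype8": functional allele carried by each of the 8
        founders (the bi-allelic default assigns allele 1 to founders 4-7).
    """

    kind: str = "biallelic"
    n_alleles: int = 2
    freqs: tuple = None
    allele_of_founder: tuple = (0, 0, 0, 0, 1, 1, 1, 1)

    def __post_init__(self):
        if self.kind not in ("biallelic", "multiallelic_k", "haplotype8"):
            raise ValueError(f"unknown genotype design kind {self.kind!r}")
        if self.freqs is not None:
            f = tuple(float(x) for x in self.freqs)
            if abs(sum(f) - 1.0) > 1e-9:
                raise ValueError("allele frequencies must sum to 1")
            object.__setattr__(self, "freqs", f)


@dataclass(frozen=True)
class SimulationSpec:
    """Data-generating model, effect sizes and genotype design for one run."""

    model: str
    n: int = 200
    effect_m: float = 0.5
    effect_y: float = 0.5
    bc_ratio: float = 1.0   # direct : indirect variance split for partial models
    genotype: GenotypeDesign = field(default_factory=GenotypeDesign)
    seed: int = 0

    def __post_init__(self):
        if self.model not in SCENARIOS:
            raise ValueError(f"unknown data-generating model {self.model!r}; "
                             f"expected one of {SCENARIOS}")
        if not (0.0 <= self.effect_m <= 1.0 and 0.0 <= self.effect_y <= 1.0):
            raise ValueError("effect sizes must lie in [0, 1]")
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.bc_ratio <= 0:
            raise ValueError("bc_ratio must be positive")


def _pop_var(v) -> float:
    return float(np.asarray(v, float).var(ddof=0))


def scale_components(signal_raw, noise_raw, phi_sq: float):
    """Scaling factors (s_beta, s_eps) for a target effect size.

    ``s_beta = sqrt(n phi^2 / ((n-1) V(signal)))`` and
    ``s_eps = sqrt(n (1-phi^2) / ((n-1) V(noise)))`` with V the population
    (divide-by-n) variance, so that the scaled signal has sample variance
    exactly phi^2 and the scaled noise exactly 1 - phi^2.
    """
    if not 0.0 <= phi_sq <= 1.0:
        raise ValueError("phi_sq must lie in [0, 1]")
    signal_raw = np.asarray(signal_raw, float)
    noise_raw = np.asarray(noise_raw, float)
    n = signal_raw.size
    v_sig = _pop_var(signal_raw)
    v_noise = _pop_var(noise_raw)
    if phi_sq > 0 and v_sig == 0:
        raise ValueError("constant signal cannot carry a nonzero effect size")
    if phi_sq < 1 and v_noise == 0:
        raise ValueError("constant noise vector")
    s_beta = 0.0 if phi_sq == 0 else np.sqrt(n * phi_sq / ((n - 1) * v_sig))
    s_eps = 0.0 if phi_sq == 1 else np.sqrt(n * (1 - phi_sq) / ((n - 1) * v_noise))
    return float(s_beta), float(s_eps)


def _scaled(vec, frac: float) -> np.ndarray:
    """Rescale a component to sample variance exactly ``frac``."""
    vec = np.asarray(vec, float)
    if frac == 0:
        return np.zeros_like(vec)
    v = _pop_var(vec)
    if v == 0:
        raise ValueError("constant component cannot carry variance")
    n = vec.size
    return vec * np.sqrt(n * frac / ((n - 1) * v))


def simulate_qtl_trait(X, phi_sq: float, rng: np.random.Generator,
                       beta_raw=None) -> np.ndarray:
    """One trait with a single QTL: scaled genetic signal plus scaled noise."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if beta_raw is None:
        beta_raw = rng.standard_normal(X.shape[1])
    signal = X @ np.asarray(beta_raw, float)
    noise = rng.standard_normal(X.shape[0])
    s_beta, s_eps = scale_components(signal, noise, phi_sq)
    return s_beta * signal + s_eps * noise


def simulate_mediation_triple(spec: SimulationSpec, X, rng: np.random.Generator):
    """Mediator and outcome vectors under one data-generating scenario.

    co-local: m and y share the genetic effect vector (same beta_raw) but are
    otherwise independent.  complete: y is driven by m alone.  partial: y
    carries both a direct X component and an indirect m component, whose
    sample variances split effect_y according to ``bc_ratio`` (1 means
    half-and-half); cross-term covariance is left random.  The reactive
    scenarios apply the same recipes with y and m swapped.  y_only gives y a
    QTL and leaves m pure noise; none leaves both pure noise.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    model = spec.model
    if model == "none":
        return _scaled(rng.standard_normal(n), 1.0), _scaled(rng.standard_normal(n), 1.0)
    if model == "y_only":
        y = simulate_qtl_trait(X, spec.effect_y, rng)
        m = _scaled(rng.standard_normal(n), 1.0)
        return m, y
    if model == "colocal":
        beta_raw = rng.standard_normal(X.shape[1])
        m = simulate_qtl_trait(X, spec.effect_m, rng, beta_raw=beta_raw)
        y = simulate_qtl_trait(X, spec.effect_y, rng, beta_raw=beta_raw)
        return m, y

    swap = model.startswith("reactive_")
    base = model.removeprefix("reactive_")
    m = simulate_qtl_trait(X, spec.effect_m, rng)
    beta_m = rng.standard_normal()
    noise = rng.standard_normal(n)
    if base == "complete":
        y = _scaled(m * beta_m, spec.effect_y) + _scaled(noise, 1 - spec.effect_y)
    else:  # partial
        beta_direct = rng.standard_normal(X.shape[1])
        b_share = spec.bc_ratio / (1.0 + spec.bc_ratio)
        indirect = _scaled(m * beta_m, spec.effect_y * b_share)
        direct = _scaled(X @ beta_direct, spec.effect_y * (1.0 - b_share))
        y = direct + indirect + _scaled(noise, 1 - spec.effect_y)
    return (y, m) if swap else (m, y)


def make_genotypes(design: GenotypeDesign, n: int, rng: np.random.Generator):
    """Genotype matrix X plus the true functional-allele label per individual.

    Balanced designs are deterministic nearest-equal splits whose rows are
    then shuffled by the seeded generator, so balance is exact (e.g. 100/100
    for a balanced bi-allelic variant at n = 200).
    """
    k = 2 if design.kind == "biallelic" else design.n_alleles
    if design.kind in ("biallelic", "multiallelic_k"):
        if design.freqs is None:
            counts = np.full(k, n // k)
            counts[: n % k] += 1
            if n % k:
                logger.info("n=%d not divisible by %d classes; using nearest "
                            "split %s", n, k, counts.tolist())
        else:
            counts = np.floor(np.asarray(design.freqs) * n).astype(int)
            counts[np.argmax(counts)] += n - counts.sum()
        labels = np.repeat(np.arange(k), counts)
        labels = labels[rng.permutation(n)]
        if design.kind == "biallelic":
            return labels[:, None].astype(float), labels
        # k-1 indicator columns (first allele as reference)
        X = np.zeros((n, k - 1))
        for j in range(1, k):
            X[:, j - 1] = labels == j
        return X, labels

    # haplotype8: two founder draws per individual, dosage rows sum to 2
    freqs = design.freqs or (0.125,) * 8
    draws = rng.choice(8, size=(n, 2), p=np.asarray(freqs))
    X = np.zeros((n, 8))
    for c in range(2):
        np.add.at(X, (np.arange(n), draws[:, c]), 1.0)
    allele = np.asarray(design.allele_of_founder)
    labels = allele[draws].sum(axis=1)  # functional-allele dosage 0/1/2
    return X, labels


def make_tag_variant(truth, collapse=None, target_r: float = None,
                     rng: np.random.Generator = None):
    """A tag variant imperfectly capturing the true functional alleles.

    Collapse mode maps each functional allele deterministically to a binary
    tag dosage (e.g. tagging the two higher of four alleles).  The target-r
    mode takes a balanced binary truth and flips a fraction ``p = (1 - r)/2``
    of entries symmetrically, which gives expected Pearson correlation
    ``1 - 2p`` with the truth; the realized correlation is returned alongside.
    """
    truth = np.asarray(truth)
    if (collapse is None) == (target_r is None):
        raise ValueError("specify exactly one of collapse or target_r")
    if collapse is not None:
        tag = np.array([float(collapse[int(t)]) for t in truth])
    else:
        if not 0.0 < target_r <= 1.0:
            raise ValueError("target_r must lie in (0, 1]")
        vals = np.unique(truth)
        if vals.size != 2:
            raise ValueError("target_r mode requires a binary truth variant")
        if rng is None:
            raise ValueError("target_r mode requires a random generator")
        binary = (truth == vals[1]).astype(float)
        p = (1.0 - target_r) / 2.0
        flips = rng.random(truth.size) < p
        tag = np.where(flips, 1.0 - binary, binary)
    t = truth.astype(float)
    if tag.std() == 0 or t.std() == 0:
        realized = 0.0
    else:
        realized = float(np.corrcoef(t, tag)[0, 1])
    return tag, realized


def simulate_dataset(spec: SimulationSpec):
    """Convenience wrapper: genotypes plus (m, y) from a seeded generator."""
    rng = np.random.default_rng(spec.seed)
    X, labels = make_genotypes(spec.genotype, spec.n, rng)
    m, y = simulate_mediation_triple(spec, X, rng)
    return X, labels, m, y
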