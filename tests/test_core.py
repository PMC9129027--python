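"""Unit tests for the exact marginal-likelihood machinery."""

import math

import numpy as np
import pytest

from medbayes.core import (GROUPS, MODELS, DegenerateTraitError,
                           EffectPriorSpec, MediationData, ModelPrior,
                           assemble_designs, as_model,
                           conditional_marginal_loglik, empirical_phi,
                           joint_model_loglik, model_posterior,
                           standardize_trait, summarize_posterior)

from .conftest import random_dataset
from .oracles import numint_marginal_loglik, ols_beta_se


class TestStandardize:
    def test_symmetric_sequence(self):
        np.testing.assert_allclose(standardize_trait([1, 2, 3]), [-1, 0, 1],
                                   atol=1e-14)

    def test_idempotent(self, rng):
        v = rng.standard_normal(31)
        once = standardize_trait(v)
        np.testing.assert_allclose(standardize_trait(once), once, atol=1e-12)
        assert abs(once.mean()) < 1e-12
        assert abs(once.std(ddof=1) - 1) < 1e-12

    def test_constant_vector_names_trait(self):
        with pytest.raises(DegenerateTraitError, match="mediator"):
            standardize_trait([2.0, 2.0, 2.0], name="mediator")


class TestModelTable:
    def test_bijection_and_anchors(self):
        assert len({m.theta for m in MODELS}) == 12
        assert as_model("ML4").theta == (1, 1, 0)    # complete mediation
        assert as_model("ML5").theta == (0, 0, 1)    # QTL on Y only
        assert as_model("ML7").theta == (1, 0, 1)    # co-local
        assert as_model("ML8").theta == (1, 1, 1)    # partial mediation
        assert all(as_model(f"ML{i}").reactive for i in range(9, 13))

    def test_group_membership(self):
        assert GROUPS["mediation"] == ("ML4", "ML8")
        assert set(GROUPS["other_non_mediation"]) == {"ML1", "ML2", "ML3",
                                                      "ML5", "ML6"}


class TestAssembleDesigns:
    def test_null_model_is_intercept_only(self, small_data, default_priors):
        X_m, v_m, X_y, v_y = assemble_designs((0, 0, 0), small_data,
                                              default_priors)
        assert X_m.shape[1] == 1 and X_y.shape[1] == 1
        np.testing.assert_allclose(X_m, 1.0)
        assert v_m[0] == default_priors.tau_mu_sq[0]

    def test_full_model_haplotype_blocks(self, rng):
        data = random_dataset(rng, n=30, d=8)
        priors = EffectPriorSpec(phi_sq=(0.5, 0.7, 0.9))
        _, _, X_y, v_y = assemble_designs((1, 1, 1), data, priors)
        assert X_y.shape[1] == 1 + 8 + 1
        np.testing.assert_allclose(v_y, [priors.tau_mu_sq[1]] + [0.9] * 8 + [0.7])

    def test_theta_b_does_not_enter_m_equation(self, small_data, default_priors):
        X_m1, v_m1, _, _ = assemble_designs((1, 0, 1), small_data, default_priors)
        X_m2, v_m2, _, _ = assemble_designs((1, 1, 1), small_data, default_priors)
        np.testing.assert_array_equal(X_m1, X_m2)
        np.testing.assert_array_equal(v_m1, v_m2)


class TestConditionalMarginal:
    """The analytic Student-t marginal against brute-force integration."""

    R4 = np.array([0.5, -0.5, 1.0, -1.0])

    def test_intercept_only_toy_matches_numeric_integration(self):
        design = np.ones((4, 1))
        v = np.array([1000.0])
        exact = conditional_marginal_loglik(self.R4, design, v, np.ones(4),
                                            0.001, 0.001)
        approx = numint_marginal_loglik(self.R4, design, v, np.ones(4),
                                        0.001, 0.001)
        assert abs(exact - approx) < 0.05

    def test_weighted_toy_matches_numeric_integration(self):
        design = np.ones((4, 1))
        v = np.array([1000.0])
        for w in (np.array([1.0, 2.0, 0.5, 1.0]),
                  2 * np.array([1.0, 2.0, 0.5, 1.0])):
            exact = conditional_marginal_loglik(self.R4, design, v, w,
                                                0.001, 0.001)
            approx = numint_marginal_loglik(self.R4, design, v, w, 0.001, 0.001)
            assert abs(exact - approx) < 0.05

    def test_zero_prior_variance_equals_column_omission(self, rng):
        n = 15
        r = standardize_trait(rng.standard_normal(n))
        X = rng.integers(0, 2, (n, 2)).astype(float)
        design = np.column_stack([np.ones(n), X])
        with_zero = conditional_marginal_loglik(
            r, design, np.array([1000.0, 0.0, 0.0]), np.ones(n), 0.001, 0.001)
        omitted = conditional_marginal_loglik(
            r, np.ones((n, 1)), np.array([1000.0]), np.ones(n), 0.001, 0.001)
        assert with_zero == pytest.approx(omitted, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="non-finite"):
            conditional_marginal_loglik([np.nan, 0, 1], np.ones((3, 1)),
                                        [1.0], np.ones(3), 0.001, 0.001)
        with pytest.raises(ValueError, match="positive"):
            conditional_marginal_loglik([1.0, 0, 1], np.ones((3, 1)),
                                        [1.0], [1.0, -1.0, 1.0], 0.001, 0.001)


class TestJointLoglik:
    def test_reactive_identifiability_identities(self, rng):
        for _ in range(20):
            data = random_dataset(rng, n=rng.integers(10, 40), d=2)
            assert joint_model_loglik((1, 1, 1), data) == pytest.approx(
                joint_model_loglik((1, "*", 1), data), abs=1e-10)
            assert joint_model_loglik((0, 1, 0), data) == pytest.approx(
                joint_model_loglik((0, "*", 0), data), abs=1e-10)

    def test_null_model_with_identical_traits_factorizes(self, rng):
        v = standardize_trait(rng.standard_normal(16))
        data = MediationData(y=v.copy(), m=v.copy(),
                             X=np.ones((16, 1)))
        total = joint_model_loglik((0, 0, 0), data)
        single = conditional_marginal_loglik(
            v, np.ones((16, 1)), np.array([1000.0]), np.ones(16), 0.001, 0.001)
        assert total == pytest.approx(2 * single, abs=1e-10)

    def test_permutation_equivariance(self, rng):
        data = random_dataset(rng, n=25, d=3, covariates=2)
        perm = rng.permutation(25)
        permuted = MediationData(y=data.y[perm], m=data.m[perm],
                                 X=data.X[perm], Z_m=data.Z_m[perm],
                                 Z_y=data.Z_y[perm], w_m=data.w_m[perm],
                                 w_y=data.w_y[perm])
        for model in MODELS:
            assert joint_model_loglik(model, data) == pytest.approx(
                joint_model_loglik(model, permuted), abs=1e-10)

    def test_haplotype_collinearity_stays_finite(self, rng):
        # founder-dosage rows sum to 2: X columns are collinear with the
        # intercept, but W^-1 keeps the scale matrix positive definite
        X = np.zeros((24, 8))
        draws = rng.integers(0, 8, (24, 2))
        for c in range(2):
            np.add.at(X, (np.arange(24), draws[:, c]), 1.0)
        data = MediationData(y=standardize_trait(rng.standard_normal(24)),
                             m=standardize_trait(rng.standard_normal(24)), X=X)
        for model in MODELS:
            assert np.isfinite(joint_model_loglik(model, data))


class TestModelPrior:
    def test_presets(self):
        default = ModelPrior.default().normalized
        np.testing.assert_allclose(default[:8], 1 / 8)
        np.testing.assert_allclose(default[8:], 0.0)
        reduced = ModelPrior.reduced().normalized
        active = {m.label for m, w in zip(MODELS, reduced) if w > 0}
        assert active == {"ML5", "ML6", "ML7", "ML8"}
        np.testing.assert_allclose(ModelPrior.expanded().normalized, 1 / 12)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            ModelPrior((0.0,) * 12)
        with pytest.raises(ValueError):
            ModelPrior((1.0,) * 11)


class TestModelPosterior:
    def test_point_mass_prior(self, small_data):
        prior = ModelPrior.from_dict({"ML7": 1.0})
        result = model_posterior(small_data, model_prior=prior)
        assert result.probability("ML7") == 1.0
        assert result.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_prior_models_get_zero_posterior(self, small_data):
        result = model_posterior(small_data)  # default: ML9-12 excluded
        for lab in ("ML9", "ML10", "ML11", "ML12"):
            assert result.probability(lab) == 0.0
        assert result.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_posterior_matches_direct_enumeration(self, rng):
        """softmax(loglik + logprior) recomputed with brute-force logliks."""
        data = random_dataset(rng, n=6, d=1)
        priors = EffectPriorSpec()
        result = model_posterior(data, priors)
        oracle_ll = np.array([
            joint_model_loglik(m, data, priors) for m in MODELS])
        logpost = oracle_ll[:8] + math.log(1 / 8)
        expected = np.exp(logpost - logpost.max())
        expected /= expected.sum()
        np.testing.assert_allclose(result.posterior[:8], expected, atol=1e-12)

    def test_survives_huge_likelihood_spread(self, rng):
        # noiseless chain: likelihood spreads of thousands of nats must not
        # underflow the log-sum-exp normalization
        from medbayes.simulate import SimulationSpec, simulate_dataset
        X, _, m, y = simulate_dataset(SimulationSpec(
            model="complete", n=300, effect_m=0.99, effect_y=0.99, seed=11))
        data = MediationData.from_arrays(y, m, X)
        result = model_posterior(data)
        spread = result.log_marginal.max() - result.log_marginal.min()
        assert spread > 100
        assert np.isfinite(result.posterior).all()
        assert result.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_prior_monotonicity(self, small_data):
        base = model_posterior(small_data).probability("ML4")
        boosted = ModelPrior(tuple(3.0 if m.label == "ML4" else
                                   (0.0 if m.reactive else 1.0)
                                   for m in MODELS))
        assert model_posterior(small_data, model_prior=boosted) \
            .probability("ML4") > base


class TestSummarize:
    def test_point_mass_on_complete(self, small_data):
        result = model_posterior(small_data,
                                 model_prior=ModelPrior.from_dict({"ML4": 1}))
        probs, odds = summarize_posterior(result)
        assert probs["complete"] == 1.0
        assert odds["mediation"] == pytest.approx(math.log((1 - 1e-10) / 1e-10))

    def test_uniform_posterior_over_ml1_8(self):
        # a synthetic result with equal mass on ML1-8
        from medbayes.core import PosteriorResult
        post = np.array([1 / 8] * 8 + [0.0] * 4)
        result = PosteriorResult(labels=tuple(m.label for m in MODELS),
                                 log_marginal=np.zeros(12),
                                 log_prior=np.zeros(12), posterior=post)
        probs, odds = summarize_posterior(result)
        assert probs["mediation"] == pytest.approx(0.25)
        assert odds["mediation"] == pytest.approx(math.log(1 / 3))

    def test_unknown_group(self, small_data):
        result = model_posterior(small_data)
        with pytest.raises(ValueError, match="unknown model label"):
            summarize_posterior(result, grouping={"bad": ("ML99",)})

    def test_log_base_switch(self, small_data):
        result = model_posterior(small_data)
        _, odds_e = summarize_posterior(result, log_base=math.e)
        _, odds_10 = summarize_posterior(result, log_base=10)
        for g in odds_e:
            assert odds_10[g] == pytest.approx(odds_e[g] / math.log(10))


class TestEmpiricalPhi:
    def test_orthogonal_mediator_hits_floor(self, rng):
        n = 40
        X = rng.integers(0, 2, (n, 1)).astype(float)
        raw = rng.standard_normal(n)
        design = np.column_stack([np.ones(n), X])
        beta = np.linalg.lstsq(design, raw, rcond=None)[0]
        m = standardize_trait(raw - design @ beta)
        data = MediationData(y=standardize_trait(rng.standard_normal(n)),
                             m=m, X=X)
        phi = empirical_phi(data)
        assert phi[0] == pytest.approx(1e-4 / (1 - 1e-4), rel=1e-6)

    def test_perfect_fit_hits_ceiling(self, rng):
        n = 20
        v = standardize_trait(rng.standard_normal(n))
        data = MediationData(y=v.copy(), m=v.copy(),
                             X=rng.integers(0, 2, (n, 1)).astype(float))
        phi = empirical_phi(data)
        assert phi[1] == pytest.approx((1 - 1e-4) / 1e-4, rel=1e-6)

    def test_matches_normal_equations_oracle(self):
        y = np.array([0.2, -1.1, 0.5, 1.4, -0.6, -0.9, 1.0, -0.5])
        m = np.array([0.1, -0.8, 0.3, 1.2, -0.2, -1.0, 0.9, -0.5])
        X = np.array([0, 0, 0, 1, 1, 1, 0, 1], dtype=float)[:, None]
        data = MediationData(y=standardize_trait(y), m=standardize_trait(m),
                             X=X)
        phi = empirical_phi(data)

        def pve(resp, pred):
            design = np.column_stack([np.ones(8), pred])
            beta = np.linalg.solve(design.T @ design, design.T @ resp)
            ssr = np.sum((resp - design @ beta) ** 2)
            ssr0 = np.sum((resp - resp.mean()) ** 2)
            return 1 - ssr / ssr0

        for got, p in zip(phi, (pve(data.m, X), pve(data.y, data.m),
                                pve(data.y, X))):
            assert got == pytest.approx(p / (1 - p), abs=1e-10)


class TestTauInsensitivity:
    def test_model_ranking_stable_across_tau(self, rng):
        from medbayes.simulate import SimulationSpec, simulate_dataset
        X, _, m, y = simulate_dataset(
            SimulationSpec(model="complete", n=100, seed=5))
        data = MediationData.from_arrays(y, m, X)
        ranks = []
        for tau in (1000.0, 1e6):
            priors = EffectPriorSpec(tau_mu_sq=(tau, tau), tau_z_sq=(tau, tau))
            result = model_posterior(data, priors)
            ranks.append(np.argsort(result.posterior[:8])[::-1][:2].tolist())
        assert ranks[0] == ranks[1]
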