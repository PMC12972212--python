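import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betaclock import (
    AgeLikelihoodProfile,
    ClockConfig,
    InfeasibleMomentsError,
    NoOverlapError,
    ReferenceMatrix,
    ValidationError,
    age_log_likelihood,
    beta_shape_params,
    log_prob_beta,
    log_prob_normal,
    predict_age,
)
from betaclock.likelihood import profile_matrix


class TestBetaShapeParams:
    @pytest.mark.parametrize("mu,var,alpha,beta", [
        (0.5, 0.05, 2.0, 2.0),
        (0.2, 0.01, 3.0, 12.0),
    ])
    def test_known_moment_pairs(self, mu, var, alpha, beta):
        shape = beta_shape_params(mu, var)
        assert shape.alpha == pytest.approx(alpha)
        assert shape.beta_param == pytest.approx(beta)

    def test_round_trips_through_beta_moment_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            mu = rng.uniform(0.02, 0.98)
            var = rng.uniform(0.05, 0.95) * mu * (1 - mu)
            a, b = beta_shape_params(mu, var)
            assert a > 0 and b > 0
            assert a / (a + b) == pytest.approx(mu, abs=1e-10)
            assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(var, abs=1e-10)

    def test_variance_at_bernoulli_bound_is_infeasible(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_shape_params(0.5, 0.25)

    @pytest.mark.parametrize("mu", [0.0, 1.0, -0.1, 1.5])
    def test_mean_outside_open_unit_interval_rejected(self, mu):
        with pytest.raises(ValidationError):
            beta_shape_params(mu, 0.01)


class TestLogDensities:
    def test_uniform_beta_density_is_zero_log(self):
        shape = beta_shape_params(0.5, 1 / 12 - 1e-9)  # ~Beta(1,1)
        for x in (0.2, 0.5, 0.9):
            assert log_prob_beta(x, shape) == pytest.approx(0.0, abs=1e-6)

    def test_beta_2_2_at_half(self):
        from betaclock import BetaShape

        assert log_prob_beta(0.5, BetaShape(2.0, 2.0)) == pytest.approx(
            np.log(1.5), abs=1e-12
        )

    def test_beta_matches_scipy_logpdf(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = rng.uniform(0.2, 50, 2)
            x = rng.uniform(0.01, 0.99)
            from betaclock import BetaShape

            assert log_prob_beta(x, BetaShape(a, b)) == pytest.approx(
                stats.beta.logpdf(x, a, b), abs=1e-10
            )

    def test_beta_finite_at_boundary_values(self):
        from betaclock import BetaShape

        assert np.isfinite(log_prob_beta(0.0, BetaShape(3.0, 7.0)))
        assert np.isfinite(log_prob_beta(1.0, BetaShape(3.0, 7.0)))

    @pytest.mark.parametrize("x,mu,sigma,expected", [
        (0.0, 0.0, 1.0, -0.9189385),
        (1.0, 0.0, 1.0, -1.4189385),
        (0.3, 0.3, 0.5, -0.2257914),
    ])
    def test_normal_reference_values(self, x, mu, sigma, expected):
        assert log_prob_normal(x, mu, sigma) == pytest.approx(expected, abs=1e-6)

    def test_normal_matches_scipy_logpdf(self):
        rng = np.random.default_rng(2)
        x, mu, sigma = rng.uniform(0, 1, 3)
        sigma = max(sigma, 0.05)
        assert log_prob_normal(x, mu, sigma) == pytest.approx(
            stats.norm.logpdf(x, mu, sigma), abs=1e-12
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            log_prob_normal(0.5, 0.5, 0.0)


def _toy_reference(n_sites=3, seed=0, n_ages=101):
    rng = np.random.default_rng(seed)
    grid = np.arange(n_ages, dtype=float)
    mu = np.clip(
        rng.uniform(0.1, 0.6, n_sites)[:, None]
        + rng.uniform(0.001, 0.004, n_sites)[:, None] * grid,
        0.01,
        0.99,
    )
    sigma = rng.uniform(0.02, 0.06, (n_sites, n_ages))
    return ReferenceMatrix(
        site_ids=[f"cg{j:08d}" for j in range(n_sites)],
        age_grid=grid,
        mu=mu,
        sigma=sigma,
    )


class TestAgeLogLikelihood:
    @pytest.mark.parametrize("family", ["normal", "beta"])
    def test_matches_per_site_loop_and_sum_oracle(self, family):
        ref = _toy_reference(n_sites=16, seed=3)
        rng = np.random.default_rng(4)
        sample = pd.Series(rng.uniform(0.05, 0.95, 16), index=ref.site_ids)
        cfg = ClockConfig(family=family)
        profile = age_log_likelihood(sample, ref, cfg)
        for k in [0, 7, 50, 100]:
            total = 0.0
            for i, site in enumerate(ref.site_ids):
                mu, sg = ref.mu[i, k], ref.sigma[i, k]
                if family == "normal":
                    total += stats.norm.logpdf(sample[site], mu, sg)
                else:
                    var = min(sg**2, 0.99 * mu * (1 - mu))
                    a = mu * (mu * (1 - mu) - var) / var
                    b = (1 - mu) * (mu * (1 - mu) - var) / var
                    total += stats.beta.logpdf(sample[site], a, b)
            assert profile.log_likelihood[k] == pytest.approx(total, abs=1e-10)

    def test_peak_at_matching_grid_age_with_constant_sigma(self):
        ref = _toy_reference(n_sites=1, seed=5)
        ref.sigma[:] = 0.05
        target = 37
        profile = age_log_likelihood(
            pd.Series({ref.site_ids[0]: ref.mu[0, target]}), ref
        )
        assert predict_age(profile) == target

    def test_missing_site_silently_excluded(self):
        ref = _toy_reference(n_sites=2, seed=6)
        sample_full = pd.Series({ref.site_ids[0]: 0.4, ref.site_ids[1]: np.nan})
        sample_one = pd.Series({ref.site_ids[0]: 0.4})
        p2 = age_log_likelihood(sample_full, ref)
        p1 = age_log_likelihood(sample_one, ref)
        assert p2.n_sites_used == 1
        np.testing.assert_array_equal(p2.log_likelihood, p1.log_likelihood)

    def test_zero_overlap_raises_named_error(self):
        ref = _toy_reference(n_sites=2, seed=7)
        with pytest.raises(NoOverlapError, match="s_bad"):
            age_log_likelihood(
                pd.Series({"cg99999999": 0.5}), ref, sample_id="s_bad"
            )

    def test_profile_is_finite_everywhere(self):
        ref = _toy_reference(n_sites=5, seed=8)
        sample = pd.Series([0.0, 1.0, 0.5, 0.999, 1e-9], index=ref.site_ids)
        for family in ("normal", "beta"):
            p = age_log_likelihood(sample, ref, ClockConfig(family=family))
            assert np.isfinite(p.log_likelihood).all()

    def test_posterior_normalizes_to_one(self):
        ref = _toy_reference(n_sites=4, seed=9)
        sample = pd.Series(0.5, index=ref.site_ids)
        p = age_log_likelihood(sample, ref)
        assert p.posterior().sum() == pytest.approx(1.0, abs=1e-12)

    def test_flat_reference_site_shifts_profile_but_not_argmax(self):
        ref = _toy_reference(n_sites=3, seed=10)
        rng = np.random.default_rng(11)
        sample = pd.Series(rng.uniform(0.2, 0.8, 3), index=ref.site_ids)
        base = age_log_likelihood(sample, ref)
        flat = ReferenceMatrix(
            site_ids=ref.site_ids + ["cgFLAT"],
            age_grid=ref.age_grid,
            mu=np.vstack([ref.mu, np.full(101, 0.5)]),
            sigma=np.vstack([ref.sigma, np.full(101, 0.05)]),
        )
        sample2 = pd.concat([sample, pd.Series({"cgFLAT": 0.31})])
        shifted = age_log_likelihood(sample2, flat)
        assert predict_age(shifted) == predict_age(base)
        diff = shifted.log_likelihood - base.log_likelihood
        np.testing.assert_allclose(diff, diff[0], atol=1e-12)


class TestPredictAge:
    def test_simple_argmax(self):
        L = np.full(101, -50.0)
        L[1] = -1.0
        p = AgeLikelihoodProfile(np.arange(101.0), L, 5)
        assert predict_age(p) == 1.0

    def test_exact_tie_resolves_to_youngest(self):
        L = np.full(101, -50.0)
        L[30] = L[40] = -2.0
        p = AgeLikelihoodProfile(np.arange(101.0), L, 5)
        assert predict_age(p) == 30.0

    def test_tie_prefers_ages_inside_training_support(self):
        # constant-extrapolated references tie every age below the training
        # range; the youngest *supported* age wins
        L = np.full(101, -50.0)
        L[:27] = -2.0
        p = AgeLikelihoodProfile(np.arange(101.0), L, 5, support=(26.0, 100.0))
        assert predict_age(p) == 26.0
        p_nosupport = AgeLikelihoodProfile(np.arange(101.0), L, 5)
        assert predict_age(p_nosupport) == 0.0

    def test_prediction_always_on_grid(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            L = rng.normal(size=101)
            p = AgeLikelihoodProfile(np.arange(101.0), L, 1)
            assert 0 <= predict_age(p) <= 100


def test_profile_matrix_flags_samples_without_overlap():
    ref = _toy_reference(n_sites=2, seed=13)
    betas = pd.DataFrame(
        {ref.site_ids[0]: [0.4, np.nan], ref.site_ids[1]: [0.5, np.nan]},
        index=["ok", "empty"],
    )
    L, n_used = profile_matrix(betas, ref)
    assert n_used.tolist() == [2, 0]
    assert np.isfinite(L[0]).all() and np.isnan(L[1]).all()
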