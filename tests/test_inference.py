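"""Gibbs sampler: oracle equivalence, symmetry, summaries, deviance."""

import numpy as np
import pandas as pd
import pytest

from geologit.dataset import CLUSTER, DISTRICT, OUTCOME, SurveyDataset
from geologit.inference import (
    MCMCSettings,
    ModelSpec,
    PosteriorDraws,
    deviance,
    fit_model,
    summarize,
)

from conftest import intercept_only_spec


def _grid_posterior(loglik, grid):
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    mean = w @ grid
    sd = np.sqrt(w @ (grid - mean) ** 2)
    return mean, sd


class TestOracleEquivalence:
    def test_intercept_only_matches_quadrature(self, intercept_only_data):
        mcmc = MCMCSettings(iterations=6000, burn_in=1000, thinning=1, seed=5)
        draws = fit_model(intercept_only_data, None, intercept_only_spec(), mcmc)
        b = np.linspace(-4, 3, 14_001)
        loglik = 35 * b - 100 * np.logaddexp(0, b) - b**2 / 2e6
        qmean, qsd = _grid_posterior(loglik, b)
        assert abs(draws.beta.mean() - qmean) < 0.02
        assert abs(draws.beta.std() - qsd) < 0.02

    def test_intercept_plus_dummy_matches_quadrature(self):
        # 2-parameter flat-prior posterior vs dense 2-D quadrature:
        # group A 30/80 successes, group B 35/50
        y = np.array([1] * 30 + [0] * 50 + [1] * 35 + [0] * 15)
        grp = np.array(["a"] * 80 + ["b"] * 50)
        ds = SurveyDataset(pd.DataFrame({OUTCOME: y, "g": grp,
                                         DISTRICT: 1, CLUSTER: 1}))
        spec = ModelSpec(model_id=1, fixed_references={"g": "a"},
                         linear_covariates=[])
        mcmc = MCMCSettings(iterations=8000, burn_in=1000, thinning=1, seed=17)
        draws = fit_model(ds, None, spec, mcmc)
        b0 = np.linspace(-2.5, 1.5, 401)
        b1 = np.linspace(-1.5, 3.5, 401)
        bb0, bb1 = np.meshgrid(b0, b1, indexing="ij")
        ll = (
            30 * bb0 - 80 * np.logaddexp(0, bb0)
            + 35 * (bb0 + bb1) - 50 * np.logaddexp(0, bb0 + bb1)
            - (bb0**2 + bb1**2) / 2e6
        )
        w = np.exp(ll - ll.max())
        w /= w.sum()
        for j, grid in ((0, bb0), (1, bb1)):
            qmean = float((w * grid).sum())
            assert abs(draws.beta[:, j].mean() - qmean) < 0.03, j

    def test_balanced_data_gives_zero_effects(self):
        # equal successes and failures at every level: posterior symmetric
        levels = np.repeat(["a", "b", "c"], 200)
        y = np.tile([0, 1], 300)
        ds = SurveyDataset(pd.DataFrame({OUTCOME: y, "g": levels,
                                         DISTRICT: 1, CLUSTER: 1}))
        spec = ModelSpec(model_id=1, fixed_references={"g": "a"},
                         linear_covariates=[])
        mcmc = MCMCSettings(iterations=4000, burn_in=500, thinning=1, seed=23)
        draws = fit_model(ds, None, spec, mcmc)
        sds = draws.beta.std(axis=0)
        assert np.all(np.abs(draws.beta.mean(axis=0)) < 3 * sds / 10)


class TestSamplerMechanics:
    def test_seeded_determinism(self, recovery_dataset, lattice):
        from geologit.studies import recovery_model_spec

        mcmc = MCMCSettings(iterations=120, burn_in=20, thinning=2, seed=31)
        a = fit_model(recovery_dataset, lattice, recovery_model_spec(4), mcmc)
        b = fit_model(recovery_dataset, lattice, recovery_model_spec(4), mcmc)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.spatial, b.spatial)
        np.testing.assert_array_equal(a.deviances, b.deviances)

    def test_constraints_hold_at_every_retained_draw(self, small_fit):
        draws, _, _ = small_fit
        for f in draws.smooths.values():
            assert np.abs(f.sum(axis=1)).max() < 1e-8
        assert np.abs(draws.spatial.sum(axis=1)).max() < 1e-8

    def test_all_draws_finite(self, small_fit):
        draws, _, _ = small_fit
        assert np.isfinite(draws.beta).all()
        assert np.isfinite(draws.deviances).all()
        for t in draws.taus.values():
            assert np.isfinite(t).all() and (t > 0).all()

    def test_spatial_model_requires_graph(self, recovery_dataset):
        from geologit.studies import recovery_model_spec

        mcmc = MCMCSettings(iterations=10, burn_in=2, thinning=1, seed=1)
        with pytest.raises(ValueError, match="graph"):
            fit_model(recovery_dataset, None, recovery_model_spec(4), mcmc)

    def test_district_missing_from_graph_rejected(self, recovery_dataset):
        from geologit.simulate import make_lattice_adjacency
        from geologit.studies import recovery_model_spec

        small = make_lattice_adjacency(2, 2)  # ids 1..4 only
        mcmc = MCMCSettings(iterations=10, burn_in=2, thinning=1, seed=1)
        with pytest.raises(ValueError, match="absent from adjacency"):
            fit_model(recovery_dataset, small, recovery_model_spec(4), mcmc)

    def test_settings_validation(self):
        with pytest.raises(ValueError, match="seed"):
            MCMCSettings(iterations=100, burn_in=10, thinning=1)
        with pytest.raises(ValueError):
            MCMCSettings(iterations=100, burn_in=200, thinning=1, seed=1)
        with pytest.raises(ValueError):
            MCMCSettings(iterations=100, burn_in=10, thinning=0, seed=1)


class TestSummarize:
    def test_degenerate_draws_give_unit_odds_ratio(self):
        draws = _manual_draws(beta=np.zeros((50, 1)))
        s = summarize(draws)
        row = s.fixed.iloc[0]
        assert row["odds_ratio"] == 1.0
        assert row["or_lower"] == 1.0 and row["or_upper"] == 1.0

    def test_odds_ratio_is_exp_of_posterior_mean(self):
        rng = np.random.default_rng(3)
        b = rng.normal(0.5841, 0.19, size=(4000, 1))
        s = summarize(_manual_draws(beta=b))
        row = s.fixed.iloc[0]
        assert np.isclose(row["odds_ratio"], np.exp(b.mean()))
        # the published tertiary-education arithmetic: exp(0.5841) = 1.7934
        assert abs(np.exp(0.5841) - 1.7934) < 5e-5
        assert row["or_lower"] < row["odds_ratio"] < row["or_upper"]

    def test_quantiles_agree_with_sorting(self):
        rng = np.random.default_rng(9)
        b = rng.standard_normal((999, 1))
        s = summarize(_manual_draws(beta=b))
        srt = np.sort(b[:, 0])
        lo = np.exp(np.quantile(srt, 0.025))
        hi = np.exp(np.quantile(srt, 0.975))
        assert np.isclose(s.fixed.iloc[0]["or_lower"], lo)
        assert np.isclose(s.fixed.iloc[0]["or_upper"], hi)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(_manual_draws(beta=np.zeros((1, 1))))


def _manual_draws(beta: np.ndarray) -> PosteriorDraws:
    r = beta.shape[0]
    return PosteriorDraws(
        beta=beta,
        beta_labels=["intercept"],
        smooths={},
        smooth_grids={},
        spatial=None,
        district_ids=None,
        taus={},
        deviances=np.full(r, 1.0),
        eta_mean=np.zeros(4),
        model_id=1,
        settings=MCMCSettings(iterations=max(r, 2), burn_in=0, thinning=1, seed=0),
    )


class TestDeviance:
    def test_two_records_at_half(self):
        # -2 * 2 * log(0.5) = 2.7726
        val = deviance(np.array([1, 0]), np.array([0.5, 0.5]))
        assert np.isclose(val, -4 * np.log(0.5))
        assert np.isclose(val, 2.7726, atol=5e-5)

    def test_perfect_fit_limit(self):
        y = np.array([1, 0, 1])
        for eps in (1e-3, 1e-6, 1e-9):
            p = np.where(y == 1, 1 - eps, eps)
            assert deviance(y, p) < deviance(y, np.abs(y - 10 * eps))
        assert deviance(y, np.where(y == 1, 1 - 1e-12, 1e-12)) < 1e-10

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            p = rng.uniform(0.01, 0.99, 50)
            assert deviance(y, p) >= 0

    def test_conflicting_boundary_probability_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            deviance(np.array([1.0]), np.array([0.0]))
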