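import warnings
from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import make_events
from fearscape import hierarchical_model as hm
from fearscape.event_prep import CameraCluster


def make_summary(mean, ci95, prob_positive, mcse=0.01, sd=0.5):
    return hm.PosteriorSummary(
        name="x", mean=mean, sd=sd, ci95=ci95,
        ci90=(ci95[0] * 0.8, ci95[1] * 0.8),
        prob_positive=prob_positive, mcse=mcse)


class TestModelSpec:
    def test_pure_interaction_rejected(self):
        with pytest.raises(ValueError, match="pure interaction"):
            hm.ModelSpec(response="y", fixed_effects=("a",),
                         interactions=(("a", "b"),))

    def test_term_names_include_interactions(self):
        spec = hm.ModelSpec(response="y", fixed_effects=("a", "b"),
                            interactions=(("a", "b"),))
        assert spec.term_names == ("a", "b", "a:b")


def test_mcmc_config_requires_warmup_lt_iterations():
    with pytest.raises(ValueError):
        hm.MCMCConfig(iterations=100, warmup=100)


class TestBuildResponse:
    def setup_method(self):
        self.clusters = [CameraCluster("K1", ("cam1", "cam2"), (0, 0),
                                       "trail")]
        self.calendar = {"K1": [date(2023, 6, 1), date(2023, 6, 2)]}

    def test_multiple_detections_one_day_binary(self):
        evs = make_events([("cam1", "oryx", 0), ("cam1", "oryx", 120),
                           ("cam2", "oryx", 300)])
        out = hm.build_response(evs, self.clusters, self.calendar, "oryx")
        assert out.loc[out["day"] == date(2023, 6, 1), "oryx"].iloc[0] == 1
        assert out.loc[out["day"] == date(2023, 6, 2), "oryx"].iloc[0] == 0

    def test_predator_lookback_24h(self):
        # lion at 2023-06-01 16:00 (minute 240): within 24 h before the
        # start of day 2023-06-02, so that day's lion_daily is 1
        evs = make_events([("cam1", "lion", 240), ("cam1", "oryx", 1500)])
        out = hm.build_response(evs, self.clusters, self.calendar, "oryx",
                                predators=["lion"])
        assert out.loc[out["day"] == date(2023, 6, 2),
                       "lion_daily"].iloc[0] == 1

    def test_masked_day_absent(self):
        evs = make_events([("cam1", "oryx", 0)])
        out = hm.build_response(evs, self.clusters,
                                {"K1": [date(2023, 6, 2)]}, "oryx")
        assert list(out["day"]) == [date(2023, 6, 2)]


class TestClassifyEffect:
    def test_ci_excluding_zero_is_strong(self):
        s = make_summary(0.66, (0.03, 1.39), 0.98)
        assert hm.classify_effect(s) == "strong"

    def test_directional_mass_is_moderate(self):
        s = make_summary(0.4, (-0.1, 1.0), 0.92)
        assert hm.classify_effect(s) == "moderate"

    def test_small_symmetric_effect_is_none(self):
        s = make_summary(0.05, (-0.5, 0.6), 0.55)
        assert hm.classify_effect(s) == "none"

    def test_weak_tier_asymmetry_rule(self):
        # large mean, CrI barely crossing zero on the off side
        s = make_summary(1.2, (-0.01, 2.9), 0.89, mcse=0.02)
        assert hm.classify_effect(s) == "weak"

    def test_weak_requires_magnitude(self):
        s = make_summary(0.5, (-0.01, 1.5), 0.89, mcse=0.02)
        assert hm.classify_effect(s) == "none"

    def test_error_scale_switch(self):
        s = make_summary(1.2, (-0.01, 2.9), 0.89, mcse=0.02, sd=2.0)
        assert hm.classify_effect(s, error_scale="sd") == "none"


class TestPrune:
    def test_near_zero_predictor_dropped(self):
        s = make_summary(0.01, (-0.15, 0.18), 0.55)
        retained, ledger = hm.prune_predictors([s])
        assert retained == []

    def test_large_mean_retained(self):
        s = make_summary(1.2, (0.5, 1.9), 0.99)
        retained, _ = hm.prune_predictors([s])
        assert retained == ["x"]

    def test_parents_of_retained_interaction_kept(self):
        a = hm.PosteriorSummary("a", 0.01, 0.1, (-0.1, 0.12), (-0.08, 0.1),
                                0.5, 0.01)
        b = hm.PosteriorSummary("b", 0.9, 0.3, (0.3, 1.5), (0.4, 1.4),
                                0.99, 0.01)
        ab = hm.PosteriorSummary("a:b", 0.8, 0.3, (0.2, 1.4), (0.3, 1.3),
                                 0.99, 0.01)
        retained, ledger = hm.prune_predictors(
            [a, b, ab], interactions=[("a", "b")])
        assert set(retained) == {"a", "b", "a:b"}
        assert "parent" in ledger.set_index("predictor").loc["a", "decision"]


class TestSampler:
    def test_prior_reproduced_under_empty_data(self):
        spec = hm.ModelSpec(response="y", fixed_effects=("x1", "x2"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = hm.sample_prior(
                spec, 2, hm.MCMCConfig(chains=4, iterations=2000,
                                       warmup=1000, seed=11))
        sds = draws.beta.reshape(-1, 2).std(axis=0)
        assert np.all(np.abs(sds - 2.0) / 2.0 < 0.10)
        assert abs(draws.intercept.std() - 5.0) / 5.0 < 0.10

    def test_parameter_recovery_single_fit(self):
        rng = np.random.default_rng(5)
        n, n_c, n_s = 3000, 30, 3
        ci = rng.integers(0, n_c, n)
        si = rng.integers(0, n_s, n)
        u = rng.normal(0, 1.0, n_c)
        v = rng.normal(0, 0.5, n_s)
        x1 = rng.standard_normal(n)
        y = (rng.random(n) < expit(-1.0 + 1.0 * x1 + u[ci] + v[si])
             ).astype(float)
        data = pd.DataFrame({"y": y, "x1": x1,
                             "cluster_id": [f"c{i}" for i in ci],
                             "survey_id": [f"s{i}" for i in si]})
        spec = hm.ModelSpec(response="y", fixed_effects=("x1",))
        draws = hm.fit_hier_bernoulli(
            spec, data, hm.MCMCConfig(chains=2, iterations=1500, warmup=500,
                                      seed=3))
        assert 0.7 < draws.beta[:, :, 0].mean() < 1.3
        assert (draws.diagnostics["rhat"] < 1.05).all()

    def test_sigma_shrinks_when_no_cluster_effect(self):
        rng = np.random.default_rng(6)
        n, n_c, n_s = 2000, 20, 2
        ci = rng.integers(0, n_c, n)
        si = rng.integers(0, n_s, n)
        y = (rng.random(n) < expit(-1.0)).astype(float)
        data = pd.DataFrame({"y": y,
                             "cluster_id": [f"c{i}" for i in ci],
                             "survey_id": [f"s{i}" for i in si]})
        spec = hm.ModelSpec(response="y", fixed_effects=())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = hm.fit_hier_bernoulli(
                spec, data, hm.MCMCConfig(chains=2, iterations=1500,
                                          warmup=500, seed=4))
        assert np.median(draws.sigma_cluster) < 0.3

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        data = pd.DataFrame({"y": (rng.random(100) < 0.5).astype(float),
                             "a": x, "b": 2 * x,
                             "cluster_id": "c0", "survey_id": "s0"})
        spec = hm.ModelSpec(response="y", fixed_effects=("a", "b"))
        with pytest.raises(ValueError, match="collinear"):
            hm.fit_hier_bernoulli(spec, data)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"y": (rng.random(200) < 0.4).astype(float),
                             "x": rng.standard_normal(200),
                             "cluster_id": [f"c{i%5}" for i in range(200)],
                             "survey_id": "s0"})
        spec = hm.ModelSpec(response="y", fixed_effects=("x",))
        cfg = hm.MCMCConfig(chains=1, iterations=300, warmup=200, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = hm.fit_hier_bernoulli(spec, data, cfg)
            d2 = hm.fit_hier_bernoulli(spec, data, cfg)
        np.testing.assert_array_equal(d1.beta, d2.beta)


class TestBayesR2:
    def _fit(self, y, x, seed=0, fixed=("x",)):
        data = pd.DataFrame({"y": y, "x": x,
                             "cluster_id": "c0", "survey_id": "s0"})
        spec = hm.ModelSpec(response="y", fixed_effects=fixed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return hm.fit_hier_bernoulli(
                spec, data, hm.MCMCConfig(chains=1, iterations=800,
                                          warmup=400, seed=seed))

    def test_coin_flip_intercept_only_near_zero(self):
        rng = np.random.default_rng(0)
        y = (rng.random(500) < 0.5).astype(float)
        draws = self._fit(y, np.zeros(500) + 0.0, fixed=())
        assert hm.bayes_r2(draws)["mean"] < 0.05

    def test_bounded_and_ordered(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(600)
        y = (rng.random(600) < expit(2.0 * x)).astype(float)
        with_x = self._fit(y, x)
        null = self._fit(y, x, fixed=())
        r2x = hm.bayes_r2(with_x)
        r20 = hm.bayes_r2(null)
        assert np.all((r2x["draws"] >= 0) & (r2x["draws"] <= 1))
        assert r2x["mean"] > r20["mean"]


def test_reparameterization_leaves_probabilities_unchanged():
    """Doubling a covariate column while halving its coefficient draws
    reproduces identical fitted probabilities (logit-link sanity)."""
    rng = np.random.default_rng(3)
    n = 50
    X = rng.standard_normal((n, 1))
    beta = rng.normal(0, 1, (2, 10, 1))
    draws = hm.PosteriorDraws(
        intercept=np.zeros((2, 10)), beta=beta,
        u_cluster=np.zeros((2, 10, 1)), v_survey=np.zeros((2, 10, 1)),
        sigma_cluster=np.ones((2, 10)), sigma_survey=np.ones((2, 10)),
        term_names=("x",), cluster_levels=("c0",), survey_levels=("s0",),
        X=X, y=np.zeros(n), cluster_idx=np.zeros(n, np.intp),
        survey_idx=np.zeros(n, np.intp))
    p1 = hm.fitted_probabilities(draws)
    draws2 = hm.PosteriorDraws(
        intercept=draws.intercept, beta=beta / 2.0,
        u_cluster=draws.u_cluster, v_survey=draws.v_survey,
        sigma_cluster=draws.sigma_cluster, sigma_survey=draws.sigma_survey,
        term_names=("x",), cluster_levels=("c0",), survey_levels=("s0",),
        X=2.0 * X, y=draws.y, cluster_idx=draws.cluster_idx,
        survey_idx=draws.survey_idx)
    np.testing.assert_allclose(p1, hm.fitted_probabilities(draws2))
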