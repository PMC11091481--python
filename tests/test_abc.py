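"""ABC machinery: priors, rejection, regression adjustment and diagnostics.

Toy reference tables with known structure (linear-Gaussian, pure noise,
perfectly informative) serve as independent oracles for the estimator and
its cross-validation / model-choice / goodness-of-fit layers.
"""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enclosim.abc import (
    PriorSpec,
    ReferenceTable,
    abc_fit,
    abc_reject,
    build_reference_table,
    confusion_matrix,
    cross_validate,
    draw_to_model,
    goodness_of_fit,
    model_posterior,
    ridge_adjust,
    sample_prior,
    variant,
)


def gaussian_table(rng, n=5000, noise=0.1, informative=True) -> ReferenceTable:
    """theta ~ N(0,1); stat = theta + N(0, noise^2), or pure noise."""
    theta = rng.normal(0.0, 1.0, n)
    stat = theta + rng.normal(0.0, noise, n) if informative else rng.normal(0.0, 1.0, n)
    return ReferenceTable(pd.DataFrame({"theta": theta}), stat.reshape(-1, 1))


class TestPriors:
    def test_selection_prior_mean_zero_support_above_minus_one(self, rng):
        s = PriorSpec().draw_s(rng, 1_000_000)
        assert s.mean() == pytest.approx(0.0, abs=0.003)
        assert s.min() > -1.0

    def test_uniform_supports(self, rng):
        spec = PriorSpec()
        mv = variant("males_only_lambda_g")
        draws = [sample_prior(spec, mv, rng) for _ in range(2000)]
        h = np.array([d["h"] for d in draws])
        g = np.array([d["g"] for d in draws])
        lam = np.array([d["lam"] for d in draws])
        assert h.min() >= 0 and h.max() <= 1
        assert lam.min() >= 0 and lam.max() <= 1
        assert g.min() >= 0 and g.max() <= 0.5

    def test_variant_parameter_sets(self):
        assert variant("males_only").sampled == ("s", "h")
        assert variant("males_only_g").integrated == ("g",)
        assert variant("males_only_lambda3").estimated == ("s", "h", "lam")
        assert variant("sex_specific").sampled == (
            "s_female", "s_male", "h_female", "h_male",
        )
        with pytest.raises(ValueError):
            variant("nope")

    def test_fixed_parameters_override_prior(self, rng):
        mv = variant("males_only", s=0.42)
        draw = sample_prior(PriorSpec(), mv, rng)
        assert "s" not in draw
        assert draw_to_model(mv, draw).s_male == 0.42

    def test_neutral_variant_materialises_neutral_model(self, rng):
        m = draw_to_model(variant("neutral"), {})
        assert m.s_male == m.s_female == 0.0


class TestBuildReferenceTable:
    def test_shape_and_determinism(self, toy):
        kw = dict(
            spec=PriorSpec(), model_variant=variant("males_only"),
            schedules=toy["trunc"], inits=toy["inits"], mode="A",
            seed=9, start_time=toy["start"],
        )
        a = build_reference_table(100, **kw)
        b = build_reference_table(100, **kw)
        n_pts = toy["design"].n_timepoints - toy["start"] + 1
        assert a.statistics.shape == (100, toy["design"].n_rooms * n_pts)
        assert list(a.parameters.columns) == ["s", "h"]
        assert np.array_equal(a.statistics, b.statistics)
        assert a.parameters.equals(b.parameters)

    def test_parameter_marginals_recover_priors(self, toy_table, rng):
        spec = PriorSpec()
        ref_s = spec.draw_s(rng, 100_000)
        assert stats.ks_2samp(toy_table.parameters["s"], ref_s).pvalue > 0.001
        u = stats.kstest(toy_table.parameters["h"], "uniform").pvalue
        assert u > 0.001

    def test_csv_round_trip(self, toy_table, tmp_path):
        p = tmp_path / "table.csv"
        toy_table.to_csv(p)
        back = ReferenceTable.from_csv(p)
        assert np.allclose(back.statistics, toy_table.statistics)
        assert back.parameters.columns.equals(toy_table.parameters.columns)
        assert back.model_label == toy_table.model_label


class TestAbcReject:
    def test_tolerance_one_returns_prior(self, rng):
        tab = gaussian_table(rng, n=4000)
        res = abc_reject(np.array([0.3]), tab, 1.0)
        assert len(res.accepted_idx) == tab.n
        ks = stats.ks_2samp(res.adjusted_sample["theta"], tab.parameters["theta"])
        assert ks.pvalue > 0.001

    def test_small_table_keeps_single_nearest(self, rng):
        tab = gaussian_table(rng, n=10)
        obs = np.array([tab.statistics[4, 0]])
        res = abc_reject(obs, tab, 0.1)
        assert len(res.accepted_idx) == 1
        assert res.accepted_idx[0] == 4

    def test_exact_match_gets_maximal_weight(self, rng):
        tab = gaussian_table(rng, n=500)
        obs = tab.statistics[17]
        res = abc_reject(obs, tab, 0.2)
        assert res.accepted_idx[0] == 17
        assert res.weights.argmax() == 0
        assert res.weights.sum() == pytest.approx(1.0)

    def test_zero_mad_column_dropped_with_warning(self, rng):
        tab = gaussian_table(rng, n=200)
        tab.statistics = np.hstack([tab.statistics, np.ones((200, 1))])
        with pytest.warns(UserWarning, match="zero-MAD"):
            res = abc_reject(np.array([0.0, 1.0]), tab, 0.5)
        assert len(res.accepted_idx) == 100


class TestRidgeAdjust:
    def test_conjugate_posterior_mean_recovered(self, rng):
        """Linear-Gaussian model: adjusted mean matches the analytic posterior."""
        noise = 0.1
        tab = gaussian_table(rng, n=50_000, noise=noise)
        obs = np.array([0.8])
        post_var = 1.0 / (1.0 + 1.0 / noise**2)
        post_mean = post_var * obs[0] / noise**2
        res = abc_fit(obs, tab, 0.1, transform=False)
        sd = np.sqrt(post_var)
        assert abs(res.posterior_mean["theta"] - post_mean) < 0.05 * sd
        lo, hi = res.interval95.loc["theta"]
        assert lo == pytest.approx(post_mean - 1.96 * sd, abs=0.15 * sd)
        assert hi == pytest.approx(post_mean + 1.96 * sd, abs=0.15 * sd)

    def test_pure_noise_statistics_leave_prior_unchanged(self, rng):
        tab = gaussian_table(rng, n=8000, informative=False)
        res = abc_fit(np.array([0.0]), tab, 0.25, transform=False)
        ks = stats.ks_2samp(res.adjusted_sample["theta"], tab.parameters["theta"])
        assert ks.pvalue > 0.001

    def test_zero_penalty_equal_weights_matches_wls_oracle(self, rng):
        """With a vanishing penalty the conditional mean equals weighted OLS."""
        n = 50
        theta = rng.normal(0, 1, n)
        stat = theta + rng.normal(0, 0.3, n)
        tab = ReferenceTable(pd.DataFrame({"theta": theta}), stat.reshape(-1, 1))
        obs = np.array([0.2])
        rej = abc_reject(obs, tab, 1.0)
        rej.weights = np.full(n, 1.0 / n)
        rej.distances = np.zeros(n)
        res = ridge_adjust(rej, obs, tab, transform=False, alpha=1e-10,
                           heteroscedastic=False)
        # independent oracle: ordinary least squares evaluated at the observation
        x = (stat - np.median(stat)) / np.median(np.abs(stat - np.median(stat)))
        x0 = (obs[0] - np.median(stat)) / np.median(np.abs(stat - np.median(stat)))
        beta = np.polyfit(x, theta, 1)
        m_obs = np.polyval(beta, x0)
        fitted = np.polyval(beta, x)
        expected_mean = np.mean(m_obs + (theta - fitted))
        assert res.posterior_mean["theta"] == pytest.approx(expected_mean, abs=1e-4)

    def test_adjusted_draws_respect_supports(self, toy, toy_table):
        res = abc_fit(toy["obs"], toy_table, 0.2)
        s = res.adjusted_sample["s"]
        h = res.adjusted_sample["h"]
        assert (s > -1).all()
        assert ((h >= 0) & (h <= 1)).all()
        assert (res.interval95.loc["h", "lo"] >= 0.0)
        assert (res.interval95.loc["h", "hi"] <= 1.0)

    def test_tiny_accepted_set_falls_back_to_rejection(self, rng):
        tab = gaussian_table(rng, n=20)
        rej = abc_reject(np.array([0.0]), tab, 0.1)
        with pytest.warns(UserWarning, match="too few"):
            res = ridge_adjust(rej, np.array([0.0]), tab)
        assert not res.adjusted

    def test_tolerance_robustness(self, rng):
        """Estimates at tolerances 0.01 / 0.1 / 0.2 agree within noise."""
        tab = gaussian_table(rng, n=30_000, noise=0.2)
        obs = np.array([0.5])
        means = [
            abc_fit(obs, tab, tol, transform=False).posterior_mean["theta"]
            for tol in (0.01, 0.1, 0.2)
        ]
        assert max(means) - min(means) < 0.1


class TestModelPosterior:
    def test_identical_tables_split_evenly(self, rng):
        a = gaussian_table(rng, n=3000, informative=False)
        b = gaussian_table(rng, n=3000, informative=False)
        mc = model_posterior(np.array([0.0]), {"m0": a, "m1": b}, 0.2)
        assert mc.posterior_probs["m0"] == pytest.approx(0.5, abs=0.05)
        assert sum(mc.posterior_probs.values()) == pytest.approx(1.0)

    def test_separated_clouds_classified_confidently(self, rng):
        near = ReferenceTable(pd.DataFrame(index=range(2000)), rng.normal(0, 1, (2000, 2)))
        far = ReferenceTable(pd.DataFrame(index=range(2000)), rng.normal(6, 1, (2000, 2)))
        mc = model_posterior(np.array([6.0, 6.0]), {"near": near, "far": far}, 0.1)
        assert mc.posterior_probs["far"] > 0.95

    def test_matches_nearest_centroid_ranking_at_full_tolerance(self, rng):
        a = ReferenceTable(pd.DataFrame(index=range(1000)), rng.normal(-2, 1, (1000, 1)))
        b = ReferenceTable(pd.DataFrame(index=range(1000)), rng.normal(2, 1, (1000, 1)))
        for obs in (-1.5, 1.5):
            mc = model_posterior(np.array([obs]), {"a": a, "b": b}, 1.0)
            centroid_pick = "a" if abs(obs + 2) < abs(obs - 2) else "b"
            assert max(mc.posterior_probs, key=mc.posterior_probs.get) == centroid_pick

    def test_dimension_mismatch_rejected(self, rng):
        a = gaussian_table(rng, n=100)
        b = ReferenceTable(pd.DataFrame(index=range(100)), rng.normal(0, 1, (100, 2)))
        with pytest.raises(ValueError):
            model_posterior(np.array([0.0]), {"a": a, "b": b}, 0.5)


class TestCrossValidate:
    def test_perfectly_informative_statistic_near_zero_error(self, rng):
        theta = rng.normal(0, 1, 3000)
        tab = ReferenceTable(pd.DataFrame({"theta": theta}), theta.reshape(-1, 1).copy())
        cv = cross_validate(tab, 200, 0.1, rng, transform=False)
        assert cv.prediction_error["theta"] < 0.05

    def test_uninformative_statistic_error_near_one(self, rng):
        tab = gaussian_table(rng, n=3000, informative=False)
        cv = cross_validate(tab, 200, 0.1, rng, transform=False)
        assert 0.7 < cv.prediction_error["theta"] < 1.3


class TestConfusionMatrix:
    def test_rows_sum_to_one_and_identical_models_confuse(self, rng):
        a = gaussian_table(rng, n=1500, informative=False)
        b = gaussian_table(rng, n=1500, informative=False)
        cm = confusion_matrix({"a": a, "b": b}, 150, 0.1, rng)
        assert np.allclose(cm.confusion.sum(axis=1), 1.0)
        assert abs(cm.confusion.loc["a", "b"] - 0.5) < 0.15

    def test_separated_models_high_diagonal(self, rng):
        a = ReferenceTable(pd.DataFrame(index=range(1500)), rng.normal(0, 1, (1500, 2)))
        b = ReferenceTable(pd.DataFrame(index=range(1500)), rng.normal(6, 1, (1500, 2)))
        cm = confusion_matrix({"a": a, "b": b}, 100, 0.1, rng)
        assert cm.confusion.loc["a", "a"] > 0.9
        assert cm.confusion.loc["b", "b"] > 0.9


class TestGoodnessOfFit:
    def test_far_outlier_rejected(self, rng):
        tab = gaussian_table(rng, n=2000)
        sd = tab.statistics.std()
        p = goodness_of_fit(np.array([10 * sd]), tab, 200, 0.1, rng)
        assert p < 0.01

    def test_null_calibration(self, rng):
        """Pseudo-observations drawn from the table give roughly uniform p."""
        tab = gaussian_table(rng, n=1000)
        picks = rng.choice(tab.n, 200, replace=False)
        ps = [
            goodness_of_fit(tab.statistics[i], tab, 100, 0.1,
                            np.random.default_rng(1000 + i))
            for i in picks
        ]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.07)
        assert 0.0 <= min(ps) <= max(ps) <= 1.0
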