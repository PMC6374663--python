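import numpy as np
import pandas as pd
import pytest

from conftest import random_stem_map
from fruitprod.covariates import build_design
from fruitprod.inference import McmcConfig, run_mcmc
from fruitprod.model_core import BinomialModel
from fruitprod.pipeline import build_model
from fruitprod.postprocess import (
    average_category_probabilities,
    prediction_curves,
    seed_mass_regressions,
    threshold_from_coefs,
    threshold_size,
    threshold_vs_dmax,
)


class TestThresholdClosedForm:
    def test_hand_example(self):
        # beta = (-2, 1), moments mean 20 / SD 10 -> z* = 2 -> 40 cm
        assert threshold_from_coefs(-2.0, 1.0, 20.0, 10.0) == pytest.approx(
            40.0
        )

    def test_zero_intercept_gives_mean_dbh(self):
        assert threshold_from_coefs(0.0, 0.7, 23.0, 8.0) == pytest.approx(
            23.0
        )

    def test_bisection_agrees_with_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            b0 = rng.normal(0, 2)
            b1 = rng.uniform(0.1, 3)
            off = rng.normal(0, 1)
            m, s = rng.uniform(10, 40), rng.uniform(3, 15)
            cf = threshold_from_coefs(b0, b1, m, s, offset=off)
            bi = threshold_from_coefs(b0, b1, m, s, offset=off,
                                      method="bisection")
            assert cf == pytest.approx(bi, abs=1e-8)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_coefs(1.0, -0.5, 20.0, 10.0)


class TestThresholdPosterior:
    def _threshold_fit(self, seed=0):
        ds_rng = np.random.default_rng(seed)
        trees = random_stem_map(ds_rng, 150)
        trees["species"] = "A"
        design = build_design(trees, None, "dbh")
        m, s = design.moments["dbh"]
        from scipy.special import expit

        eta = 0.12 * (trees["dbh_cm"].to_numpy() - 30.0)  # threshold 30 cm
        y = (ds_rng.uniform(size=150) < expit(eta)).astype(int)
        model = BinomialModel(design, y, random_effects=False)
        samples = run_mcmc(model, McmcConfig(n_chains=2, n_iterations=2500,
                                             n_burnin=800, seed=seed))
        return samples, model

    def test_recovers_generative_threshold(self):
        samples, model = self._threshold_fit(seed=1)
        est = threshold_size(samples, model, "A")
        assert est.q2_5 < 30.0 < est.q97_5
        assert est.frac_excluded < 0.2
        assert est.dmax == pytest.approx(model.design.dbh_cm.max())

    def test_model_without_dbh_rejected(self, small_dataset):
        ds = small_dataset
        m = build_model(ds.trees, ds.soil, ds.observations, "binom",
                        "intercept")
        s = run_mcmc(m, McmcConfig(n_chains=2, n_iterations=600,
                                   n_burnin=200, seed=1))
        with pytest.raises(ValueError, match="DBH"):
            threshold_size(s, m, m.design.species_names[0])


class TestScaling:
    def test_exact_half_rule_constrained_r2_one(self):
        dmax = np.array([20.0, 40.0, 80.0, 120.0])
        thr = dmax / 2
        res = threshold_vs_dmax(thr, dmax)
        assert res.constrained_r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(-np.log(2.0))

    def test_identical_dmax_rejected(self):
        with pytest.raises(ValueError, match="D_max"):
            threshold_vs_dmax(np.array([10.0, 11.0, 12.0]),
                              np.array([30.0, 30.0, 30.0]))

    def test_nonpositive_thresholds_excluded(self):
        res = threshold_vs_dmax(np.array([10.0, -1.0, 20.0, 40.0]),
                                np.array([20.0, 25.0, 40.0, 80.0]))
        assert res.n == 3

    def test_noisy_half_rule_slope_recovered(self):
        rng = np.random.default_rng(11)
        dmax = np.exp(rng.uniform(np.log(15), np.log(150), 16))
        thr = 0.5 * dmax * np.exp(rng.normal(0, 0.2, 16))
        res = threshold_vs_dmax(thr, dmax)
        # slope near 1 within ~3 SE of an OLS fit at sigma=0.2, n=16
        se = 0.2 / (np.std(np.log(dmax)) * np.sqrt(16))
        assert res.slope == pytest.approx(1.0, abs=3.5 * se)
        assert res.constrained_r2 > 0.5


class TestSeedMass:
    def test_collinear_points_r2_one(self):
        responses = pd.DataFrame(
            {"threshold": [10.0, 20.0, 30.0, 40.0]},
            index=["a", "b", "c", "d"],
        )
        sm = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        out = seed_mass_regressions(responses, sm)
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        assert out["slope"].iloc[0] == pytest.approx(10.0)

    def test_exclusion_removes_exactly_named_rows(self):
        responses = pd.DataFrame(
            {"threshold": [10.0, 20.0, 30.0, 400.0, 28.0]},
            index=list("abcde"),
        )
        sm = dict(zip("abcde", [1.0, 2.0, 3.0, 4.0, 5.0]))
        out = seed_mass_regressions(responses, sm, exclusions=["d"])
        n_all = out[out["subset"] == "all"]["n"].iloc[0]
        n_exc = out[out["subset"] == "excluding"]["n"].iloc[0]
        assert (n_all, n_exc) == (5, 4)

    def test_known_slope_recovered_within_se(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 100, 13)
        y = 5.0 + 0.3 * x + rng.normal(0, 2, 13)
        responses = pd.DataFrame({"resp": y},
                                 index=[f"s{i}" for i in range(13)])
        sm = {f"s{i}": x[i] for i in range(13)}
        out = seed_mass_regressions(responses, sm)
        from scipy import stats

        res = stats.linregress(x, y)
        assert abs(out["slope"].iloc[0] - 0.3) < 3 * res.stderr

    def test_too_few_species_rejected(self):
        responses = pd.DataFrame({"t": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="fewer than 3"):
            seed_mass_regressions(responses, {"a": 1.0, "b": 2.0})


@pytest.fixture(scope="module")
def ordinal_fit(small_dataset):
    ds = small_dataset
    m = build_model(ds.trees, ds.soil, ds.observations, "amulti", "dbh")
    s = run_mcmc(m, McmcConfig(n_chains=2, n_iterations=1500,
                               n_burnin=500, seed=7))
    return s, m


class TestCurvesAndAverages:
    def test_average_probabilities_sum_to_one(self, ordinal_fit):
        s, m = ordinal_fit
        tbl = average_category_probabilities(s, m,
                                             m.design.species_names[0])
        assert tbl["mean"].sum() == pytest.approx(1.0, abs=1e-10)
        assert (tbl["mean"] >= 0).all()

    def test_missing_species_rejected(self, ordinal_fit):
        s, m = ordinal_fit
        with pytest.raises(ValueError, match="not in fit"):
            average_category_probabilities(s, m, "NOPE")

    def test_curves_normalized_and_banded(self, ordinal_fit):
        s, m = ordinal_fit
        c = prediction_curves(s, m, m.design.species_names[0], axis="dbh")
        np.testing.assert_allclose(c.mean.sum(axis=1), 1.0, atol=1e-10)
        assert (c.lo <= c.mean + 1e-12).all()
        assert (c.hi >= c.mean - 1e-12).all()

    def test_binomial_curve_is_half_at_threshold(self):
        rng = np.random.default_rng(9)
        trees = random_stem_map(rng, 120)
        trees["species"] = "A"
        design = build_design(trees, None, "dbh")
        from scipy.special import expit

        eta = 0.15 * (trees["dbh_cm"].to_numpy() - 25.0)
        y = (rng.uniform(size=120) < expit(eta)).astype(int)
        model = BinomialModel(design, y, random_effects=False)
        s = run_mcmc(model, McmcConfig(n_chains=2, n_iterations=2000,
                                       n_burnin=700, seed=3))
        # evaluate the mean curve at the closed-form threshold of the
        # posterior-mean coefficients
        beta = s.flat("beta").mean(axis=0)
        m_, s_ = design.moments["dbh"]
        thr = threshold_from_coefs(beta[0, 0], beta[0, 1], m_, s_)
        c = prediction_curves(s, model, "A", axis="dbh",
                              grid=np.array([thr]), max_draws=10_000)
        # mean of expit != expit of mean: allow modest slack around 0.5
        assert c.mean[0] == pytest.approx(0.5, abs=0.05)

    def test_crowding_axis_requires_crowding_model(self, ordinal_fit):
        s, m = ordinal_fit
        with pytest.raises(ValueError, match="crowding"):
            prediction_curves(s, m, m.design.species_names[0],
                              axis="crowding")

    def test_monotone_dbh_effect_gives_monotone_top_category(
            self, ordinal_fit):
        s, m = ordinal_fit
        sp = m.design.species_names[0]
        c = prediction_curves(s, m, sp, axis="dbh")
        top = c.mean[:, -1]
        b_dbh = s.flat("beta")[:, 0, 1].mean()
        if b_dbh > 0:
            assert top[-1] > top[0]
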