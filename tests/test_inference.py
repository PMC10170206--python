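"""Likelihood, fitting, profile intervals, AIC lattice, deviance explained."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eggdrift.inference import (
    PROFILE_RISE_95,
    EggDispersalModel,
    ModelSpec,
    model_selection_table,
    nb_neg_loglik,
    profile_interval_1d,
)
from eggdrift.synthetic import SyntheticConfig, simulate_survey
from eggdrift.vertical import VerticalConcentration


def _flat_vertical(duration=15.0):
    z = np.linspace(0, 40, 41)
    t = np.linspace(0, duration, 4)
    dens = np.full((41, 4), 1 / 40.0)
    return VerticalConcentration(z, t, dens)


def _obs(counts, t=5.0, x=0.0, y=0.0, z=10.0, volume=264.0):
    n = len(counts)
    return pd.DataFrame(
        {
            "t_hours": np.full(n, t),
            "x_m": np.full(n, x),
            "y_m": np.full(n, y),
            "z_m": np.full(n, z),
            "count": counts,
            "volume_l": np.full(n, volume),
        }
    )


TRUTHY = {"beta": 15.0, "Kx": 10_000.0, "Ky": 10_000.0, "mu": 0.1, "k": 2.0}


class TestNegLoglik:
    def test_poisson_limit(self):
        vert = _flat_vertical()
        obs = _obs([0, 1, 2, 5, 3, 0, 1], x=200.0, y=-300.0)
        params = dict(TRUTHY, k=1e8)
        nll = nb_neg_loglik(params, obs, vert)
        model = EggDispersalModel(obs, vert)
        m = model.mean_counts(params)
        poisson_nll = -stats.poisson.logpmf(model.counts, m).sum()
        assert nll == pytest.approx(poisson_nll, abs=1e-4)

    def test_zero_count_closed_form(self):
        vert = _flat_vertical()
        obs = _obs([0])
        params = dict(TRUTHY)
        model = EggDispersalModel(obs, vert)
        m = model.mean_counts(params)[0]
        k = params["k"]
        # P(0) = (k/(k+m))^k for the NB(mean m, size k) law
        assert nb_neg_loglik(params, obs, vert) == pytest.approx(
            -k * np.log(k / (k + m)), rel=1e-12
        )

    def test_order_invariance(self, survey):
        vert = survey.vertical
        obs = survey.observations
        shuffled = obs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert nb_neg_loglik(TRUTHY, obs, vert) == pytest.approx(
            nb_neg_loglik(TRUTHY, shuffled, vert), rel=1e-12
        )


class TestFit:
    def test_refit_from_solution_is_fixed_point(self, survey, fitted):
        model = EggDispersalModel(survey.observations, survey.vertical, ModelSpec.full())
        again = model.fit(start=fitted.theta, n_starts=1)
        assert again.llf == pytest.approx(fitted.llf, abs=1e-6)

    def test_fit_is_deterministic(self, survey, fitted):
        model = EggDispersalModel(survey.observations, survey.vertical, ModelSpec.full())
        res2 = model.fit(seed=0)
        assert res2.aic == fitted.aic

    def test_aic_identity(self, fitted):
        assert fitted.aic == pytest.approx(2 * fitted.n_params - 2 * fitted.llf)

    def test_mortality_free_data_prefers_mortality_free_model(self, vertical_field):
        from eggdrift.horizontal import HorizontalParams

        cfg = SyntheticConfig(
            horizontal=HorizontalParams(Kx=14_900.0, Ky=49_100.0, mu=0.0),
            seed=8,
        )
        ds = simulate_survey(cfg, vertical_field=vertical_field)
        full = EggDispersalModel(ds.observations, vertical_field, ModelSpec.full()).fit(seed=0)
        nomort = EggDispersalModel(
            ds.observations, vertical_field, ModelSpec.no_mortality()
        ).fit(seed=0)
        assert full.params["mu"] < 0.05  # shrinks toward the lower bound
        assert nomort.aic < full.aic


class TestProfileIntervals:
    def test_gaussian_toy_matches_wald(self):
        # quadratic -logL with curvature 1/sigma^2: the 95% profile
        # interval is exactly +/- 1.96 sigma
        mu_hat, sigma = 2.0, 0.7

        def f(x):
            return 0.5 * ((x - mu_hat) / sigma) ** 2

        lo, hi = profile_interval_1d(f, mu_hat, 0.0, PROFILE_RISE_95)
        half = np.sqrt(2 * PROFILE_RISE_95) * sigma  # = 1.95996 * sigma
        assert lo == pytest.approx(mu_hat - half, abs=1e-4)
        assert hi == pytest.approx(mu_hat + half, abs=1e-4)
        assert half / sigma == pytest.approx(stats.norm.ppf(0.975), abs=1e-4)

    def test_interval_contains_mle(self, fitted):
        for p in ("Kx", "mu"):
            lo, hi = fitted.profile_interval(p)
            assert lo < fitted.params[p] < hi

    def test_higher_level_widens(self, fitted):
        lo95, hi95 = fitted.profile_interval("mu", 0.95)
        lo99, hi99 = fitted.profile_interval("mu", 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_conf_int_frame(self, fitted):
        ci = fitted.conf_int(params=["Kx", "mu"])
        assert list(ci.index) == ["Kx", "mu"]
        assert (ci["lower"] < ci["upper"]).all()


class TestModelSelection:
    def test_lattice(self, survey):
        tab = model_selection_table(survey.observations, survey.vertical, seed=0)
        assert set(tab["model"]) == {
            "full", "isotropic", "no_mortality", "isotropic_no_mortality", "intercept_only",
        }
        assert tab["delta_aic"].min() == 0.0
        # nesting: a richer model never has lower maximized log-likelihood
        ll = tab.set_index("model")["loglik"]
        assert ll["full"] >= ll["isotropic"] - 1e-6
        assert ll["full"] >= ll["no_mortality"] - 1e-6
        assert ll["isotropic"] >= ll["isotropic_no_mortality"] - 1e-6
        assert ll["isotropic_no_mortality"] >= ll["intercept_only"] - 1e-6

    def test_full_model_wins_on_anisotropic_data(self, survey):
        tab = model_selection_table(survey.observations, survey.vertical, seed=0)
        assert tab.iloc[0]["model"] == "full"


class TestDevianceExplained:
    def test_intercept_only_is_zero(self, survey):
        res = EggDispersalModel(
            survey.observations, survey.vertical, ModelSpec.intercept_only()
        ).fit(seed=0)
        assert res.deviance_explained() == pytest.approx(0.0, abs=1e-3)

    def test_increases_with_signal_to_noise(self, vertical_field):
        values = {}
        for k in (0.2, 5.0):
            cfg = SyntheticConfig(k=k, seed=4)
            ds = simulate_survey(cfg, vertical_field=vertical_field)
            res = EggDispersalModel(ds.observations, vertical_field).fit(seed=0)
            values[k] = res.deviance_explained()
        assert 0.0 < values[0.2] < values[5.0] < 1.0


class TestExposureInvariance:
    def test_split_minutes_leave_estimates_stable(self, survey, fitted):
        # splitting each minute into two half-minutes with halved volume
        # and evenly split counts is (to discretization) the same survey
        obs = survey.observations
        half = obs.copy()
        half["volume_l"] /= 2
        a = half.copy()
        b = half.copy()
        a["count"] = obs["count"] // 2
        b["count"] = obs["count"] - obs["count"] // 2
        split = pd.concat([a, b], ignore_index=True)
        res = EggDispersalModel(split, survey.vertical, ModelSpec.full()).fit(seed=0)
        for p in ("Kx", "Ky", "mu"):
            assert res.params[p] == pytest.approx(fitted.params[p], rel=0.15)


def test_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(free_kx=False, free_ky=True, free_mu=False)
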