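"""NEC threshold model: mean function, likelihood, design, and MCMC recovery."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import algaetox as at
from algaetox.nec import log_likelihood

REDUCED = at.MCMCSettings(iterations=2500, burnin=1250)


def _params(**kw):
    base = dict(alpha=1.0, beta=1.5, gamma=math.log(10), delta=0.0, sigma=0.02)
    base.update(kw)
    return at.NECParams(**base)


class TestModelMean:
    def test_constant_below_threshold(self):
        p = _params(alpha=0.9, delta=0.1)
        for x in (-5.0, 0.0, p.gamma):
            assert at.model_mean(p, x) == pytest.approx(0.8)

    def test_hand_evaluated_decay(self):
        p = _params(alpha=1.0, beta=1.0, gamma=0.0, delta=0.0)
        assert at.model_mean(p, 1.0) == pytest.approx(math.exp(-1.0))

    def test_flat_when_beta_zero(self):
        p = _params(beta=0.0, alpha=0.7, delta=0.2)
        x = np.linspace(-3, 8, 50)
        np.testing.assert_allclose(at.model_mean(p, x), 0.5)

    @given(
        alpha=st.floats(0.1, 2.0),
        beta=st.floats(0.0, 5.0),
        gamma=st.floats(-2.0, 4.0),
        delta=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_continuous_at_threshold_and_non_increasing(self, alpha, beta, gamma, delta):
        p = at.NECParams(alpha=alpha, beta=beta, gamma=gamma, delta=delta, sigma=0.01)
        eps = 1e-9
        left = at.model_mean(p, gamma - eps)
        right = at.model_mean(p, gamma + eps)
        assert left == pytest.approx(right, abs=1e-6)
        x = np.linspace(gamma - 2, gamma + 4, 200)
        mu = at.model_mean(p, x)
        assert np.all(np.diff(mu) <= 1e-12)


class TestLikelihood:
    def test_matches_direct_gaussian_density_on_random_points(self):
        """Sampler's likelihood must equal the independent normal log-density."""
        rng = np.random.default_rng(21)
        x = rng.uniform(-2, 5, 40)
        y = rng.normal(0.5, 0.3, 40)
        for _ in range(10):
            p = at.NECParams(
                alpha=rng.uniform(0.2, 1.5),
                beta=rng.uniform(0.0, 3.0),
                gamma=rng.uniform(-1, 4),
                delta=rng.uniform(-0.3, 0.3),
                sigma=rng.uniform(0.01, 0.5),
            )
            direct = float(np.sum(stats.norm.logpdf(y, at.model_mean(p, x), p.sigma)))
            assert log_likelihood(p, x, y) == pytest.approx(direct, abs=1e-9)


class TestDesignMatrix:
    def test_proportional_response_and_control_placement(self, noisy_table):
        data = at.nec_design_matrix(noisy_table, "sgr", check_response=False)
        test = noisy_table.test_rows()
        lowest = test["twa_conc"].min()
        n_controls = len(noisy_table.control_rows())
        np.testing.assert_allclose(np.sort(data.x)[:n_controls], math.log(lowest / 10.0))
        assert "10^1" in data.control_x_policy or "ln(" in data.control_x_policy
        # y = 1 - inhibition/100: controls average 1
        control_y = data.y[data.x == data.x.min()]
        assert control_y.mean() == pytest.approx(1.0, abs=0.05)

    def test_inhibition_50_maps_to_half(self, noisy_table):
        import dataclasses

        data_df = noisy_table.data.copy()
        data_df.loc[data_df["role"] == "test", "sgr_inhibition"] = 50.0
        tbl = dataclasses.replace(noisy_table, data=data_df)
        nd = at.nec_design_matrix(tbl, "sgr", check_response=False)
        test_y = nd.y[nd.x > nd.x.min()]
        np.testing.assert_allclose(test_y, 0.5)

    def test_nonresponsive_assay_short_circuits(self, flat_table):
        with pytest.raises(at.NonresponsiveAssayError):
            at.nec_design_matrix(flat_table, "sgr")


class TestFitNEC:
    def test_simulation_recovery_at_study_design(self):
        """7 concentrations x 5 reps from the threshold model: NEC ~ 10 ug/L."""
        xg = np.concatenate([[math.log(0.1)], np.log(np.geomspace(1, 100, 7))])
        data = at.simulate_from_nec(_params(), xg, n_replicates=5, seed=42)
        fit = at.fit_nec(data, REDUCED, seed=7)
        assert 8.0 <= fit.nec_value <= 12.5
        assert fit.nec_ci[0] <= fit.nec_value <= fit.nec_ci[1]

    def test_same_seed_identical_posterior(self):
        xg = np.log(np.geomspace(1, 100, 7))
        data = at.simulate_from_nec(_params(), xg, n_replicates=5, seed=3)
        small = at.MCMCSettings(iterations=800, burnin=400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = at.fit_nec(data, small, seed=5)
            f2 = at.fit_nec(data, small, seed=5)
        assert f1.posterior_draws.equals(f2.posterior_draws)

    def test_posterior_mean_at_control_matches_alpha_minus_delta(self):
        xg = np.concatenate([[math.log(0.1)], np.log(np.geomspace(1, 100, 7))])
        data = at.simulate_from_nec(_params(), xg, n_replicates=5, seed=8)
        fit = at.fit_nec(data, REDUCED, seed=9)
        draws = fit.posterior_draws
        reg = at.NECThresholdRegressor(iterations=2500, burnin=1250, random_state=9).fit(
            data.x, data.y
        )
        predicted = reg.predict(np.array([data.x.min()]))[0]
        expected = float((draws["alpha"] - draws["delta"]).mean())
        assert predicted == pytest.approx(expected, abs=1e-6)

    def test_diagnostics_reported_per_parameter(self):
        xg = np.concatenate([[math.log(0.1)], np.log(np.geomspace(1, 100, 7))])
        data = at.simulate_from_nec(_params(), xg, n_replicates=5, seed=10)
        fit = at.fit_nec(data, REDUCED, seed=11)
        assert set(fit.diagnostics) == {"alpha", "beta", "gamma", "delta", "sigma"}
        for d in fit.diagnostics.values():
            assert d["rhat"] < 1.2 and d["ess"] > 50


class TestNECSummary:
    def test_degenerate_draws(self):
        import pandas as pd

        draws = pd.DataFrame(
            {"alpha": 1.0, "beta": 1.0, "gamma": math.log(5.0), "delta": 0.0, "sigma": 0.01},
            index=range(100),
        )
        fit = at.NECFit(
            posterior_draws=draws, nec_value=None, nec_ci=None, censored=False, max_conc=100.0
        )
        value, ci, censored = at.nec_summary(fit)
        assert value == pytest.approx(5.0)
        assert ci[0] == pytest.approx(5.0) and ci[1] == pytest.approx(5.0)
        assert not censored

    def test_log_uniform_grid_has_geometric_median(self):
        import pandas as pd

        gammas = np.linspace(math.log(1.0), math.log(100.0), 101)
        draws = pd.DataFrame({"alpha": 1.0, "beta": 1.0, "gamma": gammas, "delta": 0.0, "sigma": 0.01})
        fit = at.NECFit(
            posterior_draws=draws, nec_value=None, nec_ci=None, censored=False, max_conc=100.0
        )
        value, _, _ = at.nec_summary(fit)
        assert value == pytest.approx(10.0, rel=1e-6)

    def test_censored_renders_greater_than_max(self):
        fit = at.censored_nec(4570.0)
        value, ci, censored = at.nec_summary(fit)
        assert censored and value is None and ci is None
        assert fit.to_dict()["display"] == "> 4570"
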