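"""4PL fitting, ECx inversion, bootstrap intervals, and the nonresponse path."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import algaetox as at
from algaetox.drc import FourPLRegressor, fourpl_curve


def _replicated(conc_levels, n=5):
    return np.repeat(np.asarray(conc_levels, dtype=float), n)


CONC7 = np.geomspace(1.0, 100.0, 7)


class TestFourPLFit:
    def test_noiseless_points_recover_parameters_exactly(self):
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0.0, 100.0, 1.0, 1.0)  # bottom, top, log10 EC50, hill
        fit = at.fit_4pl(conc, y)
        assert fit.bottom == pytest.approx(0.0, abs=1e-4)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.log_ec50 == pytest.approx(1.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_fit_matches_brute_force_grid_oracle(self):
        """The optimizer must do at least as well as an exhaustive coarse grid."""
        rng = np.random.default_rng(4)
        conc = _replicated(CONC7, n=3)
        y = fourpl_curve(conc, 5.0, 95.0, 1.2, 1.5) + rng.normal(0, 5, conc.size)
        fit = at.fit_4pl(conc, y)
        logc = np.log10(conc)
        grid_sse = min(
            float(np.sum((y - (b + (t - b) / (1 + 10 ** ((m - logc) * h)))) ** 2))
            for b, t, m, h in itertools.product(
                np.linspace(-10, 20, 7),
                np.linspace(80, 110, 7),
                np.linspace(0, 2, 11),
                np.linspace(0.5, 3, 11),
            )
        )
        assert fit.sse <= grid_sse + 1e-9

    def test_too_few_concentrations_is_a_design_error(self):
        conc = _replicated([1.0, 10.0, 100.0])
        y = fourpl_curve(conc, 0, 100, 1, 1)
        with pytest.raises(ValueError, match="4 distinct"):
            at.fit_4pl(conc, y)

    def test_invariant_to_replicate_ordering(self):
        rng = np.random.default_rng(5)
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0, 100, 1, 1.3) + rng.normal(0, 5, conc.size)
        perm = rng.permutation(conc.size)
        f1 = at.fit_4pl(conc, y)
        f2 = at.fit_4pl(conc[perm], y[perm])
        assert f1.log_ec50 == pytest.approx(f2.log_ec50, rel=1e-6)
        assert f1.hill == pytest.approx(f2.hill, rel=1e-6)

    def test_concentration_rescaling_rescales_ecx(self):
        rng = np.random.default_rng(6)
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0, 100, 1, 1.3) + rng.normal(0, 5, conc.size)
        f1 = at.fit_4pl(conc, y)
        f2 = at.fit_4pl(1000.0 * conc, y)  # e.g. ng/L instead of ug/L
        assert f2.ec_estimates[50.0].value == pytest.approx(
            1000.0 * f1.ec_estimates[50.0].value, rel=1e-5
        )
        assert f2.hill == pytest.approx(f1.hill, rel=1e-5)

    def test_sklearn_estimator_contract(self):
        est = FourPLRegressor()
        params = est.get_params()
        assert "n_starts" in params
        est.set_params(n_starts=6)
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0, 100, 1, 1)
        est.fit(conc, y)
        np.testing.assert_allclose(est.predict(conc), y, atol=1e-6)
        # column-vector input, as in sklearn pipelines
        est2 = FourPLRegressor().fit(conc.reshape(-1, 1), y)
        assert est2.log_ec50_ == pytest.approx(est.log_ec50_, rel=1e-6)


class TestECx:
    def test_ec50_equals_midpoint_when_bottom0_top100(self):
        fit = at.fit_4pl(_replicated(CONC7), fourpl_curve(_replicated(CONC7), 0, 100, 1, 1))
        est = at.ec_x(fit, 50.0)
        assert est.value == pytest.approx(10.0, rel=1e-6)
        assert not est.censored

    @pytest.mark.parametrize(
        "hill, level, expected",
        [(1.0, 10.0, 10.0 / 9.0), (2.0, 10.0, 10.0 / 3.0), (1.0, 90.0, 90.0)],
    )
    def test_closed_form_inversion(self, hill, level, expected):
        conc = _replicated(CONC7)
        fit = at.fit_4pl(conc, fourpl_curve(conc, 0, 100, 1, hill))
        assert at.ec_x(fit, level).value == pytest.approx(expected, rel=1e-6)

    def test_unreachable_level_is_censored_at_max_tested(self):
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0, 60, 1, 1)  # top asymptote 60%: 80% never reached
        fit = at.fit_4pl(conc, y)
        est = at.ec_x(fit, 80.0)
        assert est.censored
        assert est.value == pytest.approx(100.0)

    @given(
        bottom=st.floats(-20, 5),
        top=st.floats(70, 110),
        log_ec50=st.floats(0.2, 1.8),
        hill=st.floats(0.3, 5),
        level=st.floats(5, 65),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ecx_is_exact_inverse_of_the_curve(self, bottom, top, log_ec50, hill, level):
        fit = at.FourPLFit(
            bottom=bottom, top=top, log_ec50=log_ec50, hill=hill, r_squared=1.0,
            converged=True, n_points=35, conc_min=1.0, conc_max=1e6, sse=0.0,
        )
        est = at.ec_x(fit, level)
        if not est.censored:
            assert float(fit.predict(est.value)) == pytest.approx(level, abs=1e-9)

    def test_ec10_below_ec50_for_increasing_curve(self):
        conc = _replicated(CONC7)
        fit = at.fit_4pl(conc, fourpl_curve(conc, 0, 100, 1, 1.4))
        assert fit.ec_estimates[10.0].value < fit.ec_estimates[50.0].value


class TestBootstrapCI:
    def test_zero_noise_gives_degenerate_interval(self):
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0, 100, 1, 1)
        ci = at.bootstrap_ci(conc, y, level=50.0, n_boot=50, seed=1)
        assert ci.low == pytest.approx(10.0, rel=1e-6)
        assert ci.high == pytest.approx(10.0, rel=1e-6)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(7)
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0, 100, 1, 1.3) + rng.normal(0, 5, conc.size)
        a = at.bootstrap_ci(conc, y, level=50.0, n_boot=100, seed=9)
        b = at.bootstrap_ci(conc, y, level=50.0, n_boot=100, seed=9)
        assert (a.low, a.high) == (b.low, b.high)
        c = at.bootstrap_ci(conc, y, level=50.0, n_boot=100, seed=10)
        assert (a.low, a.high) != (c.low, c.high)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(8)
        conc = _replicated(CONC7)
        y = fourpl_curve(conc, 0, 100, 1, 1.3) + rng.normal(0, 5, conc.size)
        fit = at.fit_4pl(conc, y)
        ci = at.bootstrap_ci(conc, y, level=50.0, n_boot=200, seed=11)
        assert ci.low <= fit.ec_estimates[50.0].value <= ci.high


class TestNonresponseAnova:
    def test_identical_groups_give_f_zero_p_one(self, noisy_table):
        tbl = _tbl_with_sgr_groups(noisy_table, {"control": [1, 2, 3], "T1": [1, 2, 3]})
        res = at.nonresponse_anova(tbl, "sgr")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_are_highly_significant(self, noisy_table):
        tbl = _tbl_with_sgr_groups(
            noisy_table, {"control": [1.0, 1.001, 0.999], "T1": [2.0, 2.001, 1.999]}
        )
        res = at.nonresponse_anova(tbl, "sgr")
        assert res.p_value < 1e-3

    def test_hand_computed_three_group_anova(self, noisy_table):
        # groups {0,1},{1,2},{2,3}: MSB = 4/2, MSW = 1.5/3 -> F = 4 on (2,3) df
        tbl = _tbl_with_sgr_groups(noisy_table, {"control": [0, 1], "T1": [1, 2], "T2": [2, 3]})
        res = at.nonresponse_anova(tbl, "sgr")
        assert res.f_statistic == pytest.approx(4.0, rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 3)

    def test_exact_separation_note(self, noisy_table):
        tbl = _tbl_with_sgr_groups(noisy_table, {"control": [1, 1], "T1": [2, 2]})
        res = at.nonresponse_anova(tbl, "sgr")
        assert res.p_value == 0.0 and res.note is not None


def _tbl_with_sgr_groups(template, groups):
    import pandas as pd

    rows = []
    for tid, values in groups.items():
        role = "control" if tid == "control" else "test"
        for i, v in enumerate(values):
            rows.append(
                {
                    "treatment_id": tid, "replicate_id": f"r{i}", "role": role,
                    "nominal_conc": 0.0 if role == "control" else 1.0,
                    "twa_conc": 0.0 if role == "control" else 1.0,
                    "conc_source": "nominal", "sgr": float(v), "yield": np.nan,
                    "sgr_inhibition": 0.0, "yield_inhibition": np.nan,
                }
            )
    return dataclasses.replace(template, data=pd.DataFrame(rows))


class TestClassifyResponse:
    def test_flat_assay_is_nonresponsive(self, flat_table):
        assert at.classify_response(flat_table, "sgr") == "nonresponsive"
        assert at.classify_response(flat_table, "yield") == "nonresponsive"

    def test_sigmoid_assay_is_responsive(self, noisy_table):
        assert at.classify_response(noisy_table, "sgr") == "responsive"

    def test_significant_anova_forces_responsive_even_if_top_flat(self, flat_table):
        # make the ANOVA significant without raising top-concentration inhibition:
        # shift one low-concentration treatment far from the rest
        data = flat_table.data.copy()
        low_id = data.loc[data["role"] == "test", "treatment_id"].iloc[0]
        data.loc[data["treatment_id"] == low_id, "sgr"] *= 0.5
        tbl = dataclasses.replace(flat_table, data=data)
        res = at.nonresponse_anova(tbl, "sgr")
        assert res.p_value < 0.05
        assert at.classify_response(tbl, "sgr") == "responsive"
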