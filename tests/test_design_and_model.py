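"""APC design construction, Poisson fitting, effect extraction."""

import numpy as np
import pytest
from scipy import optimize

from lexisapc import (APCTruth, LexisGrid, LexisTable, SimConfig,
                      ValidationError, apc_fit, build_design, classify_trend,
                      default_truth, fit_poisson, natural_spline_basis,
                      poisson_deviance, simulate_lexis)


def newton_poisson_deviance(X, deaths, person_years):
    """Independent oracle: minimize the exact Poisson negative log-likelihood
    with a generic second-order optimizer, then evaluate the deviance."""
    X = np.asarray(X, float)
    d = np.asarray(deaths, float).ravel()
    off = np.log(np.asarray(person_years, float).ravel())

    def negll(beta):
        eta = X @ beta + off
        return float(np.sum(np.exp(eta)) - d @ eta)

    def grad(beta):
        mu = np.exp(X @ beta + off)
        return X.T @ (mu - d)

    def hess(beta):
        mu = np.exp(X @ beta + off)
        return X.T @ (mu[:, None] * X)

    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(negll, beta0, jac=grad, hess=hess,
                            method="Newton-CG", options={"xtol": 1e-14, "maxiter": 500})
    mu = np.exp(X @ res.x + off)
    return poisson_deviance(d, mu)


class TestSplineBasis:
    def test_column_count_equals_knot_count(self):
        x = np.linspace(0, 10, 30)
        for K in (3, 5, 7):
            B = natural_spline_basis(x, np.linspace(0, 10, K))
            assert B.shape == (30, K)

    def test_contains_constant_and_linear(self):
        x = np.linspace(0, 10, 30)
        B = natural_spline_basis(x, np.linspace(0, 10, 5))
        assert np.allclose(B[:, 0], 1.0)
        assert np.allclose(B[:, 1], x)

    def test_linear_beyond_boundary_knots(self):
        # second differences vanish outside the boundary knots
        B = natural_spline_basis(np.array([12.0, 13.0, 14.0]), np.linspace(0, 10, 5))
        second_diff = B[0] - 2 * B[1] + B[2]
        assert np.allclose(second_diff, 0.0, atol=1e-9)

    def test_too_few_or_duplicate_knots_rejected(self):
        with pytest.raises(ValidationError):
            natural_spline_basis(np.arange(5.0), [0.0, 1.0])
        with pytest.raises(ValidationError):
            natural_spline_basis(np.arange(5.0), [0.0, 1.0, 1.0, 2.0])


class TestDesign:
    def test_default_ranks_and_residual_df(self, grid, sim_table):
        design = build_design(grid, sim_table.deaths, sim_table.person_years)
        expected = {"age": 115, "age-drift": 114, "age-cohort": 111,
                    "age-period-cohort": 108, "age-period": 111}
        for model, df in expected.items():
            assert design.residual_df(model) == df

    def test_df_depends_only_on_grid_and_bases_not_counts(self, grid):
        """Two very different tables give identical residual df ladders."""
        t1 = simulate_lexis(SimConfig(grid, default_truth(grid), 1e6, seed=1))
        t2 = simulate_lexis(SimConfig(grid, APCTruth(baseline_log_rate=-10.5), 1e4, seed=2))
        for model in ("age", "age-drift", "age-cohort", "age-period-cohort", "age-period"):
            d1 = build_design(grid, t1.deaths, t1.person_years).residual_df(model)
            d2 = build_design(grid, t2.deaths, t2.person_years).residual_df(model)
            assert d1 == d2

    def test_age_only_design_rank(self, grid, sim_table):
        design = build_design(grid, sim_table.deaths, sim_table.person_years)
        assert design.rank("age") == 5

    def test_curvature_columns_orthogonal_to_constant_and_linear(self, grid, sim_table):
        design = build_design(grid, sim_table.deaths, sim_table.person_years)
        w = sim_table.person_years.ravel()
        for block, t in ((design.period_block(), design.period_cells),
                         (design.cohort_block(), design.cohort_cells)):
            X = np.column_stack([np.ones_like(t), t])
            # weighted projection coefficients of curvature columns on (1, t)
            coef = np.linalg.lstsq(np.sqrt(w)[:, None] * X,
                                   np.sqrt(w)[:, None] * block, rcond=None)[0]
            assert np.max(np.abs(coef)) < 1e-8

    def test_custom_basis_dimensions_change_rank(self, grid, sim_table):
        design = build_design(grid, sim_table.deaths, sim_table.person_years,
                              npar_age=6, npar_period=4, npar_cohort=7)
        assert design.rank("age-period-cohort") == 6 + 1 + 2 + 5
        assert design.residual_df("age-period-cohort") == 120 - 14

    def test_out_of_range_references_rejected(self, grid, sim_table):
        with pytest.raises(ValidationError):
            build_design(grid, sim_table.deaths, sim_table.person_years, ref_period=1950.0)
        with pytest.raises(ValidationError):
            build_design(grid, sim_table.deaths, sim_table.person_years, ref_cohort=1890.0)


class TestFitPoisson:
    def test_saturated_single_cell(self):
        fit = fit_poisson(np.ones((1, 1)), np.array([5.0]), np.array([1e5]))
        assert fit.fitted[0] == pytest.approx(5.0, rel=1e-8)
        assert 1e5 * np.exp(fit.params[0]) == pytest.approx(5.0, rel=1e-8)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_deaths_boundary(self):
        fit = fit_poisson(np.ones((10, 1)), np.zeros(10), np.full(10, 1e5))
        assert fit.deviance == 0.0
        assert np.allclose(fit.fitted, 0.0)
        assert fit.boundary

    def test_real_valued_deaths_accepted(self):
        d = np.array([3.6, 4.8, 12.24])
        fit = fit_poisson(np.ones((3, 1)), d, np.full(3, 1e5))
        assert 1e5 * np.exp(fit.params[0]) == pytest.approx(d.mean(), rel=1e-6)

    def test_deviance_matches_generic_optimizer_on_random_tables(self):
        """IRLS deviance equals an independent Newton optimization within 1e-6."""
        rng = np.random.default_rng(321)
        for _ in range(5):
            n, p = 24, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            beta = rng.normal(scale=0.3, size=p)
            py = rng.uniform(5e3, 5e4, size=n)
            d = rng.poisson(py * np.exp(X @ beta - 9.0)).astype(float)
            if d.sum() == 0:
                continue
            fit = fit_poisson(X, d, py)
            assert fit.deviance == pytest.approx(newton_poisson_deviance(X, d, py), abs=1e-6)

    def test_negative_deaths_and_zero_exposure_rejected(self):
        with pytest.raises(ValidationError):
            fit_poisson(np.ones((2, 1)), np.array([-1.0, 2.0]), np.ones(2))
        with pytest.raises(ValidationError):
            fit_poisson(np.ones((2, 1)), np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestAPCFit:
    def test_reference_anchoring(self, sim_table):
        fit = apc_fit(sim_table)
        p = fit.period_rr
        row = p.loc[np.isclose(p["midpoint"], 1997.5)].iloc[0]
        assert row["rr"] == pytest.approx(1.0, abs=1e-12)
        assert row["hi95"] - row["lo95"] == pytest.approx(0.0, abs=1e-12)
        c = fit.cohort_rr
        row = c.loc[np.isclose(c["midpoint"], 1950.0)].iloc[0]
        assert row["rr"] == pytest.approx(1.0, abs=1e-12)
        assert row["hi95"] - row["lo95"] == pytest.approx(0.0, abs=1e-12)

    def test_ci_ordering(self, sim_table):
        fit = apc_fit(sim_table)
        for df, col in ((fit.age_curve, "rate_per_100000"),
                        (fit.period_rr, "rr"), (fit.cohort_rr, "rr")):
            assert np.all(df["lo95"] <= df[col] + 1e-12)
            assert np.all(df[col] <= df["hi95"] + 1e-12)
            assert np.all(df["lo95"] > 0)

    def test_effect_decomposition_reproduces_fitted_rates(self, sim_table):
        """age curve x period RR x cohort RR rebuilds every fitted cell rate."""
        fit = apc_fit(sim_table)
        grid = sim_table.grid
        rates = fit.fitted_rates()
        age = fit.age_curve.set_index("midpoint")["rate_per_100000"]
        per = fit.period_rr.set_index("midpoint")["rr"]
        coh = fit.cohort_rr.set_index("midpoint")["rr"]
        for i, a in enumerate(grid.age_midpoints):
            for j, p in enumerate(grid.period_midpoints):
                rebuilt = age[a] * per[p] * coh[p - a]
                assert rebuilt == pytest.approx(rates[i, j], rel=1e-8)

    def test_drift_recovery_single_high_exposure_table(self, grid, drift_only_truth):
        table = simulate_lexis(SimConfig(grid, drift_only_truth, 1e6, seed=77))
        fit = apc_fit(table)
        se = (np.log(fit.drift_ci[1]) - np.log(fit.drift_ci[0])) / (2 * 1.959963984540054)
        assert abs(np.log(fit.drift) - 0.008) < 3 * se

    def test_fitted_rates_invariant_to_trend_reallocation(self, grid):
        """Moving a linear trend between the period and cohort curvature inputs
        of the generating truth leaves the fitted rate surface unchanged."""
        rng = np.random.default_rng(14)
        coh = rng.normal(scale=0.05, size=grid.n_cohorts)
        base = default_truth(grid)
        t_a = APCTruth(base.baseline_log_rate, base.age_curve, 0.008,
                       period_curvature=0.01 * (grid.period_midpoints - 1997.5),
                       cohort_curvature=coh)
        t_b = APCTruth(base.baseline_log_rate, base.age_curve, 0.008,
                       period_curvature=np.zeros(grid.n_periods),
                       cohort_curvature=coh - 0.01 * (grid.cohort_midpoints - 1950.0))
        tab_a = simulate_lexis(SimConfig(grid, t_a, 1e6, seed=8))
        tab_b = simulate_lexis(SimConfig(grid, t_b, 1e6, seed=8))
        # identical surfaces => identical draws at the same seed => identical fits
        assert np.array_equal(tab_a.deaths, tab_b.deaths)
        fa, fb = apc_fit(tab_a), apc_fit(tab_b)
        assert np.allclose(fa.fitted_rates(), fb.fitted_rates(), rtol=1e-8)

    def test_drift_axis_choice_moves_trend_between_axes(self, grid, drift_only_truth):
        table = simulate_lexis(SimConfig(grid, drift_only_truth, 1e6, seed=3))
        fc = apc_fit(table, drift_axis="cohort")
        fp = apc_fit(table, drift_axis="period")
        assert fc.drift == pytest.approx(fp.drift, rel=1e-10)
        # with drift on the period axis, period RRs carry the trend
        span_c = fc.period_rr["rr"].max() / fc.period_rr["rr"].min()
        span_p = fp.period_rr["rr"].max() / fp.period_rr["rr"].min()
        assert span_p > span_c

    def test_age_curve_reproduces_expected_deaths_at_reference_cohort(
            self, grid, drift_only_truth):
        """Age curve x period RR x person-years recovers the expected death
        counts in the reference cohort's cells (cohort RR = 1 there)."""
        table = simulate_lexis(SimConfig(grid, drift_only_truth, 1e6, seed=55))
        fit = apc_fit(table)
        t = drift_only_truth.resolved(grid)
        p0 = grid.period_midpoints[0]
        age = fit.age_curve.set_index("midpoint")["rate_per_100000"]
        per = fit.period_rr.set_index("midpoint")["rr"]
        checked = 0
        for i, a in enumerate(grid.age_midpoints):
            p = a + 1950.0  # calendar time of the reference cohort at age a
            if p < grid.period_midpoints[0] or p > grid.period_midpoints[-1]:
                continue
            j = int(np.argmin(np.abs(grid.period_midpoints - p)))
            mu_truth = table.person_years[i, j] * np.exp(
                t.baseline_log_rate + t.age_curve[i] + 0.008 * (p - p0))
            mu_decomp = (age[a] / 1e5) * per[p] * table.person_years[i, j]
            assert mu_decomp == pytest.approx(mu_truth, rel=0.08)
            checked += 1
        assert checked == 8  # the 1950 cohort crosses eight cells of this grid


class TestClassifyTrend:
    @pytest.mark.parametrize("drift,lo,hi,expected", [
        (1.008, 1.007, 1.009, "upward"),
        (0.999, 0.998, 1.000, "stationary"),
        (0.984, 0.983, 0.985, "downward"),
        (1.0, 0.95, 1.05, "stationary"),
        (1.001, 1.000, 1.002, "stationary"),  # CI touching 1 contains 1
    ])
    def test_rule(self, drift, lo, hi, expected):
        assert classify_trend(drift, (lo, hi)) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            classify_trend(1.0, (1.1, 0.9))
        with pytest.raises(ValidationError):
            classify_trend(-1.0, (0.9, 1.1))
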