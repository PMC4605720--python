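"""Anchored APC fit: recovery, identification conventions, uncertainties."""

import numpy as np
import pytest

from hazage.apc_model import (
    APCFitError,
    cohort_cell_counts,
    drift_coefficients,
    effect_cis,
    fit_apc,
    population_hazard,
)
from hazage.registry_io import AgeGrid, PeriodGrid, RegistryTable, RunConfig
from hazage.synthetic_data import SimulationParams, expected_counts, true_unconditional_hazard


def _noiseless_table(params: SimulationParams) -> RegistryTable:
    return RegistryTable(
        cases=expected_counts(params),
        person_years=params.population_template,
        age_grid=params.age_grid,
        period_grid=params.period_grid,
    )


def _constrained_effects(n=16, J=7):
    """Smooth nonzero period/cohort effects satisfying the fit constraints."""
    K = n + J - 1
    b = 0.06 * np.sin(np.arange(J) / 2.0)
    b -= b[3]
    c = 0.08 * np.cos(np.arange(K) / 3.0)
    d = drift_coefficients(n, J)
    c -= (d @ c) / (d @ d) * d
    c -= c[8]
    return b, c


class TestFit:
    def test_noiseless_recovery_to_1e6(self, default_config):
        b, c = _constrained_effects()
        params = SimulationParams(
            p_true=0.01, period_effects_true=b, cohort_effects_true=c, seed=0
        )
        apc = fit_apc(_noiseless_table(params), default_config)
        assert np.max(np.abs(apc.period_effects - b)) < 1e-6
        assert np.max(np.abs(apc.cohort_effects - c)) < 1e-6
        h_true = true_unconditional_hazard(params).values
        h_fit = np.exp(apc.intercept + apc.age_effects)
        assert np.max(np.abs(h_fit / h_true - 1)) < 1e-6

    def test_matches_generic_optimizer_on_same_likelihood(self, default_config):
        """Independent oracle: scipy.optimize on the identical constrained likelihood."""
        from scipy.linalg import null_space
        from scipy.optimize import minimize

        from hazage.apc_model import _constraints, _design

        params = SimulationParams(p_true=0.01, seed=0)
        from hazage.synthetic_data import simulate_counts

        table = simulate_counts(params, 11)
        n, J = 16, 7
        X, _, _ = _design(n, J)
        C, _ = _constraints(n, J, default_config.age_index, default_config.period_index)
        Z = null_space(C)
        A = X @ Z
        O, offset = table.cases.ravel(), np.log(table.person_years.ravel())

        def negll(g):
            eta = offset + A @ g
            return -np.sum(O * eta - np.exp(eta))

        def grad(g):
            eta = offset + A @ g
            return -A.T @ (O - np.exp(eta))

        res = minimize(negll, np.zeros(A.shape[1]) - 0.2, jac=grad, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
        apc = fit_apc(table, default_config)
        gamma_mine, *_ = np.linalg.lstsq(Z, apc.theta(), rcond=None)
        # same optimum: likelihood agreement and identical fitted means
        assert negll(gamma_mine) <= res.fun + 1e-6 * abs(res.fun)
        eta_oracle = offset + A @ res.x
        eta_mine = offset + A @ gamma_mine
        # compare on cells with appreciable counts (flat corner directions
        # with near-zero fitted means are not identified to high precision)
        heavy = O >= 5
        assert np.max(np.abs(eta_mine[heavy] - eta_oracle[heavy])) < 1e-4

    def test_anchors_are_exact_zeros_on_fixture(self, stomach_table, default_config):
        apc = fit_apc(stomach_table, default_config)
        i_star, j_star, k_star = apc.anchors
        assert (i_star, j_star, k_star) == (11, 4, 9)
        assert apc.age_effects[i_star - 1] == 0.0
        assert apc.period_effects[j_star - 1] == 0.0
        assert apc.cohort_effects[k_star - 1] == 0.0
        d = drift_coefficients(16, 7)
        assert abs(d @ apc.cohort_effects) < 1e-8

    def test_fitted_totals_match_observed(self, stomach_table, default_config):
        apc = fit_apc(stomach_table, default_config)
        fitted = apc.fitted_means(stomach_table.person_years)
        assert fitted.sum() == pytest.approx(stomach_table.cases.sum(), rel=1e-9)

    def test_reanchoring_leaves_fitted_means_invariant(self, stomach_table):
        m1 = fit_apc(stomach_table, RunConfig(period_index=4, age_index=11))
        m2 = fit_apc(stomach_table, RunConfig(period_index=7, age_index=5))
        f1 = m1.fitted_means(stomach_table.person_years)
        f2 = m2.fitted_means(stomach_table.person_years)
        assert np.max(np.abs(f1 / f2 - 1)) < 1e-8

    def test_single_period_reduces_to_age_only_model(self):
        rng = np.random.default_rng(3)
        n = 8
        py = np.full((n, 1), 1e5)
        cases = rng.poisson(py * np.linspace(1e-4, 8e-4, n)[:, None]).astype(float)
        table = RegistryTable(
            cases=cases, person_years=py,
            age_grid=AgeGrid(n=n), period_grid=PeriodGrid(J=1),
        )
        apc = fit_apc(table, RunConfig(period_index=1, age_index=4))
        assert np.all(apc.period_effects == 0)
        # saturated age fit: fitted means equal observed counts
        fitted = apc.fitted_means(py)
        assert np.allclose(fitted[cases > 0], cases[cases > 0], rtol=1e-6)

    def test_empty_age_row_under_exclusion_raises(self, stomach_table):
        config = RunConfig(period_index=4, age_index=11, exclude_masked=True)
        # Table 1's 20-24 row is entirely at or below 15 cases
        with pytest.raises(APCFitError, match="age row"):
            fit_apc(stomach_table, config)


class TestPopulationHazard:
    def test_anchor_value_is_exp_intercept(self, stomach_table, default_config):
        apc = fit_apc(stomach_table, default_config)
        curve = population_hazard(apc)
        i_star = apc.anchors[0] - 1
        assert curve.values[i_star] == pytest.approx(np.exp(apc.intercept), rel=1e-12)
        se_mu = np.sqrt(apc.covariance[0, 0])
        assert curve.se[i_star] == pytest.approx(np.exp(apc.intercept) * se_mu, rel=1e-9)

    def test_noiseless_hazard_recovery(self, default_params, default_config):
        apc = fit_apc(_noiseless_table(default_params), default_config)
        curve = population_hazard(apc)
        truth = true_unconditional_hazard(default_params).values
        assert np.max(np.abs(curve.values / truth - 1)) < 1e-6

    def test_all_zero_effects_give_constant_curve(self):
        # a table generated at a flat rate fits to a constant hazard
        rate = 5e-4
        py = np.full((16, 7), 1e6)
        table = RegistryTable(cases=py * rate, person_years=py)
        apc = fit_apc(table, RunConfig(period_index=4, age_index=11))
        curve = population_hazard(apc)
        assert np.allclose(curve.values, rate, rtol=1e-8)

    def test_uncertainty_shrinks_with_counts(self, default_params, default_config):
        """Scaling person-years (and counts) by 100 shrinks SEs ~10-fold."""
        base = _noiseless_table(default_params)
        big = RegistryTable(
            cases=base.cases * 100, person_years=base.person_years * 100
        )
        se_small = population_hazard(fit_apc(base, default_config)).se
        se_big = population_hazard(fit_apc(big, default_config)).se
        assert np.allclose(se_big, se_small / 10, rtol=1e-6)


class TestEffectCIs:
    def test_interval_arithmetic_and_anchor_width(self, stomach_table, default_config):
        apc = fit_apc(stomach_table, default_config)
        cis = effect_cis(apc)
        per = cis["period"]
        j_star = apc.anchors[1] - 1
        assert per.estimate[j_star] == per.lower95[j_star] == per.upper95[j_star] == 0.0
        free = np.delete(np.arange(7), j_star)
        assert np.allclose(
            per.upper95[free] - per.estimate[free], 1.96 * per.se[free], rtol=1e-3
        )
        assert np.all(per.lower95 <= per.estimate)
        assert np.all(per.estimate <= per.upper95)

    def test_display_convention_zeroes_pre_anchor_periods(
        self, stomach_table, default_config
    ):
        apc = fit_apc(stomach_table, default_config)
        per = effect_cis(apc, zero_before_anchor_period=True)["period"]
        assert np.all(per.estimate[:3] == 0) and np.all(per.se[:3] == 0)

    def test_noiseless_intervals_shrink_under_count_scaling(
        self, default_params, default_config
    ):
        base = _noiseless_table(default_params)
        big = RegistryTable(cases=base.cases * 1e4, person_years=base.person_years * 1e4)
        w_small = effect_cis(fit_apc(base, default_config))["cohort"]
        w_big = effect_cis(fit_apc(big, default_config))["cohort"]
        width_small = w_small.upper95 - w_small.lower95
        width_big = w_big.upper95 - w_big.lower95
        free = width_small > 0
        assert np.allclose(width_big[free], width_small[free] / 100, rtol=1e-3)


class TestDriftConvention:
    def test_cohort_cell_counts_geometry(self):
        m = cohort_cell_counts(16, 7)
        assert m[0] == m[-1] == 1
        assert m.max() == 7
        assert m.sum() == 16 * 7

    def test_corner_cohort_divergence_stays_local(self, default_config):
        """A zero-count single-cell corner cohort must not disturb other effects."""
        params = SimulationParams(p_true=0.01, seed=0)
        mu = expected_counts(params)
        cases = np.round(mu)
        cases[15, 0] = 0.0  # kill the (16,1) cell = the whole cohort k=1
        table = RegistryTable(cases=cases, person_years=params.population_template)
        apc = fit_apc(table, default_config)
        assert np.max(np.abs(apc.period_effects)) < 0.05
        assert np.max(np.abs(apc.cohort_effects[2:])) < 0.2
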