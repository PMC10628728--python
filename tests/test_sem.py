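import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gsenspy.sem import (
    GsensModelSpec,
    GsensParameters,
    InfeasibleModelError,
    ObservedCorrelations,
    bootstrap_ci,
    fit_gsens_xy,
    fit_gsens_y,
    heritability_sweep,
    implied_correlations,
    observed_correlations,
    prs_only_adjustment,
    solve_outcome_constraint,
)
from gsenspy.sem import wishart_ci

from conftest import simulate_analysis_frame


def _forward_matrix(lx, ly, rg, b, h2x, h2y):
    """Exact implied correlation matrix at given free parameters."""
    a = np.sqrt(h2x)
    c = solve_outcome_constraint(b, rg, a, h2y)
    par = GsensParameters(lx, ly, rg, b, a, c)
    return ObservedCorrelations(("Sx", "Sy", "X", "Y"), implied_correlations(par), 10000), par


class TestObservedCorrelations:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        corr = observed_correlations(pd.DataFrame(rng.standard_normal((20000, 4)),
                                                  columns=["Sx", "Sy", "X", "Y"]))
        off = corr.matrix[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.03)

    def test_duplicated_column_triggers_repair_warning(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        df = pd.DataFrame({"Sx": x, "Sy": x.copy(), "X": rng.standard_normal(500),
                           "Y": rng.standard_normal(500)})
        with pytest.warns(UserWarning, match="near-singular"):
            corr = observed_correlations(df)
        assert corr.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_cholesky_generated_columns_recover_target(self):
        target = np.array(
            [
                [1.0, 0.3, 0.4, 0.2],
                [0.3, 1.0, 0.1, 0.5],
                [0.4, 0.1, 1.0, 0.25],
                [0.2, 0.5, 0.25, 1.0],
            ]
        )
        L = np.linalg.cholesky(target)
        rng = np.random.default_rng(2)
        data = rng.standard_normal((50000, 4)) @ L.T
        corr = observed_correlations(pd.DataFrame(data, columns=list("abcd")))
        assert np.max(np.abs(corr.matrix - target)) < 0.02

    def test_grossly_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="not PSD"):
            observed_correlations(bad, labels=("a", "b", "c"), n=100)


class TestOutcomeConstraint:
    def test_limits(self):
        assert solve_outcome_constraint(0.0, 0.3, 0.5, 0.36) == pytest.approx(0.6)
        # rho_g = 0: c = sqrt(h2y - a^2 b^2)
        assert solve_outcome_constraint(0.4, 0.0, 0.5, 0.2) == pytest.approx(
            np.sqrt(0.2 - 0.25 * 0.16)
        )

    def test_infeasible_when_causal_genetic_variance_exceeds_h2y(self):
        with pytest.raises(InfeasibleModelError):
            solve_outcome_constraint(0.9, 0.0, 0.9, 0.2)

    @settings(max_examples=200, deadline=None)
    @given(
        b=st.floats(0, 0.6),
        rg=st.floats(-0.95, 0.95),
        a=st.floats(0.05, 0.95),
        h2y=st.floats(0.05, 1.0),
    )
    def test_root_satisfies_quadratic(self, b, rg, a, h2y):
        try:
            c = solve_outcome_constraint(b, rg, a, h2y)
        except InfeasibleModelError:
            return
        assert c >= 0
        assert c**2 + 2 * a * b * rg * c + a**2 * b**2 - h2y == pytest.approx(0, abs=1e-10)


class TestImpliedCorrelations:
    def test_hand_evaluated_formulas(self):
        lx, ly, rg, a, b, h2y = 0.5, 0.6, 0.4, 0.3, 0.1, 0.2
        c = solve_outcome_constraint(b, rg, a, h2y)
        R = implied_correlations(GsensParameters(lx, ly, rg, b, a, c))
        assert R[0, 1] == pytest.approx(lx * ly * rg)
        assert R[0, 2] == pytest.approx(lx * a)
        assert R[0, 3] == pytest.approx(lx * (b * a + c * rg))
        assert R[1, 2] == pytest.approx(ly * rg * a)
        assert R[1, 3] == pytest.approx(ly * (c + b * a * rg))
        assert R[2, 3] == pytest.approx(b + c * a * rg)
        assert np.allclose(R, R.T) and np.allclose(np.diag(R), 1.0)

    def test_no_paths_no_correlation(self):
        c = solve_outcome_constraint(0.0, 0.0, 0.5, 0.3)
        R = implied_correlations(GsensParameters(0.7, 0.7, 0.0, 0.0, 0.5, c))
        assert R[2, 3] == 0.0 and R[0, 1] == 0.0


class TestPrsOnly:
    def test_independent_scores_give_zero_confounding(self):
        R = np.eye(4)
        R[2, 3] = R[3, 2] = 0.3
        corr = ObservedCorrelations(("Sx", "Sy", "X", "Y"), R, 1000)
        res = prs_only_adjustment(corr)
        assert res.confounding_pct == pytest.approx(0.0, abs=1e-12)
        assert res.adjusted_effect == pytest.approx(0.3)

    def test_saturated_confounder_gives_full_confounding(self):
        rng = np.random.default_rng(3)
        sy = rng.standard_normal(5000)
        x = 0.5 * sy + rng.standard_normal(5000)
        df = pd.DataFrame({"Sx": rng.standard_normal(5000), "Sy": sy, "X": x, "Y": sy})
        with pytest.warns(UserWarning):
            res = prs_only_adjustment(observed_correlations(df))
        assert abs(res.adjusted_effect) < 1e-4
        assert res.confounding_pct == pytest.approx(100.0, abs=0.1)

    def test_matches_normal_equations_oracle(self):
        corr, _ = _forward_matrix(0.6, 0.6, 0.5, 0.1, 0.16, 0.3)
        res = prs_only_adjustment(corr)
        R = corr.matrix
        # independent oracle: solve the 3-predictor normal equations directly
        beta = np.linalg.lstsq(R[np.ix_([2, 0, 1], [2, 0, 1])], R[[2, 0, 1], 3],
                               rcond=None)[0]
        assert res.adjusted_effect == pytest.approx(float(beta[0]), abs=1e-10)
        assert res.total_effect == pytest.approx(R[2, 3])
        assert res.total_effect == pytest.approx(
            res.adjusted_effect + res.confounding_abs, abs=1e-12
        )


class TestFitXY:
    def test_forward_model_recovery_single_instance(self):
        corr, par = _forward_matrix(0.55, 0.75, 0.45, 0.12, 0.3, 0.35)
        res = fit_gsens_xy(corr, GsensModelSpec(mode="snv_h2", h2x=0.3, h2y=0.35))
        p = res.parameters
        assert p.lambda_x == pytest.approx(par.lambda_x, abs=1e-4)
        assert p.lambda_y == pytest.approx(par.lambda_y, abs=1e-4)
        assert p.rho_g == pytest.approx(par.rho_g, abs=1e-4)
        assert p.b == pytest.approx(par.b, abs=1e-4)
        assert res.fit_discrepancy < 1e-8

    def test_decomposition_identity(self):
        corr, _ = _forward_matrix(0.5, 0.6, 0.3, 0.15, 0.25, 0.3)
        res = fit_gsens_xy(corr, GsensModelSpec(mode="snv_h2", h2x=0.25, h2y=0.3))
        assert res.total_effect == pytest.approx(
            res.adjusted_effect + res.confounding_abs, abs=1e-10
        )

    def test_pure_confounding_pins_adjusted_at_zero(self):
        corr, _ = _forward_matrix(0.6, 0.6, 0.5, 0.0, 0.25, 0.25)
        res = fit_gsens_xy(corr, GsensModelSpec(mode="snv_h2", h2x=0.25, h2y=0.25))
        assert res.adjusted_effect == pytest.approx(0.0, abs=1e-6)
        assert res.confounding_pct == pytest.approx(100.0, abs=1e-3)

    def test_infeasible_heritability_below_prs_r2(self):
        corr, _ = _forward_matrix(0.9, 0.6, 0.3, 0.1, 0.5, 0.4)
        r2 = corr.matrix[0, 2] ** 2
        with pytest.raises(InfeasibleModelError):
            fit_gsens_xy(corr, GsensModelSpec(mode="snv_h2", h2x=r2 / 2, h2y=0.4))

    def test_confounding_increases_with_supplied_h2(self, analysis_frame):
        frame, truth = analysis_frame
        corr = observed_correlations(frame)
        pcts = []
        for h2y in (truth["h2y_std"], min(2 * truth["h2y_std"], 0.8)):
            res = fit_gsens_xy(
                corr, GsensModelSpec(mode="snv_h2", h2x=truth["h2x"], h2y=h2y)
            )
            pcts.append(res.confounding_pct)
        assert pcts[1] >= pcts[0] - 1e-6


class TestNoMeasurementErrorLimit:
    @pytest.mark.parametrize(
        "lx,ly,rg,b,h2x",
        [
            (1.0, 1.0, 0.5, 0.0, 0.25),   # pure confounding: h2y = r(Sy,Y)^2 exactly
            (1.0, 1.0, 0.9, 0.15, 0.3),   # strong pleiotropy
            (1.0, 1.0, 0.4, 0.12, 0.2),   # generic
        ],
    )
    def test_perfect_prs_reduces_to_regression_adjustment(self, lx, ly, rg, b, h2x):
        # with loadings 1 the structural equation for Y is a plain regression
        # on observed X and Sy, so the SEM must agree with prs_only; the
        # supplied h2x equals the exposure PRS r2 in every case, and h2y is
        # the model-consistent genetic variance of Y (equal to the outcome
        # PRS r2 when b = 0)
        a = np.sqrt(h2x)
        c = 0.5
        h2y = c**2 + 2 * a * b * rg * c + a**2 * b**2
        corr = ObservedCorrelations(
            ("Sx", "Sy", "X", "Y"),
            implied_correlations(GsensParameters(lx, ly, rg, b, a, c)),
            10000,
        )
        res_sem = fit_gsens_xy(corr, GsensModelSpec(mode="snv_h2", h2x=h2x, h2y=h2y))
        res_reg = prs_only_adjustment(corr)
        assert res_sem.adjusted_effect == pytest.approx(res_reg.adjusted_effect, abs=1e-4)


class TestFitY:
    def test_uncorrelated_prs_exposure_closed_form(self):
        # r(Sy,X) = 0: lambda_y = r(Sy,Y)/c, b = r(X,Y), zero confounding
        c = np.sqrt(0.36)
        R = np.eye(3)
        R[0, 2] = R[2, 0] = 0.42
        R[1, 2] = R[2, 1] = 0.2
        corr = ObservedCorrelations(("Sy", "X", "Y"), R, 5000)
        res = fit_gsens_y(corr, GsensModelSpec(mode="snv_h2", h2x=0.5, h2y=0.36))
        assert res.parameters.lambda_y == pytest.approx(0.42 / c, abs=1e-10)
        assert res.adjusted_effect == pytest.approx(0.2, abs=1e-10)
        assert res.confounding_abs == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_matches_numerical_minimizer(self):
        from scipy import optimize

        from gsenspy.sem import _y_implied, _y_objective

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 20:
            c = np.sqrt(rng.uniform(0.05, 0.8))
            ly = rng.uniform(0.2, 0.95)
            rxg = rng.uniform(-0.7, 0.7)
            b = rng.uniform(0, 0.3)
            if 1 - (b**2 + c**2 + 2 * b * c * rxg) < 0.01:
                continue
            R = _y_implied(ly, rxg, b, c)
            corr = ObservedCorrelations(("Sy", "X", "Y"), R, 5000)
            res = fit_gsens_y(
                corr, GsensModelSpec(mode="snv_h2", h2x=0.5, h2y=c**2)
            )
            best = min(
                (
                    optimize.minimize(
                        _y_objective, x0, args=(R, c), method="Nelder-Mead",
                        options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 8000},
                    )
                    for x0 in ([0.5, 0.0, 0.1], [0.9, 0.5, 0.2], [0.3, -0.5, 0.05])
                ),
                key=lambda r: r.fun,
            )
            assert res.parameters.lambda_y == pytest.approx(ly, abs=1e-6)
            assert res.parameters.b == pytest.approx(b, abs=1e-6)
            assert res.fit_discrepancy == pytest.approx(best.fun, abs=1e-6)
            checked += 1


class TestBootstrap:
    def test_same_seed_reproduces_intervals(self, analysis_frame):
        frame, truth = analysis_frame
        spec = GsensModelSpec(mode="prs_only", h2x=0.5, h2y=0.5)
        ci1 = bootstrap_ci(frame, spec, B=100, seed=5)
        ci2 = bootstrap_ci(frame, spec, B=100, seed=5)
        assert ci1.adjusted_ci == ci2.adjusted_ci
        assert ci1.confounding_pct_ci == ci2.confounding_pct_ci

    def test_null_confounding_interval_covers_zero(self):
        frame, _ = simulate_analysis_frame(seed=19, n=2000, m=800, rg=0.0, b_xy=0.15)
        spec = GsensModelSpec(mode="snv_h2", h2x=0.25, h2y=0.25)
        ci = bootstrap_ci(frame, spec, B=150, seed=1)
        lo, hi = ci.confounding_pct_ci
        assert lo <= 0.0 <= hi + 1e-9

    def test_interval_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (1500, 6000):
            frame, _ = simulate_analysis_frame(seed=29, n=n, m=600)
            ci = bootstrap_ci(frame, GsensModelSpec(mode="prs_only", h2x=0.5, h2y=0.5),
                              B=200, seed=2)
            widths[n] = ci.adjusted_ci[1] - ci.adjusted_ci[0]
        ratio = widths[6000] / widths[1500]
        assert 0.5 * 0.75 < ratio < 0.5 * 1.25 + 0.25  # ~1/2 expected for 4x n

    def test_wishart_ci_from_summary_only(self, analysis_frame):
        frame, truth = analysis_frame
        corr = observed_correlations(frame)
        ci = wishart_ci(corr, GsensModelSpec(mode="snv_h2", h2x=truth["h2x"],
                                             h2y=truth["h2y_std"]), B=100, seed=3)
        lo, hi = ci.confounding_pct_ci
        assert lo < truth["pct"] < hi
        assert ci.method == "wishart_monte_carlo"


class TestSweep:
    def test_adjusted_effect_non_increasing(self, analysis_frame):
        frame, truth = analysis_frame
        corr = observed_correlations(frame)
        spec = GsensModelSpec(mode="snv_h2", h2x=truth["h2x"], h2y=truth["h2y_std"])
        sweep = heritability_sweep(corr, np.linspace(0.1, 0.8, 8), spec, refine=False)
        adj = sweep.adjusted_effect[sweep.feasible]
        assert np.all(np.diff(adj) <= 1e-6)

    def test_single_point_grid_equals_direct_fit(self, analysis_frame):
        frame, truth = analysis_frame
        corr = observed_correlations(frame)
        spec = GsensModelSpec(mode="snv_h2", h2x=truth["h2x"], h2y=truth["h2y_std"])
        sweep = heritability_sweep(corr, np.array([truth["h2y_std"]]), spec)
        direct = fit_gsens_xy(corr, spec)
        assert sweep.adjusted_effect[0] == pytest.approx(direct.adjusted_effect, abs=1e-10)
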