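"""Bounded multistart least-squares identification and cohort statistics."""

import numpy as np
import pytest

from pelvimech import (FitConfig, OgdenModel, OgdenParameters,
                       StressStrainCurve, cohort_summary, fit_ogden,
                       load_cohort_parameters, objective_e,
                       uniaxial_nominal_stress)

from conftest import make_curve, random_stable_params


def objective_by_loop(params, curve):
    """Independent oracle: naive loop over data points."""
    total = 0.0
    for lam, p_test in zip(curve.stretch, curve.nominal_stress_mpa):
        total += (p_test - uniaxial_nominal_stress(params, float(lam))) ** 2
    return 0.5 * total


def grid_search_one_term(curve, alpha_grid):
    """Brute-force oracle for the 1-term fit.

    E is quadratic in mu for fixed alpha, so the exhaustive search scans a
    fine alpha grid and takes the exact minimising mu per candidate,
    mu*(alpha) = <P_test, g> / <g, g> with g = 2 (lam^(a-1) - lam^(-a/2-1)).
    Entirely independent of the package's optimiser.
    """
    lam = curve.stretch
    p_test = curve.nominal_stress_mpa
    best = (np.inf, None, None)
    for alpha in np.asarray(alpha_grid):
        g = 2.0 * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))
        denom = float(np.dot(g, g))
        if denom == 0.0:
            continue
        mu = max(float(np.dot(p_test, g)) / denom, 1e-9)
        e = 0.5 * float(np.sum((p_test - mu * g) ** 2))
        if e < best[0]:
            best = (e, mu, float(alpha))
    return best


class TestObjective:
    def test_zero_for_generating_parameters(self, specimen9_params):
        curve = make_curve(specimen9_params)
        assert objective_e(specimen9_params, curve) == pytest.approx(0.0, abs=1e-20)

    def test_single_point_hand_value(self):
        curve = StressStrainCurve("one", [1.0], [0.0], [1.0])
        p = OgdenParameters.from_arrays([0.01], [5.0])  # P(1) = 0
        assert objective_e(p, curve) == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            p = random_stable_params(rng)
            curve = make_curve(random_stable_params(rng), n=23)
            assert objective_e(p, curve) == pytest.approx(
                objective_by_loop(p, curve), rel=1e-12)


class TestFit:
    def test_noiseless_two_term_recovery_by_prediction(self, specimen9_params):
        """Predicted stress must match the generating law to <= 0.1% RMSE."""
        curve = make_curve(specimen9_params, lam_max=1.6, n=50)
        res = fit_ogden(curve, FitConfig(rng_seed=1))
        assert res.converged
        assert res.rmse_mpa <= 1e-3 * curve.max_stress_mpa

    def test_one_term_recovery_matches_grid_oracle(self):
        truth_mu, truth_alpha = 0.005, 10.0
        curve = make_curve(OgdenParameters.from_arrays([truth_mu], [truth_alpha]),
                           lam_max=1.5, n=50)
        res = fit_ogden(curve, FitConfig(n_terms=1, rng_seed=1))
        assert res.params.mus[0] == pytest.approx(truth_mu, rel=1e-2)
        assert res.params.alphas[0] == pytest.approx(truth_alpha, rel=1e-2)
        # brute-force confirmation that the global optimum sits at the truth
        _, mu_g, alpha_g = grid_search_one_term(curve, np.linspace(5, 15, 2001))
        assert res.params.mus[0] == pytest.approx(mu_g, rel=1e-2)
        assert res.params.alphas[0] == pytest.approx(alpha_g, rel=1e-2)

    def test_deterministic_under_fixed_seed(self, specimen9_params):
        curve = make_curve(specimen9_params)
        cfg = FitConfig(rng_seed=11, n_multistarts=4)
        a, b = fit_ogden(curve, cfg), fit_ogden(curve, cfg)
        assert a.params == b.params
        assert a.error_e == b.error_e
        assert a.start_index == b.start_index

    def test_multistart_monotonicity(self, specimen9_params):
        """More starts from the same stream never worsen the objective."""
        curve = make_curve(specimen9_params, n=30)
        errors = [fit_ogden(curve, FitConfig(rng_seed=3, n_multistarts=k)).error_e
                  for k in (1, 2, 4, 8)]
        assert all(e2 <= e1 * (1 + 1e-12) for e1, e2 in zip(errors, errors[1:]))

    def test_returned_parameters_respect_bounds_and_stability(self, rng):
        cfg = FitConfig(rng_seed=2, n_multistarts=4)
        for _ in range(3):
            curve = make_curve(random_stable_params(rng), n=40)
            res = fit_ogden(curve, cfg)
            p = res.params
            assert np.all(p.mus >= cfg.mu_bounds[0])
            assert np.all(p.mus <= cfg.mu_bounds[1])
            assert np.all(p.alphas >= cfg.alpha_bounds[0])
            assert np.all(p.alphas <= cfg.alpha_bounds[1])
            assert p.shear_stability_sum > 0

    def test_terms_sorted_by_ascending_alpha(self, specimen9_params):
        res = fit_ogden(make_curve(specimen9_params), FitConfig(rng_seed=1))
        assert res.params.alphas[0] <= res.params.alphas[1]

    def test_degenerate_zero_stress_curve(self):
        lam = np.linspace(1.0, 1.3, 12)
        curve = StressStrainCurve("flat", lam, lam - 1, np.zeros_like(lam))
        res = fit_ogden(curve, FitConfig(rng_seed=1, n_multistarts=4))
        # bounds forbid P == 0; the fit settles at a feasible near-zero model
        assert res.params.shear_stability_sum > 0
        assert abs(res.predict(1.0)) < 1e-12

    def test_short_or_narrow_curves_rejected(self, specimen9_params):
        with pytest.raises(ValueError, match="points"):
            OgdenModel(make_curve(specimen9_params, n=4), FitConfig())
        with pytest.raises(ValueError, match="range"):
            OgdenModel(make_curve(specimen9_params, lam_max=1.02, n=20))

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(mu_bounds=(0.5, 1e-6))
        with pytest.raises(ValueError):
            FitConfig(mu_bounds=(-1.0, 0.5))

    def test_plot_fit_draws_data_and_model(self, specimen9_params):
        import matplotlib
        matplotlib.use("Agg")
        res = fit_ogden(make_curve(specimen9_params),
                        FitConfig(rng_seed=1, n_multistarts=2))
        ax = res.plot_fit()
        assert len(ax.lines) == 2
        assert ax.get_ylabel().startswith("nominal stress")

    def test_from_dataframe_and_summary(self, specimen9_params):
        df = make_curve(specimen9_params).to_dataframe()
        res = OgdenModel.from_dataframe(df, "df_spec",
                                        FitConfig(rng_seed=1, n_multistarts=2)).fit()
        text = res.summary()
        assert "df_spec" in text and "mu [MPa]" in text
        assert res.predict(1.0) == pytest.approx(0.0, abs=1e-12)


class TestCohortSummary:
    def test_reproduces_published_alpha1_mu2_statistics(self):
        s = cohort_summary(load_cohort_parameters())
        assert s.n_specimens == 20
        assert round(s.mean_alphas[0], 4) == 0.1803
        assert round(s.sd_alphas[0], 4) == 0.1299
        assert round(s.mean_mus[1], 4) == 0.0216
        assert round(s.sd_mus[1], 4) == 0.0173

    def test_single_specimen_sd_zero(self, specimen9_params):
        s = cohort_summary([specimen9_params])
        assert s.mean_mus == pytest.approx(specimen9_params.mus)
        assert np.all(s.sd_mus == 0) and np.all(s.sd_alphas == 0)

    def test_two_specimen_closed_form(self):
        a = OgdenParameters.from_arrays([0.002, 0.02], [0.1, 10.0])
        b = OgdenParameters.from_arrays([0.006, 0.04], [0.3, 18.0])
        s = cohort_summary([a, b])
        assert s.mean_mus == pytest.approx((a.mus + b.mus) / 2)
        assert s.sd_mus == pytest.approx(np.abs(a.mus - b.mus) / 2)
        assert s.sd_alphas == pytest.approx(np.abs(a.alphas - b.alphas) / 2)

    def test_mixed_term_counts_rejected(self, specimen9_params):
        with pytest.raises(ValueError, match="same number of terms"):
            cohort_summary([specimen9_params,
                            OgdenParameters.from_arrays([0.005], [10.0])])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])
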