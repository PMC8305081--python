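import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fermkin as fk


class TestEvalExponential:
    def test_published_ph_curve_at_zero(self):
        # a - b at t=0: 3.382 - (-3.188) = 6.570
        assert fk.eval_exponential(3.382, -3.188, 0.071, 0.0) == pytest.approx(6.570)

    def test_asymptote_at_large_time(self):
        assert fk.eval_exponential(3.4, -3.2, 0.07, 1e6) == pytest.approx(3.4)

    def test_zero_b_gives_constant(self):
        t = np.linspace(0, 36, 7)
        assert np.allclose(fk.eval_exponential(5.0, 0.0, 0.1, t), 5.0)


class TestRSquared:
    def test_perfect_prediction(self):
        assert fk.r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        o = np.array([1.0, 2.0, 3.0])
        assert fk.r_squared(o, np.full(3, o.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # RSS = 1, CSS = 2 -> R^2 = 0.5
        assert fk.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(fk.DegenerateVarianceError):
            fk.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_bad_model_can_be_negative(self):
        assert fk.r_squared([1, 2, 3], [10, 10, 10]) < 0


class TestTitration:
    def test_zero_titrant_zero_acidity(self):
        assert fk.tta_percent(fk.TitrationRecord(naoh_ml=0.0)) == 0.0

    def test_direct_substitution(self):
        # 1.33 mL x 0.1 M x 90.08 mg / (10 mL x 1000) x 100 = 0.1198 %
        rec = fk.TitrationRecord(naoh_ml=1.33, naoh_molarity=0.1, sample_ml=10.0)
        assert fk.tta_percent(rec) == pytest.approx(0.11981, abs=1e-4)

    def test_doubling_sample_volume_halves_result(self):
        a = fk.tta_percent(fk.TitrationRecord(naoh_ml=2.0, sample_ml=10.0))
        b = fk.tta_percent(fk.TitrationRecord(naoh_ml=2.0, sample_ml=20.0))
        assert a == pytest.approx(2 * b)


class TestFitExponential:
    def test_ph_reproduces_published_parameters(self, table1):
        fit = fk.fit_exponential(table1.time_h, table1.means("pH"))
        assert fit.converged
        assert fit.a == pytest.approx(3.382, abs=0.005)
        assert fit.b == pytest.approx(-3.188, abs=0.005)
        assert fit.c == pytest.approx(0.071, abs=0.001)
        assert fit.r2 == pytest.approx(0.971, abs=0.001)
        # standard errors from the local linearisation
        assert fit.se_a == pytest.approx(0.213, abs=0.005)
        assert fit.se_b == pytest.approx(0.203, abs=0.005)
        assert fit.se_c == pytest.approx(0.013, abs=0.002)

    def test_tta_reproduces_published_parameters(self, table1):
        fit = fk.fit_exponential(table1.time_h, table1.means("tta_pct"))
        assert fit.a == pytest.approx(0.663, abs=0.002)
        assert fit.b == pytest.approx(0.575, abs=0.002)
        assert fit.c == pytest.approx(0.042, abs=0.001)
        assert fit.r2 == pytest.approx(0.981, abs=0.001)

    def test_noise_free_exact_recovery(self):
        t = np.arange(0, 37, 3.0)
        y = fk.eval_exponential(4.0, -2.0, 0.1, t)
        fit = fk.fit_exponential(t, y)
        assert (fit.a, fit.b, fit.c) == pytest.approx((4.0, -2.0, 0.1), abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.residuals, 0.0, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fk.fit_exponential([0, 3, 6], [6.4, 6.1, 5.6])

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            fk.fit_exponential([0, 6, 3, 9], [6.4, 6.1, 5.6, 5.4])

    def test_matches_brute_force_grid_oracle(self):
        # a dense grid around the optimum must not beat the fitted RSS
        t = np.arange(0, 25, 4.0)
        rng = np.random.default_rng(7)
        y = fk.eval_exponential(3.5, -2.5, 0.12, t) + rng.normal(0, 0.05, t.size)
        fit = fk.fit_exponential(t, y)
        rss_fit = float(np.sum(fit.residuals**2))
        grid_best = min(
            float(np.sum((y - fk.eval_exponential(a, b, c, t)) ** 2))
            for a, b, c in itertools.product(
                np.linspace(3.2, 3.8, 25),
                np.linspace(-2.9, -2.1, 25),
                np.linspace(0.05, 0.25, 25),
            )
        )
        assert rss_fit <= grid_best + 1e-12

    def test_fit_on_means_equals_replicate_expanded(self, table1):
        t, y = table1.time_h, table1.means("pH")
        k = 3
        fit_means = fk.fit_exponential(t, y)
        fit_reps = fk.fit_exponential(np.repeat(t, k), np.repeat(y, k))
        assert fit_reps.a == pytest.approx(fit_means.a, abs=1e-8)
        assert fit_reps.b == pytest.approx(fit_means.b, abs=1e-8)
        assert fit_reps.c == pytest.approx(fit_means.c, abs=1e-8)

    def test_converged_fit_beats_any_hand_supplied_triple(self, table1):
        t, y = table1.time_h, table1.means("pH")
        fit = fk.fit_exponential(t, y)
        for a, b, c in [(3.382, -3.188, 0.071), (3.4, -3.0, 0.08), (3.0, -3.5, 0.05)]:
            r2_hand = fk.r_squared(y, fk.eval_exponential(a, b, c, t))
            assert fit.r2 >= r2_hand - 1e-12

    def test_predictions_monotone_and_bounded_on_monotone_data(self, table1):
        fit = fk.fit_exponential(table1.time_h, table1.means("pH"))
        tt = np.linspace(0, 36, 200)
        pred = fit.predict(tt)
        assert np.all(np.diff(pred) <= 0)  # pH decreases toward the asymptote
        lo, hi = sorted([fit.a, fit.a - fit.b])
        assert np.all(pred >= lo - 1e-9) and np.all(pred <= hi + 1e-9)


class TestFitQuadratic:
    def test_glucose_reproduces_published_r2(self, table1):
        qf = fk.fit_quadratic(table1.time_h, table1.means("glucose_pct"))
        assert qf.r2 == pytest.approx(0.947, abs=0.001)
        assert qf.c0 == pytest.approx(0.584, abs=0.02)
        assert qf.c1 == pytest.approx(0.107, abs=0.01)
        assert qf.c2 == pytest.approx(-0.002, abs=0.001)

    def test_refit_beats_published_rounded_coefficients(self, table1):
        t, y = table1.time_h, table1.means("glucose_pct")
        qf = fk.fit_quadratic(t, y)
        r2_published = fk.r_squared(y, 0.584 + 0.107 * t - 0.002 * t * t)
        assert qf.r2 >= r2_published

    def test_collinear_points_give_exact_line(self):
        qf = fk.fit_quadratic([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert qf.c2 == pytest.approx(0.0, abs=1e-10)
        assert qf.r2 == pytest.approx(1.0)

    def test_repeated_times_are_singular(self):
        with pytest.raises(fk.RankDeficiencyError):
            fk.fit_quadratic([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestPlateau:
    def test_table1_ph_plateau(self, table1):
        # Welch comparisons of consecutive 3-h samples (n=3) lose
        # significance from 12 h on; multiple-range tests on raw
        # replicates place the published optimum slightly later (18 h)
        assert fk.plateau_time(table1, "pH", alpha=0.05) == 12.0

    def test_table1_tta_plateau(self, table1):
        assert fk.plateau_time(table1, "tta_pct", alpha=0.05) == 21.0

    def test_constant_series_plateaus_immediately(self):
        ts = fk.FermentationTimeSeries(
            time_h=[0, 3, 6, 9],
            variables={"pH": fk.Replicated([4.0] * 4, [0.1] * 4, [3] * 4)},
        )
        assert fk.plateau_time(ts, "pH") == 0.0

    def test_large_steps_never_plateau(self):
        ts = fk.FermentationTimeSeries(
            time_h=[0, 3, 6, 9],
            variables={"pH": fk.Replicated([7, 6, 5, 4], [0.01] * 4, [3] * 4)},
        )
        assert fk.plateau_time(ts, "pH") == 9.0

    def test_single_replicate_rejected(self):
        ts = fk.FermentationTimeSeries(
            time_h=[0, 3],
            variables={"pH": fk.Replicated([7, 6], [0.1, 0.1], [1, 3])},
        )
        with pytest.raises(fk.DataValidationError, match="replicates"):
            fk.plateau_time(ts, "pH")


@given(
    a=st.floats(1.0, 10.0),
    b=st.floats(-5.0, 5.0),
    c=st.floats(0.01, 1.0),
    t1=st.floats(0.0, 50.0),
    dt=st.floats(0.1, 50.0),
)
def test_exponential_curve_is_monotone_between_intercept_and_asymptote(a, b, c, t1, dt):
    """y = a - b exp(-ct) moves monotonically from a-b toward a."""
    y1 = fk.eval_exponential(a, b, c, t1)
    y2 = fk.eval_exponential(a, b, c, t1 + dt)
    lo, hi = sorted([a, a - b])
    assert lo - 1e-9 <= y1 <= hi + 1e-9
    if b > 0:
        assert y2 >= y1 - 1e-12
    elif b < 0:
        assert y2 <= y1 + 1e-12
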