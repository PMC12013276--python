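"""Two-phase model evaluation, fitting and censoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amoebatrack import (
    FitOptions,
    NoiseSpec,
    TwoPhaseParams,
    ValidationError,
    eval_increment,
    eval_model,
    fit_two_phase,
    relative_colonization,
    sample_curve,
)
from conftest import draw_params

P_REF = TwoPhaseParams(cIA=100, cCA=200, tx=4, tp=10, tc=50, tg=2)


class TestEvalModel:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            (TwoPhaseParams(0, 0, 1, 1, 1, 1), 17.0, 0.0),
            # hand evaluation: 100*(1-e^-4.6) + 200/2 at the logistic midpoint
            (P_REF, 50.0, 100 * (1 - np.exp(-4.6)) + 100.0),
            # asymptote cIA + cCA
            (TwoPhaseParams(60.3, 100, 4, 10, 50, 2), 1e5, 160.3),
        ],
    )
    def test_known_values(self, params, t, expected):
        assert eval_model(params, t) == pytest.approx(expected, rel=1e-9)

    def test_midpoint_is_half_plateau(self):
        """The logistic term contributes exactly cCA/2 at t = tc."""
        p = TwoPhaseParams(0, 500, 0, 1, 80, 3)
        assert eval_model(p, 80.0) == pytest.approx(250.0)

    def test_quiescent_before_excystation(self):
        p = TwoPhaseParams(100, 0, 6, 4, 50, 2)
        t = np.linspace(0, 5.99, 50)
        assert np.all(eval_model(p, t) == 0.0)

    def test_vector_and_scalar_agree(self):
        t = np.array([0.0, 10.0, 100.0])
        vec = eval_model(P_REF, t)
        assert vec.shape == (3,)
        assert vec[1] == eval_model(P_REF, 10.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_nondecreasing(self, seed):
        p = draw_params(np.random.default_rng(seed))
        t = np.linspace(0, 300, 1500)
        ca = eval_model(p, t)
        assert np.all(np.diff(ca) >= -1e-9)
        assert np.all(ca >= 0) and np.all(ca < p.cIA + p.cCA + 1e-9)

    def test_rejects_invalid(self):
        with pytest.raises(ValidationError):
            eval_model(P_REF, -1.0)
        with pytest.raises(ValidationError):
            eval_model(P_REF, np.nan)
        with pytest.raises(ValidationError):
            TwoPhaseParams(-1, 0, 1, 1, 1, 1)
        with pytest.raises(ValidationError):
            TwoPhaseParams(1, 1, 1, 0.0, 1, 1)
        with pytest.raises(ValidationError):
            TwoPhaseParams(1, np.inf, 1, 1, 1, 1)


class TestEvalIncrement:
    def test_zero_amplitudes(self):
        p = TwoPhaseParams(0, 0, 1, 1, 1, 1)
        assert np.all(eval_increment(p, np.linspace(0, 100, 7)) == 0.0)

    def test_inoculum_rate_at_onset(self):
        # cIA/tp at t = tx, with a negligible logistic tail (tc >> tx)
        p = TwoPhaseParams(100, 200, 4, 10, 150, 2)
        assert eval_increment(p, 4.0) == pytest.approx(10.0, rel=1e-6)

    def test_logistic_peak_rate(self):
        # the logistic derivative peaks at cCA/(4 tg) at t = tc
        p = TwoPhaseParams(0, 200, 1, 1, 50, 2)
        assert eval_increment(p, 50.0) == pytest.approx(200 / 8.0)

    def test_integrates_to_model(self, rng):
        """Quadrature of the rate reproduces the cumulative curve to 0.1%."""
        from scipy.integrate import cumulative_trapezoid

        for _ in range(5):
            p = draw_params(rng)
            t = np.linspace(0, 250, 20_000)
            ca_quad = cumulative_trapezoid(eval_increment(p, t), t, initial=0.0)
            ca = eval_model(p, t)
            # the rate integrates to CA(T) - CA(0); CA(0) is the (small)
            # logistic offset cCA/(1+e^{tc/tg}) already accrued at t=0
            assert np.abs(ca_quad[-1] - (ca[-1] - ca[0])) <= 1e-3 * max(ca[-1], 1.0)


class TestRelativeColonization:
    @pytest.mark.parametrize(
        "cia, cca, expected",
        [
            (69.1, 276.4, 0.8),
            (100.0, 0.0, 0.0),
            (0.0, 50.0, 1.0),
            (0.0, 0.0, 0.0),  # 0/0 maps to 0 by convention
        ],
    )
    def test_fraction(self, cia, cca, expected):
        p = TwoPhaseParams(cia, cca, 1, 1, 1, 1)
        assert relative_colonization(p) == pytest.approx(expected)

    def test_absent_colonization_forces_zero(self, hour_grid):
        p = TwoPhaseParams(cIA=88.9, cCA=0.0, tx=4.6, tp=9.3, tc=50, tg=2)
        curve, _ = sample_curve(p, hour_grid)
        fit = fit_two_phase(curve)
        assert relative_colonization(fit) == 0.0


class TestFitTwoPhase:
    def test_noiseless_round_trip(self, hour_grid):
        curve, _ = sample_curve(P_REF, hour_grid)
        fit = fit_two_phase(curve)
        err = np.abs(fit.params.as_array() - P_REF.as_array()) / P_REF.as_array()
        assert err.max() < 1e-3
        assert fit.converged and fit.r_squared > 0.9999
        assert not fit.tc_censored
        assert fit.relative_colonization == pytest.approx(2 / 3, rel=1e-3)

    def test_overlapping_phases_recovered(self, hour_grid):
        # colonization beginning while the inoculum is still exploring: the
        # regime where a single-basin fit collapses onto one term
        p = TwoPhaseParams(cIA=183.4, cCA=1469.0, tx=6.0, tp=14.2, tc=31.5, tg=7.6)
        curve, _ = sample_curve(p, hour_grid)
        fit = fit_two_phase(curve)
        err = np.abs(fit.params.as_array() - p.as_array()) / p.as_array()
        assert err.max() < 1e-3

    def test_no_colonization_is_censored(self, hour_grid):
        p = TwoPhaseParams(cIA=88.9, cCA=0.0, tx=4.6, tp=9.3, tc=50, tg=2)
        curve, _ = sample_curve(p, hour_grid)
        fit = fit_two_phase(curve)
        assert fit.colonization_absent and fit.tc_censored
        assert fit.relative_colonization == 0.0
        assert fit.tc_reported >= fit.window_end
        assert fit.tg_reported >= fit.window_end
        assert fit.tc_label() == ">200"
        # the inoculum parameters are still recovered
        assert fit.params.cIA == pytest.approx(88.9, rel=1e-3)
        assert fit.params.tx == pytest.approx(4.6, rel=1e-3)
        assert fit.params.tp == pytest.approx(9.3, rel=1e-3)

    def test_censoring_sound_when_tc_beyond_window(self, hour_grid):
        """A generating tc outside the window never yields an uncensored
        tc inside it."""
        for tc_true, seed in [(250.0, 1), (215.0, 2), (400.0, 3)]:
            p = TwoPhaseParams(cIA=100, cCA=800, tx=4, tp=9, tc=tc_true, tg=5)
            curve, _ = sample_curve(p, hour_grid, NoiseSpec(increment_cv=0.1, seed=seed))
            fit = fit_two_phase(curve)
            assert fit.tc_censored or fit.params.tc >= 0.95 * fit.window_end
            assert fit.tc_reported >= 0.95 * fit.window_end

    def test_zero_curve_degenerate(self, hour_grid):
        from amoebatrack import CumulativeActivityCurve

        curve = CumulativeActivityCurve(times=hour_grid, ca=np.zeros_like(hour_grid))
        fit = fit_two_phase(curve)
        assert not fit.converged
        assert fit.colonization_absent
        assert fit.params.cIA == 0.0 and fit.params.cCA == 0.0
        assert fit.relative_colonization == 0.0

    def test_too_few_points_rejected(self):
        from amoebatrack import CumulativeActivityCurve

        curve = CumulativeActivityCurve(times=np.arange(10.0), ca=np.arange(10.0))
        with pytest.raises(ValidationError):
            fit_two_phase(curve)

    def test_decreasing_ca_warns_and_clips(self, hour_grid):
        curve, _ = sample_curve(P_REF, hour_grid)
        ca = curve.ca.copy()
        ca[100] = ca[99] - 5.0  # single glitch
        curve.ca = ca
        with pytest.warns(UserWarning, match="clipping"):
            fit = fit_two_phase(curve)
        assert fit.converged

    def test_fit_is_deterministic(self, hour_grid):
        curve, _ = sample_curve(P_REF, hour_grid, NoiseSpec(increment_cv=0.1, seed=9))
        f1 = fit_two_phase(curve)
        f2 = fit_two_phase(curve)
        assert f1.params == f2.params

    def test_implausible_ordering_flagged(self):
        p = TwoPhaseParams(10, 10, 5, 1, 4, 1)
        assert p.implausible_ordering
        assert not TwoPhaseParams(10, 10, 5, 1, 50, 1).implausible_ordering


def test_half_plateau_limit(rng):
    """With tc far beyond the inoculum phase, CA(tc) = cIA + cCA/2 to 1%."""
    for _ in range(10):
        p = draw_params(rng)
        tc = p.tx + 5 * p.tp + rng.uniform(50, 100)
        p = TwoPhaseParams(p.cIA, max(p.cCA, 10.0), p.tx, p.tp, tc, p.tg)
        assert eval_model(p, p.tc) == pytest.approx(p.cIA + p.cCA / 2, rel=0.01)
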