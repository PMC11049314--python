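"""Single- and two-compartment IR-bSSFP simulation against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import curve_fit

from iirbssfp import (
    ConvergenceError,
    SequenceParams,
    SignalCurve,
    SinglePoolTissue,
    TwoPoolTissue,
    apparent_relaxation,
    frame_average,
    simulate_single_pool,
    simulate_two_pool,
)


def bssfp_steady_state(t1, t2, alpha_deg):
    """Independent oracle: on-resonance bSSFP steady-state amplitude in the
    short-TR limit, M0 sin(a) / ((T1/T2 + 1) - cos(a) (T1/T2 - 1))."""
    a = math.radians(alpha_deg)
    r = t1 / t2
    return math.sin(a) / ((r + 1.0) - math.cos(a) * (r - 1.0))


LONG_SEQ = SequenceParams(tinv_ms=10000.0, n_cycles_max=60)


class TestSinglePool:
    def test_zero_proton_density_gives_zero_curve(self):
        c = simulate_single_pool(SinglePoolTissue(1000.0, 100.0, pd=0.0), LONG_SEQ)
        assert np.all(c.values == 0.0)

    def test_vanishing_flip_angle_gives_vanishing_signal(self):
        seq = LONG_SEQ.replace(flip_angle_deg=0.05)
        c = simulate_single_pool(SinglePoolTissue(1000.0, 100.0), seq)
        assert c.values.max() < 1e-3

    @pytest.mark.parametrize("t1", [600.0, 1200.0, 2400.0])
    @pytest.mark.parametrize("t2", [60.0, 120.0, 240.0])
    def test_late_echo_matches_closed_form_within_1pct(self, t1, t2):
        c = simulate_single_pool(SinglePoolTissue(t1, t2), LONG_SEQ)
        ss = bssfp_steady_state(t1, t2, LONG_SEQ.flip_angle_deg)
        assert c.values[-1] == pytest.approx(ss, rel=0.01)

    def test_reference_value_0156(self):
        # T1=1000, T2=100, 30 deg: closed form ~0.156*M0
        c = simulate_single_pool(SinglePoolTissue(1000.0, 100.0), LONG_SEQ)
        assert c.values[-1] == pytest.approx(0.156, rel=0.01)

    def test_periodic_steady_state_consecutive_cycles_agree(self, seq40):
        curve, hist = simulate_single_pool(
            SinglePoolTissue(1500.0, 150.0), seq40, signed=True, keep_history=True
        )
        last, prev = hist[-1], hist[-2]
        resid = np.max(np.abs(last - prev)) / np.max(np.abs(last))
        assert resid < seq40.convergence_tol * 10

    def test_transient_fit_recovers_apparent_relaxation_within_1pct(self):
        tissue = SinglePoolTissue(1000.0, 100.0)
        _, hist = simulate_single_pool(tissue, LONG_SEQ, signed=True, keep_history=True)
        first = hist[0]  # transient from thermal equilibrium
        t = LONG_SEQ.tr_ms / 2.0 + np.arange(len(first)) * LONG_SEQ.tr_ms + LONG_SEQ.te_ms
        s = first * np.sign(first[-1])
        p, _ = curve_fit(
            lambda t, a, b, tau: a - b * np.exp(-t / tau), t, s, p0=(s[-1], 2 * s[-1], 500.0)
        )
        assert p[2] == pytest.approx(apparent_relaxation(tissue, LONG_SEQ), rel=0.01)

    def test_zero_crossing_frame_monotone_in_t1(self, seq40):
        mins = []
        for t1 in np.arange(600.0, 3001.0, 300.0):
            c = simulate_single_pool(SinglePoolTissue(t1, 80.0), seq40)
            mins.append(np.argmin(frame_average(c, 20).values))
        assert np.all(np.diff(mins) >= 0)

    def test_nonconvergence_raises_with_residual(self):
        seq = SequenceParams(tinv_ms=1000.0, n_cycles_max=2, convergence_tol=1e-12)
        with pytest.raises(ConvergenceError) as exc:
            simulate_single_pool(SinglePoolTissue(4000.0, 1800.0), seq)
        assert exc.value.residual > 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(pd=st.floats(0.1, 10.0))
    def test_signal_linear_in_proton_density(self, pd):
        seq = SequenceParams(tinv_ms=1000.0, n_cycles_max=60)
        base = simulate_single_pool(SinglePoolTissue(900.0, 90.0, 1.0), seq)
        scaled = simulate_single_pool(SinglePoolTissue(900.0, 90.0, pd), seq)
        np.testing.assert_allclose(scaled.values, pd * base.values, rtol=1e-9, atol=1e-12)


class TestApparentRelaxation:
    def test_formula_value(self):
        # 1/(cos^2(15 deg)/1000 + sin^2(15 deg)/100) ~ 624 ms
        t1s = apparent_relaxation(SinglePoolTissue(1000.0, 100.0), SequenceParams())
        assert t1s == pytest.approx(623.87, rel=1e-3)

    def test_small_angle_limit_is_t1(self):
        seq = SequenceParams(flip_angle_deg=0.01)
        assert apparent_relaxation(SinglePoolTissue(1000.0, 100.0), seq) == pytest.approx(
            1000.0, rel=1e-4
        )

    def test_large_angle_moves_toward_t2(self):
        t1s = apparent_relaxation(SinglePoolTissue(1000.0, 100.0), SequenceParams(flip_angle_deg=90.0))
        assert 100.0 < t1s < 200.0


class TestFrameAverage:
    def test_constant_train_is_constant(self):
        c = SignalCurve(np.arange(1, 101, dtype=float), np.full(100, 3.3))
        f = frame_average(c, 20)
        assert len(f) == 20
        np.testing.assert_allclose(f.values, 3.3)

    def test_temporal_footprint_150ms(self, seq40):
        c = simulate_single_pool(SinglePoolTissue(1000.0, 100.0), seq40)
        f = frame_average(c, 20)
        # T_inv = 3 s split into 20 frames -> 150 ms windows
        assert np.allclose(np.diff(f.ti_ms), 150.0)

    def test_linear_ramp_recovers_window_means(self):
        n = 100
        ti = np.arange(1, n + 1, dtype=float)
        c = SignalCurve(ti, 2.0 * ti)  # value = 2 t
        f = frame_average(c, 10)
        # analytic mean of the ramp over each 10-echo window
        expected = [2.0 * ti[k * 10 : (k + 1) * 10].mean() for k in range(10)]
        np.testing.assert_allclose(f.values, expected)

    def test_too_many_frames_rejected(self):
        c = SignalCurve(np.arange(1.0, 11.0), np.ones(10))
        with pytest.raises(ValueError, match="exceeds"):
            frame_average(c, 11)


class TestTwoPool:
    def test_degenerate_two_pool_equals_single_pool(self, seq40):
        single = simulate_single_pool(SinglePoolTissue(1000.0, 100.0), seq40)
        two = simulate_two_pool(
            TwoPoolTissue(1000.0, 100.0, mf=0.0, k_exchange_per_s=0.0), seq40
        )
        scale = single.values.max()
        np.testing.assert_allclose(two.values / scale, single.values / scale, atol=1e-6)

    def test_macromolecular_fraction_suppresses_late_signal(self, seq40):
        late = []
        for mf in np.arange(0.0, 0.31, 0.05):
            c = frame_average(
                simulate_two_pool(TwoPoolTissue(1000.0, 100.0, mf), seq40, signed=True), 20
            )
            late.append(abs(c.values[-1]))
        assert np.all(np.diff(late) <= 0)

    def test_mf_changes_normalized_curve_shape(self, seq40):
        curves = []
        for mf in (0.05, 0.15):
            c = np.abs(
                frame_average(
                    simulate_two_pool(TwoPoolTissue(1000.0, 100.0, mf), seq40, signed=True), 20
                ).values
            )
            curves.append(c / np.linalg.norm(c))
        assert curves[0] @ curves[1] < 1.0 - 1e-4
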