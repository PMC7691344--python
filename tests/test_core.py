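"""Per-window index formulas: examples, closed forms, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ripwob.core import (
    AnalysisWindow,
    RipRecording,
    SynchronyThresholds,
    classify_synchrony,
    excursion,
    lbi,
    phase_angle,
    rc_percent,
)
from ripwob.errors import DegenerateWindowError

from conftest import (
    lagged_pair,
    lbi_oracle,
    phase_oracle_deg,
    rc_percent_oracle,
    sine_window,
)

window_channels = arrays(
    np.float64,
    20,
    elements=st.floats(-100, 100, allow_nan=False, allow_infinity=False),
)


def _nondegenerate(x):
    return np.ptp(x) > 1e-3 and np.ptp(np.diff(x)) > 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestRecordingInvariants:
    def test_rejects_channel_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            RipRecording("r", 10.0, np.zeros(5), np.zeros(4))

    @pytest.mark.parametrize("bad_fs", [0.0, -1.0, math.inf, math.nan])
    def test_rejects_bad_sampling_rate(self, bad_fs):
        with pytest.raises(ValueError):
            RipRecording("r", bad_fs, np.zeros(5), np.zeros(5))

    def test_rejects_nonfinite_samples(self):
        rc = np.array([0.0, 1.0, np.nan, 0.0])
        with pytest.raises(ValueError, match="non-finite"):
            RipRecording("r", 10.0, rc, np.zeros(4))

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match="at least 2"):
            RipRecording("r", 10.0, np.zeros(1), np.zeros(1))


class TestAnalysisWindow:
    def test_rejects_below_minimum_length(self):
        with pytest.raises(ValueError, match="below minimum"):
            AnalysisWindow(np.zeros(3), np.zeros(3))

    def test_from_recording_right_aligned(self):
        rec = RipRecording("r", 10.0, np.arange(30.0), np.arange(30.0) * 2)
        w = AnalysisWindow.from_recording(rec, t_index=24, n=20)
        assert w.n == 20
        assert w.rc_w[0] == 5.0 and w.rc_w[-1] == 24.0

    def test_from_recording_out_of_bounds(self):
        rec = RipRecording("r", 10.0, np.arange(30.0), np.arange(30.0))
        with pytest.raises(ValueError, match="out of bounds"):
            AnalysisWindow.from_recording(rec, t_index=10, n=20)


# ---------------------------------------------------------------------------
# RC percent
# ---------------------------------------------------------------------------


class TestRcPercent:
    def test_equal_amplitude_sinusoids_give_fifty(self):
        w = lagged_pair(n=2000, periods=2.0, lag_deg=40.0)
        assert rc_percent(w) == pytest.approx(50.0, abs=0.02)

    def test_three_to_one_triangle_waves(self):
        tri = np.abs(np.arange(20.0) % 10 - 5)
        w = AnalysisWindow(3.0 * tri, np.roll(tri, 3))
        assert rc_percent(w) == pytest.approx(75.0, abs=1e-9)

    def test_scaled_sinusoid_ratio(self):
        # same waveform scaled 1.38 vs 1.0 -> 100 * 1.38/2.38
        s = sine_window(20, phase_deg=-40.0)
        w = AnalysisWindow(1.38 * s, s)
        assert rc_percent(w) == pytest.approx(57.98, abs=0.01)

    def test_flat_window_is_degenerate(self):
        w = AnalysisWindow(np.full(20, 3.0), np.full(20, -1.0))
        with pytest.raises(DegenerateWindowError, match="flat"):
            rc_percent(w)

    @given(x=window_channels, y=window_channels)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_complements_sum_to_hundred(self, x, y):
        if not (_nondegenerate(x) and _nondegenerate(y)):
            return
        w = AnalysisWindow(x, y)
        w_swapped = AnalysisWindow(y, x)
        assert rc_percent(w) + rc_percent(w_swapped) == pytest.approx(100.0, abs=1e-9)
        assert 0.0 <= rc_percent(w) <= 100.0


# ---------------------------------------------------------------------------
# phase angle
# ---------------------------------------------------------------------------


class TestPhaseAngle:
    def test_identical_signals_perfect_synchrony(self):
        x = sine_window(20)
        assert phase_angle(AnalysisWindow(x, x.copy())) == pytest.approx(0.0, abs=1e-9)

    def test_negated_signal_paradoxical(self):
        x = sine_window(20)
        assert phase_angle(AnalysisWindow(x, -x)) == pytest.approx(180.0, abs=1e-9)

    def test_sixty_degree_lag_over_full_period(self):
        # full-period orthogonality makes the cosine similarity exactly cos 60
        w = lagged_pair(n=20, lag_deg=60.0)
        assert phase_angle(w) == pytest.approx(60.0, abs=1e-6)

    @pytest.mark.parametrize("lag", range(0, 181, 15))
    def test_recovers_imposed_lag_on_grid(self, lag):
        w = lagged_pair(n=20, lag_deg=float(lag))
        assert phase_angle(w) == pytest.approx(float(lag), abs=0.1)
        assert phase_angle(w) == pytest.approx(phase_oracle_deg(w.rc_w, w.ab_w), abs=1e-9)

    def test_zero_variance_channel_is_degenerate(self):
        with pytest.raises(DegenerateWindowError, match="zero-variance"):
            phase_angle(AnalysisWindow(sine_window(20), np.full(20, 2.0)))

    def test_clamps_rounding_to_valid_arccos_domain(self):
        # near-exact anti-correlation can push the cosine below -1 by rounding
        x = np.array([1e-8 * (-1) ** i for i in range(20)])
        assert 0.0 <= phase_angle(AnalysisWindow(x, -x)) <= 180.0

    @given(
        x=window_channels,
        y=window_channels,
        a=st.floats(0.01, 100),
        b=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_positive_scaling_invariance(self, x, y, a, b):
        if np.ptp(x) < 1e-3 or np.ptp(y) < 1e-3:
            return
        forward = phase_angle(AnalysisWindow(x, y))
        assert phase_angle(AnalysisWindow(y, x)) == pytest.approx(forward, abs=1e-9)
        # arccos amplifies rounding near perfect (anti)correlation: a cosine
        # perturbation eps maps to an angle ~sqrt(2*eps), so 1e-4 deg is the
        # honest tolerance for scale-invariance at float64
        assert phase_angle(AnalysisWindow(a * x, b * y)) == pytest.approx(
            forward, abs=1e-4
        )
        assert 0.0 <= forward <= 180.0


# ---------------------------------------------------------------------------
# labored breathing index
# ---------------------------------------------------------------------------


class TestLbi:
    def test_in_phase_equal_sinusoids_unity(self):
        x = sine_window(20)
        assert lbi(AnalysisWindow(x, x.copy())) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "lag,expected,tol",
        [(60.0, 1.1547, 0.001), (120.0, 2.0, 0.005)],
    )
    def test_dense_sampling_matches_continuous_limit(self, lag, expected, tol):
        # 1/cos(theta/2) in the continuous limit; two whole periods at
        # 400 samples/period
        w = lagged_pair(n=800, periods=2.0, lag_deg=lag)
        assert lbi(w) == pytest.approx(expected, abs=tol)

    def test_dense_sweep_monotone_and_matches_closed_form(self):
        values = []
        for lag in range(10, 151, 10):
            w = lagged_pair(n=800, periods=2.0, lag_deg=float(lag))
            v = lbi(w)
            expected = 1.0 / math.cos(math.radians(lag / 2))
            assert v == pytest.approx(expected, rel=0.005)
            values.append(v)
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_total_paradox_degenerate_denominator(self):
        x = sine_window(20)
        with pytest.raises(DegenerateWindowError, match="tidal"):
            lbi(AnalysisWindow(x, -x))

    def test_matches_brute_force_oracle_on_random_windows(self, rng):
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            w = AnalysisWindow(x, y)
            assert lbi(w) == pytest.approx(lbi_oracle(x, y), abs=1e-9)
            assert rc_percent(w) == pytest.approx(rc_percent_oracle(x, y), abs=1e-9)

    @given(
        x=window_channels,
        y=window_channels,
        slope=st.floats(-10, 10),
        intercept=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariance_under_common_trend_and_scaling(
        self, x, y, slope, intercept, scale
    ):
        if not (_nondegenerate(x) and _nondegenerate(y)):
            return
        trend = intercept + slope * np.arange(20.0)
        w = AnalysisWindow(x, y)
        w_trended = AnalysisWindow(x + trend, y + trend)
        w_scaled = AnalysisWindow(scale * x, scale * y)
        try:
            base = lbi(w)
        except DegenerateWindowError:
            return
        assert lbi(w_trended) == pytest.approx(base, rel=1e-6)
        assert lbi(w_scaled) == pytest.approx(base, rel=1e-6)
        assert rc_percent(w_trended) == pytest.approx(rc_percent(w), abs=1e-6)
        assert base >= 1.0 - 1e-9

    def test_excursion_is_peak_to_peak_of_detrended_window(self):
        # pure drift vanishes; drift on top of a wave leaves the wave
        assert excursion(2.0 + 0.5 * np.arange(20.0)) == pytest.approx(0.0, abs=1e-12)
        wave = sine_window(20)
        assert excursion(wave + 0.3 * np.arange(20.0)) == pytest.approx(
            excursion(wave), abs=1e-9
        )


# ---------------------------------------------------------------------------
# synchrony classification
# ---------------------------------------------------------------------------


class TestClassifySynchrony:
    @pytest.mark.parametrize(
        "phase,lbi_v,expected",
        [
            (8.94, 1.04, "synchronous"),  # healthy cohort means
            (180.0, 1.2, "paradoxical"),
            (180.0, 5.0, "paradoxical"),
            (45.0, 1.2, "asynchronous"),
            (10.0, 1.2, "asynchronous"),  # low phase but elevated effort
            (29.99, 1.0499, "synchronous"),
            (150.0, 1.0, "paradoxical"),  # boundary inclusive
        ],
    )
    def test_default_thresholds(self, phase, lbi_v, expected):
        assert classify_synchrony(phase, lbi_v).label == expected

    def test_configurable_thresholds(self):
        strict = SynchronyThresholds(phase_sync_deg=10.0, lbi_sync=1.02, phase_paradox_deg=170.0)
        assert classify_synchrony(15.0, 1.01, strict).label == "asynchronous"
        assert classify_synchrony(160.0, 2.0, strict).label == "asynchronous"

    @pytest.mark.parametrize("phase,lbi_v", [(-1.0, 1.0), (181.0, 1.0), (30.0, 0.5)])
    def test_out_of_range_inputs_rejected(self, phase, lbi_v):
        with pytest.raises(ValueError):
            classify_synchrony(phase, lbi_v)
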