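import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stridekit import (
    FilterSpec,
    InvalidInputError,
    InvalidParameterError,
    UniformSignal,
    apply_butterworth,
    half_wave_rectify,
    moving_average,
    upsample_linear,
)
from stridekit.signal_core import frequency_response


def sig(values, fs=100.0, **kw):
    return UniformSignal(np.asarray(values, dtype=float), fs, **kw)


finite_arrays = hnp.arrays(
    np.float64,
    st.integers(min_value=30, max_value=200),
    elements=st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
)


class TestUniformSignal:
    def test_rejects_nan(self):
        with pytest.raises(InvalidInputError):
            sig([1.0, np.nan])

    def test_rejects_bad_rate(self):
        with pytest.raises(InvalidParameterError):
            sig([1.0], fs=0)

    def test_duration(self):
        assert sig(np.zeros(61), fs=60).duration == pytest.approx(1.0)

    def test_crop_bounds_checked(self):
        with pytest.raises(InvalidInputError):
            sig([1, 2, 3]).crop(1, 5)


class TestMovingAverage:
    @pytest.mark.parametrize(
        "values,window,expected",
        [
            ([5, 5, 5, 5], 3, [5, 5, 5, 5]),
            ([1, 2, 3], 1, [1, 2, 3]),
            ([0, 0, 3, 0, 0], 3, [0, 1, 1, 1, 0]),
        ],
    )
    def test_examples(self, values, window, expected):
        out = moving_average(sig(values), window)
        np.testing.assert_allclose(out.values, expected)

    def test_edges_truncate_to_available_samples(self):
        out = moving_average(sig([2, 4, 6, 8]), 3)
        # first window covers only two samples: mean(2, 4) = 3
        assert out.values[0] == pytest.approx(3.0)
        assert out.values[-1] == pytest.approx(7.0)

    @pytest.mark.parametrize("window", [0, 2, -1])
    def test_rejects_even_or_nonpositive_window(self, window):
        with pytest.raises(InvalidParameterError):
            moving_average(sig([1, 2, 3]), window)

    def test_rejects_window_longer_than_signal(self):
        with pytest.raises(InvalidParameterError):
            moving_average(sig([1, 2]), 3)

    def test_preserves_length_and_rate(self):
        out = moving_average(sig(np.arange(10), fs=60), 5)
        assert len(out) == 10 and out.fs == 60


class TestUpsampleLinear:
    def test_midpoint_of_line(self):
        out = upsample_linear(sig([0, 2], fs=1), 3)
        np.testing.assert_allclose(out.values, [0, 1, 2])
        assert out.fs == pytest.approx(2.0)

    def test_identity_at_same_length(self):
        s = sig([1.0, 4.0, 2.0])
        assert upsample_linear(s, 3) is s

    def test_rejects_downsampling(self):
        with pytest.raises(InvalidParameterError):
            upsample_linear(sig([1, 2, 3]), 2)

    def test_imu_to_emg_timeline(self):
        # one second of a 60 Hz ramp onto the 1000 Hz companion timeline
        s = sig(np.linspace(0, 60, 61), fs=60)
        out = upsample_linear(s, 1001)
        assert out.values[0] == 0.0 and out.values[-1] == 60.0
        assert np.all(out.values[1:-1] > 0) and np.all(out.values[1:-1] < 60)
        assert out.fs == pytest.approx(1000.0)

    @given(finite_arrays)
    @settings(deadline=None, max_examples=50)
    def test_interpolation_reproduces_input_samples(self, values):
        """Sampling the upsampled signal back at input times is exact."""
        s = sig(values, fs=10)
        factor = 3
        out = upsample_linear(s, factor * (len(s) - 1) + 1)
        np.testing.assert_allclose(out.values[::factor], values, rtol=0, atol=1e-9)


class TestApplyButterworth:
    def test_dc_passes_lowpass(self):
        s = sig(np.full(500, 3.7), fs=100)
        out = apply_butterworth(s, FilterSpec("lowpass", 4, (10.0,)))
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-6)

    def test_dc_rejected_by_highpass(self):
        s = sig(np.full(500, 3.7), fs=100)
        out = apply_butterworth(s, FilterSpec("highpass", 4, (10.0,)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-6)

    def test_zero_phase_impulse_is_symmetric(self):
        x = np.zeros(401)
        x[200] = 1.0
        out = apply_butterworth(sig(x), FilterSpec("lowpass", 4, (10.0,)))
        np.testing.assert_allclose(out.values, out.values[::-1], atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            apply_butterworth(sig(np.zeros(100)), FilterSpec("lowpass", 4, (60.0,)))

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            apply_butterworth(sig(np.zeros(10)), FilterSpec("lowpass", 7, (10.0,)))

    @given(
        hnp.arrays(
            np.float64,
            st.integers(min_value=150, max_value=400),
            elements=st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
        )
    )
    @settings(deadline=None, max_examples=30)
    def test_time_reversal_symmetry(self, values):
        """Zero-phase filtering commutes with time reversal away from the
        edge-transient region (edges depend on pad initialization)."""
        spec = FilterSpec("lowpass", 4, (10.0,))
        fwd = apply_butterworth(sig(values), spec).values
        rev = apply_butterworth(sig(values[::-1]), spec).values[::-1]
        trim = 60  # > several filter time constants at this cutoff
        np.testing.assert_allclose(
            fwd[trim:-trim], rev[trim:-trim],
            atol=1e-6 * max(1.0, np.abs(values).max()),
        )

    def test_linearity(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(300), rng.standard_normal(300)
        spec = FilterSpec("bandpass", 4, (5.0, 20.0))
        lhs = apply_butterworth(sig(2.5 * x - 1.5 * y), spec).values
        rhs = (
            2.5 * apply_butterworth(sig(x), spec).values
            - 1.5 * apply_butterworth(sig(y), spec).values
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-8, atol=1e-8)


class TestDesignedResponses:
    """-3 dB points of the single-pass designs, checked from coefficients."""

    @pytest.mark.parametrize(
        "spec,fs,cutoffs",
        [
            (FilterSpec("bandpass", 4, (10.0, 150.0)), 1000.0, (10.0, 150.0)),
            (FilterSpec("highpass", 7, (9.0,)), 1000.0, (9.0,)),
            (FilterSpec("lowpass", 7, (6.0,)), 1000.0, (6.0,)),
        ],
    )
    def test_minus_3db_at_stated_cutoffs(self, spec, fs, cutoffs):
        freqs, mag = frequency_response(spec, fs, np.asarray(cutoffs))
        db = 20 * np.log10(mag)
        np.testing.assert_allclose(db, -3.0103, atol=0.1)

    def test_notch_minimum_at_center(self):
        grid = np.linspace(1.0, 200.0, 20000)
        _, mag = frequency_response(FilterSpec("notch", 2, (60.0,), q=30.0), 1000.0, grid)
        assert grid[np.argmin(mag)] == pytest.approx(60.0, rel=0.01)


class TestHalfWaveRectify:
    def test_definition(self):
        out = half_wave_rectify(sig([1, -1, 2, -3]))
        np.testing.assert_allclose(out.values, [1, 0, 2, 0])

    def test_identity_on_nonnegative(self):
        s = sig([0, 1, 2])
        np.testing.assert_allclose(half_wave_rectify(s).values, s.values)

    def test_rectified_sine_mean(self):
        """Mean of a half-wave rectified sine is amplitude/pi."""
        fs, f, amp, n_cycles = 1000.0, 2.0, 3.0, 1200
        t = np.arange(int(n_cycles * fs / f)) / fs
        out = half_wave_rectify(sig(amp * np.sin(2 * np.pi * f * t), fs=fs))
        assert out.values.mean() == pytest.approx(amp / np.pi, rel=0.01)
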