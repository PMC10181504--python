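import numpy as np
import pytest

from stridekit import (
    EmgRecording,
    GaitCycle,
    InvalidInputError,
    InvalidParameterError,
    UniformSignal,
    cut_by_interval,
    preprocess_emg,
    segment_by_cycles,
    summarize_cycles,
    time_normalize,
)
from stridekit.activity import HalfTrial
from stridekit.emg import MUSCLES


def recording(values_per_muscle, fs=1000.0):
    return EmgRecording(
        {m: UniformSignal(np.asarray(v, dtype=float), fs, m)
         for m, v in values_per_muscle.items()}
    )


def tone_recording(freq_hz, n=10000, fs=1000.0):
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq_hz * t)
    return recording({m: x for m in MUSCLES}, fs)


def rms(x):
    return np.sqrt(np.mean(x**2))


class TestPreprocess:
    def test_mains_tone_suppressed(self):
        raw = tone_recording(60.0)
        out = preprocess_emg(raw)
        for m in MUSCLES:
            assert rms(out.channels[m].values) <= 0.1 * rms(raw.channels[m].values)

    def test_drift_attenuated_20db(self):
        raw = tone_recording(2.0)
        out = preprocess_emg(raw)
        ratio = rms(out.channels["TA"].values) / rms(raw.channels["TA"].values)
        assert 20 * np.log10(ratio) <= -20.0

    def test_passband_tone_preserved(self):
        raw = tone_recording(100.0)
        out = preprocess_emg(raw)
        assert rms(out.channels["TA"].values) == pytest.approx(
            rms(raw.channels["TA"].values), rel=0.1
        )

    def test_length_preserved(self):
        raw = tone_recording(40.0, n=4321)
        out = preprocess_emg(raw)
        assert out.n_samples == 4321

    def test_low_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            preprocess_emg(tone_recording(10.0, fs=250.0))


class TestCutByInterval:
    def test_full_range_identity(self):
        rec = tone_recording(50.0, n=2000)
        out = cut_by_interval(rec, HalfTrial(0, 2000))
        np.testing.assert_array_equal(
            out.channels["TA"].values, rec.channels["TA"].values
        )

    def test_index_arithmetic(self):
        rec = tone_recording(50.0, n=5000)
        out = cut_by_interval(rec, HalfTrial(1000, 3000))
        assert out.n_samples == 2000
        assert out.channels["TA"].t0 == pytest.approx(1.0)

    def test_crop_composition(self):
        rec = tone_recording(50.0, n=5000)
        once = cut_by_interval(rec, HalfTrial(1000, 3000))
        twice = cut_by_interval(once, HalfTrial(0, 2000))
        np.testing.assert_array_equal(
            once.channels["TA"].values, twice.channels["TA"].values
        )

    def test_out_of_bounds_rejected(self):
        with pytest.raises(InvalidInputError):
            cut_by_interval(tone_recording(50.0, n=100), HalfTrial(50, 200))


class TestSegmentByCycles:
    def test_one_crop_per_cycle(self):
        rec = tone_recording(50.0, n=13000)
        cycles = [GaitCycle(k * 1.0, (k + 1) * 1.0, "LGW", k) for k in range(12)]
        crops = segment_by_cycles(rec, cycles)
        assert len(crops) == 12
        assert all(c.n_samples == 1000 for c in crops)

    def test_empty_cycle_list(self):
        assert segment_by_cycles(tone_recording(50.0, n=100), []) == []

    def test_adjacent_crops_share_boundary_index(self):
        rec = tone_recording(50.0, n=5000)
        cycles = [GaitCycle(0.5, 1.7), GaitCycle(1.7, 3.1)]
        a, b = segment_by_cycles(rec, cycles)
        assert a.channels["TA"].t0 + a.n_samples / rec.fs == pytest.approx(
            b.channels["TA"].t0
        )

    def test_out_of_bounds_cycle_skipped(self, caplog):
        rec = tone_recording(50.0, n=1000)
        cycles = [GaitCycle(0.0, 0.5), GaitCycle(0.5, 5.0)]
        with caplog.at_level("WARNING"):
            crops = segment_by_cycles(rec, cycles)
        assert len(crops) == 1

    def test_cycle_crops_tile_the_segment(self, default_result):
        """Per-cycle crops cover [first HS, last HS) with no overlap."""
        for series, crops in zip(default_result.events, default_result.cycles):
            if len(series) < 2:
                continue
            spans = [(c.start_s, c.end_s) for c in crops]
            assert spans[0][0] == series.times_s[0]
            assert spans[-1][1] == series.times_s[-1]
            for (_, end), (start, _) in zip(spans, spans[1:]):
                assert end == start


class TestTimeNormalize:
    def test_values_preserved_at_matching_length(self):
        x = np.sin(np.linspace(0, 3, 101))
        crop = recording({"TA": x})
        out = time_normalize([crop], n_norm=101)
        np.testing.assert_allclose(out.data["TA"][0], x, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        crop = recording({"TA": np.linspace(0, 5, 773)})
        out = time_normalize([crop], n_norm=101)
        np.testing.assert_allclose(out.data["TA"][0], np.linspace(0, 5, 101), atol=1e-9)

    def test_shared_template_different_lengths(self):
        """Two cycles sampling the same waveform at different durations
        normalize to near-identical rows."""
        template = lambda phase: np.sin(2 * np.pi * phase) + 0.5 * phase
        rows = []
        for n in (600, 900):
            phase = np.linspace(0, 1, n)
            crop = recording({"TA": template(phase)})
            rows.append(time_normalize([crop], n_norm=101).data["TA"][0])
        np.testing.assert_allclose(rows[0], rows[1], atol=1e-3)

    def test_short_crop_skipped(self, caplog):
        good = recording({"TA": np.arange(50.0)})
        bad = recording({"TA": np.array([1.0])})
        with caplog.at_level("WARNING"):
            out = time_normalize([good, bad], n_norm=11)
        assert out.data["TA"].shape == (1, 11)


class TestSummarize:
    def test_identical_rows_zero_sd(self):
        crop = recording({"TA": np.ones(101)})
        matrix = time_normalize([crop, crop, crop], n_norm=101)
        summary = summarize_cycles(matrix)
        np.testing.assert_allclose(summary["sd"], 0.0, atol=1e-12)

    def test_two_point_sample_sd(self):
        rows = [recording({"TA": np.zeros(101)}), recording({"TA": np.full(101, 2.0)})]
        summary = summarize_cycles(time_normalize(rows, n_norm=101))
        np.testing.assert_allclose(summary["mean"], 1.0)
        np.testing.assert_allclose(summary["sd"], np.sqrt(2.0))

    def test_single_row_flagged(self):
        summary = summarize_cycles(time_normalize([recording({"TA": np.arange(50.0)})]))
        assert not summary["sd_defined"].any()
        np.testing.assert_allclose(summary["sd"], 0.0)

    def test_mean_is_permutation_invariant(self):
        rng = np.random.default_rng(5)
        crops = [recording({"TA": rng.standard_normal(80)}) for _ in range(5)]
        a = summarize_cycles(time_normalize(crops, n_norm=51))
        b = summarize_cycles(time_normalize(crops[::-1], n_norm=51))
        np.testing.assert_allclose(a["mean"], b["mean"], atol=1e-12)

    def test_mean_recovers_template_under_noise(self):
        """Pointwise mean converges on the shared template (CLT bound)."""
        rng = np.random.default_rng(42)
        sigma, n_rows = 0.2, 64
        template = np.sin(np.linspace(0, 2 * np.pi, 101))
        crops = [
            recording({"TA": template + rng.normal(0, sigma, 101)})
            for _ in range(n_rows)
        ]
        summary = summarize_cycles(time_normalize(crops, n_norm=101))
        np.testing.assert_array_less(
            np.abs(summary["mean"] - template), 3 * sigma / np.sqrt(n_rows) + 1e-12
        )
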