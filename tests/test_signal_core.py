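"""Recording I/O, tilt realignment and zero-phase low-pass filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneegait.errors import (
    FormatError,
    InputError,
    OrientationError,
    ParameterError,
    ParseError,
)
from kneegait.signal_core import (
    AccelerometerRecording,
    lowpass_filter,
    read_recording,
    realign_to_horizontal_vertical,
    write_recording,
)


def make_static(vec, n=128, fs=32.0):
    return AccelerometerRecording(np.tile(np.asarray(vec, float), (n, 1)), sampling_rate=fs)


def write_csv(tmp_path, df, name="rec.csv"):
    p = tmp_path / name
    df.to_csv(p, index=False)
    return p


class TestReadRecording:
    def test_sixty_seconds_at_32hz_gives_1920_samples(self, tmp_path):
        n = 60 * 32
        df = pd.DataFrame(
            {"time": np.arange(n) / 32.0, "ax": 0.0, "ay": 0.0, "az": np.ones(n)}
        )
        rec = read_recording(write_csv(tmp_path, df))
        assert len(rec) == 1920
        assert rec.sampling_rate == 32.0

    def test_missing_axis_column_is_a_format_error(self, tmp_path):
        df = pd.DataFrame({"ax": [0.0, 0.0], "ay": [0.0, 0.0]})
        with pytest.raises(FormatError):
            read_recording(write_csv(tmp_path, df))

    def test_length_and_rate_preserved(self, tmp_path):
        df = pd.DataFrame({"ax": np.zeros(77), "ay": np.zeros(77), "az": np.ones(77)})
        rec = read_recording(write_csv(tmp_path, df), sampling_rate=50.0)
        assert len(rec) == 77 and rec.sampling_rate == 50.0

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ax,ay,az\n0,0,1\n0,oops,1\n")
        with pytest.raises(ParseError) as exc:
            read_recording(p)
        assert exc.value.row == 1

    def test_fewer_than_two_rows_is_an_input_error(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("ax,ay,az\n0,0,1\n")
        with pytest.raises(InputError):
            read_recording(p)

    def test_nonuniform_time_column_rejected(self, tmp_path):
        df = pd.DataFrame({"time": [0.0, 0.1, 0.15], "ax": 0.0, "ay": 0.0, "az": [1.0] * 3})
        with pytest.raises(FormatError):
            read_recording(write_csv(tmp_path, df))

    def test_write_read_roundtrip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(42)
        rec = AccelerometerRecording(rng.normal(0, 0.3, (64, 3)) + [0, 0, 1.0])
        p = tmp_path / "rt.csv"
        write_recording(rec, p)
        back = read_recording(p)
        np.testing.assert_array_equal(back.samples, rec.samples)

    def test_sensor_sourced_range_check(self):
        bad = np.zeros((10, 3))
        bad[3, 1] = 9.5
        with pytest.raises(InputError):
            AccelerometerRecording(bad, sensor_sourced=True)


class TestRealign:
    def test_already_aligned_static_recording_gives_zero_series(self):
        cor = realign_to_horizontal_vertical(make_static([0.0, 0.0, 1.0]))
        assert np.allclose(cor.vertical, 0.0, atol=1e-12)
        assert np.allclose(cor.horizontal_ap, 0.0, atol=1e-12)
        assert np.allclose(cor.horizontal_ml, 0.0, atol=1e-12)

    def test_ten_degree_tilt_recovers_full_gravity_on_vertical(self):
        # constant gravity tilted 10 degrees in the x-z plane: after the
        # two-rotation realignment the vertical carries the full 1 g (0 after
        # gravity removal) and the horizontals are empty
        th = np.deg2rad(10.0)
        rec = make_static([np.sin(th), 0.0, np.cos(th)])
        cor = realign_to_horizontal_vertical(rec)
        assert cor.gravity_g == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(cor.vertical, 0.0, atol=1e-9)
        assert np.allclose(cor.horizontal_ap, 0.0, atol=1e-9)

    def test_zero_mean_postconditions_on_walking_signal(self):
        from kneegait.simulate import WalkSimulationSpec, simulate_walk

        rec, _ = simulate_walk(WalkSimulationSpec(seed=3))
        cor = realign_to_horizontal_vertical(rec)
        assert abs(cor.vertical.mean()) < 1e-6
        assert abs(cor.horizontal_ap.mean()) < 1e-6
        assert abs(cor.horizontal_ml.mean()) < 1e-6

    def test_rotation_preserves_per_sample_norms(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0, 0.2, (128, 3)) + [0.1, 0.05, 0.95]
        rec = AccelerometerRecording(samples)
        cor = realign_to_horizontal_vertical(rec)
        rotated = samples @ cor.rotation.T  # pre-gravity-subtraction triple
        np.testing.assert_allclose(
            np.linalg.norm(rotated, axis=1), np.linalg.norm(samples, axis=1), atol=1e-9
        )

    def test_inverse_rotation_reproduces_raw_signal(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(0, 0.1, (256, 3)) + [0.2, -0.1, 0.9]
        rec = AccelerometerRecording(samples)
        cor = realign_to_horizontal_vertical(rec)
        np.testing.assert_allclose(cor.inverse(), samples, atol=1e-9)

    @pytest.mark.parametrize("vec", [[0.0, 0.0, 0.2], [0.0, 0.0, 1.8]])
    def test_non_gravity_reference_rejected(self, vec):
        with pytest.raises(OrientationError):
            realign_to_horizontal_vertical(make_static(vec))

    def test_too_short_recording_rejected(self):
        rec = AccelerometerRecording(np.tile([0.0, 0.0, 1.0], (32, 1)))  # 1 s at 32 Hz
        with pytest.raises(InputError):
            realign_to_horizontal_vertical(rec)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_roundtrip_property_random_recordings(self, seed):
        rng = np.random.default_rng(seed)
        samples = rng.normal(0, 0.15, (96, 3)) + [0.0, 0.0, 1.0]
        cor = realign_to_horizontal_vertical(AccelerometerRecording(samples))
        np.testing.assert_allclose(cor.inverse(), samples, atol=1e-9)


class TestLowpass:
    def test_dc_gain_is_one(self):
        x = np.full(256, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, 32.0), x, atol=1e-9)

    def test_tone_attenuated_by_squared_butterworth_response(self):
        # 10 Hz tone with a 2 Hz cutoff at 64 Hz sampling: forward-backward
        # filtering attenuates by the squared Butterworth magnitude response
        # |H(f)|^2 = 1 / (1 + (W(f)/W(fc))^(2*order)) with the bilinear
        # prewarped frequency W(f) = tan(pi f / fs)
        fs, f0, fc, order = 64.0, 10.0, 2.0, 4
        t = np.arange(int(fs * 30)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = lowpass_filter(x, fs, order=order, cutoff=fc)
        ratio = np.tan(np.pi * f0 / fs) / np.tan(np.pi * fc / fs)
        expected = 1.0 / (1.0 + ratio ** (2 * order))
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        # amplitude at f0 via complex projection (robust at -110 dB)
        measured = 2 * np.abs(np.sum(y[mid] * np.exp(-2j * np.pi * f0 * t[mid]))) / len(y[mid])
        assert measured == pytest.approx(expected, rel=0.05)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_filter(np.zeros(64), 32.0, cutoff=16.0)

    def test_near_nyquist_cutoff_warns_but_runs(self):
        with pytest.warns(UserWarning):
            lowpass_filter(np.random.default_rng(0).normal(size=64), 32.0, cutoff=15.0)

    def test_passband_idempotence_on_bandlimited_signal(self):
        # content at <= 1 Hz passes a 15 Hz filter essentially unchanged
        fs = 32.0
        t = np.arange(int(fs * 20)) / fs
        x = 0.2 * np.sin(2 * np.pi * 0.8 * t) + 0.05 * np.sin(2 * np.pi * 0.3 * t)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            y = lowpass_filter(x, fs)
        assert np.max(np.abs(y - x)) < 1e-3

    def test_zero_phase_no_timing_shift(self):
        fs = 32.0
        t = np.arange(int(fs * 20)) / fs
        x = np.sin(2 * np.pi * 1.5 * t)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            y = lowpass_filter(x, fs)
        mid = slice(100, -100)
        lag = np.argmax(np.correlate(y[mid], x[mid], "full")) - (len(x[mid]) - 1)
        assert lag == 0
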