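"""Preprocessing chain: per-stage contracts, arithmetic and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegtext.preprocessing import (
    DEFAULT_MONTAGE,
    ChannelNotFoundError,
    EEGRecording,
    PreprocessConfig,
    RecordingTooShortError,
    clip_amplitude,
    crop_recording,
    expected_window_count,
    extract_windows,
    normalize_channel_name,
    preprocess,
    resample_to,
    scale_amplitude,
    select_channels,
)
from conftest import make_recording


class TestChannelSelection:
    def test_montage_subset_from_32_channels(self):
        extra = tuple(f"X{i}" for i in range(11))
        names = DEFAULT_MONTAGE + extra
        rec = make_recording(channel_names=names, duration_s=10)
        out = select_channels(rec, DEFAULT_MONTAGE)
        assert out.channel_names == DEFAULT_MONTAGE
        assert out.signal.shape == (21, rec.n_samples)

    def test_identity_when_already_montage(self):
        rec = make_recording(duration_s=10)
        out = select_channels(rec, DEFAULT_MONTAGE)
        np.testing.assert_array_equal(out.signal, rec.signal.astype(np.float32))

    def test_missing_channel_named_in_error(self):
        rec = make_recording(channel_names=DEFAULT_MONTAGE[:-1], duration_s=5)
        with pytest.raises(ChannelNotFoundError, match="A2"):
            select_channels(rec, DEFAULT_MONTAGE)

    def test_alias_normalization(self):
        assert normalize_channel_name("EEG FP1-REF") == "Fp1"
        assert normalize_channel_name("EEG CZ-LE") == "Cz"
        assert normalize_channel_name("T3") == "T3"
        aliased = tuple(f"EEG {n.upper()}-REF" for n in DEFAULT_MONTAGE)
        rec = make_recording(channel_names=aliased, duration_s=5)
        out = select_channels(rec, DEFAULT_MONTAGE)
        assert out.channel_names == DEFAULT_MONTAGE

    def test_reorders_to_montage_order(self):
        rec = make_recording(duration_s=5)
        shuffled_names = tuple(reversed(DEFAULT_MONTAGE))
        shuffled = EEGRecording(signal=rec.signal[::-1].copy(), rate=rec.rate,
                                channel_names=shuffled_names)
        out = select_channels(shuffled, DEFAULT_MONTAGE)
        np.testing.assert_allclose(out.signal, rec.signal, rtol=1e-6)


class TestCrop:
    def test_300s_at_250hz(self):
        rec = make_recording(duration_s=300, rate=250)
        out = crop_recording(rec)
        assert out.n_samples == 30_000
        np.testing.assert_array_equal(out.signal, rec.signal[:, 15_000:45_000])

    def test_exactly_180s_keeps_tail(self):
        rec = make_recording(duration_s=180, rate=100)
        out = crop_recording(rec)
        assert out.n_samples == 12_000
        np.testing.assert_array_equal(out.signal, rec.signal[:, 6_000:])

    def test_short_recording_excluded(self):
        rec = make_recording(duration_s=90, rate=100)
        with pytest.raises(RecordingTooShortError):
            crop_recording(rec)


class TestClipScaleResample:
    def test_clip_bounds(self):
        rec = make_recording(duration_s=5, rate=100)
        rec.signal[0, 0] = 900.0
        rec.signal[1, 1] = -1000.0
        rec.signal[2, 2] = 100.0
        out = clip_amplitude(rec)
        assert out.signal[0, 0] == 800.0
        assert out.signal[1, 1] == -800.0
        assert out.signal[2, 2] == 100.0

    def test_scale_arithmetic(self):
        rec = make_recording(duration_s=5, rate=100)
        rec.signal[0, :3] = [600.0, 0.0, 800.0]
        out = scale_amplitude(rec)
        np.testing.assert_allclose(out.signal[0, :3], [20.0, 0.0, 800.0 / 30.0],
                                   rtol=1e-6)

    def test_resample_sample_count(self):
        rec = make_recording(duration_s=120, rate=250)
        out = resample_to(rec, 100.0)
        assert out.rate == 100.0
        assert out.n_samples == 12_000

    def test_resample_noop_at_target_rate(self):
        rec = make_recording(duration_s=10, rate=100)
        out = resample_to(rec, 100.0)
        assert out.n_samples == rec.n_samples

    def test_resample_preserves_dominant_frequency(self):
        # FFT-peak oracle: a pure 10 Hz tone must stay at 10 Hz after 250->100
        rate = 250.0
        t = np.arange(int(30 * rate)) / rate
        signal = np.sin(2 * np.pi * 10.0 * t)[None, :].astype(np.float32)
        rec = EEGRecording(signal=signal, rate=rate, channel_names=("Cz",))
        out = resample_to(rec, 100.0)
        spectrum = np.abs(np.fft.rfft(out.signal[0]))
        freqs = np.fft.rfftfreq(out.n_samples, d=1 / 100.0)
        assert abs(freqs[np.argmax(spectrum)] - 10.0) < freqs[1] + 1e-9

    def test_resample_rejects_bad_target(self):
        rec = make_recording(duration_s=5)
        with pytest.raises(ValueError):
            resample_to(rec, -1.0)


class TestWindows:
    def test_window_count_12000_samples(self):
        rec = make_recording(duration_s=120, rate=100)
        ws = extract_windows(rec)
        # floor((12000 - 1200)/519) + 1 = 21, last start 20*519 = 10380
        assert len(ws) == 21
        assert ws.window_starts[-1] == 10_380
        np.testing.assert_array_equal(np.diff(ws.window_starts), 519)

    def test_single_window_boundary(self):
        rec = make_recording(duration_s=12, rate=100)
        assert len(extract_windows(rec)) == 1

    def test_below_minimum_warns_and_empty(self):
        rec = make_recording(duration_s=11.99, rate=100)
        with pytest.warns(UserWarning, match="no windows"):
            ws = extract_windows(rec)
        assert len(ws) == 0

    def test_windows_match_signal_content(self):
        rec = make_recording(duration_s=120, rate=100)
        ws = extract_windows(rec)
        np.testing.assert_array_equal(ws.windows[3],
                                      rec.signal[:, 3 * 519:3 * 519 + 1200])

    @given(n_samples=st.integers(min_value=0, max_value=40_000),
           length=st.integers(min_value=1, max_value=2000),
           stride=st.integers(min_value=1, max_value=1200))
    @settings(max_examples=200, deadline=None)
    def test_count_formula_matches_enumeration(self, n_samples, length, stride):
        starts = list(range(0, n_samples - length + 1, stride))
        assert expected_window_count(n_samples, length, stride) == len(starts)


class TestFullChain:
    def test_three_minute_recording_yields_21_windows(self):
        rec = make_recording(duration_s=180, rate=250)
        ws = preprocess(rec)
        assert ws.windows.shape == (21, 21, 1200)
        assert ws.rate == 100.0

    def test_chain_equals_stage_composition(self):
        rec = make_recording(duration_s=200, rate=250, seed=3)
        manual = select_channels(rec, DEFAULT_MONTAGE)
        manual = crop_recording(manual)
        manual = clip_amplitude(manual)
        manual = resample_to(manual)
        manual = scale_amplitude(manual)
        manual_windows = extract_windows(manual)
        ws = preprocess(rec)
        np.testing.assert_allclose(ws.windows, np.clip(
            manual_windows.windows, -800 / 30, 800 / 30), atol=1e-6)

    def test_determinism_bit_identical(self):
        rec = make_recording(duration_s=190, rate=250, seed=11)
        a = preprocess(rec)
        b = preprocess(rec)
        assert np.array_equal(a.windows, b.windows)

    def test_artifact_recording_bounded_by_clip_over_scale(self):
        rec = make_recording(duration_s=185, rate=250, seed=5)
        rec.signal[:] += 10_000.0  # strong artifact
        ws = preprocess(rec)
        assert np.abs(ws.windows).max() == pytest.approx(800.0 / 30.0)

    def test_error_carries_stage_name(self):
        rec = make_recording(duration_s=90, rate=250)
        with pytest.raises(RecordingTooShortError, match="crop_recording"):
            preprocess(rec)

    def test_no_nan_after_chain(self):
        rec = make_recording(duration_s=185, rate=250, seed=8)
        assert not np.isnan(preprocess(rec).windows).any()

    def test_float32_output(self):
        rec = make_recording(duration_s=185, rate=250)
        assert preprocess(rec).windows.dtype == np.float32

    def test_configurable_montage(self):
        montage = DEFAULT_MONTAGE[:4]
        rec = make_recording(duration_s=185, rate=250)
        ws = preprocess(rec, PreprocessConfig(montage=montage))
        assert ws.windows.shape[1] == 4
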