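"""Filtering, epoching, baseline and decimation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soabci import (
    bandpass,
    baseline_correct,
    concatenate_epochs,
    downsample,
    epoch,
    generate_schedule,
    preprocess_recording,
    simulate_recording,
    to_features,
    unflatten_features,
)
from soabci.errors import EdgeEpochError, InvalidFilterError, InvalidLengthError
from soabci.simulate import NoiseParams, Recording


def _sine_recording(freq_hz, schedule, n_channels=2, rate=256.0,
                    min_duration_s=0.0):
    n = int(np.ceil(max(schedule.duration_s + 2, min_duration_s)) * rate)
    t = np.arange(n) / rate
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_channels, 1))
    return Recording(data=data, rate_hz=rate,
                     channel_labels=tuple(f"ch{i}" for i in range(n_channels)),
                     schedule=schedule)


@pytest.fixture(scope="module")
def tiny_schedule():
    return generate_schedule(0.5, 1, 3, seed=0, inter_block_gap_s=2.0)


class TestBandpass:
    def test_stopband_tone_attenuated(self, tiny_schedule):
        rec = _sine_recording(20.0, tiny_schedule, min_duration_s=240.0)
        out = bandpass(rec)
        mid = slice(rec.n_samples // 4, -rec.n_samples // 4)
        ratio = np.abs(out.data[0, mid]).max() / np.abs(rec.data[0, mid]).max()
        assert ratio < 0.1

    def test_passband_tone_preserved(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule, min_duration_s=240.0)
        out = bandpass(rec)
        mid = slice(rec.n_samples // 4, -rec.n_samples // 4)
        ratio = np.abs(out.data[0, mid]).max() / np.abs(rec.data[0, mid]).max()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_dc_removed(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule)
        rec.data[:] = 5.0
        out = bandpass(rec)
        assert np.abs(out.data).max() < 0.05

    def test_invalid_cutoffs_rejected(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule)
        with pytest.raises(InvalidFilterError):
            bandpass(rec, low_hz=0.1, high_hz=200.0)
        with pytest.raises(InvalidFilterError):
            bandpass(rec, low_hz=8.0, high_hz=0.1)


class TestEpoch:
    def test_epoch_count_and_shape(self):
        sched = generate_schedule(1.1, 2, 3, seed=1, inter_block_gap_s=2.0)
        rec = simulate_recording(sched, seed=1)
        eps = epoch(rec)
        assert eps.data.shape == (36, 64, 256)
        assert eps.is_target.sum() == 6  # one target per trial

    def test_overlapping_epochs_duplicate_samples(self):
        sched = generate_schedule(0.2, 1, 2, seed=2, inter_block_gap_s=2.0)
        rec = simulate_recording(sched, seed=2)
        eps = epoch(rec)
        s0 = int(eps.meta.sample_start.iloc[0])
        s1 = int(eps.meta.sample_start.iloc[1])
        shift = s1 - s0
        assert shift < 256  # epochs overlap at 200-ms SOA
        assert np.array_equal(eps.data[0, :, shift:], eps.data[1, :, :-shift])

    def test_event_too_close_to_edge_is_named(self):
        sched = generate_schedule(0.5, 1, 2, seed=3, t_start_s=0.02)
        rec = simulate_recording(sched, seed=3)
        with pytest.raises(EdgeEpochError, match="block=0 trial=0"):
            epoch(rec)


class TestBaseline:
    def test_constant_signal_zeroed(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule)
        rec.data[:] = 5.0
        eps = baseline_correct(epoch(rec), rec)
        assert np.allclose(eps.data, 0.0)

    def test_offset_subtracted(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule)
        rec.data[:] = 2.0
        eps = epoch(rec)
        eps.data[:] = 7.0
        out = baseline_correct(eps, rec)
        assert np.allclose(out.data, 5.0)

    def test_prestim_window_mean_is_zero_after_correction(self, tiny_schedule):
        rng = np.random.default_rng(0)
        rec = _sine_recording(3.0, tiny_schedule)
        rec.data[:] = rng.normal(size=rec.data.shape)
        eps = baseline_correct(epoch(rec), rec)
        pre = 26
        for i, start in enumerate(eps.meta.sample_start):
            # Recover the subtracted constant, then re-apply it to the
            # pre-stimulus window: its mean must vanish.
            subtracted = (rec.data[:, start:start + 256] - eps.data[i])[:, 0]
            corrected_pre = (rec.data[:, start - pre:start]
                             - subtracted[:, None])
            assert np.allclose(corrected_pre.mean(axis=1), 0.0, atol=1e-9)


class TestDownsample:
    def test_constant_preserved(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule)
        eps = epoch(rec)
        eps.data[:] = 3.0
        out = downsample(eps)
        assert out.data.shape[-1] == 25
        assert np.allclose(out.data, 3.0)

    def test_first_bin_is_mean_of_first_ten(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule)
        eps = epoch(rec)
        eps.data[:] = np.arange(256.0)
        out = downsample(eps)
        assert np.allclose(out.data[..., 0], 4.5)
        assert np.allclose(out.data[..., 24], np.arange(240, 250).mean())

    def test_matches_loop_oracle(self, tiny_schedule):
        rng = np.random.default_rng(5)
        rec = _sine_recording(3.0, tiny_schedule)
        eps = epoch(rec)
        eps.data[:] = rng.normal(size=eps.data.shape)
        out = downsample(eps)
        for k in range(25):
            expected = eps.data[..., 10 * k:10 * k + 10].mean(axis=-1)
            assert np.allclose(out.data[..., k], expected)

    def test_too_short_epoch_rejected(self, tiny_schedule):
        rec = _sine_recording(3.0, tiny_schedule)
        eps = epoch(rec)
        eps.data = eps.data[..., :5]
        with pytest.raises(InvalidLengthError):
            downsample(eps)

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(10, 300), factor=st.integers(1, 20),
           seed=st.integers(0, 10**6))
    def test_bins_equal_block_means_property(self, tiny_schedule, n, factor,
                                             seed):
        if n < factor:
            return
        rng = np.random.default_rng(seed)
        rec = _sine_recording(3.0, tiny_schedule)
        eps = epoch(rec)
        eps.data = rng.normal(size=(eps.n_epochs, 2, n))
        out = downsample(eps, factor=factor)
        n_bins = n // factor
        assert out.data.shape[-1] == n_bins
        for k in range(n_bins):
            block = eps.data[..., factor * k:factor * (k + 1)].mean(axis=-1)
            assert np.allclose(out.data[..., k], block)


class TestFeatures:
    def test_flatten_shape_and_roundtrip(self, tiny_schedule):
        rec = simulate_recording(tiny_schedule, seed=4)
        eps = preprocess_recording(rec)
        X = to_features(eps)
        assert X.shape == (eps.n_epochs, 64 * 25)
        back = unflatten_features(X, 64)
        assert np.array_equal(back, eps.data)

    def test_zero_epoch_gives_zero_vector(self, tiny_schedule):
        rec = simulate_recording(tiny_schedule, seed=4)
        eps = preprocess_recording(rec)
        eps.data[:] = 0.0
        assert not to_features(eps).any()

    def test_channel_major_ordering(self, tiny_schedule):
        rec = simulate_recording(tiny_schedule, seed=4)
        eps = preprocess_recording(rec)
        X = to_features(eps)
        # Feature j indexes channel j // 25, bin j % 25.
        assert X[0, 25 * 3 + 7] == eps.data[0, 3, 7]


class TestPipeline:
    def test_deterministic_and_complete(self):
        sched = generate_schedule(0.5, 2, 4, seed=6, inter_block_gap_s=2.0)
        rec = simulate_recording(sched, seed=6)
        a = preprocess_recording(rec)
        b = preprocess_recording(rec)
        assert np.array_equal(a.data, b.data)
        assert a.n_epochs == sched.n_events  # no edge drops on padded sims

    def test_concatenate_renumbers_blocks(self):
        sched = generate_schedule(0.5, 2, 4, seed=6, inter_block_gap_s=2.0)
        rec = simulate_recording(sched, seed=6)
        eps = preprocess_recording(rec)
        both = concatenate_epochs([eps, eps])
        assert both.n_epochs == 2 * eps.n_epochs
        assert both.meta.block.nunique() == 4
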