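"""Filtering, epoching, baseline and blink correction, averaging, smoothing."""

import numpy as np
import pytest

from erpsource import (
    ERPWaveform,
    FilterSpec,
    NoiseConfig,
    SemlitschCorrector,
    SessionConfig,
    average_epochs,
    bandpass,
    baseline_correct,
    build_schedule,
    extract_epochs,
    grand_average,
    inject_blinks,
    semlitsch_correct,
    simulate_epochs,
    simulate_session,
    smooth_erp,
)
from erpsource.containers import ContinuousRecording


def _recording(data, fs=1000.0, labels=None, events=()):
    labels = labels or tuple(f"ch{i}" for i in range(np.atleast_2d(data).shape[0]))
    return ContinuousRecording(labels=labels, data=data, fs=fs, events=events)


class TestBandpass:
    def test_dc_removed_by_40_db(self):
        rec = _recording(np.full((1, 5000), 7.0))
        out = bandpass(rec, FilterSpec())
        # steady-state attenuation of a DC offset
        assert np.abs(out.data[0, 1000:-1000]).max() < 7.0 * 10 ** (-40 / 20)

    @staticmethod
    def _tone_amplitude(x, t, freq):
        # quadrature projection over whole cycles rejects the slow edge
        # transient of the 0.15 Hz high-pass section
        c = 2 * np.mean(x * np.cos(2 * np.pi * freq * t))
        s = 2 * np.mean(x * np.sin(2 * np.pi * freq * t))
        return np.hypot(c, s)

    def test_10hz_sine_passband_gain_within_5_percent(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        rec = _recording(np.sin(2 * np.pi * 10 * t)[None, :], fs=fs)
        out = bandpass(rec, FilterSpec())
        sl = slice(2000, 8000)
        amplitude = self._tone_amplitude(out.data[0, sl], t[sl], 10.0)
        assert amplitude == pytest.approx(1.0, rel=0.05)

    def test_idempotent_for_in_band_content(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        rec = _recording(np.sin(2 * np.pi * 20 * t)[None, :], fs=fs)
        once = bandpass(rec, FilterSpec())
        twice = bandpass(once, FilterSpec())
        sl = slice(2000, 8000)
        a1 = self._tone_amplitude(once.data[0, sl], t[sl], 20.0)
        a2 = self._tone_amplitude(twice.data[0, sl], t[sl], 20.0)
        assert a2 == pytest.approx(a1, rel=0.01)

    def test_cutoff_at_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 1000)), fs=180.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, FilterSpec(lowpass=100.0))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(highpass=50.0, lowpass=10.0).validate(1000.0)


class TestExtractEpochs:
    def test_window_arithmetic_at_1khz(self):
        data = np.arange(5000, dtype=float)[None, :]
        rec = _recording(data, events=((1000, "stim"),))
        epochs = extract_epochs(rec)
        assert epochs.data.shape == (1, 1, 1200)
        assert epochs.times[200] == 0.0
        # stimulus sample lands at index 200
        assert epochs.data[0, 0, 200] == 1000.0
        assert epochs.data[0, 0, 0] == 800.0

    def test_event_without_baseline_dropped(self):
        rec = _recording(np.zeros((1, 3000)), events=((50, "early"), (1500, "ok")))
        epochs = extract_epochs(rec)
        assert epochs.n_trials == 1
        assert epochs.conditions == ("ok",)

    def test_empty_event_list_rejected(self):
        rec = _recording(np.zeros((1, 3000)))
        with pytest.raises(ValueError, match="events"):
            extract_epochs(rec)

    def test_epoching_noiseless_record_recovers_projection_exactly(self):
        config = SessionConfig(n_trials=6, seed=0)
        recording = simulate_session(config, NoiseConfig(sensor_sigma=0.0, blink_rate=0))
        epochs = extract_epochs(recording)
        clean = recording.ground_truth["clean_epoch"]
        eeg = [i for i, c in enumerate(epochs.channels) if not c.startswith("VEOG")]
        grand = epochs.data[:, eeg, :].mean(axis=0)
        assert np.abs(grand - clean).max() < 1e-9


class TestBaselineCorrect:
    def _epochs(self, data):
        rec = _recording(data, events=((500, "s"),))
        return extract_epochs(rec, window=(-200.0, 400.0))

    def test_constant_offset_removed(self):
        epochs = self._epochs(np.full((2, 2000), 3.5))
        out = baseline_correct(epochs)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_already_zero_baseline_unchanged(self):
        data = np.zeros((1, 2000))
        data[0, 500:700] = 1.0  # post-stimulus only
        epochs = self._epochs(data)
        out = baseline_correct(epochs)
        assert np.array_equal(out.data, epochs.data)

    def test_linear_ramp_baseline_mean_zero(self):
        data = np.linspace(0, 1, 2000)[None, :]
        epochs = self._epochs(data)
        out = baseline_correct(epochs)
        mask = out.baseline_mask()
        assert np.abs(out.data[:, :, mask].mean()) < 1e-12
        # shape preserved up to a shift
        shift = epochs.data - out.data
        assert np.allclose(shift, shift[:, :, :1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        epochs = self._epochs(rng.standard_normal((3, 2000)))
        once = baseline_correct(epochs)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-15)

    def test_missing_baseline_rejected(self):
        rec = _recording(np.zeros((1, 3000)), events=((500, "s"),))
        with pytest.raises(ValueError):
            baseline_correct(extract_epochs(rec, window=(-0.0, 400.0)))


class TestSemlitsch:
    def _contaminated(self, seed=5, n_trials=60, blink_rate=20.0):
        config = SessionConfig(n_trials=n_trials, seed=seed)
        clean = simulate_session(
            config, NoiseConfig(sensor_sigma=0.05, blink_rate=0.0, seed=seed + 1)
        )
        dirty = inject_blinks(clean, NoiseConfig(blink_rate=blink_rate), seed=seed + 1)
        return extract_epochs(clean), extract_epochs(dirty)

    def test_propagation_recovered_and_artifact_removed(self):
        ep_clean, ep_dirty = self._contaminated()
        truth = ep_dirty.ground_truth["blinks"]["propagation"]
        veog = ep_dirty.data[:, ep_dirty.channel_index("VEOGL"), :]
        corrector = SemlitschCorrector()
        out = corrector.fit_transform(ep_dirty, veog)

        eeg = [i for i, c in enumerate(ep_dirty.channels) if not c.startswith("VEOG")]
        estimated = corrector.propagation_[eeg]
        expected = np.array([truth[ep_dirty.channels[i]] for i in eeg])
        contaminated = expected > 0
        assert np.all(
            np.abs(estimated[contaminated] - expected[contaminated])
            <= 0.1 * expected[contaminated]
        )
        before = ((ep_dirty.data[:, eeg, :] - ep_clean.data[:, eeg, :]) ** 2).sum()
        after = ((out.data[:, eeg, :] - ep_clean.data[:, eeg, :]) ** 2).sum()
        assert after <= 0.1 * before

    def test_corrected_data_correlates_with_clean_truth(self):
        ep_clean, ep_dirty = self._contaminated(seed=9)
        veog = ep_dirty.data[:, ep_dirty.channel_index("VEOGL"), :]
        out = semlitsch_correct(ep_dirty, veog)
        frontal = [i for i, c in enumerate(ep_dirty.channels) if c in ("F3", "F4", "Fz")]
        r = np.corrcoef(
            out.data[:, frontal, :].ravel(), ep_clean.data[:, frontal, :].ravel()
        )[0, 1]
        assert r >= 0.9

    def test_uncontaminated_channels_within_noise_floor(self):
        # zero propagation to occipital channels by construction
        _, ep_dirty = self._contaminated(seed=3)
        veog = ep_dirty.data[:, ep_dirty.channel_index("VEOGL"), :]
        out = semlitsch_correct(ep_dirty, veog)
        occipital = [i for i, c in enumerate(ep_dirty.channels) if c in ("O1", "O2", "Oz")]
        change = np.abs(out.data[:, occipital, :] - ep_dirty.data[:, occipital, :]).max()
        assert change < ep_dirty.ground_truth["sigma"]

    def test_flat_veog_warns_and_passes_through(self):
        config = SessionConfig(n_trials=10, seed=2)
        recording = simulate_session(config, NoiseConfig(sensor_sigma=0.0, blink_rate=0.0))
        epochs = extract_epochs(recording)
        veog = epochs.data[:, epochs.channel_index("VEOGL"), :]  # exactly zero
        corrector = SemlitschCorrector()
        with pytest.warns(UserWarning, match="no blink"):
            out = corrector.fit_transform(epochs, veog)
        assert np.array_equal(out.data, epochs.data)

    def test_blink_free_noisy_epochs_nearly_unchanged(self):
        # noise-only VEOG sweeps can cross the robust threshold, but the
        # estimated propagation is then just regression noise, so the
        # correction stays below the sensor-noise floor
        config = SessionConfig(n_trials=10, seed=2)
        recording = simulate_session(config, NoiseConfig(sensor_sigma=0.05, blink_rate=0.0))
        epochs = extract_epochs(recording)
        veog = epochs.data[:, epochs.channel_index("VEOGL"), :]
        out = SemlitschCorrector().fit_transform(epochs, veog)
        sigma = epochs.ground_truth["sigma"]
        assert np.abs(out.data - epochs.data).max() < sigma


class TestAveraging:
    def _epochs(self, data, conditions):
        times = np.arange(-200.0, 1000.0)
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
        from erpsource.containers import EpochSet

        return EpochSet(
            data=data, times=times, channels=channels, conditions=conditions, fs=1000.0
        )

    def test_identical_trials_average_to_any_trial(self, rng):
        trial = rng.standard_normal((1, 2, 1200))
        epochs = self._epochs(np.repeat(trial, 5, axis=0), ("a",) * 5)
        avg = average_epochs(epochs, group_by=None)
        assert np.allclose(avg.data, trial[0])
        assert avg.n == 5

    def test_opposite_trials_cancel(self, rng):
        x = rng.standard_normal((1, 2, 1200))
        epochs = self._epochs(np.concatenate([x, -x]), ("a", "a"))
        avg = average_epochs(epochs, group_by=None)
        assert np.allclose(avg.data, 0.0)

    def test_grand_average_is_unweighted_across_subjects(self, rng):
        # two subjects with unequal trial counts: the grand average must be
        # the mean of subject means, not the pooled-trial mean
        times = np.arange(-200.0, 1000.0)
        s1 = ERPWaveform(np.full((1, 1200), 1.0), times, ("ch0",), n=10)
        s2 = ERPWaveform(np.full((1, 1200), 3.0), times, ("ch0",), n=1)
        grand = grand_average([s1, s2])
        assert np.allclose(grand.data, 2.0)  # pooled mean would be 1.18...
        assert grand.n == 2

    def test_group_by_condition(self, rng):
        data = rng.standard_normal((4, 2, 1200))
        epochs = self._epochs(data, ("t", "d", "t", "d"))
        groups = average_epochs(epochs, group_by="condition")
        assert set(groups) == {"t", "d"}
        assert np.allclose(groups["t"].data, data[[0, 2]].mean(axis=0))
        assert groups["t"].n == 2


class TestSmoothing:
    def _waveform(self, data):
        times = np.arange(data.shape[-1], dtype=float)
        return ERPWaveform(data, times, tuple(f"c{i}" for i in range(data.shape[0])), n=1)

    def test_constant_signal_unchanged(self):
        w = self._waveform(np.full((1, 500), 2.5))
        out = smooth_erp(w, "moving_average", 20.0)
        assert np.allclose(out.data, 2.5)

    def test_impulse_becomes_rectangle(self):
        data = np.zeros((1, 500))
        data[0, 250] = 1.0
        out = smooth_erp(self._waveform(data), "moving_average", 21.0)
        assert out.data.max() == pytest.approx(1.0 / 21)
        assert np.count_nonzero(out.data) == 21

    def test_white_noise_variance_reduced_by_window_factor(self, rng):
        w = self._waveform(rng.standard_normal((1, 200_000)))
        width = 20
        out = smooth_erp(w, "moving_average", float(width))
        ratio = w.data.var() / out.data.var()
        assert ratio == pytest.approx(width, rel=0.05)

    def test_window_longer_than_signal_rejected(self):
        w = self._waveform(np.zeros((1, 50)))
        with pytest.raises(ValueError):
            smooth_erp(w, "moving_average", 500.0)

    def test_lowpass_variant_preserves_dc(self):
        w = self._waveform(np.full((1, 2000), 1.5))
        out = smooth_erp(w, "lowpass", 30.0)
        assert np.allclose(out.data, 1.5, atol=1e-6)
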