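"""Synthetic-data generator: trial structure, epochs, blinks, EDF round trip."""

import numpy as np
import pytest

from erpsource import (
    ContinuousRecording,
    NoiseConfig,
    SessionConfig,
    build_schedule,
    inject_blinks,
    simulate_epochs,
    simulate_session,
    simulate_trial_sequence,
)
from erpsource.containers import VEOG_LABELS, read_recording, write_recording
from erpsource.edf import EDFError, read_edf, write_edf


class TestTrialSequence:
    def test_default_session_is_150_trials_spaced_1000ms(self):
        trials = simulate_trial_sequence(SessionConfig(seed=0))
        assert len(trials) == 150
        onsets = np.array([t for t, _ in trials])
        assert np.all(np.diff(onsets) == 1000.0)

    def test_zero_target_fraction_gives_only_distracters(self):
        trials = simulate_trial_sequence(SessionConfig(target_fraction=0.0, seed=1))
        assert all(label == "distracter" for _, label in trials)

    def test_fixed_seed_reproducible(self):
        a = simulate_trial_sequence(SessionConfig(seed=7))
        b = simulate_trial_sequence(SessionConfig(seed=7))
        assert a == b

    def test_target_rate_converges_to_quarter(self):
        n = 10_000
        trials = simulate_trial_sequence(SessionConfig(n_trials=n, seed=3))
        fraction = sum(label == "target" for _, label in trials) / n
        # 99.9% binomial CI around 0.25 at n=10,000
        half_width = 3.29 * np.sqrt(0.25 * 0.75 / n)
        assert abs(fraction - 0.25) < half_width

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(target_fraction=1.5)
        with pytest.raises(ValueError):
            SessionConfig(n_trials=0)
        with pytest.raises(ValueError):
            SessionConfig(fs=0)


class TestSimulateEpochs:
    def test_noiseless_trials_equal_projection(self, head, montage):
        schedule = build_schedule("attention")
        epochs = simulate_epochs(
            schedule, head, montage, NoiseConfig(sensor_sigma=0.0), n_trials=3, seed=0
        )
        clean = epochs.ground_truth["projection"]
        for trial in epochs.data:
            assert np.array_equal(trial, clean)

    def test_time_axis_covers_epoch_window(self, head, montage):
        schedule = build_schedule("attention")
        epochs = simulate_epochs(
            schedule, head, montage, NoiseConfig(sensor_sigma=0.0), n_trials=1, seed=0
        )
        assert epochs.times[0] == -200.0
        assert epochs.times[-1] == 999.0
        assert epochs.data.shape[-1] == 1200
        assert epochs.times[200] == 0.0

    def test_baseline_noise_matches_configured_sigma(self, head, montage):
        schedule = build_schedule("attention")
        epochs = simulate_epochs(
            schedule, head, montage, NoiseConfig(sensor_sigma=0.1), n_trials=250, seed=4
        )
        peak = epochs.ground_truth["peak"]
        baseline = epochs.data[:, :, epochs.baseline_mask()]
        observed = baseline.std()
        assert observed == pytest.approx(0.1 * peak, rel=0.02)

    def test_trial_mean_converges_to_projection(self, head, montage):
        schedule = build_schedule("attention")
        epochs = simulate_epochs(
            schedule, head, montage, NoiseConfig(sensor_sigma=0.1), n_trials=400, seed=5
        )
        clean = epochs.ground_truth["projection"]
        err = np.abs(epochs.data.mean(axis=0) - clean).max()
        assert err < 5 * epochs.ground_truth["sigma"] / np.sqrt(400)

    def test_fixed_seed_bit_identical(self, head, montage):
        schedule = build_schedule("attention")
        kwargs = dict(noise=NoiseConfig(sensor_sigma=0.2), n_trials=5, seed=11)
        a = simulate_epochs(schedule, head, montage, **kwargs)
        b = simulate_epochs(schedule, head, montage, **kwargs)
        assert np.array_equal(a.data, b.data)
        assert a.conditions == b.conditions

    def test_pink_background_is_pure_function_of_seed(self, head, montage):
        schedule = build_schedule("attention")
        kwargs = dict(
            noise=NoiseConfig(sensor_sigma=0.2, pink_background=True), n_trials=4, seed=2
        )
        a = simulate_epochs(schedule, head, montage, **kwargs)
        b = simulate_epochs(schedule, head, montage, **kwargs)
        assert np.array_equal(a.data, b.data)


class TestInjectBlinks:
    def _recording(self, seed=0, n_trials=20, sigma=0.02):
        config = SessionConfig(n_trials=n_trials, seed=seed)
        return simulate_session(
            config, NoiseConfig(sensor_sigma=sigma, blink_rate=0.0, seed=seed)
        )

    def test_zero_rate_leaves_recording_unchanged(self):
        recording = self._recording()
        out = inject_blinks(recording, NoiseConfig(blink_rate=0.0), seed=1)
        assert np.array_equal(out.data, recording.data)

    def test_frontal_contamination_exceeds_occipital(self):
        recording = self._recording()
        out = inject_blinks(recording, NoiseConfig(blink_rate=10.0), seed=2)
        coeffs = out.ground_truth["blinks"]["propagation"]
        assert coeffs["Fz"] > 0
        assert coeffs["F3"] > 0
        for occipital in ("O1", "O2", "Oz", "P7", "P8", "Pz"):
            assert coeffs[occipital] == 0.0
        assert coeffs["Fz"] > coeffs["Cz"]

    def test_added_veog_energy_equals_template_energy_times_count(self):
        recording = self._recording(n_trials=60)
        out = inject_blinks(recording, NoiseConfig(blink_rate=3.0), seed=3)
        blinks = out.ground_truth["blinks"]
        starts = blinks["starts"]
        template = blinks["template"]
        # blinks at this rate/seed do not overlap, so energies add exactly
        assert np.all(np.diff(starts) > template.size)
        veog = recording.labels.index("VEOGL")
        added = out.data[veog] - recording.data[veog]
        assert np.sum(added**2) == pytest.approx(len(starts) * np.sum(template**2))

    def test_missing_veog_channels_rejected(self):
        bare = ContinuousRecording(labels=("Cz",), data=np.zeros((1, 1000)), fs=1000.0)
        with pytest.raises(ValueError, match="VEOG"):
            inject_blinks(bare, NoiseConfig(blink_rate=5.0), seed=0)


class TestRecordingIO:
    def test_edf_round_trip_within_quantization(self, tmp_path, rng):
        fs = 100.0
        data = rng.standard_normal((14, int(10 * fs)))
        labels = [f"ch{i}" for i in range(14)]
        path = tmp_path / "x.edf"
        write_edf(path, data, fs, labels)
        loaded, fs2, labels2 = read_edf(path)
        assert fs2 == fs
        assert labels2 == labels
        step = (data.max(axis=1) - data.min(axis=1)) / 65535
        assert np.all(np.abs(loaded - data) <= step[:, None])

    def test_event_sidecar_round_trip(self, tmp_path):
        config = SessionConfig(n_trials=5, seed=0)
        recording = simulate_session(config, NoiseConfig(sensor_sigma=0.05, blink_rate=0))
        write_recording(recording, tmp_path / "rec.edf")
        loaded = read_recording(tmp_path / "rec.edf")
        assert loaded.events == recording.events
        assert loaded.labels == recording.labels

    def test_truncated_file_raises_explicitly(self, tmp_path, rng):
        path = tmp_path / "t.edf"
        write_edf(path, rng.standard_normal((3, 500)), 100.0, ["a", "b", "c"])
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) - 100])
        with pytest.raises(EDFError, match="truncated"):
            read_edf(path)

    def test_non_edf_content_raises_parse_error(self, tmp_path):
        path = tmp_path / "junk.edf"
        path.write_bytes(b"x" * 400)
        with pytest.raises(EDFError):
            read_edf(path)

    def test_mne_reads_our_edf_identically(self, tmp_path):
        # Independent reader oracle for the EDF writer.
        import mne
        config = SessionConfig(n_trials=3, seed=1)
        recording = simulate_session(config, NoiseConfig(sensor_sigma=0.05, blink_rate=5, seed=2))
        edf_path, _ = write_recording(recording, tmp_path / "rec.edf")
        raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
        ours = read_recording(edf_path)
        theirs = raw.get_data() * 1e6  # MNE converts uV to V on read
        assert raw.ch_names == list(ours.labels)
        n = ours.n_samples
        assert np.allclose(theirs[:, :n], ours.data, atol=1e-12)


class TestSession:
    def test_session_has_veog_channels_and_markers(self):
        config = SessionConfig(n_trials=4, seed=2)
        recording = simulate_session(config, NoiseConfig(sensor_sigma=0.05, blink_rate=0))
        assert recording.labels[-2:] == VEOG_LABELS
        assert len(recording.events) == 4
        labels = {label for _, label in recording.events}
        assert labels <= {"target", "distracter"}
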