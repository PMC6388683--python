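"""Synthetic task-structured EEG with known ground truth.

Generates what the forward model predicts for a module-activation schedule —
triangular dipole spikes projected to a 12-site 10-20 montage at 1,000 Hz —
plus the nuisance structure of a real recording: additive Gaussian sensor
noise (optionally 1/f-shaped background), stereotyped blink artifacts on the
VEOG channels that propagate with front-weighted coefficients into the EEG,
and the trial structure of the two tasks (attention: 150 trials, 25% targets,
500 ms stimulus + 500 ms ISI; PPVT: word event followed by a picture-display
event).  Every output is a pure function of (config, seed), and every
generated data set carries its ground truth so downstream estimators can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actr import ModuleSchedule, build_schedule, spike_waveform
from .containers import VEOG_LABELS, ContinuousRecording, EpochSet
from .head import ElectrodeMontage, HeadModel, leadfield, project_sources

__all__ = [
    "SessionConfig",
    "NoiseConfig",
    "simulate_trial_sequence",
    "schedule_projection",
    "simulate_epochs",
    "simulate_session",
    "inject_blinks",
]

TARGET, DISTRACTER = "target", "distracter"


@dataclass(frozen=True)
class SessionConfig:
    """Trial structure of one recording session (defaults: attention task)."""

    task: str = "attention"
    n_trials: int = 150
    n_practice: int = 12
    stimulus_duration: float = 500.0  # ms
    isi: float = 500.0  # ms
    target_fraction: float = 0.25
    fs: float = 1000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError(f"target_fraction must lie in [0, 1], got {self.target_fraction}")
        if self.n_trials <= 0:
            raise ValueError(f"n_trials must be > 0, got {self.n_trials}")

    @property
    def trial_spacing_ms(self) -> float:
        return self.stimulus_duration + self.isi


@dataclass(frozen=True)
class NoiseConfig:
    """Recording nuisance model.

    ``sensor_sigma`` is the white-noise standard deviation as a fraction of
    the peak noiseless scalp amplitude; ``blink_rate`` is events per minute
    (preschoolers blink often; default 8/min) and ``blink_amplitude`` is the
    VEOG template peak in the same relative units as the projected signal
    (default about ten times a typical single-dipole scalp peak, mirroring
    the real-world dominance of ocular potentials over ERPs).
    """

    sensor_sigma: float = 0.1
    pink_background: bool = False
    blink_rate: float = 8.0
    blink_amplitude: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor_sigma < 0:
            raise ValueError(f"sensor_sigma must be >= 0, got {self.sensor_sigma}")
        if self.blink_rate < 0:
            raise ValueError(f"blink_rate must be >= 0, got {self.blink_rate}")


def simulate_trial_sequence(config: SessionConfig) -> list[tuple[float, str]]:
    """Stimulus onsets and condition labels for one session.

    Trials are evenly spaced at stimulus_duration + ISI; the condition is an
    independent Bernoulli(target_fraction) draw per trial (150 is not
    divisible by 4, so exact-count shuffling cannot hit one quarter exactly).
    """
    rng = np.random.default_rng(config.seed)
    onsets = np.arange(config.n_trials) * config.trial_spacing_ms
    is_target = rng.random(config.n_trials) < config.target_fraction
    return [
        (float(onset), TARGET if hit else DISTRACTER)
        for onset, hit in zip(onsets, is_target)
    ]


def schedule_projection(
    schedule: ModuleSchedule,
    head: HeadModel,
    montage: ElectrodeMontage,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Noiseless scalp projection of a schedule: channels x samples.

    Each event contributes leadfield column(s) of its module's dipoles times
    the triangular spike timecourse times the event amplitude; contributions
    superpose across events.
    """
    out = np.zeros((len(montage), time_grid.size))
    for event in schedule.events:
        L = leadfield(montage, list(event.module.dipole_specs), head)
        wave = spike_waveform(event, time_grid)
        strengths = np.array([dip.strength_p for dip in event.module.dipole_specs])
        out += project_sources(L * strengths, np.tile(wave, (L.shape[1], 1))) * event.amplitude
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f-shaped noise per row, synthesized by spectral shaping."""
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    weight = np.zeros_like(freqs)
    weight[freqs > 0] = 1.0 / np.sqrt(freqs[freqs > 0])
    shaped = np.fft.irfft(spectrum * weight, n=shape[-1], axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_epochs(
    schedule: ModuleSchedule,
    head: HeadModel,
    montage: ElectrodeMontage,
    noise: NoiseConfig,
    n_trials: int,
    seed: int | np.random.SeedSequence | None = None,
    window: tuple[float, float] = (-200.0, 1000.0),
    fs: float = 1000.0,
    conditions: list[str] | None = None,
) -> EpochSet:
    """Epochs = noiseless schedule projection + per-trial sensor noise.

    The noise standard deviation is ``sensor_sigma`` times the peak absolute
    noiseless amplitude, so the across-trial mean converges to the noiseless
    projection.  Ground truth (projection, leadfield columns, noise sigma,
    schedule) is stored on the returned :class:`EpochSet`.
    """
    if n_trials <= 0:
        raise ValueError(f"n_trials must be > 0, got {n_trials}")
    lo, hi = window
    if (lo, hi) != schedule.window:
        raise ValueError(
            f"schedule window {schedule.window} does not match requested epoch window {window}"
        )
    step = 1000.0 / fs
    times = np.arange(lo, hi, step)
    clean = schedule_projection(schedule, head, montage, times)
    peak = np.abs(clean).max()
    if peak == 0:
        raise ValueError("schedule projects to an all-zero scalp signal")
    sigma = noise.sensor_sigma * peak

    rng = np.random.default_rng(seed)
    shape = (n_trials, len(montage), times.size)
    data = np.broadcast_to(clean, shape).copy()
    if sigma > 0:
        if noise.pink_background:
            flat = _pink_noise(rng, (n_trials * len(montage), times.size))
            data += sigma * flat.reshape(shape)
        else:
            data += sigma * rng.standard_normal(shape)
    if conditions is None:
        conditions = [DISTRACTER] * n_trials
    if len(conditions) != n_trials:
        raise ValueError("one condition label per trial required")
    return EpochSet(
        data=data,
        times=times,
        channels=montage.labels,
        conditions=tuple(conditions),
        fs=fs,
        ground_truth={
            "projection": clean,
            "schedule": schedule,
            "sigma": sigma,
            "peak": peak,
            "head": head,
            "montage": montage,
        },
    )


def blink_template(fs: float, duration_ms: float = 300.0, amplitude: float = 1.0) -> np.ndarray:
    """Stereotyped blink: half-cosine (Hann) bump of ~300 ms."""
    n = int(round(duration_ms * fs / 1000.0))
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def blink_propagation(montage: ElectrodeMontage, frontal_gain: float = 0.4) -> np.ndarray:
    """Per-EEG-channel blink propagation coefficients.

    Proportional to how anterior the electrode is (positive y), zero at and
    behind the coronal midline, so coefficients decrease front to back and
    occipital channels are uncontaminated by construction.
    """
    y = montage.positions[:, 1] / montage.scalp_radius
    return frontal_gain * np.clip(y, 0.0, None)


def inject_blinks(
    recording: ContinuousRecording,
    noise: NoiseConfig,
    seed: int | np.random.SeedSequence | None = None,
    frontal_gain: float = 0.4,
) -> ContinuousRecording:
    """Add Poisson-timed blink artifacts to VEOG and frontal EEG channels.

    The VEOG channels receive the full template; each EEG channel receives
    the template scaled by its propagation coefficient.  Blink times,
    template and coefficients are stored as ground truth.
    """
    veog_idx = recording.veog_indices()
    if not veog_idx:
        raise ValueError(f"no VEOG channels ({VEOG_LABELS}) present in {recording.labels}")
    data = recording.data.copy()
    template = blink_template(recording.fs, amplitude=noise.blink_amplitude)
    duration_min = recording.n_samples / recording.fs / 60.0
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    n_blinks = rng.poisson(noise.blink_rate * duration_min) if noise.blink_rate > 0 else 0
    latest = recording.n_samples - template.size
    starts = np.sort(rng.integers(0, max(latest, 1), size=n_blinks)) if n_blinks else np.array([], int)

    eeg_idx = recording.eeg_indices()
    eeg_positions = recording.labels
    montage_like = [recording.labels[i] for i in eeg_idx]
    coeffs = np.zeros(len(eeg_idx))
    gt_montage = recording.ground_truth.get("montage")
    if gt_montage is not None:
        coeffs = blink_propagation(gt_montage, frontal_gain)
    else:
        # Fall back on label heuristics: frontal labels start with F.
        coeffs = np.array([frontal_gain * 0.7 if lab[0] == "F" else 0.0 for lab in montage_like])

    for start in starts:
        sl = slice(int(start), int(start) + template.size)
        for idx in veog_idx:
            data[idx, sl] += template
        for coeff, idx in zip(coeffs, eeg_idx):
            data[idx, sl] += coeff * template

    ground_truth = dict(recording.ground_truth)
    ground_truth["blinks"] = {
        "starts": starts,
        "template": template,
        "propagation": dict(zip(montage_like, coeffs)),
    }
    return ContinuousRecording(
        labels=recording.labels,
        data=data,
        fs=recording.fs,
        events=recording.events,
        ground_truth=ground_truth,
    )


def simulate_session(
    config: SessionConfig,
    noise: NoiseConfig,
    head: HeadModel | None = None,
    montage: ElectrodeMontage | None = None,
    schedule: ModuleSchedule | None = None,
    pad_ms: float = 1000.0,
) -> ContinuousRecording:
    """Continuous recording for a full session: EEG + VEOG channels.

    Each trial places the noiseless schedule projection at its onset; sensor
    noise and blinks are then added over the whole record.  Events are marked
    at the stimulus samples.
    """
    head = head or HeadModel()
    montage = montage or ElectrodeMontage.default(head)
    schedule = schedule or build_schedule(config.task, head_radius=head.scalp_radius)
    trials = simulate_trial_sequence(config)

    fs = config.fs
    step = 1000.0 / fs
    epoch_times = np.arange(schedule.window[0], schedule.window[1], step)
    clean_epoch = schedule_projection(schedule, head, montage, epoch_times)
    peak = np.abs(clean_epoch).max()
    sigma = noise.sensor_sigma * peak

    total_ms = 2 * pad_ms + trials[-1][0] + schedule.window[1]
    n_samples = int(round(total_ms * fs / 1000.0))
    n_eeg = len(montage)
    labels = montage.labels + VEOG_LABELS
    data = np.zeros((n_eeg + len(VEOG_LABELS), n_samples))

    events = []
    offset = int(round(schedule.window[0] * fs / 1000.0))  # negative: baseline before onset
    for onset_ms, condition in trials:
        stim_sample = int(round((pad_ms + onset_ms) * fs / 1000.0))
        start = stim_sample + offset
        data[:n_eeg, start : start + clean_epoch.shape[1]] += clean_epoch
        events.append((stim_sample, condition))

    rng = np.random.default_rng(config.seed + 1)
    if sigma > 0:
        if noise.pink_background:
            data += sigma * _pink_noise(rng, data.shape)
        else:
            data += sigma * rng.standard_normal(data.shape)

    recording = ContinuousRecording(
        labels=labels,
        data=data,
        fs=fs,
        events=tuple(events),
        ground_truth={
            "schedule": schedule,
            "clean_epoch": clean_epoch,
            "sigma": sigma,
            "montage": montage,
            "head": head,
        },
    )
    if noise.blink_rate > 0:
        recording = inject_blinks(recording, noise, seed=noise.seed)
    return recording
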