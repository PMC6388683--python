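"""Filtering, epoching, baseline correction, ocular-artifact correction and
averaging of ERP data.

The band-pass (0.15-100 Hz by default, matching typical clinical amplifier
settings) is applied zero-phase to the continuous recording.  Epochs span
the half-open window [-200, 1000) ms around each stimulus; baseline
correction subtracts the mean of the 200 ms pre-stimulus interval per trial
and channel.  Blink correction follows the average-artifact-subtraction
scheme of Semlitsch and colleagues: an average artifact response is built
from blink sweeps detected on the VEOG, a per-channel propagation
coefficient is estimated by least squares, and the scaled artifact is
subtracted sweep by sweep, point by point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ContinuousRecording, EpochSet, ERPWaveform

__all__ = [
    "FilterSpec",
    "SemlitschCorrector",
    "bandpass",
    "extract_epochs",
    "baseline_correct",
    "semlitsch_correct",
    "average_epochs",
    "grand_average",
    "smooth_erp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; defaults mirror a 0.15-100 Hz recording chain."""

    highpass: float = 0.15
    lowpass: float = 100.0
    order: int = 4
    family: str = "butter"

    def validate(self, fs: float) -> None:
        if not 0 <= self.highpass < self.lowpass:
            raise ValueError(f"need 0 <= highpass < lowpass, got {self.highpass}, {self.lowpass}")
        if self.lowpass >= fs / 2:
            raise ValueError(f"lowpass {self.lowpass} Hz at or above Nyquist ({fs / 2} Hz)")
        if self.family != "butter":
            raise ValueError(f"unsupported filter family {self.family!r}")


def _design(spec: FilterSpec, fs: float) -> np.ndarray:
    # Cascade separate high- and low-pass sections: a single band-pass design
    # is numerically fragile when the band edges differ by three decades.
    spec.validate(fs)
    low = signal.butter(spec.order, spec.lowpass, btype="lowpass", fs=fs, output="sos")
    if spec.highpass > 0:
        high = signal.butter(spec.order, spec.highpass, btype="highpass", fs=fs, output="sos")
        return np.vstack([high, low])
    return low


def bandpass(
    recording: ContinuousRecording | np.ndarray,
    spec: FilterSpec | None = None,
    fs: float | None = None,
) -> ContinuousRecording | np.ndarray:
    """Zero-phase (forward-backward) band-pass; removes DC, passband gain ~1."""
    spec = spec or FilterSpec()
    if isinstance(recording, ContinuousRecording):
        sos = _design(spec, recording.fs)
        filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
        return ContinuousRecording(
            labels=recording.labels,
            data=filtered,
            fs=recording.fs,
            events=recording.events,
            ground_truth=recording.ground_truth,
        )
    if fs is None:
        raise ValueError("fs is required when filtering a bare array")
    sos = _design(spec, fs)
    return signal.sosfiltfilt(sos, np.asarray(recording, dtype=float), axis=-1)


def extract_epochs(
    recording: ContinuousRecording,
    events: list[tuple[int, str]] | None = None,
    window: tuple[float, float] = (-200.0, 1000.0),
) -> EpochSet:
    """Cut stimulus-locked epochs over the half-open window [start, stop) ms.

    At 1,000 Hz the default window yields 1,200 samples with the stimulus at
    sample index 200.  Events whose window falls outside the record are
    dropped with a logged count.
    """
    events = list(events) if events is not None else list(recording.events)
    if not events:
        raise ValueError("no events to epoch around")
    fs = recording.fs
    lo, hi = window
    start_offset = int(round(lo * fs / 1000.0))
    stop_offset = int(round(hi * fs / 1000.0))
    n_samples = stop_offset - start_offset
    times = (np.arange(n_samples) + start_offset) * 1000.0 / fs

    kept, conditions = [], []
    dropped = 0
    for sample, label in events:
        start = int(sample) + start_offset
        stop = int(sample) + stop_offset
        if start < 0 or stop > recording.n_samples:
            dropped += 1
            continue
        kept.append(recording.data[:, start:stop])
        conditions.append(label)
    if dropped:
        logger.info("extract_epochs: dropped %d of %d events outside the record", dropped, len(events))
    if not kept:
        raise ValueError("all events fell outside the record bounds")
    return EpochSet(
        data=np.stack(kept),
        times=times,
        channels=recording.labels,
        conditions=tuple(conditions),
        fs=fs,
        ground_truth=recording.ground_truth,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the mean over the pre-stimulus interval per trial and channel."""
    mask = epochs.baseline_mask()
    if not mask.any():
        raise ValueError("no pre-stimulus samples available for baseline correction")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - baseline)


class SemlitschCorrector(BaseEstimator, TransformerMixin):
    """Average-artifact-subtraction blink correction.

    Blink sweeps are detected as trials whose VEOG excursion exceeds
    ``threshold_mads`` robust standard deviations (median absolute deviation
    based) of the VEOG.  A per-channel propagation coefficient is estimated
    by least squares of each channel on the VEOG over the artifact samples,
    and the scaled VEOG artifact is subtracted from blink sweeps point by
    point.

    Fitted attributes: ``propagation_`` (per channel), ``blink_sweeps_``
    (boolean per trial), ``average_artifact_`` (VEOG average over blink
    sweeps), ``n_blinks_``.
    """

    def __init__(self, threshold_mads: float = 3.0):
        self.threshold_mads = threshold_mads

    def fit(self, epochs: EpochSet, veog: np.ndarray):
        veog = np.asarray(veog, dtype=float)
        if veog.shape != (epochs.n_trials, epochs.times.size):
            raise ValueError(
                f"VEOG shape {veog.shape} does not align with epochs "
                f"({epochs.n_trials} trials x {epochs.times.size} samples)"
            )
        center = np.median(veog)
        mad = np.median(np.abs(veog - center))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            robust_sd = veog.std() or 1.0
        threshold = self.threshold_mads * robust_sd
        excursion = np.abs(veog - center)
        self.blink_sweeps_ = excursion.max(axis=1) > threshold
        self.n_blinks_ = int(self.blink_sweeps_.sum())
        self.threshold_ = threshold
        self.veog_center_ = center

        n_channels = epochs.data.shape[1]
        self.propagation_ = np.zeros(n_channels)
        if self.n_blinks_ == 0:
            warnings.warn("no blink sweeps detected; correction is the identity", stacklevel=2)
            self.average_artifact_ = np.zeros(epochs.times.size)
            self.artifact_mask_ = np.zeros_like(veog, dtype=bool)
            return self

        self.average_artifact_ = (veog[self.blink_sweeps_] - center).mean(axis=0)
        # Artifact samples: where the blink actually deflects the VEOG.
        mask = np.zeros_like(veog, dtype=bool)
        mask[self.blink_sweeps_] = excursion[self.blink_sweeps_] > threshold / 2.0
        self.artifact_mask_ = mask
        v = (veog - center)[mask]
        v = v - v.mean()
        denom = float(v @ v)
        for ch in range(n_channels):
            if epochs.channels[ch].startswith("VEOG"):
                continue  # the ocular reference itself is never "corrected"
            x = epochs.data[:, ch, :][mask]
            x = x - x.mean()
            self.propagation_[ch] = float(v @ x) / denom if denom > 0 else 0.0
        return self

    def transform(self, epochs: EpochSet, veog: np.ndarray) -> EpochSet:
        veog = np.asarray(veog, dtype=float)
        data = epochs.data.copy()
        if getattr(self, "n_blinks_", 0):
            artifact = veog - self.veog_center_
            for trial in np.flatnonzero(self.blink_sweeps_):
                data[trial] -= np.outer(self.propagation_, artifact[trial])
        return epochs.copy_with(data=data)

    def fit_transform(self, epochs: EpochSet, veog: np.ndarray) -> EpochSet:
        return self.fit(epochs, veog).transform(epochs, veog)


def semlitsch_correct(
    epochs: EpochSet, veog: np.ndarray, threshold_mads: float = 3.0
) -> EpochSet:
    """Functional wrapper over :class:`SemlitschCorrector`."""
    return SemlitschCorrector(threshold_mads=threshold_mads).fit_transform(epochs, veog)


def average_epochs(
    epochs: EpochSet, group_by: str | None = "condition"
) -> ERPWaveform | dict[str, ERPWaveform]:
    """Arithmetic mean across trials, optionally per condition."""
    if epochs.n_trials < 1:
        raise ValueError("cannot average an empty epoch set")
    if group_by is None:
        return ERPWaveform(
            data=epochs.data.mean(axis=0),
            times=epochs.times,
            channels=epochs.channels,
            n=epochs.n_trials,
            condition="all",
        )
    if group_by != "condition":
        raise ValueError(f"unsupported group_by {group_by!r}")
    out: dict[str, ERPWaveform] = {}
    for condition in dict.fromkeys(epochs.conditions):  # stable order
        idx = [i for i, c in enumerate(epochs.conditions) if c == condition]
        out[condition] = ERPWaveform(
            data=epochs.data[idx].mean(axis=0),
            times=epochs.times,
            channels=epochs.channels,
            n=len(idx),
            condition=condition,
        )
    return out


def grand_average(waveforms: list[ERPWaveform]) -> ERPWaveform:
    """Unweighted mean of per-subject averages (not the pooled-trial mean)."""
    if not waveforms:
        raise ValueError("cannot grand-average an empty list")
    first = waveforms[0]
    for w in waveforms[1:]:
        if w.data.shape != first.data.shape or w.channels != first.channels:
            raise ValueError("all waveforms must share channels and time axis")
    stacked = np.stack([w.data for w in waveforms])
    return ERPWaveform(
        data=stacked.mean(axis=0),
        times=first.times,
        channels=first.channels,
        n=len(waveforms),
        condition=first.condition,
    )


def smooth_erp(
    waveform: ERPWaveform, method: str = "moving_average", parameter: float = 20.0
) -> ERPWaveform:
    """Linear smoothing for display/evaluation; preserves DC.

    ``parameter`` is the moving-average window in ms, or the low-pass corner
    frequency in Hz for ``method="lowpass"``.
    """
    fs = 1000.0 / float(np.diff(waveform.times).mean())
    if method == "moving_average":
        width = int(round(parameter * fs / 1000.0))
        if width < 1 or width > waveform.times.size:
            raise ValueError(f"window of {parameter} ms invalid for this waveform")
        smoothed = ndimage.uniform_filter1d(waveform.data, size=width, axis=-1, mode="nearest")
    elif method == "lowpass":
        if not 0 < parameter < fs / 2:
            raise ValueError(f"lowpass corner {parameter} Hz invalid at fs={fs}")
        sos = signal.butter(4, parameter, btype="lowpass", fs=fs, output="sos")
        smoothed = signal.sosfiltfilt(sos, waveform.data, axis=-1)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return ERPWaveform(
        data=smoothed,
        times=waveform.times,
        channels=waveform.channels,
        n=waveform.n,
        condition=waveform.condition,
    )
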