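"""Rebuild the full-epoch scalp ERP from a fitted neurocognitive model and
quantify the fit.

A neurocognitive model couples a module-activation schedule (triangular
spikes at module peak times) to fitted dipoles; its forward reconstruction is
the sum over modules of leadfield column(s) times spike timecourse times a
non-negative amplitude.  Amplitudes are estimated by non-negative least
squares against a measured ERP (spikes model recruitment magnitude, so sign
lives in the dipole orientation).  Fit quality is the coefficient of
determination pooled over all channel x time samples, with per-channel
variants reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .actr import CognitiveModule, ModuleSchedule, SpikeEvent, spike_waveform
from .head import Dipole, ElectrodeMontage, HeadModel, leadfield
from .dipolefit import DipoleFitResult

__all__ = [
    "NeurocognitiveModel",
    "FitSummary",
    "reconstruct_erp",
    "fit_amplitudes",
    "r_squared",
    "model_from_components",
]


@dataclass(frozen=True)
class NeurocognitiveModel:
    """Schedule + fitted dipoles + head/montage references."""

    schedule: ModuleSchedule
    head: HeadModel
    montage: ElectrodeMontage

    def __post_init__(self) -> None:
        for event in self.schedule.events:
            if len(event.module.dipole_specs) < 1:
                raise ValueError(f"event at {event.peak_time} ms has no dipole")
            if event.amplitude < 0:
                raise ValueError("model amplitudes are non-negative")

    @property
    def n_modules(self) -> int:
        return len(self.schedule.events)


@dataclass(frozen=True)
class FitSummary:
    """Coefficient-of-determination summary of measured vs reconstructed."""

    r_squared: float  # pooled over channels x time
    per_channel_r_squared: tuple[float, ...]
    per_component_r_squared: tuple[float, ...]
    residual_profile: tuple[float, ...]  # per-channel residual RMS

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "per_channel_r_squared": list(self.per_channel_r_squared),
            "per_component_r_squared": list(self.per_component_r_squared),
            "residual_profile": list(self.residual_profile),
        }


def _event_basis(model: NeurocognitiveModel, event: SpikeEvent, time_grid: np.ndarray) -> np.ndarray:
    """Unit-amplitude scalp contribution of one event: channels x samples."""
    L = leadfield(model.montage, list(event.module.dipole_specs), model.head)
    strengths = np.array([dip.strength_p for dip in event.module.dipole_specs])
    wave = spike_waveform(
        SpikeEvent(event.module, event.peak_time, event.half_width, 1.0), time_grid
    )
    return (L @ strengths)[:, None] * wave[None, :]


def reconstruct_erp(model: NeurocognitiveModel, time_grid: np.ndarray) -> np.ndarray:
    """Forward reconstruction: sum over modules of dipole maps x spikes."""
    time_grid = np.asarray(time_grid, dtype=float)
    if not model.schedule.events:
        raise ValueError("cannot reconstruct from an empty schedule")
    out = np.zeros((len(model.montage), time_grid.size))
    for event in model.schedule.events:
        out += event.amplitude * _event_basis(model, event, time_grid)
    return out


def fit_amplitudes(
    measured: np.ndarray,
    model: NeurocognitiveModel,
    time_grid: np.ndarray,
    collinearity_tol: float = 1.0 - 1e-4,
) -> NeurocognitiveModel:
    """Solve per-event amplitudes by non-negative least squares.

    The design has one regressor per scheduled event (its unit-amplitude
    reconstruction, flattened over channels x time).  Near-collinear
    regressors (identical events) raise an error naming the events.
    """
    measured = np.asarray(measured, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    events = model.schedule.events
    basis = np.column_stack(
        [_event_basis(model, event, time_grid).ravel() for event in events]
    )
    norms = np.linalg.norm(basis, axis=0)
    if np.any(norms == 0):
        bad = [events[i].module.name for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"events with zero scalp projection: {bad}")
    unit = basis / norms
    gram = np.abs(unit.T @ unit)
    np.fill_diagonal(gram, 0.0)
    i, j = np.unravel_index(np.argmax(gram), gram.shape)
    if gram[i, j] > collinearity_tol:
        raise ValueError(
            "collinear amplitude basis: events "
            f"{events[i].module.name!r} and {events[j].module.name!r} "
            f"(|cos| = {gram[i, j]:.6f})"
        )
    amplitudes, _ = nnls(basis, measured.ravel())
    return NeurocognitiveModel(
        schedule=model.schedule.with_amplitudes(amplitudes),
        head=model.head,
        montage=model.montage,
    )


def r_squared(
    measured: np.ndarray,
    predicted: np.ndarray,
    per_component: tuple[float, ...] = (),
) -> FitSummary:
    """Pooled coefficient of determination, 1 - SS_res/SS_tot.

    SS_tot is taken about the grand mean of the measured data pooled over all
    channel x time samples, so predicting that mean scores exactly zero.
    """
    measured = np.atleast_2d(np.asarray(measured, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if measured.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {measured.shape} vs {predicted.shape}")
    grand_mean = measured.mean()
    ss_tot = float(((measured - grand_mean) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("measured data has zero variance")
    residual = measured - predicted
    ss_res = float((residual**2).sum())
    pooled = 1.0 - ss_res / ss_tot

    per_channel = []
    for ch in range(measured.shape[0]):
        sst = float(((measured[ch] - measured[ch].mean()) ** 2).sum())
        ssr = float((residual[ch] ** 2).sum())
        per_channel.append(1.0 - ssr / sst if sst > 0 else float("nan"))

    rms = np.sqrt((residual**2).mean(axis=1))
    return FitSummary(
        r_squared=pooled,
        per_channel_r_squared=tuple(per_channel),
        per_component_r_squared=tuple(per_component),
        residual_profile=tuple(float(v) for v in rms),
    )


def model_from_components(
    decomposition,
    selected: list[int],
    fits: dict[int, DipoleFitResult],
    times: np.ndarray,
    head: HeadModel,
    montage: ElectrodeMontage,
    task: str = "recovered",
    half_width: float = 50.0,
    window: tuple[float, float] = (-200.0, 1000.0),
) -> NeurocognitiveModel:
    """Build a model skeleton from retained ICA components and their dipole fits.

    Each retained component becomes one module whose dipoles come from its
    fit and whose spike peaks at the component source's peak-latency sample.
    Amplitudes are left at 1 for downstream estimation.
    """
    times = np.asarray(times, dtype=float)
    events = []
    for i in selected:
        source = decomposition.sources[i]
        peak_time = float(times[int(np.argmax(np.abs(source)))])
        fit = fits[i]
        module = CognitiveModule(
            name=f"component_{i}",
            anatomical_label=f"component {i}",
            dipole_specs=fit.dipoles,
        )
        events.append(
            SpikeEvent(module=module, peak_time=peak_time, half_width=half_width, amplitude=1.0)
        )
    if not events:
        raise ValueError("no components selected; cannot build a model")
    schedule = ModuleSchedule(task=task, events=tuple(events), window=window)
    return NeurocognitiveModel(schedule=schedule, head=head, montage=montage)
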