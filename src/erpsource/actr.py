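"""Minimal ACT-R production/buffer timing engine and module-activation schedules.

ACT-R models cognition as independent modules (visual, imaginal, declarative,
retrieval, procedural, ...) that communicate through single-chunk buffers
under a production system in which rules fire one at a time, each firing
costing a fixed 50 ms.  For ERP simulation each cognitive module is a source
of one or two equivalent current dipoles, and its activation is a triangular
spike: zero outside ``peak +- half_width``, rising linearly to the peak and
dropping at the same rate.

The two tasks modelled here (a visual selective-attention task and a
picture-vocabulary word-verification task) come with fixed module activation
schedules: peak times and generating regions for eight modules per task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .head import Dipole

__all__ = [
    "Chunk",
    "Buffer",
    "ProductionRule",
    "CognitiveModule",
    "SpikeEvent",
    "ModuleSchedule",
    "PRODUCTION_COST_MS",
    "TASKS",
    "step_production_system",
    "build_schedule",
    "spike_waveform",
    "region_dipoles",
]

PRODUCTION_COST_MS = 50.0


@dataclass(frozen=True)
class Chunk:
    """Predicated slot/value record, e.g. ``Chunk({"is-a": "duck"})``."""

    slots: tuple[tuple[str, object], ...]

    def __init__(self, slots: dict[str, object] | tuple[tuple[str, object], ...]):
        items = tuple(slots.items()) if isinstance(slots, dict) else tuple(slots)
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("slot names must be unique within a chunk")
        object.__setattr__(self, "slots", items)

    def get(self, slot: str, default: object = None) -> object:
        return dict(self.slots).get(slot, default)

    def matches(self, pattern: dict[str, object]) -> bool:
        content = dict(self.slots)
        return all(slot in content and content[slot] == value for slot, value in pattern.items())


@dataclass
class Buffer:
    """Holds at most one chunk at a time."""

    name: str
    content: Chunk | None = None


@dataclass(frozen=True)
class ProductionRule:
    """If/then rule over named buffers.

    ``condition`` maps buffer name -> slot pattern the buffer's chunk must
    match (an empty pattern requires only that the buffer holds a chunk; a
    pattern of None requires the buffer to be empty).  ``action`` maps buffer
    name -> new Chunk, or None to clear the buffer.
    """

    name: str
    condition: dict[str, dict[str, object] | None]
    action: dict[str, Chunk | None]
    cost_ms: float = PRODUCTION_COST_MS

    def matches(self, buffers: dict[str, Buffer]) -> bool:
        for buffer_name, pattern in self.condition.items():
            buffer = buffers.get(buffer_name)
            if pattern is None:
                if buffer is not None and buffer.content is not None:
                    return False
                continue
            if buffer is None or buffer.content is None:
                return False
            if not buffer.content.matches(pattern):
                return False
        return True


@dataclass(frozen=True)
class Firing:
    time_ms: float
    rule_name: str
    updates: dict[str, Chunk | None]


def step_production_system(
    buffers: dict[str, Buffer],
    rules: list[ProductionRule],
    until_ms: float,
) -> list[Firing]:
    """Run the match-fire-update cycle up to a time horizon.

    At most one production fires per step; buffer updates take effect only
    after the firing rule's cost has elapsed, so a rule enabled by another's
    action fires one cost later.  When several rules match simultaneously the
    earlier-declared rule wins (documented tie-break).  With no matching rule
    the system is quiescent and the trace ends.
    """
    if not np.isfinite(until_ms):
        raise ValueError("until_ms must be finite")
    trace: list[Firing] = []
    t = 0.0
    while t < until_ms:
        fired = next((rule for rule in rules if rule.matches(buffers)), None)
        if fired is None:
            break
        trace.append(Firing(time_ms=t, rule_name=fired.name, updates=dict(fired.action)))
        t += fired.cost_ms
        for buffer_name, chunk in fired.action.items():
            buffers.setdefault(buffer_name, Buffer(buffer_name)).content = chunk
    return trace


# ---------------------------------------------------------------------------
# Module -> dipole placement
# ---------------------------------------------------------------------------

# Representative dipole coordinates per anatomical region, on the default
# 85 mm sphere (mm; x right, y anterior, z up).  "lateral" is the left-
# hemisphere site (mirror x for right); "midline" is used when a region is
# listed bilaterally alongside other regions.  Basal rows are treated as deep
# midline-adjacent sources (assumption: basal ganglia), oriented +z since a
# radial direction is ill-defined near the centre.
REGION_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "occipital": {"lateral": (-28.0, -52.0, 12.0), "midline": (0.0, -58.0, 15.0)},
    "parietal": {"lateral": (-30.0, -30.0, 50.0), "midline": (0.0, -35.0, 55.0)},
    "frontal": {"lateral": (-28.0, 48.0, 25.0), "midline": (0.0, 55.0, 28.0)},
    "temporal": {"lateral": (-55.0, -15.0, -5.0), "midline": (0.0, -20.0, 0.0)},
    "basal": {"lateral": (-12.0, 5.0, -5.0), "midline": (0.0, 5.0, -8.0)},
}

_DEEP_RADIUS_MM = 20.0  # below this, use +z instead of a radial orientation


def _place(region: str, side: str, scale: float = 1.0) -> Dipole:
    coords = REGION_COORDS[region]
    if side == "left":
        loc = np.array(coords["lateral"])
    elif side == "right":
        loc = np.array(coords["lateral"]) * np.array([-1.0, 1.0, 1.0])
    else:  # midline
        loc = np.array(coords["midline"])
    loc = loc * scale
    if np.linalg.norm(loc) < _DEEP_RADIUS_MM * scale:
        orientation = np.array([0.0, 0.0, 1.0])
    else:
        orientation = loc / np.linalg.norm(loc)
    return Dipole(location=loc, orientation=orientation, strength_p=1.0)


def region_dipoles(spec: str, head_radius: float = 85.0) -> tuple[str, list[Dipole]]:
    """Parse a region row like ``"Occipital/Basal, Bilateral"`` into dipoles.

    Placement rule (a module carries at most two dipoles):

    * a single bilateral region -> two mirrored lateral dipoles;
    * each additional region token contributes one dipole, lateralized if it
      names a side, at the region midline otherwise;
    * rows naming more than two regions keep the first two.
    """
    scale = head_radius / 85.0
    text = spec.strip()
    row_side = "midline"
    if "," in text:
        text, qualifier = (part.strip() for part in text.rsplit(",", 1))
        row_side = qualifier.lower()
    entries: list[tuple[str, str]] = []
    for token in text.split("/"):
        words = token.strip().lower().split()
        side = row_side
        if words[0] in ("left", "right", "bilateral"):
            side = words[0]
            words = words[1:]
        region = " ".join(words)
        if region not in REGION_COORDS:
            raise ValueError(f"unknown region {region!r} in {spec!r}")
        entries.append((region, side))
    if len(entries) == 1 and entries[0][1] == "bilateral":
        region = entries[0][0]
        dipoles = [_place(region, "left", scale), _place(region, "right", scale)]
    else:
        dipoles = []
        for region, side in entries[:2]:
            dipoles.append(_place(region, side if side in ("left", "right") else "midline", scale))
    label = spec.strip()
    return label, dipoles


@dataclass(frozen=True)
class CognitiveModule:
    """A locally generated cognitive function with 1-2 dipole sources."""

    name: str
    anatomical_label: str
    dipole_specs: tuple[Dipole, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dipole_specs", tuple(self.dipole_specs))
        if not 1 <= len(self.dipole_specs) <= 2:
            raise ValueError("a module generates between one and two dipoles")


@dataclass(frozen=True)
class SpikeEvent:
    """Triangular activation spike of one module."""

    module: CognitiveModule
    peak_time: float  # ms
    half_width: float = 50.0  # ms
    amplitude: float = 1.0  # relative units

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError(f"half_width must be > 0, got {self.half_width}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class ModuleSchedule:
    """Ordered module activations for one task."""

    task: str
    events: tuple[SpikeEvent, ...]
    window: tuple[float, float] = (-200.0, 1000.0)

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.peak_time))
        object.__setattr__(self, "events", events)
        lo, hi = self.window
        for event in events:
            if not lo <= event.peak_time <= hi:
                raise ValueError(
                    f"event peak {event.peak_time} ms outside epoch window {self.window}"
                )

    def with_amplitudes(self, amplitudes: np.ndarray) -> "ModuleSchedule":
        if len(amplitudes) != len(self.events):
            raise ValueError("one amplitude per event required")
        events = tuple(
            replace(event, amplitude=float(a)) for event, a in zip(self.events, amplitudes)
        )
        return replace(self, events=events)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "window": list(self.window),
            "events": [
                {
                    "module": {
                        "name": event.module.name,
                        "anatomical_label": event.module.anatomical_label,
                        "dipoles": [
                            {
                                "location": dip.location.tolist(),
                                "orientation": dip.orientation.tolist(),
                                "strength_p": dip.strength_p,
                            }
                            for dip in event.module.dipole_specs
                        ],
                    },
                    "peak_time": event.peak_time,
                    "half_width": event.half_width,
                    "amplitude": event.amplitude,
                }
                for event in self.events
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ModuleSchedule":
        events = []
        for entry in payload["events"]:
            module = CognitiveModule(
                name=entry["module"]["name"],
                anatomical_label=entry["module"]["anatomical_label"],
                dipole_specs=tuple(
                    Dipole(d["location"], d["orientation"], d["strength_p"])
                    for d in entry["module"]["dipoles"]
                ),
            )
            events.append(
                SpikeEvent(
                    module=module,
                    peak_time=entry["peak_time"],
                    half_width=entry["half_width"],
                    amplitude=entry["amplitude"],
                )
            )
        return cls(task=payload["task"], events=tuple(events), window=tuple(payload["window"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModuleSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Task schedules: module peak times (ms) and generating regions
# ---------------------------------------------------------------------------

# Viewing-pictures column drives both the attention task and the PPVT
# picture-display event; word verification has its own column.  Rows absent
# from a column are omitted.
_VIEWING_PICTURES: tuple[tuple[float, str], ...] = (
    (100.0, "Occipital/Basal, Bilateral"),
    (125.0, "Parietal/Basal, Bilateral"),
    (170.0, "Right Occipital/Left Frontal"),
    (220.0, "Basal, Bilateral"),
    (280.0, "Parietal/Frontal, Bilateral"),
    (320.0, "Right Parietal/Right Temporal"),
    (380.0, "Left Parietal"),
    (690.0, "Left Occipital/Left Basal"),
)

_WORD_VERIFICATION: tuple[tuple[float, str], ...] = (
    (100.0, "Bilateral Occipital/Right Frontal"),
    (125.0, "Parietal/Basal, Bilateral"),
    (170.0, "Right Occipital/Left Frontal"),
    (280.0, "Left Frontal/Left Occipital/Right Temporal"),
    (320.0, "Left Frontal/Left Occipital/Right Temporal"),
    (380.0, "Left Frontal/Left Occipital/Right Temporal"),
    (690.0, "Left Occipital"),
    (850.0, "Right Occipital/Bilateral Temporal"),
)

TASKS = ("attention", "ppvt_pictures", "ppvt_word")


def build_schedule(
    task: str,
    half_width: float = 50.0,
    amplitude: float = 1.0,
    head_radius: float = 85.0,
    window: tuple[float, float] = (-200.0, 1000.0),
) -> ModuleSchedule:
    """Module activation schedule for one of the three supported task labels.

    ``attention`` and ``ppvt_pictures`` use the viewing-pictures column;
    ``ppvt_word`` uses the word-verification column.
    """
    if task in ("attention", "ppvt_pictures"):
        rows = _VIEWING_PICTURES
    elif task == "ppvt_word":
        rows = _WORD_VERIFICATION
    else:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    events = []
    for peak_time, region_spec in rows:
        label, dipoles = region_dipoles(region_spec, head_radius)
        module = CognitiveModule(
            name=f"{task}@{peak_time:g}ms",
            anatomical_label=label,
            dipole_specs=tuple(dipoles),
        )
        events.append(
            SpikeEvent(
                module=module, peak_time=peak_time, half_width=half_width, amplitude=amplitude
            )
        )
    return ModuleSchedule(task=task, events=tuple(events), window=window)


def spike_waveform(event: SpikeEvent, time_grid: np.ndarray) -> np.ndarray:
    """Triangular activation timecourse on a time grid (ms).

    Zero outside ``[peak - half_width, peak + half_width]``, rising linearly
    to ``amplitude`` at the peak and dropping at the same rate.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or (t.size > 1 and not np.all(np.diff(t) > 0)):
        raise ValueError("time grid must be 1-D and strictly increasing")
    return event.amplitude * np.clip(1.0 - np.abs(t - event.peak_time) / event.half_width, 0.0, None)
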