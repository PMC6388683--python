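"""Spherical head geometry, electrode montage and the Coulomb dipole forward model.

The scalp potential of an equivalent current dipole is computed directly from
Coulomb's law, ``V = k * p * cos(theta) / r**2``, where ``p`` is the dipole
strength, ``r`` the electrode-to-dipole distance and ``theta`` the angle
between the dipole orientation and the dipole-to-electrode vector.  The head
is a single homogeneous sphere and potentials are expressed in relative
units, so the field constant ``k`` never needs a physical value.

Coordinate convention: right-handed head frame in millimetres with the origin
at the sphere centre, +x toward the right ear, +y toward the nasion and +z
toward the vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HeadModel",
    "ElectrodeMontage",
    "Dipole",
    "FieldGeometry",
    "GeometryError",
    "DEFAULT_ELECTRODES",
    "compute_geometry",
    "dipole_potential",
    "leadfield",
    "project_sources",
]


class GeometryError(ValueError):
    """Raised for degenerate source/sensor geometry (e.g. r = 0)."""


# Idealized 10-20 positions on the unit sphere (x right, y anterior, z up).
# Midline sites lie on the nasion-inion great circle; temporal/occipito-
# temporal sites lie on the equator through the pre-auricular points.
# Stored as data, not computed; scaled to the scalp radius at montage build.
_UNIT_1020 = {
    "Cz": (0.0, 0.0, 1.0),
    "Fz": (0.0, 0.70710678, 0.70710678),
    "Pz": (0.0, -0.70710678, 0.70710678),
    "Oz": (0.0, -1.0, 0.0),
    "O1": (-0.30901699, -0.95105652, 0.0),
    "O2": (0.30901699, -0.95105652, 0.0),
    "P7": (-0.80901699, -0.58778525, 0.0),
    "P8": (0.80901699, -0.58778525, 0.0),
    "T7": (-1.0, 0.0, 0.0),
    "T8": (1.0, 0.0, 0.0),
    "F3": (-0.54500000, 0.67300000, 0.50000000),
    "F4": (0.54500000, 0.67300000, 0.50000000),
}

DEFAULT_ELECTRODES = ("Cz", "F3", "F4", "Fz", "O1", "O2", "Oz", "P7", "P8", "Pz", "T7", "T8")


@dataclass(frozen=True)
class HeadModel:
    """Single homogeneous sphere.

    Parameters
    ----------
    scalp_radius : float
        Sphere radius in mm.  85 mm is a child-sized default; configurable so
        results stay reportable in mm for other head sizes.
    field_constant_k : float
        Dimensionless field scale.  Only relative magnitudes matter, so the
        default of 1 is never changed in practice.
    """

    scalp_radius: float = 85.0
    field_constant_k: float = 1.0

    def __post_init__(self) -> None:
        if not self.scalp_radius > 0:
            raise ValueError(f"scalp_radius must be > 0, got {self.scalp_radius}")
        if not self.field_constant_k > 0:
            raise ValueError(f"field_constant_k must be > 0, got {self.field_constant_k}")


@dataclass(frozen=True)
class ElectrodeMontage:
    """Named electrode positions on the scalp sphere (mm)."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_electrodes, 3)
    scalp_radius: float = 85.0

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if positions.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {positions.shape} does not match {len(self.labels)} labels"
            )
        norms = np.linalg.norm(positions, axis=1)
        if not np.allclose(norms, self.scalp_radius, rtol=1e-6):
            raise ValueError("every electrode must lie on the scalp sphere")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage {self.labels}") from None

    @classmethod
    def default(cls, head: HeadModel | None = None) -> "ElectrodeMontage":
        """The study's 12-site 10-20 montage scaled to the head radius."""
        head = head or HeadModel()
        unit = np.array([_UNIT_1020[name] for name in DEFAULT_ELECTRODES])
        unit /= np.linalg.norm(unit, axis=1, keepdims=True)
        return cls(DEFAULT_ELECTRODES, unit * head.scalp_radius, head.scalp_radius)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        frame.insert(0, "label", list(self.labels))
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, scalp_radius: float | None = None) -> "ElectrodeMontage":
        frame = pd.read_csv(path, sep="\t")
        positions = frame[["x", "y", "z"]].to_numpy(dtype=float)
        if scalp_radius is None:
            scalp_radius = float(np.linalg.norm(positions, axis=1).mean())
        return cls(tuple(frame["label"]), positions, scalp_radius)


@dataclass(frozen=True)
class Dipole:
    """Equivalent current dipole inside the head sphere.

    ``strength_p`` is a relative charge-moment magnitude; the signed moment
    vector is ``strength_p * orientation``.
    """

    location: np.ndarray  # (3,) mm
    orientation: np.ndarray  # (3,) unit vector
    strength_p: float = 1.0

    def __post_init__(self) -> None:
        location = np.asarray(self.location, dtype=float).reshape(3)
        orientation = np.asarray(self.orientation, dtype=float).reshape(3)
        norm = np.linalg.norm(orientation)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError("orientation must be a non-zero finite vector")
        orientation = orientation / norm
        object.__setattr__(self, "location", location)
        object.__setattr__(self, "orientation", orientation)
        if not np.all(np.isfinite(location)):
            raise ValueError("dipole location must be finite")
        if self.strength_p < 0:
            raise ValueError(f"strength_p must be >= 0, got {self.strength_p}")

    def inside(self, head: HeadModel) -> bool:
        return bool(np.linalg.norm(self.location) < head.scalp_radius)

    def moment(self) -> np.ndarray:
        return self.strength_p * self.orientation


@dataclass(frozen=True)
class FieldGeometry:
    """Distance and angle linking one dipole to one electrode."""

    r: float  # mm, > 0
    theta: float  # radians in [0, pi]

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise GeometryError(f"r must be > 0, got {self.r}")
        if not 0.0 <= self.theta <= np.pi + 1e-12:
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")


def compute_geometry(dipole: Dipole, electrode_position: np.ndarray) -> FieldGeometry:
    """Euclidean distance and orientation angle from dipole to electrode.

    ``theta`` is measured between the dipole orientation and the vector from
    the dipole location toward the electrode.
    """
    electrode_position = np.asarray(electrode_position, dtype=float).reshape(3)
    delta = electrode_position - dipole.location
    r = float(np.linalg.norm(delta))
    if r == 0.0:
        raise GeometryError("electrode coincides with the dipole location (r = 0)")
    cos_theta = float(np.dot(dipole.orientation, delta) / r)
    theta = float(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    return FieldGeometry(r=r, theta=theta)


def dipole_potential(
    dipole: Dipole, electrode_position: np.ndarray, head: HeadModel | None = None
) -> float:
    """Scalp potential ``k * p * cos(theta) / r**2`` in relative units."""
    head = head or HeadModel()
    electrode_position = np.asarray(electrode_position, dtype=float).reshape(3)
    if not np.all(np.isfinite(electrode_position)):
        raise ValueError("electrode position must be finite")
    geom = compute_geometry(dipole, electrode_position)
    return head.field_constant_k * dipole.strength_p * np.cos(geom.theta) / geom.r**2


def _gain(electrode_positions: np.ndarray, location: np.ndarray, k: float) -> np.ndarray:
    """Per-electrode gain vectors: potential is ``gain @ moment``.

    ``k * p * cos(theta) / r**2 == k * (moment . delta) / r**3`` with
    ``delta = electrode - location``, so the potential is linear in the
    moment vector.  Returns shape (n_electrodes, 3).
    """
    delta = electrode_positions - location[None, :]
    r = np.linalg.norm(delta, axis=1)
    if np.any(r == 0):
        raise GeometryError("electrode coincides with the dipole location (r = 0)")
    return k * delta / r[:, None] ** 3


def leadfield(
    montage: ElectrodeMontage, dipoles: list[Dipole], head: HeadModel | None = None
) -> np.ndarray:
    """Unit-strength potentials, shape (n_electrodes, n_dipoles).

    Column d holds :func:`dipole_potential` of dipole d with ``strength_p = 1``
    at every electrode; multiplying by a vector of source strengths and
    summing columns realizes the superposition of dipole contributions.
    """
    head = head or HeadModel()
    if len(montage) < 1 or len(dipoles) < 1:
        raise ValueError("need at least one electrode and one dipole")
    columns = []
    for dip in dipoles:
        if not dip.inside(head):
            raise ValueError(
                f"dipole at {dip.location} lies outside the scalp sphere (R={head.scalp_radius})"
            )
        gain = _gain(montage.positions, dip.location, head.field_constant_k)
        columns.append(gain @ dip.orientation)
    return np.column_stack(columns)


def project_sources(L: np.ndarray, source_timecourses: np.ndarray) -> np.ndarray:
    """Scalp signal as the summed contribution of all dipoles: ``L @ S``."""
    L = np.asarray(L, dtype=float)
    S = np.asarray(source_timecourses, dtype=float)
    if L.ndim != 2 or S.ndim != 2 or L.shape[1] != S.shape[0]:
        raise ValueError(
            f"shape mismatch: leadfield {L.shape} vs source timecourses {S.shape}"
        )
    return L @ S
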