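"""Coordinate frames, electrode and sensor-array geometry, landmark
co-registration, and error metrics.

Conventions
-----------
* Right-handed MEG head frame.  Electrode poses, search grids and landmark
  coordinates are expressed in **millimetres**; sensor positions are stored in
  **metres**, the scale at which magnetic fields are evaluated.  The
  millimetre-to-metre conversion happens once, at the forward-model boundary.
* The electrode axis is the unit vector from the tip towards the uppermost
  ring contact (C8).  Axial rotation ``rot`` is measured in degrees about this
  axis; by convention segmented contact C2 sits at azimuth ``rot`` relative to
  the frame's +x direction projected off-axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DegenerateGeometryError, ParameterError

__all__ = [
    "SensorArray",
    "ElectrodeGeometry",
    "ElectrodePose",
    "RigidTransform",
    "FiducialSet",
    "ContactSite",
    "CONTACT_LAYOUT",
    "make_helmet_array",
    "contact_centroids",
    "fit_rigid_transform",
    "localization_error",
    "angular_error",
    "read_sensor_array",
    "write_sensor_array",
    "read_fiducials",
    "write_fiducials",
]

_UNIT_TOL = 1e-9

#: Fixed contact layout of the 1-3-3-1 segmented lead: label -> (level,
#: segment index) where segment is ``"ring"`` for the full-circumference
#: contacts and 0..2 for the three 90-degree segments of the middle levels.
CONTACT_LAYOUT: dict[str, tuple[int, int | str]] = {
    "C1": (0, "ring"),
    "C2": (1, 0),
    "C3": (1, 1),
    "C4": (1, 2),
    "C5": (2, 0),
    "C6": (2, 1),
    "C7": (2, 2),
    "C8": (3, "ring"),
}


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise ParameterError(f"{name} must be a finite non-zero 3-vector")
    return v / n


@dataclass(frozen=True)
class SensorArray:
    """Magnetometer positions (metres) and unit measurement orientations."""

    ids: tuple[str, ...]
    positions: np.ndarray  # (n, 3) metres
    orientations: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self):
        ids = tuple(str(i) for i in self.ids)
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if len(ids) < 1:
            raise ParameterError("sensor array needs at least one sensor")
        if len(set(ids)) != len(ids):
            raise ParameterError("sensor ids must be unique")
        if pos.shape != (len(ids), 3) or ori.shape != (len(ids), 3):
            raise ParameterError("positions/orientations must be (n, 3)")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ParameterError("sensor orientations must be unit vectors")
        # re-normalise to machine precision so downstream checks at 1e-9 pass
        ori = ori / norms[:, None]
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, sensor_id: str) -> int:
        return self.ids.index(sensor_id)

    def subset(self, indices: Sequence[int]) -> "SensorArray":
        idx = np.asarray(indices, dtype=int)
        return SensorArray(
            tuple(self.ids[i] for i in idx),
            self.positions[idx],
            self.orientations[idx],
        )


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Dimensions of the segmented lead (all lengths in millimetres).

    Defaults reproduce the ~2 mm spacing between consecutive contact-level
    centroids of a 1-3-3-1 directional lead.
    """

    lead_radius: float = 0.65
    contact_length: float = 1.5
    inter_level_gap: float = 0.5
    tip_to_first_contact: float = 0.6
    segment_span: float = 90.0
    segment_gap: float = 30.0
    layout: Mapping[str, tuple[int, int | str]] = field(
        default_factory=lambda: dict(CONTACT_LAYOUT)
    )

    def __post_init__(self):
        for name in ("lead_radius", "contact_length", "inter_level_gap",
                     "tip_to_first_contact"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if abs(3 * (self.segment_span + self.segment_gap) - 360.0) > 1e-9:
            raise ParameterError(
                "segment_span + segment_gap must divide 360 exactly 3 times"
            )

    @property
    def level_pitch(self) -> float:
        """Distance between consecutive level centroids (mm)."""
        return self.contact_length + self.inter_level_gap

    def level_height(self, level: int) -> float:
        """Axial distance (mm) from the tip to the centroid of *level*."""
        return (
            self.tip_to_first_contact
            + level * self.level_pitch
            + self.contact_length / 2.0
        )


@dataclass(frozen=True)
class ElectrodePose:
    """Tip position (mm), axis direction (unit, tip -> C8) and axial rotation
    ``rot`` in degrees, wrapped into [0, 360)."""

    tip: np.ndarray
    axis: np.ndarray
    rot: float = 0.0

    def __post_init__(self):
        tip = np.asarray(self.tip, dtype=float).reshape(3)
        axis = _as_unit(self.axis, "axis")
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "rot", float(self.rot) % 360.0)

    def translated(self, offset) -> "ElectrodePose":
        return ElectrodePose(self.tip + np.asarray(offset, float), self.axis, self.rot)

    def with_rot(self, rot: float) -> "ElectrodePose":
        return ElectrodePose(self.tip, self.axis, rot)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map x -> rotation @ x + translation (mm)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-6:
            raise ParameterError("rotation must be orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ParameterError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


_REQUIRED_FIDUCIALS = ("nasion", "lpa", "rpa")


@dataclass(frozen=True)
class FiducialSet:
    """Named anatomical landmarks (mm).  Nasion, LPA and RPA are required and
    must be non-collinear; extra named points are allowed."""

    points: Mapping[str, np.ndarray]

    def __post_init__(self):
        pts = {str(k).lower(): np.asarray(v, float).reshape(3)
               for k, v in self.points.items()}
        missing = [n for n in _REQUIRED_FIDUCIALS if n not in pts]
        if missing:
            raise ParameterError(f"missing required landmarks: {missing}")
        a, b, c = (pts[n] for n in _REQUIRED_FIDUCIALS)
        area = np.linalg.norm(np.cross(b - a, c - a))
        if area < 1e-9:
            raise DegenerateGeometryError("nasion/LPA/RPA are collinear")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name.lower()]

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)


@dataclass(frozen=True)
class ContactSite:
    """Centroid (mm) of one contact plus, for segmented contacts, the outward
    radial unit vector; ``radial`` is None for ring contacts."""

    position: np.ndarray
    radial: np.ndarray | None


def axis_frame(axis) -> tuple[np.ndarray, np.ndarray]:
    """Return the (e1, e2) right-handed basis perpendicular to *axis*.

    e1 is the frame's +x projected off-axis (falling back to +y when the axis
    is parallel to x); e2 = axis x e1, so azimuths rotate right-handedly about
    the axis.
    """
    a = _as_unit(axis, "axis")
    for ref in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
        e1 = ref - np.dot(ref, a) * a
        n = np.linalg.norm(e1)
        if n > 1e-6:
            return e1 / n, np.cross(a, e1 / n)
    raise DegenerateGeometryError("could not build a frame for the axis")


def make_helmet_array(
    n_sensors: int,
    radius: float = 120.0,
    coverage_deg: float = 120.0,
    seed: int = 0,
) -> SensorArray:
    """Quasi-uniform magnetometer cap on a sphere (synthetic helmet).

    Sensors are laid out on a Fibonacci lattice over the spherical cap of
    half-angle ``coverage_deg`` measured from the +z apex, at ``radius``
    millimetres from the head origin.  Orientations are the outward surface
    normals.  ``seed`` fixes the azimuthal phase of the lattice; the layout is
    deterministic for a fixed seed.
    """
    if n_sensors < 1:
        raise ParameterError("n_sensors must be >= 1")
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if not (0 < coverage_deg <= 180):
        raise ParameterError("coverage_deg must be in (0, 180]")
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2 * np.pi)
    if n_sensors == 1:
        unit = np.array([[0.0, 0.0, 1.0]])
    else:
        zmin = np.cos(np.radians(coverage_deg))
        i = np.arange(n_sensors)
        z = 1.0 - (i + 0.5) / n_sensors * (1.0 - zmin)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        phi = phi0 + i * golden
        rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        unit = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    ids = tuple(f"M{i:03d}" for i in range(n_sensors))
    return SensorArray(ids, radius * 1e-3 * unit, unit)


def contact_centroids(
    geometry: ElectrodeGeometry, pose: ElectrodePose
) -> dict[str, ContactSite]:
    """Centroid positions (mm) and outward radial directions of all contacts.

    Ring contacts (C1, C8) sit on the electrode axis; segmented contacts sit
    at ``lead_radius`` from the axis at azimuths ``rot + k*120`` degrees
    (C2/C5 at ``rot`` by convention).
    """
    e1, e2 = axis_frame(pose.axis)
    seg_step = geometry.segment_span + geometry.segment_gap
    out: dict[str, ContactSite] = {}
    for label, (level, seg) in geometry.layout.items():
        center = pose.tip + geometry.level_height(level) * pose.axis
        if seg == "ring":
            out[label] = ContactSite(center, None)
        else:
            az = np.radians(pose.rot + seg * seg_step)
            radial = np.cos(az) * e1 + np.sin(az) * e2
            out[label] = ContactSite(center + geometry.lead_radius * radial, radial)
    return out


def fit_rigid_transform(source, target) -> RigidTransform:
    """Closed-form orthogonal-Procrustes (Kabsch) landmark alignment.

    ``source``/``target`` are either matching (n, 3) arrays (n >= 3) or
    mappings from landmark name to 3-vector with matching keys.  Returns the
    proper rigid transform minimising the sum of squared residuals.
    """
    if isinstance(source, Mapping) and isinstance(target, Mapping):
        keys = sorted(set(source) & set(target))
        if len(keys) < 3:
            raise ParameterError("need >= 3 shared labelled points")
        src = np.array([np.asarray(source[k], float).reshape(3) for k in keys])
        tgt = np.array([np.asarray(target[k], float).reshape(3) for k in keys])
    else:
        src = np.atleast_2d(np.asarray(source, float))
        tgt = np.atleast_2d(np.asarray(target, float))
    if src.shape != tgt.shape or src.shape[0] < 3 or src.shape[1] != 3:
        raise ParameterError("need matching (n, 3) point sets with n >= 3")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    a, b = src - cs, tgt - ct
    u, s, vt = np.linalg.svd(a.T @ b)
    if s[1] <= 1e-9 * max(s[0], 1e-300):
        raise DegenerateGeometryError("landmarks are (numerically) collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, ct - rot @ cs)


def localization_error(estimated, truth) -> float:
    """Euclidean distance (mm) between an estimated and a true position."""
    est = np.asarray(estimated, float).reshape(3)
    tru = np.asarray(truth, float).reshape(3)
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(tru))):
        raise ParameterError("coordinates must be finite")
    return float(np.linalg.norm(est - tru))


def angular_error(a: float, b: float) -> float:
    """Absolute circular difference between two angles, degrees in [0, 180]."""
    d = abs(float(a) - float(b)) % 360.0
    return float(min(d, 360.0 - d))


# ---------------------------------------------------------------------------
# File interfaces

_SENSOR_HEADER = ["id", "x_m", "y_m", "z_m", "nx", "ny", "nz"]


def write_sensor_array(array: SensorArray, path) -> None:
    """Tab-separated sensor file: ``id  x_m  y_m  z_m  nx  ny  nz``."""
    lines = ["\t".join(_SENSOR_HEADER)]
    for i, sid in enumerate(array.ids):
        p, o = array.positions[i], array.orientations[i]
        lines.append("\t".join([sid] + [f"{v:.12e}" for v in (*p, *o)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sensor_array(path) -> SensorArray:
    rows = [ln.split("\t") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not rows or [c.strip() for c in rows[0]] != _SENSOR_HEADER:
        raise ParameterError(f"bad sensor-file header in {path}")
    ids, pos, ori = [], [], []
    for row in rows[1:]:
        ids.append(row[0])
        vals = [float(v) for v in row[1:7]]
        pos.append(vals[:3])
        ori.append(vals[3:])
    return SensorArray(tuple(ids), np.array(pos), np.array(ori))


def write_fiducials(fiducials: FiducialSet, path) -> None:
    """Tab-separated fiducial file: ``name  x_mm  y_mm  z_mm``."""
    lines = ["name\tx_mm\ty_mm\tz_mm"]
    for name in fiducials.names():
        p = fiducials[name]
        lines.append("\t".join([name] + [f"{v:.6f}" for v in p]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fiducials(path) -> FiducialSet:
    rows = [ln.split("\t") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not rows or [c.strip().lower() for c in rows[0][:1]] != ["name"]:
        raise ParameterError(f"bad fiducial-file header in {path}")
    pts = {row[0]: [float(v) for v in row[1:4]] for row in rows[1:]}
    return FiducialSet(pts)
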