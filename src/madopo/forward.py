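"""Quasi-static magnetic forward models.

Two source models predict the signed field component measured by each
magnetometer for a given electrode pose and bipolar stimulation
configuration:

* ``"dipole"`` — a single equivalent current dipole at the centre of
  stimulation, with moment Q = I*d pointing from the fraction-weighted anode
  centroid towards the cathode centroid (the direction of conventional
  current flow through the medium).  This is the classic infinite
  homogeneous-medium Biot-Savart current-dipole field.
* ``"distributed"`` — every cathode/anode contact pair contributes its
  fraction-weighted current, split into ``n_path`` collinear dipole elements
  along the straight centroid-to-centroid path.  This serves as the fine
  source model for post-localization and orientation scanning; it reduces
  exactly to the equivalent dipole for single-pair configurations with
  ``n_path=1`` and converges to it in the far field.

Both models neglect volume-conduction (boundary) currents: for bipolar
configurations the primary current is confined to a few millimetres around
the lead while the sensors sit ~10 cm away, where the dipolar term dominates.

Units are SI inside this module (tesla, metres, amperes); poses and contact
geometry arrive in millimetres and are converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import AlignmentError, ParameterError, SingularityError
from .geometry import (
    ContactSite,
    ElectrodeGeometry,
    ElectrodePose,
    SensorArray,
    contact_centroids,
)

__all__ = [
    "MU0",
    "CurrentDipole",
    "StimConfig",
    "FieldMap",
    "dipole_field",
    "project_normal",
    "config_equivalent_dipole",
    "config_distributed_dipoles",
    "predict_fieldmap",
    "attenuation_db",
    "tangential_fraction",
    "fieldmaps_for_tips",
    "read_fieldmap",
    "write_fieldmap",
    "read_protocol",
    "write_protocol",
    "FAMILIES",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A
_K = MU0 / (4 * np.pi)
_MIN_DIST = 1e-9  # metres; below this the evaluation point is "on" a source

FAMILIES = ("vertical", "diagonal", "horizontal", "symmetrical")


@dataclass(frozen=True)
class CurrentDipole:
    """Point current dipole: location (m) and moment (A*m)."""

    location: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        loc = np.asarray(self.location, float).reshape(3)
        mom = np.asarray(self.moment, float).reshape(3)
        if not (np.all(np.isfinite(loc)) and np.all(np.isfinite(mom))):
            raise ParameterError("dipole location/moment must be finite")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "moment", mom)


@dataclass(frozen=True)
class StimConfig:
    """Bipolar stimulation configuration.

    ``cathode`` and ``anode`` map contact labels to current fractions (each
    side sums to 1); ``amplitude`` is the total stimulation current in
    amperes; ``family`` classifies the current-flow direction (vertical,
    diagonal, horizontal or symmetrical).
    """

    label: str
    cathode: Mapping[str, float]
    anode: Mapping[str, float]
    amplitude: float
    family: str

    def __post_init__(self):
        cat = {str(k): float(v) for k, v in self.cathode.items()}
        ano = {str(k): float(v) for k, v in self.anode.items()}
        if not cat or not ano:
            raise ParameterError("cathode and anode sets must be non-empty")
        for name, side in (("cathode", cat), ("anode", ano)):
            if abs(sum(side.values()) - 1.0) > 1e-6:
                raise ParameterError(f"{name} fractions must sum to 1")
        if set(cat) & set(ano):
            raise ParameterError("cathode and anode sets must be disjoint")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be > 0")
        if self.family not in FAMILIES:
            raise ParameterError(f"family must be one of {FAMILIES}")
        object.__setattr__(self, "cathode", cat)
        object.__setattr__(self, "anode", ano)
        object.__setattr__(self, "amplitude", float(self.amplitude))

    def swapped(self) -> "StimConfig":
        """Same configuration with cathode and anode exchanged."""
        return StimConfig(self.label, self.anode, self.cathode,
                          self.amplitude, self.family)


@dataclass(frozen=True)
class FieldMap:
    """One signed scalar field value (tesla) per sensor, keyed by sensor id."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        ids = tuple(str(i) for i in self.ids)
        vals = np.asarray(self.values, float).reshape(len(ids))
        if len(set(ids)) != len(ids):
            raise ParameterError("field-map sensor ids must be unique")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("field-map values must be finite")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.ids)

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        """Values reordered to the given id sequence (keys must match)."""
        ids = tuple(str(i) for i in ids)
        if set(ids) != set(self.ids):
            raise AlignmentError("field map and sensor array key sets differ")
        if ids == self.ids:
            return self.values.copy()
        lookup = {s: i for i, s in enumerate(self.ids)}
        return self.values[[lookup[s] for s in ids]]

    def scaled(self, factor: float) -> "FieldMap":
        return FieldMap(self.ids, self.values * factor)

    def __neg__(self) -> "FieldMap":
        return FieldMap(self.ids, -self.values)


# ---------------------------------------------------------------------------
# Field evaluation

def dipole_field(dipole: CurrentDipole, point) -> np.ndarray:
    """Magnetic flux density (T) of a current dipole at ``point`` (m).

    B(R) = (mu0 / 4 pi) * Q x (R - L) / |R - L|^3.
    """
    pts = np.asarray(point, float)
    r = pts - dipole.location
    dist = np.linalg.norm(r, axis=-1)
    if np.any(dist < _MIN_DIST):
        raise SingularityError("field evaluation at the dipole location")
    b = _K * np.cross(np.broadcast_to(dipole.moment, r.shape), r)
    return b / np.expand_dims(dist**3, -1)


def project_normal(field, sensor_orientation) -> float | np.ndarray:
    """Signed component of a field vector along a unit sensor orientation."""
    s = np.asarray(sensor_orientation, float)
    if np.any(np.abs(np.linalg.norm(s, axis=-1) - 1.0) > 1e-6):
        raise ParameterError("sensor orientation must be a unit vector")
    return np.sum(np.asarray(field, float) * s, axis=-1)


def _weighted_centroid(side: Mapping[str, float],
                       sites: Mapping[str, ContactSite]) -> np.ndarray:
    return sum(frac * sites[c].position for c, frac in side.items())


def config_equivalent_dipole(
    pose: ElectrodePose,
    geometry: ElectrodeGeometry,
    config: StimConfig,
) -> CurrentDipole:
    """Single equivalent dipole of a bipolar configuration.

    Located midway between the fraction-weighted cathode and anode centroids;
    moment = amplitude * (cathode_centroid - anode_centroid), i.e. pointing
    from anode to cathode, in A*m.
    """
    sites = contact_centroids(geometry, pose)
    c_cat = _weighted_centroid(config.cathode, sites)
    c_ano = _weighted_centroid(config.anode, sites)
    location_m = 1e-3 * (c_cat + c_ano) / 2.0
    moment = config.amplitude * 1e-3 * (c_cat - c_ano)
    return CurrentDipole(location_m, moment)


def config_distributed_dipoles(
    pose: ElectrodePose,
    geometry: ElectrodeGeometry,
    config: StimConfig,
    n_path: int = 7,
) -> list[CurrentDipole]:
    """Distributed source: per cathode/anode pair, ``n_path`` collinear
    elements along the straight centroid-to-centroid path.

    Pair (i, j) carries current amplitude * f_i * f_j; the summed moment over
    all elements equals the equivalent dipole's moment exactly.
    """
    if n_path < 1:
        raise ParameterError("n_path must be >= 1")
    sites = contact_centroids(geometry, pose)
    dipoles: list[CurrentDipole] = []
    offsets = (np.arange(n_path) + 0.5) / n_path
    for ci, fi in config.cathode.items():
        for cj, fj in config.anode.items():
            p_cat = sites[ci].position
            p_ano = sites[cj].position
            pair_moment = config.amplitude * fi * fj * 1e-3 * (p_cat - p_ano)
            for t in offsets:
                loc_mm = p_ano + t * (p_cat - p_ano)
                dipoles.append(CurrentDipole(1e-3 * loc_mm, pair_moment / n_path))
    return dipoles


def _config_dipoles(pose, geometry, config, model, n_path):
    if model == "dipole":
        return [config_equivalent_dipole(pose, geometry, config)]
    if model == "distributed":
        return config_distributed_dipoles(pose, geometry, config, n_path)
    raise ParameterError("model must be 'dipole' or 'distributed'")


def predict_fieldmap(
    pose: ElectrodePose,
    config: StimConfig,
    sensors: SensorArray,
    geometry: ElectrodeGeometry | None = None,
    model: str = "dipole",
    n_path: int = 7,
) -> FieldMap:
    """Predicted signed field component (T) at every sensor.

    Linear in the stimulation amplitude; swapping cathode and anode negates
    the map.
    """
    geometry = geometry or ElectrodeGeometry()
    dipoles = _config_dipoles(pose, geometry, config, model, n_path)
    values = np.zeros(len(sensors))
    for d in dipoles:
        b = dipole_field(d, sensors.positions)
        values += np.sum(b * sensors.orientations, axis=1)
    return FieldMap(sensors.ids, values)


def predict_field_vectors(
    pose: ElectrodePose,
    config: StimConfig,
    sensors: SensorArray,
    geometry: ElectrodeGeometry | None = None,
    model: str = "dipole",
    n_path: int = 7,
) -> np.ndarray:
    """Full 3-vector field (T) at every sensor position, shape (n, 3)."""
    geometry = geometry or ElectrodeGeometry()
    dipoles = _config_dipoles(pose, geometry, config, model, n_path)
    vec = np.zeros((len(sensors), 3))
    for d in dipoles:
        vec += dipole_field(d, sensors.positions)
    return vec


def fieldmaps_for_tips(
    tips_mm: np.ndarray,
    dipole_offsets_mm: np.ndarray,
    dipole_moments: np.ndarray,
    sensors: SensorArray,
    chunk: int = 4096,
) -> np.ndarray:
    """Batched projected maps for many candidate tip positions.

    The source is a fixed set of dipoles expressed as offsets (mm) from the
    electrode tip with fixed moments (A*m); only the tip translates.  Returns
    an (n_tips, n_sensors) array of projected field values (T).  Used by the
    grid scans, where the pose axis and rotation are held fixed.
    """
    tips = np.atleast_2d(np.asarray(tips_mm, float))
    offs = np.atleast_2d(np.asarray(dipole_offsets_mm, float))
    moms = np.atleast_2d(np.asarray(dipole_moments, float))
    pos = sensors.positions  # (s, 3) m
    ori = sensors.orientations
    out = np.zeros((tips.shape[0], pos.shape[0]))
    for start in range(0, tips.shape[0], chunk):
        block = tips[start:start + chunk]
        acc = np.zeros((block.shape[0], pos.shape[0]))
        for off, q in zip(offs, moms):
            loc = 1e-3 * (block + off)  # (m, 3)
            r = pos[None, :, :] - loc[:, None, :]  # (m, s, 3)
            dist = np.linalg.norm(r, axis=2)
            if np.any(dist < _MIN_DIST):
                raise SingularityError("candidate source coincides with a sensor")
            # B . s = k * q . (r x s) / |r|^3
            rxs = np.cross(r, ori[None, :, :])
            acc += _K * (rxs @ q) / dist**3
        out[start:start + chunk] = acc
    return out


def attenuation_db(factor: float) -> float:
    """Attenuation in dB of a positive amplitude ratio: 10*log10(factor)."""
    if factor <= 0:
        raise ParameterError("factor must be > 0")
    return float(10.0 * np.log10(factor))


def tangential_fraction(field_vectors: np.ndarray,
                        sensors: SensorArray) -> np.ndarray:
    """Per-sensor |tangential| / |total| field ratio, in [0, 1].

    Sensors with zero field magnitude get NaN (undefined / missing).
    """
    vec = np.atleast_2d(np.asarray(field_vectors, float))
    if vec.shape != (len(sensors), 3):
        raise ParameterError("field_vectors must be (n_sensors, 3)")
    normal = np.sum(vec * sensors.orientations, axis=1)
    tang = vec - normal[:, None] * sensors.orientations
    total = np.linalg.norm(vec, axis=1)
    out = np.full(len(sensors), np.nan)
    ok = total > 0
    out[ok] = np.linalg.norm(tang[ok], axis=1) / total[ok]
    return out


# ---------------------------------------------------------------------------
# File interfaces

def write_fieldmap(fieldmap: FieldMap, path) -> None:
    """CSV field-map file: header ``sensor_id,b_tesla``, full precision."""
    lines = ["sensor_id,b_tesla"]
    for sid, val in zip(fieldmap.ids, fieldmap.values):
        lines.append(f"{sid},{val:.12e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fieldmap(path) -> FieldMap:
    rows = [ln.split(",") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not rows or [c.strip() for c in rows[0]] != ["sensor_id", "b_tesla"]:
        raise ParameterError(f"bad field-map header in {path}")
    ids = tuple(r[0] for r in rows[1:])
    vals = np.array([float(r[1]) for r in rows[1:]])
    return FieldMap(ids, vals)


def _format_side(side: Mapping[str, float]) -> str:
    return ",".join(f"{c}:{f:.12g}" for c, f in side.items())


def _parse_side(text: str) -> dict[str, float]:
    out = {}
    for item in text.split(","):
        contact, frac = item.split(":")
        out[contact] = float(frac)
    return out


def write_protocol(configs: Iterable[StimConfig], path) -> None:
    """Protocol file: one configuration per line, e.g.
    ``#13  cathode=C2:1.0  anode=C3:1.0  amplitude_mA=3.0  family=horizontal``.
    """
    lines = []
    for c in configs:
        lines.append(
            f"{c.label}\tcathode={_format_side(c.cathode)}"
            f"\tanode={_format_side(c.anode)}"
            f"\tamplitude_mA={c.amplitude * 1e3:g}\tfamily={c.family}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_protocol(path) -> list[StimConfig]:
    configs = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("//"):
            continue
        fields = ln.split()
        label = fields[0]
        kv = dict(f.split("=", 1) for f in fields[1:])
        configs.append(
            StimConfig(
                label=label,
                cathode=_parse_side(kv["cathode"]),
                anode=_parse_side(kv["anode"]),
                amplitude=float(kv["amplitude_mA"]) * 1e-3,
                family=kv["family"],
            )
        )
    return configs
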