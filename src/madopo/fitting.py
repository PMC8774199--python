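"""Inverse fitting: goodness-of-fit, coarse pre-localization, fine
post-localization, axial-orientation scanning and half-turn ambiguity
resolution.

All fits are exhaustive grid searches scored with the normalised
root-mean-square error between measured and modelled field maps, expressed
as a goodness of fit

    GoF = 1 - || m_hat - x_hat || / || m_hat - mean(m_hat) ||,

where ``m_hat`` and ``x_hat`` are the modelled and measured maps, each
normalised to its own absolute maximum.  GoF equals 1 iff the normalised
maps coincide and is invariant to multiplying either map by any positive
scalar.  Joint fits average per-measurement GoF values, hierarchically over
configuration families when requested.

The estimators follow the statsmodels convention: a model object is built
from the geometry/search settings, ``fit()`` takes the measurements and
returns a results object with the estimate, its GoF landscape and a
``summary()``.  Predicted candidate maps are cached on the model object, so
repeated fits (e.g. across noise realisations) reuse them; results are
identical with a cold or warm cache.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    AlignmentError,
    FitError,
    IdentifiabilityError,
    ParameterError,
)
from .forward import (
    FieldMap,
    StimConfig,
    _config_dipoles,
    fieldmaps_for_tips,
)
from .geometry import (
    ElectrodeGeometry,
    ElectrodePose,
    SensorArray,
    angular_error,
    contact_centroids,
)

__all__ = [
    "GridSpec",
    "OrientationGrid",
    "gof",
    "joint_gof",
    "PreLocalizer",
    "PreLocalizationResult",
    "ElectrodeLocalizer",
    "LocalizationResult",
    "OrientationModel",
    "OrientationResult",
    "AmbiguityResult",
    "pre_localize",
    "post_localize",
    "detect_orientation",
    "resolve_ambiguity",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular cubic search lattice: centre (mm), per-axis extent (mm) and
    step (mm).  Points per axis = round(extent / step) + 1."""

    center: np.ndarray
    extent: float | np.ndarray
    step: float

    def __post_init__(self):
        center = np.asarray(self.center, float).reshape(3)
        extent = np.asarray(self.extent, float) * np.ones(3)
        if np.any(extent < 0) or self.step <= 0:
            raise ParameterError("extent must be >= 0 and step > 0")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "extent", extent)
        object.__setattr__(self, "step", float(self.step))

    @classmethod
    def around(cls, point, extent, step) -> "GridSpec":
        """Grid of the given extent/step whose lattice contains ``point``.

        With an even number of intervals the centre itself is a node; with an
        odd number the centre is shifted by half a step so the point still
        lies on the lattice.
        """
        point = np.asarray(point, float).reshape(3)
        n_intervals = int(round(np.asarray(extent, float).max() / step))
        shift = (step / 2.0) if n_intervals % 2 else 0.0
        return cls(point + shift, extent, step)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.step)) + 1 for e in self.extent)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for c, e, n in zip(self.center, self.extent, self.shape):
            out.append(c - e / 2.0 + self.step * np.arange(n))
        return tuple(out)

    def lattice(self) -> np.ndarray:
        """All lattice points, (n_points, 3), lexicographic (x slowest)."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class OrientationGrid:
    """Candidate dipole orientations: tilts from +z (degrees) crossed with
    azimuths (degrees); the tilt-0 pole is kept once."""

    tilts: tuple[float, ...] = tuple(range(0, 35, 5))
    azimuths: tuple[float, ...] = tuple(range(0, 360, 45))

    def __post_init__(self):
        object.__setattr__(self, "tilts", tuple(float(t) for t in self.tilts))
        object.__setattr__(self, "azimuths",
                           tuple(float(a) for a in self.azimuths))

    def vectors(self) -> np.ndarray:
        """Deduplicated unit direction vectors, (n, 3)."""
        dirs = []
        pole_done = False
        for t in self.tilts:
            tr = np.radians(t)
            if abs(np.sin(tr)) < 1e-12:
                if not pole_done:
                    dirs.append([0.0, 0.0, np.cos(tr)])
                    pole_done = True
                continue
            for a in self.azimuths:
                ar = np.radians(a)
                dirs.append([np.sin(tr) * np.cos(ar),
                             np.sin(tr) * np.sin(ar),
                             np.cos(tr)])
        return np.asarray(dirs)

    @property
    def n_candidates(self) -> int:
        return len(self.vectors())


# ---------------------------------------------------------------------------
# Goodness of fit

def _normalize_maxabs(v: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(v))
    if m == 0:
        raise ParameterError("cannot normalise an all-zero map")
    return v / m


def gof(measured, modeled) -> float:
    """Goodness of fit (<= 1) between a measured and a modelled field map.

    Accepts FieldMap objects (keys are aligned; mismatched key sets raise an
    alignment error) or plain arrays in matching order.
    """
    if isinstance(measured, FieldMap) and isinstance(modeled, FieldMap):
        x = measured.aligned_to(modeled.ids)
        m = modeled.values
    else:
        x = np.asarray(measured, float).ravel()
        m = np.asarray(modeled, float).ravel()
        if x.shape != m.shape:
            raise AlignmentError("measured and modelled maps differ in length")
    m_hat = _normalize_maxabs(m)
    x_hat = _normalize_maxabs(x)
    denom = np.linalg.norm(m_hat - np.mean(m_hat))
    if denom == 0:
        raise ParameterError("modelled map is constant across sensors")
    return float(1.0 - np.linalg.norm(m_hat - x_hat) / denom)


def gof_many(measured: np.ndarray, modeled: np.ndarray) -> np.ndarray:
    """Vectorised GoF of one measured map against many modelled maps.

    ``modeled`` is (n_candidates, n_sensors); rows that cannot be scored
    (all-zero or constant) get -inf.
    """
    x = np.asarray(measured, float).ravel()
    m = np.atleast_2d(np.asarray(modeled, float))
    x_hat = _normalize_maxabs(x)
    scale = np.max(np.abs(m), axis=1)
    ok = scale > 0
    out = np.full(m.shape[0], -np.inf)
    if not np.any(ok):
        return out
    m_hat = m[ok] / scale[ok, None]
    denom = np.linalg.norm(m_hat - m_hat.mean(axis=1, keepdims=True), axis=1)
    good = denom > 0
    res = np.linalg.norm(m_hat - x_hat[None, :], axis=1)
    vals = np.full(m_hat.shape[0], -np.inf)
    vals[good] = 1.0 - res[good] / denom[good]
    out[ok] = vals
    return out


def joint_gof(values, grouping: str = "total",
              families: Sequence[str] | None = None) -> float:
    """Hierarchical mean of per-measurement GoF values.

    ``grouping='config-family'`` averages measurements that share one family
    (all supplied values must belong to it); ``'multi-family'`` takes the
    mean of per-family means; ``'total'`` aggregates the family-level means
    the same way (with a single layer of families the two coincide; without
    family labels it is the plain mean).
    """
    vals = np.asarray(list(values), float)
    if vals.size == 0:
        raise ParameterError("empty GoF group")
    if grouping not in ("config-family", "multi-family", "total"):
        raise ParameterError("unknown grouping")
    if families is None or grouping == "config-family":
        if grouping == "config-family" and families is not None:
            if len(set(families)) > 1:
                raise ParameterError(
                    "config-family grouping requires a single family")
        return float(vals.mean())
    families = list(families)
    if len(families) != vals.size:
        raise ParameterError("families must parallel the GoF values")
    fams = sorted(set(families))
    fam_means = [vals[[f == fam for f in families]].mean() for fam in fams]
    return float(np.mean(fam_means))


def _joint_curves(curves: np.ndarray, families: Sequence[str],
                  grouping: str) -> np.ndarray:
    """Aggregate per-measurement GoF curves (n_meas, k) to one (k,) curve."""
    if grouping in ("multi-family", "total") and len(set(families)) > 1:
        fams = sorted(set(families))
        fam_curves = [curves[[f == fam for f in families]].mean(axis=0)
                      for fam in fams]
        return np.mean(fam_curves, axis=0)
    return curves.mean(axis=0)


def _check_measurements(measurements) -> list[tuple[FieldMap, StimConfig]]:
    items = list(measurements)
    if not items:
        raise ParameterError("at least one measurement is required")
    for fm, cfg in items:
        if not isinstance(fm, FieldMap) or not isinstance(cfg, StimConfig):
            raise ParameterError(
                "measurements must be (FieldMap, StimConfig) pairs")
    return items


def _argmax_first(values: np.ndarray) -> int:
    """First index attaining the maximum (deterministic tie-break)."""
    return int(np.argmax(values))


def _summary_table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows)
    lines = [title, "=" * len(title)]
    lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Pre-localization (coarse single-dipole scan)

class PreLocalizer:
    """Coarse single-dipole grid scan over position x orientation candidates.

    Parameters
    ----------
    sensors : SensorArray
    grid : GridSpec, default 90 mm cube at 10 mm resolution about the origin
    orientations : OrientationGrid, default 0-30 degree tilts in 5-degree
        steps crossed with 45-degree azimuths (49 unique directions)
    allow_flip : bool
        Also score each candidate direction with its moment negated, so the
        scan is insensitive to the unknown polarity of the bipolar source.
    """

    def __init__(self, sensors: SensorArray, grid: GridSpec | None = None,
                 orientations: OrientationGrid | None = None,
                 allow_flip: bool = True,
                 roi_extent: float = 29.0, roi_step: float = 1.0):
        self.sensors = sensors
        self.grid = grid or GridSpec(np.zeros(3), 90.0, 10.0)
        self.orientations = orientations or OrientationGrid()
        self.allow_flip = bool(allow_flip)
        self.roi_extent = float(roi_extent)
        self.roi_step = float(roi_step)
        self._kernel: np.ndarray | None = None

    def _position_kernel(self) -> np.ndarray:
        """(n_pos, n_sens, 3) kernel K with B.s = K @ q for a unit dipole."""
        if self._kernel is None:
            pos_mm = self.grid.lattice()
            loc = 1e-3 * pos_mm  # (p, 3) m
            r = self.sensors.positions[None, :, :] - loc[:, None, :]
            dist = np.linalg.norm(r, axis=2)
            rxs = np.cross(r, self.sensors.orientations[None, :, :])
            self._kernel = 1e-7 * rxs / dist[:, :, None] ** 3
        return self._kernel

    def fit(self, measured: FieldMap) -> "PreLocalizationResult":
        x = measured.aligned_to(self.sensors.ids)
        kernel = self._position_kernel()  # (p, s, 3)
        dirs = self.orientations.vectors()  # (a, 3)
        maps = np.einsum("psk,ak->pas", kernel, dirs)
        n_pos, n_ori, n_sens = maps.shape
        flat = maps.reshape(n_pos * n_ori, n_sens)
        gofs = gof_many(x, flat)
        signs = np.ones_like(gofs)
        if self.allow_flip:
            gofs_neg = gof_many(x, -flat)
            flip = gofs_neg > gofs
            gofs = np.where(flip, gofs_neg, gofs)
            signs = np.where(flip, -1.0, 1.0)
        if not np.any(np.isfinite(gofs)):
            raise FitError("no candidate produced a finite GoF")
        gofs = gofs.reshape(n_pos, n_ori)
        signs = signs.reshape(n_pos, n_ori)
        best = _argmax_first(gofs.ravel())
        ip, ia = divmod(best, n_ori)
        position = self.grid.lattice()[ip]
        orientation = signs[ip, ia] * dirs[ia]
        landscape = gofs.max(axis=1)
        roi = GridSpec(position, self.roi_extent, self.roi_step)
        return PreLocalizationResult(
            position_mm=position,
            orientation=orientation,
            gof=float(gofs[ip, ia]),
            gof_landscape=landscape,
            gof_array=gofs,
            n_position_candidates=n_pos,
            n_orientation_candidates=n_ori,
            grid=self.grid,
            roi=roi,
        )


@dataclass(frozen=True)
class PreLocalizationResult:
    """Best coarse dipole candidate plus the full GoF landscape and the
    region of interest handed to post-localization."""

    position_mm: np.ndarray
    orientation: np.ndarray
    gof: float
    gof_landscape: np.ndarray  # (n_pos,) max over orientations
    gof_array: np.ndarray  # (n_pos, n_ori)
    n_position_candidates: int
    n_orientation_candidates: int
    grid: GridSpec
    roi: GridSpec

    def summary(self) -> str:
        p = self.position_mm
        return _summary_table("Pre-localization (single-dipole scan)", [
            ("position [mm]", f"[{p[0]:.1f}, {p[1]:.1f}, {p[2]:.1f}]"),
            ("orientation", np.array2string(self.orientation, precision=3)),
            ("GoF", f"{self.gof:.4f}"),
            ("candidates", f"{self.n_position_candidates} positions x "
                           f"{self.n_orientation_candidates} orientations"),
            ("ROI", f"{self.roi.extent[0]:.0f} mm cube @ "
                    f"{self.roi.step:g} mm about the best node"),
        ])


# ---------------------------------------------------------------------------
# Post-localization (fine electrode-model scan)

class ElectrodeLocalizer:
    """Fine grid scan of the electrode tip over a region of interest.

    The electrode axis and axial rotation are held fixed (translation-only
    search); candidate maps per stimulation configuration are computed once
    and cached across ``fit`` calls.
    """

    def __init__(self, sensors: SensorArray, geometry: ElectrodeGeometry,
                 roi: GridSpec, axis, rot: float = 0.0,
                 model: str = "distributed", n_path: int = 7):
        self.sensors = sensors
        self.geometry = geometry
        self.roi = roi
        self.axis = np.asarray(axis, float)
        self.rot = float(rot)
        self.model = model
        self.n_path = int(n_path)
        self._map_cache: dict[str, np.ndarray] = {}

    def clear_cache(self) -> None:
        self._map_cache.clear()

    def _source_elements(self, config: StimConfig):
        """Dipole offsets (mm, tip-relative) and moments for one config."""
        pose0 = ElectrodePose(np.zeros(3), self.axis, self.rot)
        dipoles = _config_dipoles(pose0, self.geometry, config,
                                  self.model, self.n_path)
        offsets = np.array([1e3 * d.location for d in dipoles])
        moments = np.array([d.moment for d in dipoles])
        return offsets, moments

    def candidate_maps(self, config: StimConfig) -> np.ndarray:
        """(n_candidates, n_sensors) predicted maps for one configuration."""
        if config.label not in self._map_cache:
            offsets, moments = self._source_elements(config)
            self._map_cache[config.label] = fieldmaps_for_tips(
                self.roi.lattice(), offsets, moments, self.sensors)
        return self._map_cache[config.label]

    def fit(self, measurements: Iterable[tuple[FieldMap, StimConfig]]
            ) -> "LocalizationResult":
        items = _check_measurements(measurements)
        per_meas = []
        labels = []
        for fm, cfg in items:
            x = fm.aligned_to(self.sensors.ids)
            per_meas.append(gof_many(x, self.candidate_maps(cfg)))
            labels.append(cfg.label)
        per_meas = np.asarray(per_meas)  # (n_meas, n_cand)
        joint = per_meas.mean(axis=0)
        if not np.any(np.isfinite(joint)):
            raise FitError("no candidate produced a finite GoF")
        best = _argmax_first(joint)
        tip = self.roi.lattice()[best]
        pose = ElectrodePose(tip, self.axis, self.rot)
        contacts = {lbl: site.position
                    for lbl, site in contact_centroids(self.geometry, pose).items()}
        return LocalizationResult(
            tip_mm=tip,
            pose=pose,
            gof=float(joint[best]),
            per_measurement_gof={lbl: float(per_meas[i, best])
                                 for i, lbl in enumerate(labels)},
            gof_landscape=joint,
            n_candidates=self.roi.n_points,
            roi=self.roi,
            contact_positions=contacts,
        )


@dataclass(frozen=True)
class LocalizationResult:
    """Best electrode tip position with joint GoF and per-contact positions."""

    tip_mm: np.ndarray
    pose: ElectrodePose
    gof: float
    per_measurement_gof: Mapping[str, float]
    gof_landscape: np.ndarray
    n_candidates: int
    roi: GridSpec
    contact_positions: Mapping[str, np.ndarray]

    def summary(self) -> str:
        p = self.tip_mm
        rows = [
            ("tip [mm]", f"[{p[0]:.1f}, {p[1]:.1f}, {p[2]:.1f}]"),
            ("joint GoF", f"{self.gof:.4f}"),
            ("candidates", str(self.n_candidates)),
        ]
        for lbl, g in self.per_measurement_gof.items():
            rows.append((f"GoF {lbl}", f"{g:.4f}"))
        return _summary_table("Electrode localization (ROI scan)", rows)


# ---------------------------------------------------------------------------
# Orientation detection

class OrientationModel:
    """Axial-rotation scan of the electrode about its own axis.

    The electrode position is assumed known (from localization); candidate
    maps per (rotation, configuration) are cached across fits.  Vertical
    (ring-to-ring) configurations are rotation-invariant and therefore cannot
    identify the rotation on their own.
    """

    def __init__(self, sensors: SensorArray, geometry: ElectrodeGeometry,
                 tip, axis, rot_step: float = 1.0,
                 model: str = "distributed", n_path: int = 7):
        if rot_step <= 0:
            raise ParameterError("rot_step must be > 0")
        self.sensors = sensors
        self.geometry = geometry
        self.tip = np.asarray(tip, float)
        self.axis = np.asarray(axis, float)
        self.rot_step = float(rot_step)
        self.model = model
        self.n_path = int(n_path)
        self._map_cache: dict[str, np.ndarray] = {}

    @property
    def angles(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.rot_step)

    def clear_cache(self) -> None:
        self._map_cache.clear()

    def candidate_maps(self, config: StimConfig) -> np.ndarray:
        """(n_rot, n_sensors) predicted maps for one configuration."""
        if config.label not in self._map_cache:
            maps = np.empty((self.angles.size, len(self.sensors)))
            for i, rot in enumerate(self.angles):
                pose = ElectrodePose(self.tip, self.axis, rot)
                dipoles = _config_dipoles(pose, self.geometry, config,
                                          self.model, self.n_path)
                offsets = np.array([1e3 * d.location for d in dipoles])
                moments = np.array([d.moment for d in dipoles])
                maps[i] = fieldmaps_for_tips(
                    np.zeros((1, 3)), offsets, moments, self.sensors)[0]
            self._map_cache[config.label] = maps
        return self._map_cache[config.label]

    def fit(self, measurements: Iterable[tuple[FieldMap, StimConfig]],
            grouping: str = "multi-family") -> "OrientationResult":
        items = _check_measurements(measurements)
        if all(cfg.family == "vertical" for _, cfg in items):
            raise IdentifiabilityError(
                "rotation is unidentifiable from vertical (ring) "
                "configurations alone")
        curves, labels, families = [], [], []
        for fm, cfg in items:
            x = fm.aligned_to(self.sensors.ids)
            curves.append(gof_many(x, self.candidate_maps(cfg)))
            labels.append(cfg.label)
            families.append(cfg.family)
        curves = np.asarray(curves)  # (n_meas, n_rot)
        joint = _joint_curves(curves, families, grouping)
        if not np.any(np.isfinite(joint)):
            raise FitError("no rotation candidate produced a finite GoF")
        best = _argmax_first(joint)
        return OrientationResult(
            rot_deg=float(self.angles[best]),
            gof=float(joint[best]),
            angles=self.angles.copy(),
            gof_curve=joint,
            per_measurement_curves={lbl: curves[i]
                                    for i, lbl in enumerate(labels)},
            per_measurement_gof={lbl: float(curves[i, best])
                                 for i, lbl in enumerate(labels)},
            n_candidates=self.angles.size,
            grouping=grouping,
        )

    def resolve(self, measurement: tuple[FieldMap, StimConfig],
                candidates: tuple[float, float],
                margin: float = 1e-3) -> "AmbiguityResult":
        """Pick the member of an ambiguous angle pair with the higher GoF.

        A single directional measurement suffices; below ``margin`` GoF
        difference the result is flagged 'undecided' rather than silently
        picking one.
        """
        fm, cfg = measurement
        if cfg.family == "vertical":
            raise IdentifiabilityError(
                "a vertical (ring) configuration is uninformative about "
                "rotation")
        x = fm.aligned_to(self.sensors.ids)
        gofs = {}
        for theta in candidates:
            pose = ElectrodePose(self.tip, self.axis, theta)
            dipoles = _config_dipoles(pose, self.geometry, cfg,
                                      self.model, self.n_path)
            offsets = np.array([1e3 * d.location for d in dipoles])
            moments = np.array([d.moment for d in dipoles])
            modeled = fieldmaps_for_tips(np.zeros((1, 3)), offsets, moments,
                                         self.sensors)[0]
            gofs[float(theta)] = gof(x, modeled)
        (t1, g1), (t2, g2) = gofs.items()
        diff = abs(g1 - g2)
        if diff < margin:
            return AmbiguityResult(None, dict(gofs), diff, "undecided")
        chosen = t1 if g1 > g2 else t2
        return AmbiguityResult(chosen, dict(gofs), diff, "decided")


@dataclass(frozen=True)
class OrientationResult:
    """Best axial rotation plus the full GoF-versus-angle curve(s)."""

    rot_deg: float
    gof: float
    angles: np.ndarray
    gof_curve: np.ndarray
    per_measurement_curves: Mapping[str, np.ndarray]
    per_measurement_gof: Mapping[str, float]
    n_candidates: int
    grouping: str

    def curve_range(self) -> float:
        """Spread of the joint GoF curve (flatness diagnostic)."""
        finite = self.gof_curve[np.isfinite(self.gof_curve)]
        return float(finite.max() - finite.min())

    def error_to(self, true_rot: float) -> float:
        return angular_error(self.rot_deg, true_rot)

    def plot_curve(self, ax=None):
        """GoF-versus-rotation curves (joint plus per measurement)."""
        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        for label, curve in self.per_measurement_curves.items():
            ax.plot(self.angles, curve, alpha=0.4, label=label)
        ax.plot(self.angles, self.gof_curve, "k", lw=2, label="joint")
        ax.axvline(self.rot_deg, color="r", ls="--")
        ax.set_xlabel("rotation [deg]")
        ax.set_ylabel("GoF")
        ax.legend(fontsize="small", ncol=2)
        return ax

    def summary(self) -> str:
        rows = [
            ("rotation [deg]", f"{self.rot_deg:.1f}"),
            ("joint GoF", f"{self.gof:.4f}"),
            ("candidates", str(self.n_candidates)),
            ("grouping", self.grouping),
            ("curve range", f"{self.curve_range():.4f}"),
        ]
        for lbl, g in self.per_measurement_gof.items():
            rows.append((f"GoF {lbl}", f"{g:.4f}"))
        return _summary_table("Electrode orientation (rotation scan)", rows)


@dataclass(frozen=True)
class AmbiguityResult:
    """Outcome of the half-turn disambiguation."""

    chosen: float | None
    gofs: Mapping[float, float]
    margin: float
    status: str  # "decided" | "undecided"


# ---------------------------------------------------------------------------
# Functional wrappers

def pre_localize(measured: FieldMap, sensors: SensorArray,
                 grid: GridSpec | None = None,
                 orientations: OrientationGrid | None = None,
                 **kwargs) -> PreLocalizationResult:
    return PreLocalizer(sensors, grid, orientations, **kwargs).fit(measured)


def post_localize(measurements, sensors: SensorArray, roi: GridSpec,
                  axis, rot: float = 0.0,
                  geometry: ElectrodeGeometry | None = None,
                  model: str = "distributed", n_path: int = 7
                  ) -> LocalizationResult:
    geometry = geometry or ElectrodeGeometry()
    return ElectrodeLocalizer(sensors, geometry, roi, axis, rot,
                              model, n_path).fit(measurements)


def detect_orientation(measurements, sensors: SensorArray, tip, axis,
                       geometry: ElectrodeGeometry | None = None,
                       rot_step: float = 1.0, grouping: str = "multi-family",
                       model: str = "distributed", n_path: int = 7
                       ) -> OrientationResult:
    geometry = geometry or ElectrodeGeometry()
    return OrientationModel(sensors, geometry, tip, axis, rot_step,
                            model, n_path).fit(measurements, grouping)


def resolve_ambiguity(measurement, sensors: SensorArray, tip, axis,
                      candidates: tuple[float, float],
                      geometry: ElectrodeGeometry | None = None,
                      margin: float = 1e-3, model: str = "distributed",
                      n_path: int = 7) -> AmbiguityResult:
    geometry = geometry or ElectrodeGeometry()
    return OrientationModel(sensors, geometry, tip, axis, 1.0, model,
                            n_path).resolve(measurement, candidates, margin)
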