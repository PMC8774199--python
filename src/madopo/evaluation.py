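"""Sweep analyses over synthetic fixtures: sensor count and placement,
measurement time / SNR, electrode-displacement robustness of the orientation
estimate, plus machine-readable run reports.

All sweeps are seeded and report per-point mean, SD and n over noise
realisations; absolute breakpoints (e.g. how many sensors are "enough")
depend on the noise field, so downstream assertions should target trends and
tolerance bands rather than single draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .fitting import (
    ElectrodeLocalizer,
    GridSpec,
    LocalizationResult,
    OrientationModel,
    OrientationResult,
    PreLocalizationResult,
)
from .forward import FieldMap
from .geometry import SensorArray, angular_error, localization_error
from .signal import n_averages, snr_gain_db
from .simulate import FixtureCase, perturb_fieldmap

__all__ = [
    "SweepResult",
    "sensor_subset",
    "sweep_sensor_count",
    "sweep_duration",
    "orientation_vs_displacement",
    "report",
    "write_report",
    "result_to_dict",
]


@dataclass(frozen=True)
class SweepResult:
    """One swept parameter with per-value error statistics, possibly split
    into named groups (e.g. subsetting strategies or displacement axes)."""

    parameter: str
    metric: str
    values: tuple
    series: Mapping[str, Mapping[str, np.ndarray]]  # group -> mean/sd/n
    annotations: Mapping[str, object] = field(default_factory=dict)

    def mean(self, group: str) -> np.ndarray:
        return np.asarray(self.series[group]["mean"])

    def plot(self, ax=None):
        """Mean metric versus the swept parameter, one line per group."""
        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        for group, stats in self.series.items():
            ax.errorbar(self.values, stats["mean"], yerr=stats["sd"],
                        marker="o", capsize=3, label=group)
        ax.set_xlabel(self.parameter)
        ax.set_ylabel(self.metric)
        ax.legend(fontsize="small")
        return ax

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, stats in self.series.items():
            for i, v in enumerate(self.values):
                rows.append({
                    "param": self.parameter,
                    "value": v,
                    "group": group,
                    "metric_mean": float(stats["mean"][i]),
                    "metric_sd": float(stats["sd"][i]),
                    "n": int(stats["n"][i]),
                })
        return pd.DataFrame(rows)


def _stats(per_seed: np.ndarray) -> tuple[float, float, int]:
    arr = np.asarray(per_seed, float)
    return float(arr.mean()), float(arr.std(ddof=0)), int(arr.size)


# ---------------------------------------------------------------------------
# Sensor subsetting

def sensor_subset(sensors: SensorArray, n: int, strategy: str = "uniform",
                  reference=None, seed: int = 0) -> SensorArray:
    """Keep ``n`` sensors: ``"nearest"`` keeps those closest to ``reference``
    (mm, e.g. the electrode position); ``"uniform"`` keeps a deterministic
    spatially stratified subset via seeded farthest-point thinning."""
    if not (1 <= n <= len(sensors)):
        raise ParameterError("n out of range")
    if n == len(sensors):
        return sensors
    if strategy == "nearest":
        if reference is None:
            raise ParameterError("nearest strategy needs a reference point")
        ref_m = 1e-3 * np.asarray(reference, float).reshape(3)
        dist = np.linalg.norm(sensors.positions - ref_m, axis=1)
        keep = np.sort(np.argsort(dist)[:n])
        return sensors.subset(keep)
    if strategy == "uniform":
        rng = np.random.default_rng(seed)
        pos = sensors.positions
        selected = [int(rng.integers(len(sensors)))]
        mind = np.linalg.norm(pos - pos[selected[0]], axis=1)
        while len(selected) < n:
            nxt = int(np.argmax(mind))
            selected.append(nxt)
            mind = np.minimum(mind, np.linalg.norm(pos - pos[nxt], axis=1))
        return sensors.subset(np.sort(selected))
    raise ParameterError("strategy must be 'uniform' or 'nearest'")


def _subset_map(fieldmap: FieldMap, sensors: SensorArray) -> FieldMap:
    lookup = {s: i for i, s in enumerate(fieldmap.ids)}
    idx = [lookup[s] for s in sensors.ids]
    return FieldMap(sensors.ids, fieldmap.values[idx])


def _localization_error_for(case: FixtureCase, sensors: SensorArray,
                            measurements, roi: GridSpec,
                            localizer_cache: dict) -> ElectrodeLocalizer:
    key = sensors.ids
    if key not in localizer_cache:
        localizer_cache[key] = ElectrodeLocalizer(
            sensors, case.geometry, roi, case.pose.axis, case.pose.rot)
    return localizer_cache[key]


# ---------------------------------------------------------------------------
# Sweeps

def sweep_sensor_count(
    case: FixtureCase,
    counts: Sequence[int],
    strategies: Sequence[str] = ("uniform", "nearest"),
    seeds: Sequence[int] = tuple(range(10)),
    snr_db: float = 10.0,
    roi_extent: float = 10.0,
    roi_step: float = 2.0,
    families: Sequence[str] = ("vertical",),
) -> SweepResult:
    """Tip localization error versus number of sensors, per strategy.

    Noise is added to the full-array maps at ``snr_db`` before subsetting,
    so concentrating sensors near the source keeps the strongest channels.
    """
    roi = GridSpec(case.pose.tip, roi_extent, roi_step)
    meas_full = case.measurements(families)
    series: dict[str, dict[str, np.ndarray]] = {}
    cache: dict = {}
    for strategy in strategies:
        means, sds, ns = [], [], []
        for count in counts:
            subset = sensor_subset(case.sensors, int(count), strategy,
                                   reference=case.pose.tip, seed=0)
            loc = _localization_error_for(case, subset, meas_full, roi, cache)
            errors = []
            for seed in seeds:
                rng = np.random.default_rng(seed)
                meas = [(_subset_map(perturb_fieldmap(fm, snr_db, rng), subset),
                         cfg) for fm, cfg in meas_full]
                res = loc.fit(meas)
                errors.append(localization_error(res.tip_mm, case.pose.tip))
            m, s, n = _stats(errors)
            means.append(m); sds.append(s); ns.append(n)
        series[strategy] = {"mean": np.array(means), "sd": np.array(sds),
                            "n": np.array(ns)}
    return SweepResult("n_sensors", "localization_error_mm", tuple(counts),
                       series, {"snr_db": snr_db})


def sweep_duration(
    case: FixtureCase,
    durations: Sequence[float],
    seeds: Sequence[int] = tuple(range(10)),
    single_epoch_snr_db: float = 0.0,
    roi_extent: float = 10.0,
    roi_step: float = 2.0,
    families: Sequence[str] = ("vertical",),
) -> SweepResult:
    """Tip localization error versus measurement duration.

    The post-averaging SNR at duration d is
    ``single_epoch_snr_db + snr_gain_db(n_averages(d, f))``; the per-point
    gain and epoch count are attached as annotations.  Durations shorter than
    two stimulation periods are skipped with a note.
    """
    freq = case.train.frequency
    kept, skipped, gains, navgs = [], [], [], []
    for d in durations:
        if d < 2.0 / freq:
            skipped.append(float(d))
            continue
        kept.append(float(d))
        n = n_averages(d, freq)
        navgs.append(n)
        gains.append(snr_gain_db(n))
    roi = GridSpec(case.pose.tip, roi_extent, roi_step)
    meas_full = case.measurements(families)
    loc = ElectrodeLocalizer(case.sensors, case.geometry, roi,
                             case.pose.axis, case.pose.rot)
    means, sds, ns = [], [], []
    for d, gain in zip(kept, gains):
        snr = single_epoch_snr_db + gain
        errors = []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            meas = [(perturb_fieldmap(fm, snr, rng), cfg)
                    for fm, cfg in meas_full]
            res = loc.fit(meas)
            errors.append(localization_error(res.tip_mm, case.pose.tip))
        m, s, n = _stats(errors)
        means.append(m); sds.append(s); ns.append(n)
    series = {"all": {"mean": np.array(means), "sd": np.array(sds),
                      "n": np.array(ns)}}
    return SweepResult("duration_s", "localization_error_mm", tuple(kept),
                       series, {
                           "snr_gain_db": gains,
                           "n_averages": navgs,
                           "single_epoch_snr_db": single_epoch_snr_db,
                           "skipped_durations": skipped,
                       })


def orientation_vs_displacement(
    case: FixtureCase,
    offsets: Sequence[float] = tuple(range(-15, 16)),
    seeds: Sequence[int] | None = None,
    snr_db: float | None = None,
    rot_step: float = 1.0,
    families: Sequence[str] = ("horizontal", "symmetrical"),
) -> SweepResult:
    """Orientation error and GoF versus electrode displacement per axis.

    The assumed electrode position is displaced by each offset along each
    Cartesian axis while the data stay at the true position; the drop in GoF
    and the induced angular error quantify how sensitive orientation
    detection is to localization error.  Noiseless by default.
    """
    meas_truth = case.measurements(families)
    axes = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
            "z": np.array([0, 0, 1.0])}
    seeds = list(seeds) if seeds is not None else [None]
    series: dict[str, dict[str, np.ndarray]] = {}
    gof_curves: dict[str, list[float]] = {}
    for name, direction in axes.items():
        means, sds, ns, gofs = [], [], [], []
        for off in offsets:
            tip = case.pose.tip + off * direction
            model = OrientationModel(case.sensors, case.geometry, tip,
                                     case.pose.axis, rot_step)
            errs, gvals = [], []
            for seed in seeds:
                if seed is None or snr_db is None:
                    meas = meas_truth
                else:
                    rng = np.random.default_rng(seed)
                    meas = [(perturb_fieldmap(fm, snr_db, rng), cfg)
                            for fm, cfg in meas_truth]
                res = model.fit(meas)
                errs.append(res.error_to(case.pose.rot))
                gvals.append(res.gof)
            m, s, n = _stats(errs)
            means.append(m); sds.append(s); ns.append(n)
            gofs.append(float(np.mean(gvals)))
        series[name] = {"mean": np.array(means), "sd": np.array(sds),
                        "n": np.array(ns)}
        gof_curves[name] = gofs
    return SweepResult("displacement_mm", "angular_error_deg", tuple(offsets),
                       series, {"gof": gof_curves, "snr_db": snr_db})


# ---------------------------------------------------------------------------
# Reporting

def result_to_dict(result) -> dict:
    """JSON-serialisable view of any fit result."""
    if isinstance(result, PreLocalizationResult):
        return {
            "kind": "pre_localization",
            "position_mm": [float(v) for v in result.position_mm],
            "orientation": [float(v) for v in result.orientation],
            "gof": result.gof,
            "n_position_candidates": result.n_position_candidates,
            "n_orientation_candidates": result.n_orientation_candidates,
            "roi_center_mm": [float(v) for v in result.roi.center],
            "roi_extent_mm": [float(v) for v in result.roi.extent],
            "roi_step_mm": result.roi.step,
        }
    if isinstance(result, LocalizationResult):
        return {
            "kind": "localization",
            "tip_mm": [float(v) for v in result.tip_mm],
            "gof": result.gof,
            "per_measurement_gof": dict(result.per_measurement_gof),
            "n_candidates": result.n_candidates,
            "contact_positions_mm": {
                k: [float(x) for x in v]
                for k, v in result.contact_positions.items()},
        }
    if isinstance(result, OrientationResult):
        return {
            "kind": "orientation",
            "rot_deg": result.rot_deg,
            "gof": result.gof,
            "grouping": result.grouping,
            "per_measurement_gof": dict(result.per_measurement_gof),
            "n_candidates": result.n_candidates,
            "angles_deg": [float(a) for a in result.angles],
            "gof_curve": [float(g) for g in result.gof_curve],
            "per_measurement_curves": {
                k: [float(g) for g in v]
                for k, v in result.per_measurement_curves.items()},
        }
    raise ParameterError(f"cannot serialise {type(result).__name__}")


def _sweep_to_dict(sweep: SweepResult) -> dict:
    def _clean(obj):
        if isinstance(obj, np.ndarray):
            return [float(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return {
        "parameter": sweep.parameter,
        "metric": sweep.metric,
        "values": list(sweep.values),
        "series": {g: {k: _clean(v) for k, v in s.items()}
                   for g, s in sorted(sweep.series.items())},
        "annotations": _clean(dict(sweep.annotations)),
    }


def report(fits: Iterable = (), sweeps: Iterable[SweepResult] = (),
           config: Mapping | None = None,
           seeds: Sequence[int] = (),
           timestamp: str | None = None) -> dict:
    """Aggregate fits, sweeps, configuration and seeds into one
    machine-readable report with deterministic ordering."""
    from . import __version__

    out = {
        "madopo_version": __version__,
        "seeds": [int(s) for s in seeds],
        "config": dict(config or {}),
        "fits": [result_to_dict(r) for r in fits],
        "sweeps": [_sweep_to_dict(s) for s in sweeps],
    }
    if timestamp is not None:
        out["timestamp"] = timestamp
    return out


def write_report(rep: Mapping, path) -> None:
    Path(path).write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
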