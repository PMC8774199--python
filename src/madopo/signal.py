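"""Measurement-to-fieldmap pipeline.

A stimulation recording is reduced to one signed field value per sensor in
four steps: high-pass filtering (to strip drifts and mains-band content well
below the stimulation frequency), detection of the periodic stimulation
peaks, epoching and coherent averaging, and extraction of the per-channel
value at the single epoch sample with the largest across-channel RMS.  The
common time index preserves each channel's sign, which the dipole fit needs.

The filter is applied zero-phase (forward-backward Butterworth) by default so
that the pulse peak latency is not skewed across channels; ``causal=True``
restores a single forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .exceptions import DetectionError, ParameterError
from .forward import FieldMap
from .geometry import SensorArray

__all__ = [
    "Recording",
    "PulseTrain",
    "EpochAverage",
    "highpass",
    "detect_pulses",
    "epoch_average",
    "extract_fieldmap",
    "n_averages",
    "snr_gain_db",
    "best_channel",
    "measure_fieldmap",
    "read_recording_h5",
    "write_recording_h5",
    "read_recording_csv",
    "write_recording_csv",
]


@dataclass(frozen=True)
class Recording:
    """Multichannel recording: ids, (channels x samples) data in tesla, rate."""

    ids: tuple[str, ...]
    data: np.ndarray
    rate: float

    def __post_init__(self):
        ids = tuple(str(i) for i in self.ids)
        data = np.atleast_2d(np.asarray(self.data, float))
        if self.rate <= 0:
            raise ParameterError("sampling rate must be > 0")
        if len(set(ids)) != len(ids):
            raise ParameterError("channel ids must be unique")
        if data.shape[0] != len(ids):
            raise ParameterError("data must be (n_channels, n_samples)")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class PulseTrain:
    """Biphasic stimulation train: active rectangular phase of ``pulse_width``
    seconds at ``amplitude`` amperes repeating at ``frequency`` Hz for
    ``duration`` seconds, followed each period by a passive exponential
    charge-balancing phase whose integrated area cancels the pulse area."""

    amplitude: float = 3e-3
    pulse_width: float = 60e-6
    frequency: float = 130.0
    duration: float = 180.0
    recharge_tau_ratio: float = 5.0  # recharge time constant / pulse width

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be > 0")
        if self.pulse_width <= 0 or self.frequency <= 0:
            raise ParameterError("pulse_width and frequency must be > 0")
        if self.frequency * self.pulse_width >= 1:
            raise ParameterError("pulse must fit inside one period")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")

    @property
    def recharge_fraction(self) -> float:
        """Approximate peak amplitude of the recharge phase relative to the
        stimulation phase (pulse_width / recharge time constant)."""
        return 1.0 / self.recharge_tau_ratio


@dataclass(frozen=True)
class EpochAverage:
    """Average over complete epochs plus bookkeeping."""

    data: np.ndarray  # (channels, epoch_span)
    n_epochs: int
    n_dropped: int


def highpass(recording: Recording, cutoff: float = 60.0, order: int = 6,
             causal: bool = False) -> Recording:
    """Butterworth high-pass; zero-phase (forward-backward) by default."""
    nyq = recording.rate / 2.0
    if not (0 < cutoff < nyq):
        raise ParameterError("cutoff must lie below the Nyquist frequency")
    sos = sps.butter(order, cutoff, btype="highpass", fs=recording.rate,
                     output="sos")
    if causal:
        filtered = sps.sosfilt(sos, recording.data, axis=1)
    else:
        filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(recording.ids, filtered, recording.rate)


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_pulses(channel: np.ndarray, rate: float, stim_frequency: float,
                  threshold_factor: float = 5.0) -> np.ndarray:
    """Sample indices of successive stimulation peaks on one channel.

    Peaks are found on the absolute signal above ``threshold_factor`` times a
    robust (MAD-based) noise SD, with a minimum spacing of 0.8 periods.
    """
    x = np.asarray(channel, float).ravel()
    period = rate / stim_frequency
    if x.size < 2 * period:
        raise ParameterError("recording shorter than two stimulation periods")
    sd = _robust_sd(x)
    if sd == 0:
        sd = float(np.std(x)) or np.finfo(float).tiny
    threshold = threshold_factor * sd
    peaks, props = sps.find_peaks(np.abs(x), height=threshold,
                                  distance=max(1, int(0.8 * period)))
    if peaks.size == 0:
        peak_amp = float(np.max(np.abs(x))) if x.size else 0.0
        snr = 10 * np.log10(peak_amp / sd) if peak_amp > 0 else -np.inf
        raise DetectionError(
            f"no stimulation peaks above {threshold_factor}x noise SD "
            f"(peak/noise ~ {snr:.1f} dB)", snr_estimate=snr)
    return peaks


def epoch_average(recording: Recording, peak_indices, epoch_span: int) -> EpochAverage:
    """Average complete epochs of ``epoch_span`` samples centred on the peaks.

    Epochs extending past either end of the recording are dropped and
    counted; at least two complete epochs are required.
    """
    peaks = np.asarray(peak_indices, int).ravel()
    if epoch_span < 1:
        raise ParameterError("epoch_span must be >= 1")
    half = epoch_span // 2
    starts = peaks - half
    ok = (starts >= 0) & (starts + epoch_span <= recording.n_samples)
    n_dropped = int(np.sum(~ok))
    starts = starts[ok]
    if starts.size < 2:
        raise ParameterError("need at least two complete epochs")
    idx = starts[:, None] + np.arange(epoch_span)[None, :]
    # (channels, epochs, span) -> mean over epochs
    avg = recording.data[:, idx].mean(axis=1)
    return EpochAverage(avg, int(starts.size), n_dropped)


def extract_fieldmap(epoch: EpochAverage | np.ndarray,
                     sensors: SensorArray) -> FieldMap:
    """Per-channel signed value at the common epoch sample t* maximising the
    across-channel RMS of the averaged epoch."""
    data = epoch.data if isinstance(epoch, EpochAverage) else np.atleast_2d(epoch)
    if data.size == 0 or not np.any(data):
        raise ParameterError("degenerate (all-zero or empty) averaged epoch")
    if data.shape[0] != len(sensors):
        raise ParameterError("epoch channel count does not match sensor array")
    rms = np.sqrt(np.mean(data**2, axis=0))
    t_star = int(np.argmax(rms))
    return FieldMap(sensors.ids, data[:, t_star])


def n_averages(duration: float, stim_frequency: float) -> int:
    """Number of stimulation epochs in ``duration`` seconds: floor(d * f)."""
    if duration <= 0 or stim_frequency <= 0:
        raise ParameterError("duration and stim_frequency must be > 0")
    return int(np.floor(duration * stim_frequency))


def snr_gain_db(n: int) -> float:
    """SNR gain from averaging n epochs: 10*log10(sqrt(n)) = 5*log10(n).

    This is the amplitude-ratio dB convention under which coherent averaging
    of n epochs (amplitude noise reduction by sqrt(n)) gains 5*log10(n) dB.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    return float(5.0 * np.log10(n))


def best_channel(recording: Recording) -> int:
    """Index of the channel with the largest variance (strongest artifact)."""
    return int(np.argmax(np.var(recording.data, axis=1)))


def measure_fieldmap(recording: Recording, sensors: SensorArray,
                     stim_frequency: float, cutoff: float = 60.0,
                     causal: bool = False) -> tuple[FieldMap, EpochAverage]:
    """Full pipeline: filter -> detect peaks -> epoch-average -> extract.

    Returns the field map plus the averaged epoch (for inspection).  Channel
    order must match the sensor array.
    """
    if recording.ids != sensors.ids:
        raise ParameterError("recording channels must match the sensor array")
    filtered = highpass(recording, cutoff=cutoff, causal=causal)
    ch = best_channel(filtered)
    peaks = detect_pulses(filtered.data[ch], filtered.rate, stim_frequency)
    span = int(round(filtered.rate / stim_frequency))
    avg = epoch_average(filtered, peaks, span)
    return extract_fieldmap(avg, sensors), avg


# ---------------------------------------------------------------------------
# Containers on disk

def write_recording_h5(recording: Recording, path) -> None:
    """HDF5 layout: /data (channels x samples, float64 T), /rate, /ids."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("rate", data=float(recording.rate))
        f.create_dataset("ids", data=np.array(recording.ids, dtype="S"))


def read_recording_h5(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        rate = float(f["rate"][()])
        ids = tuple(s.decode() for s in f["ids"][()])
    return Recording(ids, data, rate)


def write_recording_csv(recording: Recording, path) -> None:
    """Plain CSV fallback for small fixtures: first column channel id, then
    samples; a leading ``# rate=<Hz>`` comment carries the rate."""
    lines = [f"# rate={recording.rate:g}"]
    for sid, row in zip(recording.ids, recording.data):
        lines.append(sid + "," + ",".join(f"{v:.9e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_recording_csv(path) -> Recording:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# rate="):
        raise ParameterError(f"bad recording CSV header in {path}")
    rate = float(lines[0].split("=", 1)[1])
    ids, rows = [], []
    for ln in lines[1:]:
        parts = ln.split(",")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return Recording(tuple(ids), np.array(rows), rate)
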