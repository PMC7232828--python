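"""Session data model and readers/writers.

A recording session holds six ECoG channels on a 2x3 bilateral grid
(left/right x anterior/middle/posterior), one nuchal EMG channel, a
3-axis headstage accelerometer, a 2-D overhead position track, and the
session's epoch layout (Rest1 / Task / Rest2).  All channels share time
zero; times are seconds from session start and intervals are half-open
``[start, end)``.

Supported on-disk formats:

* ``native`` -- one ``.npy`` array per channel plus a JSON sidecar with
  labels, rates, units, epochs and metadata (lossless round-trip);
* ``edf``    -- EDF/EDF+ for ECoG/EMG, read through :mod:`mne`, with a
  user-supplied map from EDF signal labels to grid slots;
* ``tabular`` -- delimited tables with a header row for accelerometer
  ``(t, ax, ay, az)``, position ``(t, x, y)`` and behavior tables.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

ECOG_SLOTS = (
    "left_anterior", "left_middle", "left_posterior",
    "right_anterior", "right_middle", "right_posterior",
)
EPOCH_LABELS = ("Rest1", "Task", "Rest2")


@dataclass
class TimeSeriesChannel:
    """A uniformly sampled channel starting at session time zero."""

    label: str
    samples: np.ndarray
    sampling_rate: float
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def crop(self, start_s: float, end_s: float) -> "TimeSeriesChannel":
        """Samples with start_s <= t < end_s, re-zeroed to start_s."""
        i0 = int(round(start_s * self.sampling_rate))
        i1 = int(round(end_s * self.sampling_rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        return replace(self, samples=self.samples[i0:i1].copy())


class IntervalSet:
    """Sorted, non-overlapping half-open intervals ``[start, end)`` in seconds.

    Used for hypnograms (sleep bouts) and analysis-window masks.
    """

    def __init__(self, intervals=()) -> None:
        arr = np.asarray(list(intervals), dtype=float).reshape(-1, 2)
        if arr.size:
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("every interval must satisfy end > start")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("intervals overlap")
        self._arr = arr

    @property
    def intervals(self) -> np.ndarray:
        return self._arr.copy()

    def __len__(self) -> int:
        return self._arr.shape[0]

    def __iter__(self):
        return iter(map(tuple, self._arr))

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and np.array_equal(self._arr, other._arr)

    def __repr__(self) -> str:
        return f"IntervalSet({self._arr.tolist()!r})"

    def durations(self) -> np.ndarray:
        if not len(self):
            return np.empty(0)
        return self._arr[:, 1] - self._arr[:, 0]

    def total_duration(self) -> float:
        return float(self.durations().sum())

    def contains_interval(self, start: float, end: float, tol: float = 1e-9) -> bool:
        """True if [start, end) lies inside a single member interval."""
        for a, b in self._arr:
            if start >= a - tol and end <= b + tol:
                return True
        return False

    def contains_times(self, t: np.ndarray) -> np.ndarray:
        """Boolean membership per time point."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for a, b in self._arr:
            out |= (t >= a) & (t < b)
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        for a0, a1 in self._arr:
            for b0, b1 in other._arr:
                lo, hi = max(a0, b0), min(a1, b1)
                if hi > lo:
                    out.append((lo, hi))
        return IntervalSet(out)

    def shift(self, offset: float) -> "IntervalSet":
        return IntervalSet(self._arr + offset)

    @staticmethod
    def from_mask(mask: np.ndarray, bin_s: float, t0: float = 0.0) -> "IntervalSet":
        """Intervals covering maximal True runs of a uniformly binned mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0:
            return IntervalSet()
        edges = np.diff(mask.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if mask[0]:
            starts.insert(0, 0)
        if mask[-1]:
            ends.append(mask.size)
        return IntervalSet([(t0 + s * bin_s, t0 + e * bin_s) for s, e in zip(starts, ends)])


@dataclass
class Recording:
    """One session: channels, epoch layout and metadata.

    ``ecog`` maps grid slots (see :data:`ECOG_SLOTS`) to channels; a slot
    absent from the dict is explicitly missing.  ``epochs`` is an ordered,
    non-overlapping list of ``(label, start_s, end_s)``.
    """

    ecog: dict = field(default_factory=dict)
    emg: TimeSeriesChannel | None = None
    accel: list | None = None            # [x, y, z] channels, m/s^2
    position: list | None = None         # [x, y] channels, cm
    epochs: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for slot in self.ecog:
            if slot not in ECOG_SLOTS:
                raise ValueError(f"unknown ECoG slot {slot!r}; expected one of {ECOG_SLOTS}")
        prev_end = -math.inf
        for label, start, end in self.epochs:
            if end <= start:
                raise ValueError(f"epoch {label!r} has end <= start")
            if start < prev_end:
                raise ValueError("epochs overlap or are out of order")
            prev_end = end

    def epoch_span(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.epochs:
            if lab == label:
                return float(start), float(end)
        available = [lab for lab, *_ in self.epochs]
        raise KeyError(f"epoch {label!r} not found; available: {available}")

    def all_channels(self):
        chans = list(self.ecog.values())
        if self.emg is not None:
            chans.append(self.emg)
        for group in (self.accel, self.position):
            if group is not None:
                chans.extend(group)
        return chans


# ---------------------------------------------------------------------------
# epoch slicing and rate conversion

def slice_epoch(rec: Recording, label: str) -> Recording:
    """Crop every channel to the named epoch and re-zero its clock.

    Metadata is preserved; the epoch list of the result contains the single
    sliced epoch starting at time 0.
    """
    start, end = rec.epoch_span(label)
    return Recording(
        ecog={slot: ch.crop(start, end) for slot, ch in rec.ecog.items()},
        emg=rec.emg.crop(start, end) if rec.emg is not None else None,
        accel=[ch.crop(start, end) for ch in rec.accel] if rec.accel is not None else None,
        position=[ch.crop(start, end) for ch in rec.position] if rec.position is not None else None,
        epochs=[(label, 0.0, end - start)],
        meta=dict(rec.meta),
    )


def decimate_channel(ch: TimeSeriesChannel, target_rate: float) -> TimeSeriesChannel:
    """Anti-aliased resampling to ``target_rate`` (<= source rate).

    Integer and rational rate ratios are handled with a polyphase FIR
    resampler; duration is preserved to within one sample period.
    """
    if target_rate > ch.sampling_rate:
        raise ValueError(
            f"target_rate {target_rate} Hz exceeds source rate {ch.sampling_rate} Hz"
        )
    if math.isclose(target_rate, ch.sampling_rate):
        return replace(ch, samples=ch.samples.copy())
    frac = Fraction(target_rate / ch.sampling_rate).limit_denominator(10_000)
    out = sps.resample_poly(ch.samples, frac.numerator, frac.denominator)
    return TimeSeriesChannel(ch.label, out, sampling_rate=target_rate, units=ch.units)


# ---------------------------------------------------------------------------
# native format: .npy per channel + JSON sidecar

def save_recording(rec: Recording, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {"epochs": [[lab, s, e] for lab, s, e in rec.epochs],
               "meta": rec.meta, "channels": {}}

    def _put(key: str, ch: TimeSeriesChannel) -> None:
        np.save(path / f"{key}.npy", ch.samples)
        sidecar["channels"][key] = {
            "label": ch.label, "sampling_rate": ch.sampling_rate, "units": ch.units,
        }

    for slot, ch in rec.ecog.items():
        _put(f"ecog_{slot}", ch)
    if rec.emg is not None:
        _put("emg", rec.emg)
    if rec.accel is not None:
        for ax, ch in zip("xyz", rec.accel):
            _put(f"accel_{ax}", ch)
    if rec.position is not None:
        for ax, ch in zip("xy", rec.position):
            _put(f"position_{ax}", ch)
    (path / "sidecar.json").write_text(json.dumps(sidecar, indent=1))


def _load_native(path: Path) -> Recording:
    sidecar = json.loads((path / "sidecar.json").read_text())

    def _get(key: str) -> TimeSeriesChannel:
        info = sidecar["channels"][key]
        return TimeSeriesChannel(info["label"], np.load(path / f"{key}.npy"),
                                 info["sampling_rate"], info["units"])

    keys = sidecar["channels"]
    ecog = {slot: _get(f"ecog_{slot}") for slot in ECOG_SLOTS if f"ecog_{slot}" in keys}
    emg = _get("emg") if "emg" in keys else None
    accel = [_get(f"accel_{ax}") for ax in "xyz"] if "accel_x" in keys else None
    position = [_get(f"position_{ax}") for ax in "xy"] if "position_x" in keys else None
    return Recording(ecog=ecog, emg=emg, accel=accel, position=position,
                     epochs=[tuple(e) for e in sidecar["epochs"]], meta=sidecar["meta"])


# ---------------------------------------------------------------------------
# EDF and tabular readers

def _load_edf(path: Path, channel_map: dict | None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    data = raw.get_data()
    labels = raw.ch_names
    if channel_map is None:
        channel_map = {}
        for name in labels:
            key = name.strip().lower().replace(" ", "_")
            if key in ECOG_SLOTS or key == "emg":
                channel_map[name] = key
    ecog, emg = {}, None
    for name, target in channel_map.items():
        if name not in labels:
            raise ValueError(f"EDF signal {name!r} not found; file has {labels}")
        ch = TimeSeriesChannel(name, data[labels.index(name)], sfreq, units="uV")
        if target == "emg":
            emg = ch
        elif target in ECOG_SLOTS:
            ecog[target] = ch
        else:
            raise ValueError(f"channel map target {target!r} is not a known slot")
    if "right_anterior" not in ecog:
        raise ValueError("mandatory channel missing: right_anterior ECoG")
    return Recording(ecog=ecog, emg=emg)


def load_accel_table(path, sampling_rate: float | None = None) -> list:
    """Read ``(t, ax, ay, az)`` CSV/TSV into three accelerometer channels."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"t", "ax", "ay", "az"}
    if not required.issubset(df.columns):
        raise ValueError(f"accelerometer table needs columns {sorted(required)}")
    if sampling_rate is None:
        dt = np.diff(df["t"].to_numpy())
        sampling_rate = 1.0 / float(np.median(dt))
    return [TimeSeriesChannel(f"accel_{ax}", df[f"a{ax}"].to_numpy(), sampling_rate, "m/s^2")
            for ax in "xyz"]


def load_position_table(path, fps: float | None = None) -> list:
    """Read ``(t, x, y)`` CSV/TSV into a position channel pair (cm)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"t", "x", "y"}.issubset(df.columns):
        raise ValueError("position table needs columns t, x, y")
    if fps is None:
        fps = 1.0 / float(np.nanmedian(np.diff(df["t"].to_numpy())))
    return [TimeSeriesChannel(f"position_{ax}", df[ax].to_numpy(), fps, "cm") for ax in "xy"]


def load_behavior_table(path) -> pd.DataFrame:
    """Read a ``(subject, day, trial, latency_s)`` behavior table."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject", "day", "trial", "latency_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"behavior table needs columns {sorted(required)}")
    return df


def load_recording(path, format: str = "native", channel_map: dict | None = None) -> Recording:
    """Load a session from ``native`` or ``edf`` storage.

    ``channel_map`` (EDF only) maps EDF signal labels to grid slots /
    ``"emg"``; without it, signal labels matching slot names are used.
    """
    path = Path(path)
    if format == "native":
        return _load_native(path)
    if format == "edf":
        return _load_edf(path, channel_map)
    raise ValueError(f"unknown format {format!r}; expected 'native' or 'edf'")


def export_hypnogram_bed(hyp: IntervalSet, path) -> None:
    """BED-like 3-column interval file: start_s, end_s, 'sleep'."""
    with open(path, "w") as fh:
        for a, b in hyp:
            fh.write(f"{a:.3f}\t{b:.3f}\tsleep\n")
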