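"""Sleep/wake scoring from accelerometer jerk, EMG tone, and locomotion speed.

A 1-s bin is a *candidate* sleep bin when at least two of three quiescence
conditions hold: summed absolute jerk below 1 m/s^3, EMG muscle tone below a
session-specific threshold, and speed below 2 cm/s.  Maximal runs of
candidate bins lasting strictly longer than 40 s become sleep bouts; scoring
is restricted to a 110-min analysis window starting 5 min into each rest
epoch.  The EMG threshold, scored visually in the original workflow, is here
a logged quantile of the session's tone distribution with a manual override.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .recording import IntervalSet, Recording, TimeSeriesChannel

log = logging.getLogger(__name__)


@dataclass
class SleepCriteria:
    """Thresholds for the 2-of-3 sleep rule."""

    jerk_threshold: float = 1.0        # m/s^3 per bin
    emg_threshold: float | None = None  # session tone units; None -> quantile rule
    emg_quantile: float = 0.6
    speed_threshold: float = 2.0       # cm/s
    min_sleep_duration_s: float = 40.0  # runs must exceed this (strict)
    bin_s: float = 1.0

    def __post_init__(self) -> None:
        if self.jerk_threshold <= 0 or self.speed_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.emg_threshold is not None and self.emg_threshold <= 0:
            raise ValueError("emg_threshold must be > 0")
        if self.min_sleep_duration_s < self.bin_s:
            raise ValueError("min_sleep_duration_s must be >= bin_s")


@dataclass
class FeatureSeries:
    """Per-bin features on a uniform grid; a missing stream is None."""

    t: np.ndarray                    # bin centers, s
    bin_s: float
    jerk: np.ndarray | None = None       # m/s^3
    emg_tone: np.ndarray | None = None   # tone units
    speed: np.ndarray | None = None      # cm/s
    t0: float = 0.0                  # left edge of the first bin

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("jerk", "emg_tone", "speed"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ValueError(f"{name} length {arr.size} != {n}")

    @property
    def n_bins(self) -> int:
        return self.t.size


def _bin_reduce(x: np.ndarray, samples_per_bin: int, reduce=np.mean) -> np.ndarray:
    n_bins = x.size // samples_per_bin
    if n_bins == 0:
        raise ValueError("signal shorter than one bin")
    return reduce(x[: n_bins * samples_per_bin].reshape(n_bins, samples_per_bin), axis=1)


def compute_jerk(accel: list[TimeSeriesChannel], bin_s: float = 1.0) -> np.ndarray:
    """Per-bin summed absolute jerk, m/s^3.

    jerk(bin) = sum over samples in the bin, over the three axes, of
    |a[i] - a[i-1]| * rate; the first sample's derivative is taken as 0.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    n = {ch.n_samples for ch in accel}
    if len(n) != 1:
        raise ValueError(f"accelerometer axes have mismatched lengths {sorted(n)}")
    rate = accel[0].sampling_rate
    total = np.zeros(accel[0].n_samples)
    for ch in accel:
        d = np.abs(np.diff(ch.samples, prepend=ch.samples[:1])) * rate
        total += d
    return _bin_reduce(total, int(round(bin_s * rate)), reduce=np.sum)


def compute_emg_tone(emg: TimeSeriesChannel, band=(70.0, 250.0),
                     smooth_ms: float = 200.0) -> TimeSeriesChannel:
    """Muscle tone: band-pass 70-250 Hz, rectify, 200-ms centered moving average.

    Returns a full-rate channel; bin with :func:`bin_tone` for scoring.
    """
    nyq = emg.sampling_rate / 2
    if band[1] >= nyq:
        raise ValueError(
            f"EMG rate {emg.sampling_rate} Hz too low for the {band[0]}-{band[1]} Hz "
            f"band; need > {2 * band[1]} Hz"
        )
    sos = sps.butter(4, band, btype="bandpass", fs=emg.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, emg.samples)
    win = max(int(round(smooth_ms / 1000 * emg.sampling_rate)), 1)
    tone = ndimage.uniform_filter1d(np.abs(filtered), win, mode="nearest")
    return TimeSeriesChannel("emg_tone", tone, emg.sampling_rate, "tone")


def bin_tone(tone: TimeSeriesChannel, bin_s: float = 1.0) -> np.ndarray:
    return _bin_reduce(tone.samples, int(round(bin_s * tone.sampling_rate)))


def compute_speed(position: list[TimeSeriesChannel], bin_s: float = 1.0,
                  smooth_s: float = 0.5, max_gap_s: float = 1.0) -> np.ndarray:
    """Per-bin locomotion speed (cm/s) from the x,y track.

    Per-frame displacement over the frame interval, median-smoothed over
    ``smooth_s``, averaged per bin.  NaN frames (tracking dropouts) are
    linearly interpolated for gaps up to ``max_gap_s``.
    """
    x, y = (ch.samples.copy() for ch in position)
    fps = position[0].sampling_rate
    bad = np.isnan(x) | np.isnan(y)
    if bad.mean() > 0.5:
        raise ValueError(f"{bad.mean():.0%} of position frames are NaN (> 50%)")
    if bad.any():
        idx = np.arange(x.size)
        for arr in (x, y):
            arr[bad] = np.interp(idx[bad], idx[~bad], arr[~bad])
        # leave long gaps NaN: find runs of bad frames longer than max_gap_s
        gaps = IntervalSet.from_mask(bad, 1.0 / fps)
        for a, b in gaps:
            if b - a > max_gap_s:
                sl = slice(int(round(a * fps)), int(round(b * fps)))
                x[sl] = np.nan
                y[sl] = np.nan
    speed = np.hypot(np.diff(x, prepend=x[:1]), np.diff(y, prepend=y[:1])) * fps
    k = int(round(smooth_s * fps))
    k += 1 - k % 2  # odd kernel
    if k >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            speed = sps.medfilt(np.nan_to_num(speed, nan=0.0), kernel_size=k)
    return _bin_reduce(speed, int(round(bin_s * fps)))


def score_emg_threshold(tone: np.ndarray, bin_s: float = 1.0,
                        quantile: float = 0.6) -> float:
    """Automatic session EMG-tone threshold: a quantile of the tone distribution.

    Stands in for per-session visual scoring; the value is logged so the
    provenance of every hypnogram is recoverable.  Requires >= 10 min of tone.
    """
    tone = np.asarray(tone, dtype=float)
    if tone.size * bin_s < 600:
        raise ValueError("need >= 10 min of tone data to estimate a threshold")
    if np.ptp(tone) == 0:
        raise ValueError("tone is constant; set SleepCriteria.emg_threshold manually")
    thr = float(np.quantile(tone, quantile))
    log.info("EMG tone threshold = %.6g (quantile %.2f of %d bins)", thr, quantile, tone.size)
    return thr


def build_features(rec: Recording, window: IntervalSet, criteria: SleepCriteria,
                   emg_tone: TimeSeriesChannel | None = None) -> FeatureSeries:
    """Per-bin jerk / EMG tone / speed over an analysis window.

    Streams absent from the recording yield None features (the classifier
    then requires both remaining conditions).  Pass a precomputed session-
    level tone channel (``emg_tone``) to avoid refiltering per window.
    """
    if len(window) != 1:
        raise ValueError("expected a single-interval analysis window")
    (t0, t1), = window
    n_bins = int((t1 - t0) // criteria.bin_s)
    t = t0 + (np.arange(n_bins) + 0.5) * criteria.bin_s

    jerk = emg = speed = None
    if rec.accel is not None:
        jerk = compute_jerk([ch.crop(t0, t1) for ch in rec.accel], criteria.bin_s)[:n_bins]
    if emg_tone is not None or rec.emg is not None:
        tone = emg_tone if emg_tone is not None else compute_emg_tone(rec.emg)
        emg = bin_tone(tone.crop(t0, t1), criteria.bin_s)[:n_bins]
    if rec.position is not None:
        speed = compute_speed([ch.crop(t0, t1) for ch in rec.position], criteria.bin_s)[:n_bins]
    return FeatureSeries(t=t, bin_s=criteria.bin_s, jerk=jerk, emg_tone=emg,
                         speed=speed, t0=t0)


def classify_sleep(features: FeatureSeries, criteria: SleepCriteria) -> IntervalSet:
    """Hypnogram from the 2-of-3 quiescence rule with strict >40-s persistence.

    Conditions per bin: C1 jerk < jerk_threshold, C2 emg_tone < emg_threshold,
    C3 speed < speed_threshold.  Bins where >= 2 of 3 hold are candidates;
    maximal candidate runs strictly longer than ``min_sleep_duration_s``
    become sleep bouts.  With a missing stream, both remaining conditions
    must hold (logged).
    """
    if features.n_bins == 0:
        raise ValueError("empty feature series")
    conds = []
    if features.jerk is not None:
        conds.append(features.jerk < criteria.jerk_threshold)
    if features.emg_tone is not None:
        thr = criteria.emg_threshold
        if thr is None:
            thr = score_emg_threshold(features.emg_tone, features.bin_s, criteria.emg_quantile)
        conds.append(features.emg_tone < thr)
    if features.speed is not None:
        conds.append(features.speed < criteria.speed_threshold)
    if len(conds) < 2:
        raise ValueError("need at least two feature streams to score sleep")
    if len(conds) == 2:
        log.warning("one feature stream missing: requiring both remaining conditions")
        candidate = conds[0] & conds[1]
    else:
        candidate = np.sum(conds, axis=0) >= 2

    runs = IntervalSet.from_mask(candidate, features.bin_s, t0=features.t0)
    kept = [(a, b) for a, b in runs if (b - a) > criteria.min_sleep_duration_s]
    return IntervalSet(kept)


def analysis_window(epoch_span: tuple[float, float], offset_s: float = 300.0,
                    duration_s: float = 6600.0) -> IntervalSet:
    """Analysis mask for one rest epoch: [start+offset, start+offset+duration).

    Defaults give the 110-min window beginning 5 min after epoch start.  A
    window extending past the epoch end is truncated with a warning.
    """
    start, end = epoch_span
    w0 = start + offset_s
    w1 = w0 + duration_s
    if w0 >= end:
        raise ValueError(f"epoch of {end - start:.0f} s is shorter than the {offset_s:.0f}-s offset")
    if w1 > end:
        warnings.warn(
            f"analysis window truncated from {duration_s:.0f} s to {end - w0:.0f} s "
            "by the epoch end", stacklevel=2)
        w1 = end
    return IntervalSet([(w0, w1)])
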