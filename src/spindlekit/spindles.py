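"""Sigma-band sleep-spindle detection on re-referenced ECoG.

The detector follows a dual-threshold crossing scheme: the right-anterior
ECoG channel is re-referenced against the left-hemisphere common average,
band-pass filtered to the sigma band (9-16 Hz, order-12 Butterworth,
zero phase), and converted to an amplitude envelope smoothed with a 20-ms
Hanning kernel.  Envelope samples during scored sleep are Winsorized at the
10th/90th percentiles to yield a robust center and SD; candidate events are
maximal excursions above 1.7 SD containing a sample above 2.5 SD (strict),
kept when they last 0.5-2 s (inclusive) and fall entirely within a sleep
bout.  Each event is quantified by duration, percent sigma-power increase
over baseline sleep, and Burg (order 40) peak frequency within the band.

The amplitude envelope is computed as ``(2/pi) * |analytic signal|`` of the
filtered trace before smoothing.  This equals the cycle-averaged rectified
amplitude (a pure in-band tone of amplitude A gives a plateau of 2A/pi), but
is free of the rectification ripple at twice the oscillation frequency,
which the short 20-ms kernel cannot remove and which would otherwise cut
every supra-threshold excursion into sub-cycle fragments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sps

from .recording import IntervalSet, Recording

log = logging.getLogger(__name__)


@dataclass
class SpindleParams:
    sigma_band: tuple = (9.0, 16.0)      # Hz
    filter_order: int = 12               # final band-pass order (Butterworth)
    smooth_window_ms: float = 20.0       # Hanning kernel width
    peak_z: float = 2.5                  # SD units, strict >
    edge_z: float = 1.7                  # SD units, strict >
    min_dur_s: float = 0.5               # inclusive
    max_dur_s: float = 2.0               # inclusive
    winsor_limits: tuple = (10.0, 90.0)  # percentiles
    burg_order: int = 40
    burg_input: str = "raw"              # "raw" | "filtered" event segment

    def __post_init__(self) -> None:
        if not 0 < self.edge_z < self.peak_z:
            raise ValueError("require 0 < edge_z < peak_z")
        if not 0 < self.min_dur_s < self.max_dur_s:
            raise ValueError("require 0 < min_dur_s < max_dur_s")
        if not self.sigma_band[0] < self.sigma_band[1]:
            raise ValueError("band low must be < band high")
        if not self.winsor_limits[0] < self.winsor_limits[1]:
            raise ValueError("winsor percentiles must be strictly ordered")
        if self.burg_input not in ("raw", "filtered"):
            raise ValueError("burg_input must be 'raw' or 'filtered'")


@dataclass
class SpindleEvent:
    start_s: float
    end_s: float
    peak_z: float
    amplitude_pct: float = np.nan
    peak_freq_hz: float = np.nan

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def events_to_frame(events, session_id: str | None = None):
    import pandas as pd

    rows = [{"start_s": e.start_s, "end_s": e.end_s, "duration_s": e.duration_s,
             "peak_z": e.peak_z, "amplitude_pct": e.amplitude_pct,
             "peak_freq_hz": e.peak_freq_hz} for e in events]
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s", "peak_z",
                                     "amplitude_pct", "peak_freq_hz"])
    if session_id is not None:
        df["session"] = session_id
    return df


# ---------------------------------------------------------------------------
# signal chain

LEFT_SLOTS = ("left_anterior", "left_middle", "left_posterior")


def common_average_reference(rec: Recording) -> tuple[np.ndarray, float]:
    """Right-anterior ECoG minus the mean of the left-hemisphere channels.

    Returns ``(signal, sampling_rate)``.  Requires the right-anterior slot
    and at least one left-hemisphere slot.
    """
    if "right_anterior" not in rec.ecog:
        raise ValueError("spindle detection requires the right_anterior ECoG channel")
    left = [rec.ecog[s] for s in LEFT_SLOTS if s in rec.ecog]
    if not left:
        raise ValueError(f"no left-hemisphere ECoG channel present (need one of {LEFT_SLOTS})")
    ra = rec.ecog["right_anterior"]
    rates = {ra.sampling_rate} | {ch.sampling_rate for ch in left}
    if len(rates) != 1:
        raise ValueError(f"ECoG channels have mixed sampling rates {sorted(rates)}")
    ref = ra.samples - np.mean([ch.samples for ch in left], axis=0)
    return ref, ra.sampling_rate


def _sigma_sos(fs: float, params: SpindleParams):
    # scipy's butter doubles the order for a band-pass design
    return sps.butter(params.filter_order // 2, params.sigma_band,
                      btype="bandpass", fs=fs, output="sos")


def sigma_filter(signal: np.ndarray, fs: float, params: SpindleParams) -> np.ndarray:
    """Zero-phase sigma-band Butterworth filtering (second-order sections)."""
    if fs < 4 * params.sigma_band[1]:
        if fs < 2 * params.sigma_band[1]:
            raise ValueError(f"sampling rate {fs} Hz below Nyquist for the sigma band")
        log.warning("sampling rate %g Hz is marginal for a %g-Hz band edge", fs,
                    params.sigma_band[1])
    out = sps.sosfiltfilt(_sigma_sos(fs, params), signal)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("sigma-band filter produced non-finite output")
    return out


def sigma_band_gain(freq_hz, fs: float, params: SpindleParams) -> np.ndarray:
    """Amplitude gain of the zero-phase filter chain at given frequencies.

    Forward-backward filtering applies the magnitude response twice.
    """
    _, h = sps.sosfreqz(_sigma_sos(fs, params), worN=np.atleast_1d(freq_hz), fs=fs)
    return np.abs(h) ** 2


def sigma_envelope(signal: np.ndarray, fs: float, params: SpindleParams | None = None) -> np.ndarray:
    """Smoothed sigma-band amplitude envelope (cycle-averaged rectified units)."""
    params = params or SpindleParams()
    filtered = sigma_filter(np.asarray(signal, dtype=float), fs, params)
    n = filtered.size
    analytic = sps.hilbert(filtered, N=sp_fft.next_fast_len(n))[:n]
    env = (2.0 / np.pi) * np.abs(analytic)
    win = int(round(params.smooth_window_ms / 1000 * fs))
    if win >= 2:
        kernel = sps.windows.hann(win)
        kernel /= kernel.sum()
        env = sps.convolve(env, kernel, mode="same", method="auto")
    return env


def winsorized_sd(values: np.ndarray, limits: tuple = (10.0, 90.0)) -> tuple[float, float]:
    """Winsorized mean and SD: clip outside the given percentiles, then moment.

    Robust to the spindle excursions themselves; z-scoring uses
    ``(x - center) / sd``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError(f"need >= 100 samples for Winsorized statistics, got {values.size}")
    lo, hi = np.percentile(values, limits)
    clipped = np.clip(values, lo, hi)
    center = float(np.mean(clipped))
    sd = float(np.std(clipped, ddof=1))
    if sd == 0:
        raise ValueError("degenerate envelope: Winsorized SD is zero")
    return center, sd


def detect_candidates(envelope: np.ndarray, center: float, sd: float,
                      params: SpindleParams, fs: float, t0: float = 0.0) -> list:
    """Maximal excursions above edge_z containing a sample above peak_z.

    Both thresholds are strict.  Boundaries sit at the edge_z crossings;
    returns ``(start_s, end_s, peak_z)`` triples (half-open, seconds).
    """
    z = (np.asarray(envelope, dtype=float) - center) / sd
    above = z > params.edge_z
    out = []
    for a, b in IntervalSet.from_mask(above, 1.0, 0.0).intervals.astype(int):
        zmax = float(np.max(z[a:b]))
        if zmax > params.peak_z:
            out.append((t0 + a / fs, t0 + b / fs, zmax))
    return out


def gate_events(candidates, hypnogram: IntervalSet, params: SpindleParams) -> list[SpindleEvent]:
    """Duration gate (min_dur_s <= d <= max_dur_s, inclusive) and sleep containment."""
    kept = []
    for start, end, peak in candidates:
        dur = end - start
        if not params.min_dur_s <= dur <= params.max_dur_s:
            log.debug("candidate at %.2f s dropped: duration %.3f s out of bounds", start, dur)
            continue
        if not hypnogram.contains_interval(start, end):
            log.debug("candidate at %.2f s dropped: not contained in sleep", start)
            continue
        kept.append(SpindleEvent(start_s=start, end_s=end, peak_z=peak))
    return kept


def spindle_amplitude(event: SpindleEvent, envelope: np.ndarray, baseline: float,
                      fs: float, t0: float = 0.0) -> float:
    """Percent increase of sigma power during the event over baseline sleep.

    ``baseline`` is the mean squared envelope over sleep samples outside all
    detected events (see :func:`sleep_baseline_power`).
    """
    if baseline <= 0:
        raise ValueError("baseline sigma power must be > 0")
    i0 = int(round((event.start_s - t0) * fs))
    i1 = int(round((event.end_s - t0) * fs))
    power = float(np.mean(envelope[i0:i1] ** 2))
    return 100.0 * (power - baseline) / baseline


def sleep_baseline_power(envelope: np.ndarray, hypnogram: IntervalSet, events,
                         fs: float, t0: float = 0.0) -> float:
    t = t0 + np.arange(envelope.size) / fs
    mask = hypnogram.contains_times(t)
    for e in events:
        mask &= ~((t >= e.start_s) & (t < e.end_s))
    if not mask.any():
        raise ValueError("no sleep samples outside events; cannot form a baseline")
    return float(np.mean(envelope[mask] ** 2))


def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg's method: AR polynomial coefficients and driving-noise variance.

    Returns ``(a, E)`` with ``A(z) = 1 + a[1] z^-1 + ... + a[order] z^-order``
    minimizing the combined forward/backward prediction error; the AR power
    spectrum is ``E / |A(e^{-i omega})|^2``.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= order:
        raise ValueError(f"need more than {order} samples for AR order {order}")
    ef = x.copy()
    eb = x.copy()
    a = np.array([1.0])
    E = float(np.dot(x, x)) / x.size
    for _ in range(order):
        efp = ef[1:]
        ebp = eb[:-1]
        den = np.dot(efp, efp) + np.dot(ebp, ebp)
        if den == 0:
            raise ValueError("degenerate segment: zero prediction-error energy")
        k = -2.0 * np.dot(ebp, efp) / den
        ef = efp + k * ebp
        eb = ebp + k * efp
        a = np.append(a, 0.0)
        a = a + k * a[::-1]
        E *= 1.0 - k * k
    return a, E


def spindle_peak_frequency(segment: np.ndarray, fs: float,
                           params: SpindleParams | None = None) -> float:
    """Peak of the Burg AR spectrum of an event segment, restricted to the band.

    The AR order (default 40) is reduced to floor(N/3) with a warning when
    the segment is too short.  The spectrum is evaluated on a 0.05-Hz grid.
    """
    params = params or SpindleParams()
    segment = np.asarray(segment, dtype=float)
    order = params.burg_order
    if segment.size < order + 1:
        order = max(segment.size // 3, 2)
        warnings.warn(f"segment of {segment.size} samples too short for AR order "
                      f"{params.burg_order}; reduced to {order}", stacklevel=2)
    a, E = burg_ar(segment - segment.mean(), order)
    freqs = np.arange(params.sigma_band[0], params.sigma_band[1] + 1e-9, 0.05)
    phase = np.exp(-2j * np.pi * np.outer(freqs, np.arange(order + 1)) / fs)
    psd = E / np.abs(phase @ a) ** 2
    return float(freqs[np.argmax(psd)])


# ---------------------------------------------------------------------------
# full chain

def detect_spindles_on_signal(signal: np.ndarray, fs: float, hypnogram: IntervalSet,
                              params: SpindleParams | None = None,
                              t0: float = 0.0) -> list[SpindleEvent]:
    """Detector on an already re-referenced trace; deterministic given inputs."""
    params = params or SpindleParams()
    envelope = sigma_envelope(signal, fs, params)
    t = t0 + np.arange(envelope.size) / fs
    sleep_mask = hypnogram.contains_times(t)
    if not sleep_mask.any():
        return []
    center, sd = winsorized_sd(envelope[sleep_mask], params.winsor_limits)
    candidates = detect_candidates(envelope, center, sd, params, fs, t0)
    events = gate_events(candidates, hypnogram, params)
    if not events:
        return events
    baseline = sleep_baseline_power(envelope, hypnogram, events, fs, t0)
    source = signal if params.burg_input == "raw" else sigma_filter(signal, fs, params)
    for e in events:
        e.amplitude_pct = spindle_amplitude(e, envelope, baseline, fs, t0)
        i0 = int(round((e.start_s - t0) * fs))
        i1 = int(round((e.end_s - t0) * fs))
        e.peak_freq_hz = spindle_peak_frequency(source[i0:i1], fs, params)
    return events


def detect_spindles(rec: Recording, hypnogram: IntervalSet,
                    params: SpindleParams | None = None) -> list[SpindleEvent]:
    """Re-reference, then run the threshold-crossing detector over the session."""
    signal, fs = common_average_reference(rec)
    return detect_spindles_on_signal(signal, fs, hypnogram, params)
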