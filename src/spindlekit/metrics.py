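"""Per-session fragmentation and spindle summary metrics, plus subject QC.

Fragmentation is summarized as percent time asleep, sleep bouts per minute
of analysis window, and mean bout duration; spindle activity as spindles
per minute of sleep plus mean event duration, amplitude, and peak
frequency.  When Rest1 and Rest2 are combined, seconds and counts are
pooled across both windows before dividing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .recording import IntervalSet


@dataclass
class SessionMetrics:
    subject: str = ""
    day: str = ""
    epoch: str = ""      # Rest1 / Rest2 / combined
    task: str = ""
    week: int = 0
    pct_time_asleep: float = np.nan
    bouts_per_min: float = np.nan
    mean_bout_dur_s: float = np.nan
    n_bouts: int = 0
    spindle_density: float = np.nan  # events per minute of sleep
    mean_spindle_dur_s: float = np.nan
    mean_amplitude_pct: float = np.nan
    mean_peak_freq_hz: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def fragmentation_metrics(hypnogram: IntervalSet, window: IntervalSet,
                          **keys) -> SessionMetrics:
    """Sleep-architecture metrics of one or more pooled analysis windows.

    ``window`` may contain several intervals (e.g. Rest1 + Rest2 combined);
    durations and bout counts are pooled before forming rates.
    """
    win_s = window.total_duration()
    if win_s <= 0:
        raise ValueError("empty analysis window")
    clipped = hypnogram.intersect(window)
    if not np.isclose(clipped.total_duration(), hypnogram.total_duration()):
        raise ValueError("hypnogram extends outside the analysis window")
    durs = clipped.durations()
    return SessionMetrics(
        pct_time_asleep=100.0 * durs.sum() / win_s if len(durs) else 0.0,
        bouts_per_min=len(clipped) / (win_s / 60.0),
        mean_bout_dur_s=float(durs.mean()) if len(durs) else np.nan,
        n_bouts=len(clipped),
        **keys,
    )


def spindle_density(events, hypnogram: IntervalSet) -> float:
    """Detected events per minute of scored sleep; NaN when there is no sleep."""
    sleep_s = hypnogram.total_duration()
    if sleep_s <= 0:
        return np.nan
    return len(events) / (sleep_s / 60.0)


def spindle_metrics(events, hypnogram: IntervalSet, **keys) -> SessionMetrics:
    m = SessionMetrics(spindle_density=spindle_density(events, hypnogram), **keys)
    if events:
        m.mean_spindle_dur_s = float(np.mean([e.duration_s for e in events]))
        m.mean_amplitude_pct = float(np.nanmean([e.amplitude_pct for e in events]))
        m.mean_peak_freq_hz = float(np.nanmean([e.peak_freq_hz for e in events]))
    return m


def session_metrics(hypnogram: IntervalSet, window: IntervalSet, events,
                    **keys) -> SessionMetrics:
    """Combined fragmentation + spindle metrics for one session/epoch."""
    m = fragmentation_metrics(hypnogram, window, **keys)
    s = spindle_metrics(events, hypnogram)
    m.spindle_density = s.spindle_density
    m.mean_spindle_dur_s = s.mean_spindle_dur_s
    m.mean_amplitude_pct = s.mean_amplitude_pct
    m.mean_peak_freq_hz = s.mean_peak_freq_hz
    return m


def qc_exclude(per_day_counts: pd.DataFrame, max_zero_days_per_week: int = 2) -> pd.DataFrame:
    """Subject-level inclusion flags.

    ``per_day_counts`` needs columns ``subject, week, day, n_spindles`` and
    optionally boolean ``single_hemisphere`` / ``incomplete`` flags.  A
    subject is excluded when it has more than ``max_zero_days_per_week``
    zero-spindle days in either week, was recorded from a single hemisphere,
    or did not complete the experiment.  Returns one row per subject with
    ``included`` and ``reason``.
    """
    required = {"subject", "week", "day", "n_spindles"}
    if not required.issubset(per_day_counts.columns):
        raise ValueError(f"QC table needs columns {sorted(required)}")
    rows = []
    for subject, grp in per_day_counts.groupby("subject", sort=True):
        reason = ""
        if "single_hemisphere" in grp and grp["single_hemisphere"].any():
            reason = "single hemisphere"
        elif "incomplete" in grp and grp["incomplete"].any():
            reason = "incomplete experiment"
        else:
            zero_days = (grp[grp["n_spindles"] == 0].groupby("week")["day"].nunique())
            bad_weeks = zero_days[zero_days > max_zero_days_per_week]
            if len(bad_weeks):
                week = int(bad_weeks.index[0])
                reason = (f"{int(bad_weeks.iloc[0])} zero-spindle days in week {week} "
                          f"(> {max_zero_days_per_week})")
        rows.append({"subject": subject, "included": reason == "", "reason": reason})
    return pd.DataFrame(rows)
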