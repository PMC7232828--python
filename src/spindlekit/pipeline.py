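"""Session- and cohort-level orchestration used by the command line."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (dump_config, sleep_criteria_from_config,
                     spindle_params_from_config, window_for_scale)
from .metrics import qc_exclude, session_metrics
from .recording import IntervalSet, Recording, export_hypnogram_bed
from .sleep import (analysis_window, bin_tone, build_features, classify_sleep,
                    compute_emg_tone, score_emg_threshold)
from .spindles import detect_spindles, events_to_frame
from .simulate import session_from_manifest_row
from .stats import compare_groups_table

log = logging.getLogger(__name__)


def load_hypnogram_bed(path) -> IntervalSet:
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            a, b, *_ = line.split("\t")
            rows.append((float(a), float(b)))
    return IntervalSet(rows)


def score_session_sleep(rec: Recording, cfg: dict) -> dict:
    """Hypnogram per rest epoch plus the union, under the configured criteria."""
    criteria = sleep_criteria_from_config(cfg)
    tone_channel = None
    if rec.emg is not None:
        tone_channel = compute_emg_tone(rec.emg)
        if criteria.emg_threshold is None:
            # session-wide threshold: the tone distribution of the whole session
            tone = bin_tone(tone_channel, criteria.bin_s)
            criteria.emg_threshold = score_emg_threshold(tone, criteria.bin_s,
                                                         criteria.emg_quantile)
    scale = rec.meta.get("scale", "full")
    offset, duration = window_for_scale(cfg, scale)
    out = {"epochs": {}, "windows": {}}
    pieces = []
    for label in ("Rest1", "Rest2"):
        try:
            span = rec.epoch_span(label)
        except KeyError:
            continue
        window = analysis_window(span, offset, duration)
        features = build_features(rec, window, criteria, emg_tone=tone_channel)
        hyp = classify_sleep(features, criteria)
        out["epochs"][label] = hyp
        out["windows"][label] = window
        pieces.extend(hyp)
    out["combined"] = IntervalSet(pieces)
    out["combined_window"] = IntervalSet(
        [iv for w in out["windows"].values() for iv in w])
    return out


def run_session(rec: Recording, cfg: dict, session_id: str | None = None) -> dict:
    """Full per-session pipeline: sleep scoring, spindle detection, metrics."""
    sleep_out = score_session_sleep(rec, cfg)
    params = spindle_params_from_config(cfg)
    events = detect_spindles(rec, sleep_out["combined"], params)

    meta = rec.meta
    keys = dict(subject=str(meta.get("subject", meta.get("preset", ""))),
                day=str(meta.get("day", "")), task=str(meta.get("task", "")),
                week=int(meta.get("week", 0)))
    metric_rows = []
    for label, hyp in sleep_out["epochs"].items():
        ev = [e for e in events if hyp.contains_interval(e.start_s, e.end_s)]
        metric_rows.append(session_metrics(hyp, sleep_out["windows"][label], ev,
                                           epoch=label, **keys).to_dict())
    metric_rows.append(session_metrics(sleep_out["combined"], sleep_out["combined_window"],
                                       events, epoch="combined", **keys).to_dict())
    metrics = pd.DataFrame(metric_rows)
    if session_id is not None:
        metrics.insert(0, "session", session_id)
    return {"hypnogram": sleep_out["combined"], "epochs": sleep_out["epochs"],
            "windows": sleep_out["windows"], "events": events,
            "metrics": metrics}


def write_session_outputs(result: dict, out_dir, cfg: dict, session_id: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_hypnogram_bed(result["hypnogram"], out / "hypnogram.bed")
    durs = result["hypnogram"].durations()
    pd.DataFrame({"bout": np.arange(1, durs.size + 1), "duration_s": durs}).to_csv(
        out / "bouts.csv", index=False)
    events_to_frame(result["events"], session_id).to_csv(out / "events.csv", index=False)
    result["metrics"].to_csv(out / "metrics.csv", index=False)
    dump_config(cfg, out / "config.yaml")
    (out / "version.txt").write_text(__version__ + "\n")


def run_cohort(manifest: pd.DataFrame, cfg: dict,
               loader=session_from_manifest_row) -> dict:
    """Run every manifest row, apply QC, and compare the declared groups.

    ``loader`` maps a manifest row to ``(Recording, GroundTruth-or-None)``;
    the default simulates the session from its preset and seed.  Returns
    tidy metrics, the QC report, and the group-stats table.
    """
    all_metrics, qc_rows = [], []
    for _, row in manifest.iterrows():
        rec, _truth = loader(row)
        rec.meta.update({k: row[k] for k in ("subject", "week", "day", "task")
                         if k in row})
        result = run_session(rec, cfg, session_id=row.get("session"))
        all_metrics.append(result["metrics"])
        qc_rows.append({"subject": row["subject"], "week": int(row.get("week", 1)),
                        "day": str(row.get("day", "")),
                        "n_spindles": len(result["events"])})
        log.info("session %s: %d events", row.get("session"), len(result["events"]))
    metrics = pd.concat(all_metrics, ignore_index=True)
    metrics = metrics.merge(manifest[["subject", "group"]].drop_duplicates(), on="subject")

    qc = qc_exclude(pd.DataFrame(qc_rows))
    included = set(qc.loc[qc["included"], "subject"])

    # genotype-style contrast on per-subject week-1 combined metrics
    combined = metrics[(metrics["epoch"] == "combined") & (metrics["week"] <= 1)]
    combined = combined[combined["subject"].isin(included)]
    per_subject = combined.groupby(["subject", "group"], as_index=False)[
        cfg["stats"]["family"]].mean()
    groups = per_subject["group"].unique()
    stats_table = None
    sizes = per_subject["group"].value_counts()
    if len(groups) >= 2 and min(sizes.get(groups[0], 0), sizes.get(groups[1], 0)) >= 4:
        stats_table = compare_groups_table(per_subject, cfg["stats"]["family"],
                                           "group", groups[0], groups[1],
                                           alpha=cfg["stats"]["alpha"])
        stats_table.insert(0, "contrast", f"{groups[0]}_vs_{groups[1]}")
    return {"metrics": metrics, "qc": qc, "stats": stats_table,
            "per_subject": per_subject}


def write_cohort_outputs(result: dict, out_dir, cfg: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["metrics"].to_csv(out / "metrics.csv", index=False)
    result["qc"].to_csv(out / "qc.csv", index=False)
    if result["stats"] is not None:
        records = result["stats"].to_dict(orient="records")
        (out / "stats.json").write_text(json.dumps(records, indent=1, default=float))
    dump_config(cfg, out / "config.yaml")
    (out / "version.txt").write_text(__version__ + "\n")
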