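import numpy as np
import pytest

import spindlekit as sk


@pytest.fixture(scope="session")
def desk_session():
    """One deterministic desk-scale WT session with ground truth."""
    return sk.simulate_session(sk.preset_params("wt", seed=1))


@pytest.fixture(scope="session")
def desk_session_g():
    return sk.simulate_session(sk.preset_params("g2019s", seed=2))


def write_minimal_edf(path, signals, labels, fs, record_dur_s=1.0):
    """Header-writing oracle: a minimal single-rate EDF file.

    ``signals`` is a (n_chan, n_samples) float array; samples are scaled to
    int16 with a physical range of +/- 1000 units.
    """
    signals = np.asarray(signals, dtype=float)
    n_chan, n_samp = signals.shape
    spr = int(round(fs * record_dur_s))          # samples per record per channel
    n_records = n_samp // spr
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(text, width):
        return str(text)[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("synthetic fixture", 80), pad("synthetic", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 + 256 * n_chan, 8), pad("", 44), pad(n_records, 8),
        pad(record_dur_s, 8), pad(n_chan, 4),
    ])
    header += b"".join(pad(lab, 16) for lab in labels)
    header += b"".join(pad("", 80) for _ in labels)           # transducer
    header += b"".join(pad("uV", 8) for _ in labels)
    header += b"".join(pad(phys_min, 8) for _ in labels)
    header += b"".join(pad(phys_max, 8) for _ in labels)
    header += b"".join(pad(dig_min, 8) for _ in labels)
    header += b"".join(pad(dig_max, 8) for _ in labels)
    header += b"".join(pad("", 80) for _ in labels)           # prefiltering
    header += b"".join(pad(spr, 8) for _ in labels)
    header += b"".join(pad("", 32) for _ in labels)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip((signals - phys_min) * scale + dig_min, dig_min, dig_max)
    digital = np.round(digital).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(n_chan):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())


def brute_force_classify(jerk, emg, speed, thr_jerk, thr_emg, thr_speed,
                         min_dur_s, bin_s, t0=0.0):
    """Independent enumeration oracle for the 2-of-3 + persistence rule."""
    n = len(jerk)
    cand = []
    for i in range(n):
        score = int(jerk[i] < thr_jerk) + int(emg[i] < thr_emg) + int(speed[i] < thr_speed)
        cand.append(score >= 2)
    intervals = []
    i = 0
    while i < n:
        if cand[i]:
            j = i
            while j < n and cand[j]:
                j += 1
            if (j - i) * bin_s > min_dur_s:
                intervals.append((t0 + i * bin_s, t0 + j * bin_s))
            i = j
        else:
            i += 1
    return intervals


def match_events(events, truth_table, min_frac=0.5):
    """Greedy one-to-one matching of detected events to true bursts by overlap."""
    used = set()
    tp = 0
    freq_err = []
    for r in truth_table.itertuples():
        for j, e in enumerate(events):
            if j in used:
                continue
            ov = min(e.end_s, r.end_s) - max(e.start_s, r.start_s)
            if ov >= min_frac * r.duration_s:
                used.add(j)
                tp += 1
                freq_err.append(abs(e.peak_freq_hz - r.freq_hz))
                break
    fp = len(events) - len(used)
    fn = len(truth_table) - tp
    return tp, fp, fn, freq_err
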