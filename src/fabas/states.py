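"""Behavioral-state (heart rate pattern) classification of 10-min windows.

Fetal behavioral states leave characteristic heart rate patterns (HRP):

- HRP I (quiet sleep, 1F): stable heart rate — floating-baseline drift
  below 10 bpm per 3 min, oscillation bandwidth within ±5 bpm, at most two
  isolated accelerations per 10 min, baseline not above 160 bpm.
- HRP II (active sleep, 2F): bandwidth beyond ±5 bpm, at least three
  accelerations (>15 bpm for >15 s) per 10 min, rate above 160 bpm only
  during accelerations.
- HRP III (active awakeness, 4F): long-lasting accelerations above
  160 bpm, frequently fused into sustained tachycardia.

The published classification is an expert consensus; this module is a
transparent rule engine operationalizing the written criteria. Every
evidence number is exported so a human can overrule it via an annotation
file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import BeatIntervalSeries, FabasError, InstantaneousHeartRate, SegmentSpec, extract_segment, instantaneous_hr
from .ctg import EventList, detect_events_sampled

WINDOW_S = 600.0
STEP_S = 60.0
BANDWIDTH_GATE_BPM = 5.0
DRIFT_GATE_BPM_PER_3MIN = 10.0
TACHY_BPM = 160.0
#: HRP III "sustained" tachycardia: time above 160 bpm outside AC (s)
SUSTAINED_TACHY_S = 60.0
#: deviation runs beyond this gate for >15 s (either sign) are excluded from
#: the bandwidth percentiles (robustness to sub-threshold excursions)
EXCLUDE_GATE_BPM = 10.0


@dataclass
class HRPClassification:
    window: SegmentSpec
    label: str  # HRP_I, HRP_II, HRP_III, unclassified
    evidence: dict


def floating_baseline(hr: InstantaneousHeartRate, window_s: float = 180.0) -> np.ndarray:
    """3-min centered moving median of the beat-by-beat rate (time-based
    window), the operational stand-in for the visually determined floating
    baseline."""
    if hr.times[-1] - hr.times[0] < window_s:
        raise FabasError("need at least 3 min for a floating baseline")
    s = pd.Series(hr.values, index=pd.to_timedelta(hr.times, unit="s"))
    med = s.rolling(pd.Timedelta(seconds=window_s), center=True, min_periods=1).median()
    return med.to_numpy()


def _beat_dt(hr: InstantaneousHeartRate) -> np.ndarray:
    # per-sample duration: the interval each beat opens (s)
    return 60.0 / hr.values


def _smooth(values: np.ndarray, times: np.ndarray, window_s: float = 11.0) -> np.ndarray:
    """Centered time-based moving average; beat noise would otherwise split
    an excursion into sub-threshold run fragments."""
    half = window_s / 2.0
    lo = np.searchsorted(times, times - half, side="left")
    hi = np.searchsorted(times, times + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def classify_hrp(
    hr: InstantaneousHeartRate,
    baseline: np.ndarray,
    ac_events: Optional[EventList] = None,
    window: Optional[SegmentSpec] = None,
    tol_s: float = 5.0,
) -> HRPClassification:
    """Classify one exactly-10-min window into HRP I/II/III or unclassified.

    Rules are evaluated as exclusive hits with precedence I, III, II;
    conflicting simultaneous hits yield ``unclassified``.
    """
    span = hr.times[-1] - hr.times[0]
    if abs(span - WINDOW_S) > WINDOW_S * 0.1 + tol_s:
        raise FabasError(f"classification window must span 10 min, got {span:.0f} s")
    dev = hr.values - baseline
    dt = _beat_dt(hr)
    dev_smooth = _smooth(dev, hr.times)

    if ac_events is None:
        ac_events = detect_events_sampled(hr.times, dt, dev_smooth, "state_classification")
    acs = ac_events.of_kind("AC")
    n_ac = len(acs)

    # samples inside any sustained >10 bpm excursion are excluded from the
    # bandwidth estimate; AC spans are excluded from the tachycardia clock
    excl_events = detect_events_sampled(hr.times, dt, dev_smooth, "ctg_dawes").events
    excl = np.zeros(len(hr), dtype=bool)
    for e in excl_events:
        excl |= (hr.times >= e.onset_s) & (hr.times < e.end_s)
    for e in acs:
        excl |= (hr.times >= e.onset_s) & (hr.times < e.end_s)

    quiet_dev = dev[~excl]
    if len(quiet_dev) >= 10:
        lo, hi = np.percentile(quiet_dev, [2.5, 97.5])
        bandwidth = float(max(abs(lo), abs(hi)))
    else:
        bandwidth = float(np.max(np.abs(dev)))

    # baseline drift per 3 min: largest baseline change over any 180 s span
    t = hr.times
    j = np.searchsorted(t, t + 180.0, side="left")
    ok = j < len(t)
    drift = float(np.max(np.abs(baseline[j[ok]] - baseline[ok]))) if ok.any() else 0.0

    # the tachycardia clock excludes accelerative excursions of any kind:
    # detected ACs plus sustained >10 bpm rises (AC tails)
    in_ac = np.zeros(len(hr), dtype=bool)
    for e in acs + [e for e in excl_events if e.kind == "AC"]:
        in_ac |= (t >= e.onset_s) & (t < e.end_s)
    tachy_s = float(np.sum(dt[(hr.values > TACHY_BPM) & ~in_ac]))
    base_med = float(np.median(baseline))

    hit_i = (
        drift < DRIFT_GATE_BPM_PER_3MIN
        and bandwidth < BANDWIDTH_GATE_BPM
        and n_ac <= 2
        and base_med <= TACHY_BPM
    )
    hit_iii = tachy_s > SUSTAINED_TACHY_S
    hit_ii = bandwidth > BANDWIDTH_GATE_BPM and n_ac >= 3 and not hit_iii

    if hit_i and not (hit_ii or hit_iii):
        label = "HRP_I"
    elif hit_iii and not hit_i:
        label = "HRP_III"
    elif hit_ii and not hit_i:
        label = "HRP_II"
    else:
        label = "unclassified"

    spec = window or SegmentSpec(float(t[0]), float(t[0]) + WINDOW_S, "unclassified")
    return HRPClassification(
        window=spec,
        label=label,
        evidence={
            "baseline_drift_bpm_per_3min": drift,
            "bandwidth_bpm": bandwidth,
            "n_ac": n_ac,
            "tachy_outside_ac_s": tachy_s,
            "exceeds160": tachy_s > 0,
            "baseline_median_bpm": base_med,
        },
    )


def classify_windows(
    series: BeatIntervalSeries,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> List[HRPClassification]:
    """Classify sliding 10-min windows (1-min step) over a recording."""
    hr = instantaneous_hr(series)
    base = floating_baseline(hr)
    t0 = series.beat_times[0]
    results = []
    start = t0
    while start + window_s <= series.end_times[-1] + 1e-6:
        m = (hr.times >= start) & (hr.times < start + window_s)
        if np.sum(m) >= 10:
            sub = InstantaneousHeartRate(values=hr.values[m], times=hr.times[m])
            try:
                c = classify_hrp(sub, base[m],
                                 window=SegmentSpec(start, start + window_s, "unclassified"))
                results.append(c)
            except FabasError:
                pass
        start += step_s
    return results


#: label mapping from HRP class to segment label
_SEG_LABEL = {"HRP_I": "quiet", "HRP_II": "active", "HRP_III": "awake"}


def select_segments(
    series: BeatIntervalSeries,
    classifications: Optional[List[HRPClassification]] = None,
) -> List[Tuple[SegmentSpec, str]]:
    """Pick at most one 10-min segment per state from the sliding windows:
    for quiet sleep the window with the smallest bandwidth, for active sleep
    the rule-satisfying window with the largest bandwidth. Ties go to the
    earliest window."""
    if classifications is None:
        classifications = classify_windows(series)
    selected: List[Tuple[SegmentSpec, str]] = []
    quiet = [c for c in classifications if c.label == "HRP_I"]
    if quiet:
        best = min(quiet, key=lambda c: (c.evidence["bandwidth_bpm"], c.window.start))
        selected.append(
            (SegmentSpec(best.window.start, best.window.end, "quiet"), "HRP_I")
        )
    active = [c for c in classifications if c.label == "HRP_II"]
    if active:
        best = max(active, key=lambda c: (c.evidence["bandwidth_bpm"], -c.window.start))
        selected.append(
            (SegmentSpec(best.window.start, best.window.end, "active"), "HRP_II")
        )
    selected.sort(key=lambda p: p[0].start)
    return selected


def load_annotations(path) -> List[Tuple[SegmentSpec, str]]:
    """Manual-override annotations: JSON list of {start_s, end_s, label}.

    When present these bypass the automatic classifier entirely.
    """
    import json

    with open(path) as fh:
        items = json.load(fh)
    out = []
    for it in items:
        label = it["label"]
        seg_label = _SEG_LABEL.get(label, label)
        out.append((SegmentSpec(float(it["start_s"]), float(it["end_s"]), seg_label), label))
    return out
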