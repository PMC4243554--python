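"""Pattern segmentation inside quiet-sleep segments.

Within a 10-min quiet-sleep segment, eight 3-min windows (1-min step) are
scanned. A window belongs to the *w/o DC* set if no heart rate sample drops
more than 10 bpm below the window's own baseline, and to the *basic* set
(basic rhythm) if additionally no sample rises more than 10 bpm above it.
Index variants are the mean of the per-window index over the qualifying
windows — they isolate the basic sympatho-vagal rhythm from the
acceleration/deceleration patterns superimposed on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .core import BeatIntervalSeries, FabasError, SegmentSpec, extract_segment, instantaneous_hr
from .indices import IndexVector, gmse3, pnn5, skewness, vlf_lf

SEGMENT_S = 600.0
WINDOW_S = 180.0
STEP_S = 60.0
GATE_BPM = 10.0
#: minimum interval count for the complexity index inside a 3-min window
#: (relaxed from the full-segment precondition)
GMSE_MIN_WINDOW = 120

VARIANT_INDICES = ("skewness", "pnn5_percent", "ln_vlf_lf", "gmse3")


@dataclass
class Window:
    start_s: float
    end_s: float
    has_ac: bool = False
    has_dc: bool = False


@dataclass
class WindowSet:
    windows: List[Window]
    segment: SegmentSpec

    def qualifying(self, mode: str) -> List[Window]:
        if mode == "woDC":
            return [w for w in self.windows if not w.has_dc]
        if mode == "basic":
            return [w for w in self.windows if not w.has_dc and not w.has_ac]
        raise FabasError(f"unknown mode {mode!r}")

    def to_dict(self) -> dict:
        return {
            "segment": {"start_s": self.segment.start, "end_s": self.segment.end},
            "windows": [
                {"start_s": w.start_s, "end_s": w.end_s, "has_ac": w.has_ac, "has_dc": w.has_dc}
                for w in self.windows
            ],
        }


def build_windows(segment: SegmentSpec, tol_s: float = 1.0) -> WindowSet:
    """Eight half-open 180 s windows stepping by 60 s over a 600 s segment."""
    if abs(segment.duration - SEGMENT_S) > tol_s:
        raise FabasError(f"pattern segmentation needs a 600 s segment, got {segment.duration} s")
    starts = segment.start + np.arange(0, SEGMENT_S - WINDOW_S + 1, STEP_S)
    return WindowSet(
        windows=[Window(float(s), float(s + WINDOW_S)) for s in starts],
        segment=segment,
    )


def flag_windows(
    ws: WindowSet,
    hr_values: np.ndarray,
    hr_times: np.ndarray,
    gate_bpm: float = GATE_BPM,
    min_excursion_s: float = 0.0,
) -> WindowSet:
    """Flag each window for accelerations/decelerations against its own
    baseline (median heart rate over that window).

    By definition a single sample beyond the 10 bpm gate flags the window;
    ``min_excursion_s`` optionally requires the excursion to persist, as a
    guard against lone artifact samples when validity flags are unreliable.
    """
    for w in ws.windows:
        m = (hr_times >= w.start_s) & (hr_times < w.end_s)
        if not np.any(m):
            w.has_ac = w.has_dc = False
            continue
        v = hr_values[m]
        base = float(np.median(v))
        dev = v - base
        dt = 60.0 / v  # seconds each beat occupies
        if min_excursion_s <= 0:
            w.has_ac = bool(np.any(dev > gate_bpm))
            w.has_dc = bool(np.any(dev < -gate_bpm))
        else:
            w.has_ac = _sustained(dev > gate_bpm, dt, min_excursion_s)
            w.has_dc = _sustained(dev < -gate_bpm, dt, min_excursion_s)
    return ws


def _sustained(mask: np.ndarray, dt: np.ndarray, min_s: float) -> bool:
    from .ctg import _runs

    return any(np.sum(dt[i:j]) >= min_s for i, j in _runs(mask))


def segmented_indices(
    segment_series: BeatIntervalSeries,
    ws: WindowSet,
    mode: str,
) -> Dict[str, Optional[float]]:
    """Mean per-window skewness, pNN5, lnVLF/LF and gMSE3 over qualifying
    windows (``woDC`` or ``basic``). AMP has no pattern-segmented variant.

    Returns the four variant values plus ``n_windows``; all four are None
    with a reason when no window qualifies.
    """
    qual = ws.qualifying(mode)
    out: Dict[str, Optional[float]] = {k: None for k in VARIANT_INDICES}
    out["n_windows"] = len(qual)
    if not qual:
        out["reason"] = "all windows contain DC/AC"
        return out
    per: Dict[str, list] = {k: [] for k in VARIANT_INDICES}
    for w in qual:
        sub = extract_segment(
            segment_series,
            SegmentSpec(w.start_s - ws.segment.start, w.end_s - ws.segment.start, "unclassified"),
        )
        sk = skewness(instantaneous_hr(sub))
        if sk is not None:
            per["skewness"].append(sk)
        p = pnn5(sub)
        if p is not None:
            per["pnn5_percent"].append(p)
        vl = vlf_lf(sub)
        if vl is not None:
            per["ln_vlf_lf"].append(vl)
        g = gmse3(sub, min_intervals=GMSE_MIN_WINDOW)
        if g is not None:
            per["gmse3"].append(g)
    for k, vals in per.items():
        out[k] = float(np.mean(vals)) if vals else None
    return out


def pattern_segmented_variants(
    segment_series: BeatIntervalSeries, segment: Optional[SegmentSpec] = None
) -> tuple:
    """Convenience: build + flag windows on a quiet segment and compute both
    variant sets. Returns (WindowSet, {"woDC": {...}, "basic": {...}})."""
    if segment is None:
        segment = SegmentSpec(0.0, SEGMENT_S, "quiet")
    ws = build_windows(segment)
    hr = instantaneous_hr(segment_series)
    times = hr.times + segment.start - segment_series.beat_times[0]
    flag_windows(ws, hr.values, times)
    variants = {mode: segmented_indices(segment_series, ws, mode) for mode in ("woDC", "basic")}
    return ws, variants
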