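"""Seeded synthetic fetal NN-interval recordings with ground truth.

The generator emulates the phenomenology a 30-min fetal heart rate recording
presents to the analysis pipeline: an age-dependent baseline rate (150 bpm
at 21 weeks falling linearly to 135 bpm at 40 weeks), alternating quiet and
active behavioral-state blocks, band-limited oscillations (0.05 and 0.15 Hz)
plus slow autoregressive drift on the rate, trapezoidal acceleration and
deceleration patterns, beat-level AR(1)-plus-white interval noise, and
flagged artifact spans.

Maturation enters through smooth monotone maps: beat-to-beat noise grows
with age (driving pNN5), modulation amplitude grows (driving AMP), the AR
coefficient grows (driving the gMSE3 complexity index), and acceleration
rate/amplitude grow (driving skewness). The process is a *test fixture*
exposing each index's sensitivity, not a physiological model.

Every sample path is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import BeatIntervalSeries, FabasError

GRID_HZ = 4.0
RAMP_S = 5.0
ARTIFACT_SPAN_S = 10.0

DEFAULT_SCHEDULE: Tuple[Tuple[str, float], ...] = (("quiet", 900.0), ("active", 900.0))


def baseline_hr_bpm(wga: float) -> float:
    """Mean heart rate map: 150 bpm at 21 weeks -> 135 bpm at 40 weeks."""
    a = (wga - 21.0) / 19.0
    return 150.0 - 15.0 * a


def state_params(state: str, wga: float, scale: float = 1.0) -> Dict[str, float]:
    """Per-state generating parameters at gestational age ``wga``.

    ``scale`` multiplies every variability amplitude (modulation, noise and
    event depths) without touching rates, durations or the AR coefficient.
    """
    a = (wga - 21.0) / 19.0
    if state == "quiet":
        return {
            "vlf_amp_bpm": 0.8 * scale,
            "lf_amp_bpm": 0.6 * scale,
            "slow_sd_bpm": 0.6 * scale,
            "white_ms": (1.2 + 1.2 * a) * scale,
            "ar_sd_ms": (2.0 + 3.0 * a) * scale,
            "ar_phi": 0.75 + 0.2 * a,
            "ac_rate_per_10min": 0.5,
            "ac_amp_bpm": (5.0 + 2.0 * a) * scale,
            "ac_dur_s": 15.0,
            "dc_rate_per_10min": 0.3,
            "dc_amp_bpm": 15.0 * scale,
            "dc_dur_s": 30.0,
        }
    if state == "active":
        return {
            "vlf_amp_bpm": (4.0 + 2.0 * a) * scale,
            "lf_amp_bpm": (1.5 + 1.0 * a) * scale,
            "slow_sd_bpm": 2.5 * scale,
            "white_ms": (1.8 + 2.7 * a) * scale,
            "ar_sd_ms": (4.0 + 3.0 * a) * scale,
            "ar_phi": 0.78 + 0.17 * a,
            "ac_rate_per_10min": 4.5 + 2.5 * a,
            "ac_amp_bpm": (25.0 + 3.0 * a) * scale,
            "ac_dur_s": 30.0,
            "dc_rate_per_10min": 0.0,
            "dc_amp_bpm": 15.0 * scale,
            "dc_dur_s": 30.0,
        }
    raise FabasError(f"unknown state {state!r}")


@dataclass
class GeneratorConfig:
    wga: float
    seed: int
    duration_s: float = 1800.0
    schedule: Tuple[Tuple[str, float], ...] = DEFAULT_SCHEDULE
    variability_scale: float = 1.0
    artifact_fraction: float = 0.02
    #: per-state parameter overrides, e.g. {"quiet": {"dc_rate_per_10min": 2.0}}
    overrides: Dict[str, Dict[str, float]] = field(default_factory=dict)
    recording_id: str = ""
    movement_count: Optional[int] = None

    def __post_init__(self) -> None:
        total = sum(d for _, d in self.schedule)
        if abs(total - self.duration_s) > 1e-6:
            raise FabasError(
                f"state schedule spans {total} s but duration is {self.duration_s} s"
            )
        if not (0.0 <= self.artifact_fraction < 0.5):
            raise FabasError("artifact_fraction must be in [0, 0.5)")

    def params_for(self, state: str) -> Dict[str, float]:
        p = state_params(state, self.wga, self.variability_scale)
        p.update(self.overrides.get(state, {}))
        return p


@dataclass
class GroundTruth:
    states: List[Tuple[float, float, str]]  # (start_s, end_s, state)
    events: List[dict]  # kind, state, onset_s, duration_s, amp_bpm
    artifact_spans: List[Tuple[float, float]]
    params: dict

    def events_in(self, start: float, end: float, kind: Optional[str] = None) -> List[dict]:
        return [
            e
            for e in self.events
            if e["onset_s"] < end and e["onset_s"] + e["duration_s"] > start
            and (kind is None or e["kind"] == kind)
        ]


def _trapezoid(t: np.ndarray, onset: float, dur: float, amp: float, ramp: float = RAMP_S) -> np.ndarray:
    """Trapezoidal bump: linear ramps of ``ramp`` s around a plateau."""
    x = t - onset
    up = np.clip(x / ramp, 0.0, 1.0)
    down = np.clip((dur - x) / ramp, 0.0, 1.0)
    return amp * np.clip(np.minimum(up, down), 0.0, 1.0) * ((x >= 0) & (x <= dur))


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    from scipy.signal import lfilter

    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - phi**2, 1e-12)), n)
    return lfilter([1.0], [1.0, -phi], innov)


def _place_events(
    rng: np.random.Generator, block_start: float, block_dur: float,
    rate_per_10min: float, ev_dur: float,
) -> List[float]:
    """Deterministic count (rate x block length), jittered onsets, one per
    equal slot so events never overlap and spacing is bounded below."""
    count = int(round(rate_per_10min * block_dur / 600.0))
    if count <= 0:
        return []
    slot = block_dur / count
    if slot <= ev_dur + 2.0:
        count = max(1, int(block_dur // (ev_dur + 10.0)))
        slot = block_dur / count
    onsets = []
    for k in range(count):
        # central portion of the slot only, so consecutive events keep a
        # guaranteed gap of ~0.3 slot lengths between them
        lo = block_start + k * slot + 0.15 * slot
        hi = block_start + k * slot + 0.85 * slot - ev_dur
        onsets.append(float(rng.uniform(lo, max(lo + 0.1, hi))))
    return onsets


def generate_recording(cfg: GeneratorConfig) -> Tuple[BeatIntervalSeries, GroundTruth]:
    """Generate one seeded recording and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / GRID_HZ
    n = int(round(cfg.duration_s * GRID_HZ))
    t = np.arange(n) * dt
    hr = np.full(n, baseline_hr_bpm(cfg.wga))

    states: List[Tuple[float, float, str]] = []
    events: List[dict] = []
    ev_bump = np.zeros(n)
    cursor = 0.0
    for state, dur in cfg.schedule:
        p = cfg.params_for(state)
        m = (t >= cursor) & (t < cursor + dur)
        tb = t[m]
        phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
        hr[m] += p["vlf_amp_bpm"] * np.sin(2 * np.pi * 0.05 * tb + phase1)
        hr[m] += p["lf_amp_bpm"] * np.sin(2 * np.pi * 0.15 * tb + phase2)
        slow = _ar1(rng, int(m.sum()), np.exp(-dt / 30.0), p["slow_sd_bpm"])
        hr[m] += slow - slow.mean()
        for kind, rate_key, amp_key, dur_key, sign in (
            ("AC", "ac_rate_per_10min", "ac_amp_bpm", "ac_dur_s", +1.0),
            ("DC", "dc_rate_per_10min", "dc_amp_bpm", "dc_dur_s", -1.0),
        ):
            for onset in _place_events(rng, cursor, dur, p[rate_key], p[dur_key]):
                ev_bump += sign * _trapezoid(t, onset, p[dur_key], p[amp_key])
                events.append(
                    {"kind": kind, "state": state, "onset_s": onset,
                     "duration_s": p[dur_key], "amp_bpm": p[amp_key]}
                )
        states.append((cursor, cursor + dur, state))
        cursor += dur
    # events are de-meaned globally (a constant offset) so the realized mean
    # rate stays on the baseline map without introducing steps between states
    hr += ev_bump - ev_bump.mean()
    events.sort(key=lambda e: e["onset_s"])

    # integrate rate -> beat times at integer beat counts
    beats = np.concatenate([[0.0], np.cumsum(hr / 60.0 * dt)])
    tgrid = np.concatenate([t, [cfg.duration_s]])
    n_beats = int(np.floor(beats[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), beats, tgrid)
    nn = np.diff(beat_times) * 1000.0
    onsets = beat_times[:-1]

    # beat-level interval noise: AR(1) + white, state-dependent amplitude,
    # de-meaned so the total duration is preserved
    state_of_beat = np.zeros(len(nn), dtype=int)
    for i, (s0, s1, _) in enumerate(states):
        state_of_beat[(onsets >= s0) & (onsets < s1)] = i
    phi = np.mean([cfg.params_for(s)["ar_phi"] for _, _, s in states])
    ar_unit = _ar1(rng, len(nn), float(phi), 1.0)
    white_unit = rng.normal(0.0, 1.0, len(nn))
    ar_sd = np.array([cfg.params_for(s)["ar_sd_ms"] for _, _, s in states])
    white_sd = np.array([cfg.params_for(s)["white_ms"] for _, _, s in states])
    noise = ar_unit * ar_sd[state_of_beat] + white_unit * white_sd[state_of_beat]
    noise -= noise.mean()
    nn = np.maximum(nn + noise, 150.0)
    beat_times = np.concatenate([[beat_times[0]], beat_times[0] + np.cumsum(nn) / 1000.0])
    onsets = beat_times[:-1]

    # artifact spans: intervals flagged invalid, values untouched
    valid = np.ones(len(nn), dtype=bool)
    spans: List[Tuple[float, float]] = []
    n_spans = int(round(cfg.artifact_fraction * cfg.duration_s / ARTIFACT_SPAN_S))
    tries = 0
    while len(spans) < n_spans and tries < 100 * max(1, n_spans):
        tries += 1
        s = float(rng.uniform(0.0, cfg.duration_s - ARTIFACT_SPAN_S))
        if all(s + ARTIFACT_SPAN_S < a or s > b for a, b in spans):
            spans.append((s, s + ARTIFACT_SPAN_S))
    spans.sort()
    for a, b in spans:
        valid &= ~((onsets >= a) & (onsets < b))

    series = BeatIntervalSeries(
        beat_times=onsets,
        nn_intervals=nn,
        valid=valid,
        recording_id=cfg.recording_id or f"sim-wga{cfg.wga:g}-seed{cfg.seed}",
        wga=cfg.wga,
        movement_count=cfg.movement_count,
    )
    truth = GroundTruth(
        states=states,
        events=events,
        artifact_spans=spans,
        params={
            "wga": cfg.wga,
            "seed": cfg.seed,
            "variability_scale": cfg.variability_scale,
            "artifact_fraction": cfg.artifact_fraction,
            "baseline_hr_bpm": baseline_hr_bpm(cfg.wga),
            "schedule": [list(x) for x in cfg.schedule],
        },
    )
    return series, truth


def generate_cohort(
    n: int,
    age_range: Tuple[int, int] = (21, 40),
    seed: int = 0,
    **config_kw,
) -> Tuple[List[Tuple[BeatIntervalSeries, GroundTruth]], pd.DataFrame]:
    """Generate ``n`` recordings with integer ages uniform over
    ``age_range`` (inclusive); per-recording seeds derive deterministically
    from the master seed."""
    if n < 1:
        raise FabasError("cohort size must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n + 1)[1:]]
    recordings = []
    rows = []
    for i, (wga, child) in enumerate(zip(ages, child_seeds)):
        # movement count rises mildly with age; only used by the normality
        # criteria, which need at least one movement in a healthy recording
        movements = int(10 + (wga - 21) // 2)
        cfg = GeneratorConfig(
            wga=float(wga), seed=child, recording_id=f"sim{i:04d}",
            movement_count=movements, **config_kw,
        )
        rec = generate_recording(cfg)
        recordings.append(rec)
        rows.append({"recording_id": cfg.recording_id, "wga": float(wga), "seed": child,
                     "movement_count": movements})
    return recordings, pd.DataFrame(rows)
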