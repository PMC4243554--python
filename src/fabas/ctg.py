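"""CTG-compatible analysis: epoching, STV/LTV, baseline, AC/DC events and
the Dawes–Redman normality criteria.

Beat intervals are integrated over 3.75 s epochs to emulate the temporal
resolution of clinical cardiotocography. Short term variability (STV) is the
mean absolute difference between consecutive epoch values inside analyzable
one-minute sections (16 epochs); long term variability (LTV) is the mean
per-minute fluctuation range about the baseline, computed on the interval
scale (ms). A one-minute section is analyzable if it overlaps no large
deceleration and is at most 50% artifact.

Accelerations (AC) and decelerations (DC) are excursions of the epoch heart
rate about a slowly varying baseline. Under the CTG rule set an AC is a rise
of >10 bpm sustained for >15 s; a DC is a drop of >20 bpm for >30 s or
>10 bpm for >60 s. The ``lost beats`` of a DC is the time integral of the
heart-rate deficit below baseline, in beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import BeatIntervalSeries, FabasError, logger

EPOCH_S = 3.75
EPOCHS_PER_MINUTE = 16  # 16 x 3.75 s = 60 s

RULE_SETS = ("ctg_dawes", "state_classification", "pattern_10bpm")

#: default minute-range threshold (ms) defining "high variation", and the
#: episode rule: a maximal run of >=6 consecutive minutes in which at least
#: 5 of any 6 exceed the threshold. Convention from the Dawes-Redman
#: literature; both configurable.
HIGH_VARIATION_THRESHOLD_MS = 32.0
EPISODE_MIN_MINUTES = 6

LARGE_DC_LOST_BEATS = 20.0


# ----------------------------------------------------------------------
# Epoching


@dataclass
class EpochSeries:
    """Mean NN interval per 3.75 s epoch with per-epoch artifact fraction."""

    values: np.ndarray  # ms; nan where no valid time in the epoch
    artifact_fraction: np.ndarray
    epoch_duration: float = EPOCH_S

    @property
    def n_epochs(self) -> int:
        return len(self.values)

    def hr_bpm(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 60000.0 / self.values

    def epoch_starts(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_duration


def epoch_series(series: BeatIntervalSeries, epoch_s: float = EPOCH_S) -> EpochSeries:
    """Integrate NN intervals over fixed epochs (time-weighted mean of valid
    intervals overlapping each epoch).

    ``artifact_fraction`` is the share of epoch time not covered by valid
    intervals (gaps and invalid beats both count as artifact).
    """
    t0 = series.beat_times[0]
    onsets = series.beat_times - t0
    ends = series.end_times - t0
    total = ends[-1]
    n_epochs = int(np.floor(total / epoch_s))
    if n_epochs < 1:
        raise FabasError(f"recording shorter than one epoch ({epoch_s} s)")

    v = series.valid
    # piecewise-linear cumulative integrals over time:
    #   I(t) = integral of nn(t') dt' over valid intervals, V(t) = valid time
    bp = np.empty(2 * int(v.sum()) + 1)
    Iv = np.empty_like(bp)
    Vv = np.empty_like(bp)
    bp[0], Iv[0], Vv[0] = 0.0, 0.0, 0.0
    von, vend, vnn = onsets[v], ends[v], series.nn_intervals[v]
    bp[1::2] = von
    bp[2::2] = vend
    seg_I = vnn * (vend - von)
    seg_V = vend - von
    Iv[1::2] = np.concatenate([[0.0], np.cumsum(seg_I)[:-1]])
    Iv[2::2] = np.cumsum(seg_I)
    Vv[1::2] = np.concatenate([[0.0], np.cumsum(seg_V)[:-1]])
    Vv[2::2] = np.cumsum(seg_V)
    # guard against a first valid interval starting exactly at 0
    order = np.argsort(bp, kind="stable")
    bp, Iv, Vv = bp[order], Iv[order], Vv[order]

    edges = np.arange(n_epochs + 1) * epoch_s
    I_at = np.interp(edges, bp, Iv)
    V_at = np.interp(edges, bp, Vv)
    valid_time = np.diff(V_at)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(valid_time > 1e-9, np.diff(I_at) / valid_time, np.nan)
    artifact = np.clip(1.0 - valid_time / epoch_s, 0.0, 1.0)
    return EpochSeries(values=values, artifact_fraction=artifact, epoch_duration=epoch_s)


# ----------------------------------------------------------------------
# Baseline


@dataclass
class BaselineSeries:
    """Slowly varying baseline heart rate (bpm), one value per epoch."""

    values: np.ndarray
    method: str = "iterated_trimmed_median"
    converged: bool = True

    def as_ms(self) -> np.ndarray:
        return 60000.0 / self.values


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    med = s.rolling(window, center=True, min_periods=1).median()
    med = med.interpolate(limit_direction="both")
    return med.to_numpy()


def estimate_baseline(
    epochs: EpochSeries,
    window_s: float = 180.0,
    trim_bpm: float = 10.0,
    max_iter: int = 5,
    tol_bpm: float = 0.1,
) -> BaselineSeries:
    """Iterated trimmed moving-median baseline.

    Convert epochs to bpm, take a 3-min centered moving median, exclude
    points deviating more than ``trim_bpm`` from the current baseline, refit,
    and repeat to convergence (or ``max_iter``). This makes the baseline
    insensitive to accelerations and decelerations. The method is a pluggable
    stand-in for the original (unpublished here) CTG baseline estimator and
    is tagged in the output.
    """
    if epochs.n_epochs * epochs.epoch_duration < window_s:
        raise FabasError("need at least one baseline window of epochs")
    window = max(3, int(round(window_s / epochs.epoch_duration)))
    hr = epochs.hr_bpm()
    # the first trim is against the global median: a local first pass can
    # converge into a deceleration when most of an edge window lies inside it
    base = np.full(epochs.n_epochs, np.nanmedian(hr))
    converged = False
    for _ in range(max_iter):
        trimmed = np.where(np.abs(hr - base) > trim_bpm, np.nan, hr)
        new = _rolling_median(trimmed, window)
        if np.nanmax(np.abs(new - base)) < tol_bpm:
            base = new
            converged = True
            break
        base = new
    if not converged:
        logger.warning("baseline estimation did not converge in %d iterations", max_iter)
    return BaselineSeries(values=base, converged=converged)


# ----------------------------------------------------------------------
# AC / DC events


@dataclass
class Event:
    kind: str  # "AC" or "DC"
    onset_s: float
    duration_s: float
    peak_deviation_bpm: float
    lost_beats: float = 0.0

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "onset_s": self.onset_s,
            "duration_s": self.duration_s,
            "peak_deviation_bpm": self.peak_deviation_bpm,
            "lost_beats": self.lost_beats,
        }


@dataclass
class EventList:
    events: List[Event]
    rule_set: str

    def of_kind(self, kind: str) -> List[Event]:
        return [e for e in self.events if e.kind == kind]

    def overlapping(self, start: float, end: float) -> List[Event]:
        return [e for e in self.events if e.onset_s < end and e.end_s > start]


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as half-open index ranges."""
    if not mask.any():
        return []
    m = np.asarray(mask, dtype=int)
    d = np.diff(np.concatenate([[0], m, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def detect_events_sampled(
    times: np.ndarray,
    dt: np.ndarray,
    deviation_bpm: np.ndarray,
    rule_set: str,
) -> EventList:
    """Run-based AC/DC detection on any sampled deviation series.

    ``deviation_bpm`` is heart rate minus baseline at sample times with
    per-sample durations ``dt`` (s). NaN samples break runs. Rule sets:

    - ``ctg_dawes``: AC >10 bpm for >15 s; DC >20 bpm below for >30 s or
      >10 bpm below for >60 s.
    - ``state_classification``: AC >15 bpm for >15 s; DC as ctg_dawes.
    - ``pattern_10bpm``: any excursion >10 bpm in either direction, no
      duration minimum.
    """
    if rule_set not in RULE_SETS:
        raise FabasError(f"unknown rule set {rule_set!r}")
    dev = np.where(np.isfinite(deviation_bpm), deviation_bpm, 0.0)
    events: List[Event] = []

    def run_duration(i, j):
        return float(np.sum(dt[i:j]))

    if rule_set == "ctg_dawes":
        ac_gate, ac_dur = 10.0, 15.0
    elif rule_set == "state_classification":
        ac_gate, ac_dur = 15.0, 15.0
    else:
        ac_gate, ac_dur = 10.0, 0.0
    for i, j in _runs(dev > ac_gate):
        dur = run_duration(i, j)
        if dur > ac_dur:
            events.append(
                Event("AC", float(times[i]), dur, float(np.max(dev[i:j])))
            )

    for i, j in _runs(dev < -10.0):
        dur = run_duration(i, j)
        deficit = -dev[i:j]
        is_dc = False
        if rule_set == "pattern_10bpm":
            is_dc = True
        else:
            if dur > 60.0:
                is_dc = True
            else:
                # deep sub-run: >20 bpm below for >30 s
                for a, b in _runs(deficit > 20.0):
                    if np.sum(dt[i + a : i + b]) > 30.0:
                        is_dc = True
                        break
        if is_dc:
            lost = float(np.sum(deficit * dt[i:j]) / 60.0)
            events.append(Event("DC", float(times[i]), dur, float(np.max(deficit)), lost))

    events.sort(key=lambda e: e.onset_s)
    return EventList(events=events, rule_set=rule_set)


def detect_events(
    epochs: EpochSeries, baseline: BaselineSeries, rule_set: str = "ctg_dawes"
) -> EventList:
    """AC/DC detection on the epoch grid against the estimated baseline."""
    dev = epochs.hr_bpm() - baseline.values
    dt = np.full(epochs.n_epochs, epochs.epoch_duration)
    return detect_events_sampled(epochs.epoch_starts(), dt, dev, rule_set)


# ----------------------------------------------------------------------
# Minute sections, STV, LTV


@dataclass
class MinuteSection:
    index: int
    epoch_start: int  # first epoch of the 16-epoch block
    analyzable: bool
    minute_range_ms: Optional[float] = None

    @property
    def start_s(self) -> float:
        return self.epoch_start * EPOCH_S


def mark_analyzable(
    epochs: EpochSeries,
    dc_events: EventList,
    max_artifact: float = 0.5,
    large_dc_lost_beats: float = LARGE_DC_LOST_BEATS,
) -> List[MinuteSection]:
    """A minute is analyzable iff it overlaps no large DC (lost beats above
    ``large_dc_lost_beats``) and its mean artifact fraction is <= 50%."""
    n_minutes = epochs.n_epochs // EPOCHS_PER_MINUTE
    large = [
        e for e in dc_events.of_kind("DC") if e.lost_beats > large_dc_lost_beats
    ]
    minutes = []
    for m in range(n_minutes):
        e0 = m * EPOCHS_PER_MINUTE
        art = float(np.mean(epochs.artifact_fraction[e0 : e0 + EPOCHS_PER_MINUTE]))
        t0, t1 = e0 * epochs.epoch_duration, (e0 + EPOCHS_PER_MINUTE) * epochs.epoch_duration
        hit = any(e.onset_s < t1 and e.end_s > t0 for e in large)
        minutes.append(MinuteSection(index=m, epoch_start=e0, analyzable=(art <= max_artifact and not hit)))
    return minutes


def stv(epochs: EpochSeries, minutes: Sequence[MinuteSection]) -> Optional[float]:
    """Short term variability: mean |consecutive epoch difference| inside each
    analyzable minute (15 pairs), averaged over analyzable minutes. ms."""
    per_minute = []
    for m in minutes:
        if not m.analyzable:
            continue
        block = epochs.values[m.epoch_start : m.epoch_start + EPOCHS_PER_MINUTE]
        diffs = np.abs(np.diff(block))
        if np.all(np.isnan(diffs)):
            continue
        per_minute.append(float(np.nanmean(diffs)))
    if not per_minute:
        logger.info("STV missing: no analyzable minutes")
        return None
    return float(np.mean(per_minute))


def ltv(
    epochs: EpochSeries,
    minutes: Sequence[MinuteSection],
    baseline: BaselineSeries,
) -> Optional[float]:
    """Long term variability: per analyzable minute, (max deviation above
    baseline)+ + (max deviation below baseline)+ on the interval scale (ms);
    averaged over analyzable minutes. Fills ``minute_range_ms``."""
    base_ms = baseline.as_ms()
    per_minute = []
    for m in minutes:
        if not m.analyzable:
            continue
        sl = slice(m.epoch_start, m.epoch_start + EPOCHS_PER_MINUTE)
        dev = epochs.values[sl] - base_ms[sl]
        if np.all(np.isnan(dev)):
            continue
        above = max(float(np.nanmax(dev)), 0.0)
        below = max(float(-np.nanmin(dev)), 0.0)
        m.minute_range_ms = above + below
        per_minute.append(m.minute_range_ms)
    if not per_minute:
        logger.info("LTV missing: no analyzable minutes")
        return None
    return float(np.mean(per_minute))


# ----------------------------------------------------------------------
# Episodes of high variation


def episodes_of_high_variation(
    minutes: Sequence[MinuteSection],
    threshold_ms: float = HIGH_VARIATION_THRESHOLD_MS,
    min_minutes: int = EPISODE_MIN_MINUTES,
) -> List[Tuple[int, int]]:
    """Maximal runs of >=``min_minutes`` consecutive minutes in which at
    least 5 of any 6 have a fluctuation range above the threshold.

    Returns half-open epoch index ranges. Implementation convention (the
    underlying clinical definition is not public); threshold configurable.
    """
    high = np.array(
        [bool(m.analyzable and m.minute_range_ms is not None and m.minute_range_ms > threshold_ms)
         for m in minutes]
    )
    n = len(high)
    if n == 0:
        return []
    member = np.zeros(n, dtype=bool)
    w = 6
    if n < w:
        if high.sum() >= max(5, n):  # degenerate short recording
            member[:] = high
    else:
        for s in range(n - w + 1):
            if high[s : s + w].sum() >= 5:
                member[s : s + w] = True
    episodes = []
    for i, j in _runs(member):
        if j - i >= min_minutes:
            episodes.append(
                (minutes[i].epoch_start, minutes[j - 1].epoch_start + EPOCHS_PER_MINUTE)
            )
    return episodes


def episode_ltv(
    minutes: Sequence[MinuteSection], episodes: Sequence[Tuple[int, int]]
) -> Optional[float]:
    """LTV averaged across minutes belonging to episodes of high variation."""
    vals = [
        m.minute_range_ms
        for m in minutes
        for (e0, e1) in episodes
        if e0 <= m.epoch_start < e1 and m.minute_range_ms is not None
    ]
    return float(np.mean(vals)) if vals else None


# ----------------------------------------------------------------------
# Reference percentiles


@dataclass
class ReferencePercentiles:
    """Per-WGA LTV reference values for Dawes-Redman criteria 2, 4 and 8.

    Columns: wga, ltv_p3_ms, ltv_p10_ms, ltv_expected_ms, ltv_sd_ms. The
    published reference table is proprietary; the package ships a synthetic
    default derived from its own generator, and :func:`derive_reference_percentiles`
    rebuilds one from any user cohort.
    """

    table: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        req = {"wga", "ltv_p3_ms", "ltv_p10_ms", "ltv_expected_ms", "ltv_sd_ms"}
        missing = req - set(self.table.columns)
        if missing:
            raise FabasError(f"reference table missing columns {sorted(missing)}")
        if (self.table["ltv_p3_ms"] > self.table["ltv_p10_ms"]).any():
            raise FabasError("reference table violates p3 <= p10")

    @classmethod
    def from_csv(cls, path) -> "ReferencePercentiles":
        return cls(table=pd.read_csv(path), source=str(path))

    @classmethod
    def default(cls) -> "ReferencePercentiles":
        from importlib.resources import files

        path = files("fabas").joinpath("data/ltv_reference_synthetic.csv")
        with path.open() as fh:
            return cls(table=pd.read_csv(fh), source="builtin-synthetic")

    def lookup(self, wga: float) -> Optional[pd.Series]:
        week = int(np.floor(wga))
        rows = self.table[self.table["wga"] == week]
        if rows.empty:
            return None
        return rows.iloc[0]


def derive_reference_percentiles(
    wgas: Sequence[float],
    episode_ltvs: Sequence[float],
    overall_ltvs: Optional[Sequence[float]] = None,
) -> ReferencePercentiles:
    """Build a reference table from a cohort.

    The 3rd/10th percentile columns come from episode-averaged LTV (used by
    criteria 2 and 4); the expected value and SD come from the overall LTV
    (used by criterion 8). Per completed week, pooled with +/-1 week
    neighbours to stabilise small bins.
    """
    if overall_ltvs is None:
        overall_ltvs = episode_ltvs
    df = pd.DataFrame(
        {"wga": np.floor(wgas).astype(int), "ep": episode_ltvs, "ov": overall_ltvs}
    ).dropna()
    if df.empty:
        raise FabasError("no cohort rows to derive percentiles from")
    rows = []
    for week in range(int(df["wga"].min()), int(df["wga"].max()) + 1):
        pool = df[(df["wga"] >= week - 1) & (df["wga"] <= week + 1)]
        if len(pool) < 3:
            continue
        rows.append(
            {
                "wga": week,
                "ltv_p3_ms": float(np.percentile(pool["ep"], 3)),
                "ltv_p10_ms": float(np.percentile(pool["ep"], 10)),
                "ltv_expected_ms": float(pool["ov"].mean()),
                "ltv_sd_ms": float(pool["ov"].std(ddof=1)),
            }
        )
    return ReferencePercentiles(table=pd.DataFrame(rows), source="derived")


# ----------------------------------------------------------------------
# Dawes-Redman criteria


@dataclass
class CriterionResult:
    passed: Optional[bool]  # None = indeterminate
    evidence: str


@dataclass
class DawesRedmanVerdict:
    criteria: dict  # id (1..9) -> CriterionResult
    overall: bool
    wga_used: float

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "wga": self.wga_used,
            "criteria": {
                str(k): {"passed": v.passed, "evidence": v.evidence}
                for k, v in self.criteria.items()
            },
        }


def sinusoidal_concentration(series: BeatIntervalSeries) -> float:
    """Share of 0.02-0.2 Hz tachogram power in the single strongest Welch bin.

    A genuinely sinusoidal heart rate rhythm concentrates nearly all band
    power in one frequency bin; broadband variability spreads it out.
    """
    from .indices import resample_tachogram
    from scipy.signal import welch

    t, x = resample_tachogram(series)
    x = x - np.mean(x)
    fs = 1.0 / (t[1] - t[0])
    nper = min(len(x), int(200 * fs))
    f, p = welch(x, fs=fs, nperseg=nper, noverlap=nper // 2)
    band = (f >= 0.02) & (f <= 0.2)
    pb = p[band]
    total = float(np.sum(pb))
    if total <= 0:
        return 0.0
    return float(np.max(pb) / total)


def evaluate_dawes_redman(
    series: BeatIntervalSeries,
    epochs: EpochSeries,
    baseline: BaselineSeries,
    events: EventList,
    episodes: Sequence[Tuple[int, int]],
    wga: float,
    movement_count: Optional[int],
    refs: Optional[ReferencePercentiles],
    minutes: Optional[Sequence[MinuteSection]] = None,
    sinusoidal_threshold: float = 0.6,
) -> DawesRedmanVerdict:
    """Evaluate the nine normality criteria on a recording of >=26 WGA.

    Criteria needing the (unpublished) LTV reference table are marked
    indeterminate when ``refs`` is None or lacks the week, and indeterminate
    criteria make the overall verdict False.
    """
    if wga < 26:
        raise FabasError("Dawes-Redman criteria defined from 26 WGA upwards")
    if minutes is None:
        minutes = mark_analyzable(epochs, events)
        ltv(epochs, minutes, baseline)
    stv_ms = stv(epochs, minutes)
    ltv_ms = ltv(epochs, minutes, baseline)
    ep_ltv = episode_ltv(minutes, episodes)
    acs = events.of_kind("AC")
    dcs = events.of_kind("DC")
    duration_min = series.duration / 60.0
    basal = float(np.nanmedian(baseline.values))
    loss = series.signal_loss_fraction()
    ref_row = refs.lookup(wga) if refs is not None else None
    mov = movement_count
    mov_per_hour = None if mov is None else mov / (duration_min / 60.0)
    mov_per_min = None if mov is None else mov / duration_min

    crit: dict = {}

    # 1 -- at least one episode of high variation
    crit[1] = CriterionResult(len(episodes) >= 1, f"{len(episodes)} episode(s) of high variation")

    # 2 -- STV > 3.0 ms; if < 4.5 ms, episode LTV must beat the 3rd percentile
    if stv_ms is None:
        crit[2] = CriterionResult(None, "STV not computable (no analyzable minutes)")
    elif stv_ms <= 3.0:
        crit[2] = CriterionResult(False, f"STV {stv_ms:.2f} ms <= 3.0 ms")
    elif stv_ms < 4.5:
        if ref_row is None:
            crit[2] = CriterionResult(None, f"STV {stv_ms:.2f} ms < 4.5 ms and no LTV reference")
        elif ep_ltv is None:
            crit[2] = CriterionResult(False, f"STV {stv_ms:.2f} ms < 4.5 ms and no episode LTV")
        else:
            ok = ep_ltv > ref_row["ltv_p3_ms"]
            crit[2] = CriterionResult(
                bool(ok),
                f"STV {stv_ms:.2f} ms; episode LTV {ep_ltv:.1f} ms vs p3 {ref_row['ltv_p3_ms']:.1f} ms",
            )
    else:
        crit[2] = CriterionResult(True, f"STV {stv_ms:.2f} ms > 4.5 ms")

    # 3 -- no high-frequency sinusoidal rhythm (spectral concentration test)
    conc = sinusoidal_concentration(series)
    crit[3] = CriterionResult(
        conc <= sinusoidal_threshold,
        f"max single-bin share of 0.02-0.2 Hz power = {conc:.2f} (gate {sinusoidal_threshold})",
    )

    # 4 -- >=1 AC, or movement rate >=20/h with episode LTV > 10th percentile
    if len(acs) >= 1:
        crit[4] = CriterionResult(True, f"{len(acs)} AC present")
    elif mov_per_hour is not None and mov_per_hour >= 20.0:
        if ref_row is None:
            crit[4] = CriterionResult(None, "no AC; movement rate ok but no LTV reference")
        elif ep_ltv is None:
            crit[4] = CriterionResult(False, "no AC; movement rate ok but no episode LTV")
        else:
            ok = ep_ltv > ref_row["ltv_p10_ms"]
            crit[4] = CriterionResult(
                bool(ok),
                f"no AC; movements {mov_per_hour:.0f}/h; episode LTV {ep_ltv:.1f} vs p10 "
                f"{ref_row['ltv_p10_ms']:.1f} ms",
            )
    else:
        crit[4] = CriterionResult(False, "no AC and movement rate < 20/h")

    # 5 -- at least one fetal movement or three AC
    ok5 = (mov is not None and mov >= 1) or len(acs) >= 3
    crit[5] = CriterionResult(ok5, f"movements={mov}, AC={len(acs)}")

    # 6 -- lost-beat limits on DC
    big = [d for d in dcs if d.lost_beats > 100.0]
    mid = [d for d in dcs if 20.0 < d.lost_beats <= 100.0]
    if duration_min <= 30.0:
        ok6 = not mid and not big
        crit[6] = CriterionResult(ok6, f"{len(mid) + len(big)} DC >20 lost beats (<=30 min rule)")
    else:
        ok6 = len(mid) <= 1 and not big
        crit[6] = CriterionResult(ok6, f"{len(mid)} DC 21-100 lost beats, {len(big)} DC >100")

    # 7 -- basal heart rate 116-160 bpm
    crit[7] = CriterionResult(116.0 <= basal <= 160.0, f"basal fHR {basal:.1f} bpm")

    # 8 -- overall LTV within 3 SD of its expected value, or the (a)-(d) fallback
    fallback = (
        stv_ms is not None
        and stv_ms > 5.0
        and len(episodes) >= 1
        and mov_per_min is not None
        and mov_per_min >= 0.5
        and basal >= 120.0
        and loss < 0.30
    )
    if ref_row is not None and ltv_ms is not None and ref_row["ltv_sd_ms"] > 0:
        dev_sd = abs(ltv_ms - ref_row["ltv_expected_ms"]) / ref_row["ltv_sd_ms"]
        ok8 = dev_sd <= 3.0 or fallback
        crit[8] = CriterionResult(bool(ok8), f"LTV {dev_sd:.1f} SD from expected; fallback={fallback}")
    elif fallback:
        crit[8] = CriterionResult(True, "no LTV reference; fallback (a)-(d) satisfied")
    else:
        crit[8] = CriterionResult(None, "no LTV reference and fallback not satisfied")

    # 9 -- clean ending: final epoch outside any DC, final minute not artifact-ridden
    t_last0 = (epochs.n_epochs - 1) * epochs.epoch_duration
    t_last1 = epochs.n_epochs * epochs.epoch_duration
    in_dc = any(d.onset_s < t_last1 and d.end_s > t_last0 for d in dcs)
    tail = epochs.artifact_fraction[-EPOCHS_PER_MINUTE:]
    tail_art = float(np.mean(tail))
    ok9 = (not in_dc) and tail_art <= 0.5
    crit[9] = CriterionResult(ok9, f"final epoch in DC={in_dc}; final-minute artifact {tail_art:.0%}")

    overall = all(c.passed is True for c in crit.values())
    return DawesRedmanVerdict(criteria=crit, overall=overall, wga_used=wga)
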