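"""Hand-designed beat-interval traces for exercising the normality criteria.

Each trace is a slow triangular interval modulation (symmetric per 2-minute
pair, so the heart rate oscillates about a stable baseline) plus optional
per-pair beat noise, a sinusoidal component, and trapezoidal heart-rate
bumps (accelerations/decelerations). The defaults satisfy all nine
criteria; each entry in :data:`SINGLE_VIOLATION_CASES` perturbs exactly one
property so that exactly one criterion fails.
"""

import numpy as np
import pandas as pd

from fabas import ctg
from fabas.core import BeatIntervalSeries

#: reference percentiles used with these traces (LTV in ms; wga 26-40)
TEST_REFS = ctg.ReferencePercentiles(
    table=pd.DataFrame(
        [{"wga": w, "ltv_p3_ms": 30.0, "ltv_p10_ms": 35.0,
          "ltv_expected_ms": 80.0, "ltv_sd_ms": 20.0} for w in range(26, 41)]
    ),
    source="test-fixture",
)


def make_trace(
    slope_pattern=(1.4,),
    noise_pattern=(4.0,),
    base_nn=430.0,
    sine=None,
    bumps=(),
    jitter=(0.9, 1.1),
    end_pair_slope=None,
    seed=0,
    duration=1800.0,
) -> BeatIntervalSeries:
    """Construct a deterministic 30-min trace.

    slope_pattern: ms/s interval ramp magnitude per 2-min pair (cycled);
    a pair ramps the interval from -30*s to +30*s and back, giving a
    per-minute fluctuation range of 60*s ms and epoch-to-epoch steps of
    3.75*s ms. noise_pattern: white beat noise (ms) per pair. bumps:
    (onset_s, duration_s, amp_bpm) trapezoids with 5 s ramps; a bump
    reaching the end of the recording holds its plateau (no recovery).
    """
    rng = np.random.default_rng(seed)
    dt = 0.25
    t = np.arange(0.0, duration, dt)
    n_min = int(duration // 60)
    n_pairs = n_min // 2
    pat = list(slope_pattern)
    pair_slope = np.array(
        [pat[p % len(pat)] * rng.uniform(*jitter) for p in range(n_pairs)]
    )
    if end_pair_slope is not None:
        pair_slope[-1] = end_pair_slope
    pair = np.clip((t // 120).astype(int), 0, n_pairs - 1)
    u = t - 120.0 * pair
    s = pair_slope[pair]
    x = np.where(u < 60.0, s * (u - 30.0), s * (90.0 - u))
    nn_target = base_nn + x
    if sine is not None:
        f, a = sine
        nn_target = nn_target + a * np.sin(2 * np.pi * f * t)
    hr = 60000.0 / nn_target
    for onset, dur, amp in bumps:
        z = t - onset
        up = np.clip(z / 5.0, 0, 1)
        if onset + dur >= duration - 1.0:
            down = 1.0  # hold to the end of the recording
        else:
            down = np.clip((dur - z) / 5.0, 0, 1)
        hr = hr + amp * np.clip(np.minimum(up, down), 0, 1) * ((z >= 0) & (z <= dur))
    beats = np.concatenate([[0.0], np.cumsum(hr / 60.0 * dt)])
    tg = np.concatenate([t, [duration]])
    n_beats = int(np.floor(beats[-1]))
    bt = np.interp(np.arange(1, n_beats + 1), beats, tg)
    nn = np.diff(bt) * 1000.0
    onsets0 = bt[:-1]
    minute_of_beat = np.clip((onsets0 // 60).astype(int), 0, n_min - 1)
    pairs_of_beat = minute_of_beat // 2
    noise_sd = np.array(
        [list(noise_pattern)[p % len(noise_pattern)] for p in range(n_pairs + 1)]
    )
    noise = rng.normal(0, 1, len(nn)) * noise_sd[pairs_of_beat]
    noise -= noise.mean()
    nn = nn + noise
    onsets = np.concatenate([[bt[0]], bt[0] + np.cumsum(nn[:-1]) / 1000.0])
    return BeatIntervalSeries(
        beat_times=onsets, nn_intervals=nn, valid=np.ones(len(nn), bool), wga=30.0
    )


def evaluate_trace(series: BeatIntervalSeries, movement_count=30) -> ctg.DawesRedmanVerdict:
    """Full criteria pipeline with the fixture reference table."""
    epochs = ctg.epoch_series(series)
    base = ctg.estimate_baseline(epochs)
    events = ctg.detect_events(epochs, base, "ctg_dawes")
    minutes = ctg.mark_analyzable(epochs, events)
    ctg.ltv(epochs, minutes, base)
    episodes = ctg.episodes_of_high_variation(minutes)
    return ctg.evaluate_dawes_redman(
        series, epochs, base, events, episodes,
        wga=30.0, movement_count=movement_count, refs=TEST_REFS, minutes=minutes,
    )


#: criterion id -> (trace kwargs, movement count). Each violates exactly
#: that criterion:
#: 1 isolated bursts of high variation never 5-of-6 minutes -> no episode;
#: 2 shallow ramps: STV below 3.0 ms while ranges stay above 32 ms;
#: 3 a large 0.05 Hz sinusoidal component dominating the band;
#: 4 no accelerations and movement rate below 20/h;
#: 5 no movements and only two (planted) accelerations;
#: 6 one deep 90 s deceleration losing ~40 beats;
#: 7 basal rate 170 bpm;
#: 8 huge fluctuation range (LTV far beyond 3 SD), fallback blocked by a
#:   movement rate under 0.5/min;
#: 9 a shallow 70 s deceleration running into the final epoch.
SINGLE_VIOLATION_CASES = {
    1: dict(kw=dict(slope_pattern=(1.9, 0.2, 0.2), noise_pattern=(4.0, 9.0, 9.0),
                    bumps=((155.0, 50.0, 20.0),)), mov=30),
    2: dict(kw=dict(slope_pattern=(0.65,)), mov=30),
    3: dict(kw=dict(sine=(0.05, 15.0)), mov=30),
    4: dict(kw=dict(slope_pattern=(0.85,)), mov=5),
    5: dict(kw=dict(slope_pattern=(0.85,),
                    bumps=((815.0, 50.0, 20.0), (1055.0, 50.0, 20.0))), mov=0),
    6: dict(kw=dict(bumps=((855.0, 90.0, -25.0),)), mov=30),
    7: dict(kw=dict(base_nn=60000.0 / 170.0, slope_pattern=(1.0,)), mov=30),
    8: dict(kw=dict(slope_pattern=(3.0,)), mov=5),
    9: dict(kw=dict(end_pair_slope=0.05, bumps=((1730.0, 70.0, -13.0),)), mov=30),
}
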