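"""The five heart rate variability indices behind the autonomic brain age
score, computed on one segment's NN-interval series.

=============  =====================================================
AMP            20-95 inter-quantile distance of the detrended NN
               series (ms) -- overall fluctuation amplitude.
skewness       sample skewness g1 of the instantaneous heart rate
               series -- asymmetry from acceleration/deceleration
               patterns.
pNN5           percentage of adjacent NN differences strictly
               greater than 5 ms -- fast, vagally mediated rhythms.
lnVLF/LF       log ratio of very-low (0.02-0.08 Hz) to low
               (0.08-0.2 Hz) frequency band power of the tachogram.
gMSE3          auto mutual information (lag 1, nats) of the NN
               series coarse-grained at scale 3 -- complexity of
               sympatho-vagal rhythms.
=============  =====================================================

Every index is missing-capable: when its precondition fails the value is
None and a reason code is recorded. Estimator settings (binning rule,
spectral taper, quantile convention, ...) are fixed defaults, configurable,
and fingerprinted into the output for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import interpolate, signal, stats

from .core import BeatIntervalSeries, FabasError, InstantaneousHeartRate, config_fingerprint, instantaneous_hr

DETREND_WINDOW_S = 60.0
RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 150.0
VLF_BAND = (0.02, 0.08)
LF_BAND = (0.08, 0.2)
GMSE_SCALE = 3
GMSE_LAG = 1
GMSE_MIN_INTERVALS = 300

_SETTINGS = {
    "detrend_window_s": DETREND_WINDOW_S,
    "resample_hz": RESAMPLE_HZ,
    "welch_segment_s": WELCH_SEGMENT_S,
    "taper": "hann",
    "quantiles": "linear",
    "skewness": "g1_biased",
    "gmse_scale": GMSE_SCALE,
    "gmse_lag": GMSE_LAG,
    "gmse_binning": "equiprobable",
    "gmse_bins_rule": "floor(sqrt(M/5))",
    "gmse_units": "nats",
}

SETTINGS_FINGERPRINT = config_fingerprint(_SETTINGS)


@dataclass
class IndexVector:
    """The five indices for one segment, plus optional pattern-segmented
    variants (``woDC``: windows without decelerations; ``basic``: windows
    with neither accelerations nor decelerations)."""

    amp_ms: Optional[float] = None
    skewness: Optional[float] = None
    pnn5_percent: Optional[float] = None
    ln_vlf_lf: Optional[float] = None
    gmse3: Optional[float] = None
    variants: Dict[str, Dict[str, Optional[float]]] = field(default_factory=dict)
    segment_label: str = ""
    n_beats: int = 0
    missing_reasons: Dict[str, str] = field(default_factory=dict)
    settings_fingerprint: str = SETTINGS_FINGERPRINT

    _PLAIN = ("amp_ms", "skewness", "pnn5_percent", "ln_vlf_lf", "gmse3")

    def to_dict(self) -> dict:
        return {
            "segment_label": self.segment_label,
            "n_beats": self.n_beats,
            "amp_ms": self.amp_ms,
            "skewness": self.skewness,
            "pnn5_percent": self.pnn5_percent,
            "ln_vlf_lf": self.ln_vlf_lf,
            "gmse3": self.gmse3,
            "variants": self.variants,
            "missing_reasons": self.missing_reasons,
            "settings_fingerprint": self.settings_fingerprint,
        }


# ----------------------------------------------------------------------


def detrend(series: BeatIntervalSeries, window_s: float = DETREND_WINDOW_S) -> np.ndarray:
    """NN values minus a centered moving average over ``window_s`` seconds of
    the valid beats; windows shrink at the edges. Returns locally zero-mean
    values (ms), one per valid interval."""
    if series.duration < window_s:
        raise FabasError(f"segment shorter than detrend window {window_s} s")
    t = series.valid_times()
    x = series.valid_nn()
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    means = (csum[hi] - csum[lo]) / (hi - lo)
    return x - means


def amp(detrended: np.ndarray) -> Optional[float]:
    """20-95 inter-quantile distance (ms) of the detrended NN series."""
    if len(detrended) < 20:
        return None
    q20, q95 = np.percentile(detrended, [20, 95])
    return float(q95 - q20)


def skewness(hr: InstantaneousHeartRate) -> Optional[float]:
    """Sample skewness g1 = m3 / m2^(3/2) of the instantaneous heart rate."""
    if len(hr) < 3:
        return None
    v = hr.values
    if np.ptp(v) == 0:
        return None
    g1 = float(stats.skew(v, bias=True))
    return g1 if np.isfinite(g1) else None


def pnn5(series: BeatIntervalSeries, threshold_ms: float = 5.0) -> Optional[float]:
    """Percentage of adjacent NN differences with |dNN| strictly > 5 ms.

    Only differences between two consecutive *valid* intervals count; pairs
    spanning an invalid beat are excluded.
    """
    nn = series.nn_intervals
    v = series.valid
    pair_ok = v[:-1] & v[1:]
    n_pairs = int(np.sum(pair_ok))
    if n_pairs == 0:
        return None
    d = np.abs(np.diff(nn))[pair_ok]
    return float(100.0 * np.sum(d > threshold_ms) / n_pairs)


def resample_tachogram(
    series: BeatIntervalSeries, fs: float = RESAMPLE_HZ
) -> Tuple[np.ndarray, np.ndarray]:
    """Evenly resample the valid NN series (ms) at ``fs`` Hz by cubic
    interpolation over beat onset times."""
    t = series.valid_times()
    x = series.valid_nn()
    if len(t) < 4:
        raise FabasError("too few valid beats to resample")
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    f = interpolate.interp1d(t, x, kind="cubic", assume_sorted=True)
    return grid, f(grid)


def vlf_lf(series: BeatIntervalSeries) -> Optional[float]:
    """ln of very-low-frequency to low-frequency band power ratio.

    The valid NN series is resampled at 4 Hz (cubic), mean-removed, and
    band powers are integrated from a Welch periodogram (150 s Hann
    segments, 50% overlap).
    """
    if series.duration < 150.0:
        return None
    grid, x = resample_tachogram(series)
    x = x - np.mean(x)
    fs = RESAMPLE_HZ
    nper = min(len(x), int(WELCH_SEGMENT_S * fs))
    f, p = signal.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2, window="hann")
    df = f[1] - f[0]
    p_vlf = float(np.sum(p[(f >= VLF_BAND[0]) & (f < VLF_BAND[1])]) * df)
    p_lf = float(np.sum(p[(f >= LF_BAND[0]) & (f < LF_BAND[1])]) * df)
    if p_lf <= 0 or p_vlf <= 0:
        return None
    return float(np.log(p_vlf / p_lf))


# ----------------------------------------------------------------------
# Generalized mutual information at coarse-graining level 3


def coarse_grain(x: np.ndarray, scale: int = GMSE_SCALE) -> np.ndarray:
    """Non-overlapping means of ``scale`` consecutive values (multiscale
    entropy convention); yields floor(N/scale) values."""
    n = len(x) // scale
    if n == 0:
        return np.empty(0)
    return np.asarray(x[: n * scale], dtype=float).reshape(n, scale).mean(axis=1)


def _equiprobable_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value a bin index 0..n_bins-1 with (near) equal counts,
    by rank. Ties broken by position (stable sort)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=int)
    ranks[order] = np.arange(len(x))
    return (ranks * n_bins) // len(x)


def mutual_information_binned(
    x: np.ndarray, y: np.ndarray, n_bins: int
) -> float:
    """Plug-in mutual information (nats) between two series using marginal
    equiprobable binning."""
    bx = _equiprobable_bins(x, n_bins)
    by = _equiprobable_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def gmse3(
    series_or_values,
    scale: int = GMSE_SCALE,
    lag: int = GMSE_LAG,
    min_intervals: int = GMSE_MIN_INTERVALS,
) -> Optional[float]:
    """Auto mutual information (lag ``lag``, nats) of the NN series after
    coarse-graining at ``scale``: the complexity index of the score.

    Bin count B = floor(sqrt(M/5)) where M is the number of lagged pairs;
    rank-based equiprobable binning makes the estimate invariant under
    strictly monotone transformations of the intervals.
    """
    if isinstance(series_or_values, BeatIntervalSeries):
        x = series_or_values.valid_nn()
    else:
        x = np.asarray(series_or_values, dtype=float)
    if len(x) < min_intervals:
        return None
    cg = coarse_grain(x, scale)
    m = len(cg) - lag
    n_bins = int(np.floor(np.sqrt(m / 5.0)))
    if n_bins < 2:
        return None
    return mutual_information_binned(cg[:-lag], cg[lag:], n_bins)


# ----------------------------------------------------------------------


def compute_indices(
    series: BeatIntervalSeries,
    label: str = "",
    gmse_min_intervals: int = GMSE_MIN_INTERVALS,
) -> IndexVector:
    """All five indices for one segment; missing indices carry reason codes."""
    iv = IndexVector(segment_label=label, n_beats=series.n_valid)

    try:
        iv.amp_ms = amp(detrend(series))
        if iv.amp_ms is None:
            iv.missing_reasons["amp_ms"] = "fewer than 20 valid intervals"
    except FabasError as e:
        iv.missing_reasons["amp_ms"] = str(e)

    try:
        hr = instantaneous_hr(series)
        iv.skewness = skewness(hr)
        if iv.skewness is None:
            iv.missing_reasons["skewness"] = "zero variance or <3 beats"
    except FabasError as e:
        iv.missing_reasons["skewness"] = str(e)

    iv.pnn5_percent = pnn5(series)
    if iv.pnn5_percent is None:
        iv.missing_reasons["pnn5_percent"] = "no valid adjacent pairs"

    try:
        iv.ln_vlf_lf = vlf_lf(series)
        if iv.ln_vlf_lf is None:
            iv.missing_reasons["ln_vlf_lf"] = "segment <150 s or zero band power"
    except FabasError as e:
        iv.missing_reasons["ln_vlf_lf"] = str(e)

    iv.gmse3 = gmse3(series, min_intervals=gmse_min_intervals)
    if iv.gmse3 is None:
        iv.missing_reasons["gmse3"] = f"fewer than {gmse_min_intervals} valid intervals"

    return iv
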