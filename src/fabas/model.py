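"""Age-prediction models: stepwise weighted regression of gestational age on
heart rate variability indices, and the resulting normograms.

The score is the fitted value of a weighted least-squares regression of
gestational age (weeks) on a selected subset of HRV indices. Selection is
classical bidirectional stepwise on the partial F test: forward inclusion
while P(F) < 0.05, backward exclusion while P(F) > 0.10. Cases are weighted
so the effective age distribution is approximately uniform (weight
proportional to the inverse count of the case's completed-week bin,
normalized to mean one). Quadratic models add centered squared terms of the
same indices to the candidate pool.

Model families mirror the analysis designs they serve:

- ``full30``: indices of the entire 30-min recording;
- ``active10`` / ``quiet10``: indices of the selected 10-min state segment;
- ``quiet10_patternseg``: quiet-segment indices plus their w/o-DC and basic
  pattern-segmented variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import FabasError, config_fingerprint, logger

P_ENTER = 0.05
P_REMOVE = 0.10

FAMILY_CANDIDATES = {
    "full30": ["amp_ms", "skewness", "pnn5_percent", "ln_vlf_lf", "gmse3"],
    "active10": ["amp_ms", "skewness", "pnn5_percent", "ln_vlf_lf", "gmse3"],
    "quiet10": ["amp_ms", "skewness", "pnn5_percent", "ln_vlf_lf", "gmse3"],
    "quiet10_patternseg": [
        "amp_ms", "skewness", "pnn5_percent", "ln_vlf_lf", "gmse3",
        "skewness_woDC", "pnn5_percent_woDC", "ln_vlf_lf_woDC", "gmse3_woDC",
        "skewness_basic", "pnn5_percent_basic", "ln_vlf_lf_basic", "gmse3_basic",
    ],
}

#: normogram bins: 21-24 and 37-40 completed weeks merged, weekly otherwise
NORMOGRAM_BINS: List[Tuple[int, int]] = (
    [(21, 24)] + [(w, w) for w in range(25, 37)] + [(37, 40)]
)


@dataclass
class StepwiseConfig:
    p_enter: float = P_ENTER
    p_remove: float = P_REMOVE
    quadratic: bool = False
    candidates: Sequence[str] = ()

    def __post_init__(self) -> None:
        if not self.p_enter < self.p_remove:
            raise FabasError("p_enter must be < p_remove")


def case_weights(ages: Sequence[float]) -> np.ndarray:
    """Inverse completed-week-bin-count weights, normalized to mean 1, so
    the weighted cohort is approximately uniform over gestational age."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise FabasError("no ages")
    weeks = np.floor(ages).astype(int)
    _, inverse, counts = np.unique(weeks, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inverse]
    return w / w.mean()


@dataclass
class AgeModel:
    family: str
    predictors: List[str]
    coefficients: Dict[str, float]  # includes "intercept"
    adjusted_r2: float
    centers: Dict[str, float] = field(default_factory=dict)  # for squared terms
    quadratic: bool = False
    n_rows: int = 0
    fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "predictors": self.predictors,
            "coefficients": self.coefficients,
            "adjusted_r2": self.adjusted_r2,
            "centers": self.centers,
            "quadratic": self.quadratic,
            "n_rows": self.n_rows,
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeModel":
        return cls(
            family=d["family"],
            predictors=list(d["predictors"]),
            coefficients=dict(d["coefficients"]),
            adjusted_r2=float(d["adjusted_r2"]),
            centers=dict(d.get("centers", {})),
            quadratic=bool(d.get("quadratic", False)),
            n_rows=int(d.get("n_rows", 0)),
            fingerprint=d.get("fingerprint", ""),
        )


def _design(ft: pd.DataFrame, candidates: Sequence[str], quadratic: bool):
    """Candidate design columns; squared terms are centered before squaring."""
    cols = {}
    centers = {}
    for c in candidates:
        cols[c] = ft[c].to_numpy(dtype=float)
    if quadratic:
        for c in list(candidates):
            mu = float(np.mean(cols[c]))
            centers[c + "^2"] = mu
            cols[c + "^2"] = (cols[c] - mu) ** 2
    return pd.DataFrame(cols, index=ft.index), centers


def _wls_pvalues(y, X, w):
    model = sm.WLS(y, sm.add_constant(X, has_constant="add"), weights=w).fit()
    return model


def stepwise_fit(
    feature_table: pd.DataFrame,
    cfg: StepwiseConfig,
    target: str = "wga",
    weights: Optional[np.ndarray] = None,
    family: str = "custom",
) -> AgeModel:
    """Bidirectional stepwise weighted least squares.

    Forward: add the candidate with the smallest partial-F p-value if it is
    below ``p_enter``. Backward: drop any included predictor whose p-value
    exceeds ``p_remove``. Iterate to a fixed point. Rows with a missing
    candidate or target are dropped (count logged); constant candidates are
    excluded with a warning.
    """
    candidates = list(cfg.candidates)
    cols = candidates + [target]
    ft = feature_table[cols].apply(pd.to_numeric, errors="coerce")
    n0 = len(ft)
    keep = ft.notna().all(axis=1)
    ft = ft[keep]
    if len(ft) < n0:
        logger.info("stepwise: dropped %d of %d rows with missing values", n0 - len(ft), n0)
    if weights is None:
        w = case_weights(ft[target].to_numpy())
    else:
        w = np.asarray(weights, dtype=float)[keep.to_numpy()]
        w = w / w.mean()
    if np.any(w <= 0):
        raise FabasError("case weights must be positive")

    X_all, centers = _design(ft, candidates, cfg.quadratic)
    pool = []
    for c in X_all.columns:
        if np.std(X_all[c].to_numpy()) == 0:
            logger.warning("stepwise: dropping constant candidate %r", c)
        else:
            pool.append(c)
    if ft.shape[0] < 10 * max(1, len(candidates)):
        logger.warning(
            "stepwise: only %d rows for %d candidates", ft.shape[0], len(candidates)
        )
    y = ft[target].to_numpy(dtype=float)

    included: List[str] = []
    changed = True
    while changed:
        changed = False
        # forward
        best_p, best_c = None, None
        for c in pool:
            if c in included:
                continue
            res = _wls_pvalues(y, X_all[included + [c]], w)
            p = float(res.pvalues.iloc[-1])
            if np.isnan(p):
                continue
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < cfg.p_enter:
            included.append(best_c)
            changed = True
        # backward
        while included:
            res = _wls_pvalues(y, X_all[included], w)
            pv = res.pvalues.iloc[1:]  # skip intercept
            worst = pv.idxmax()
            if float(pv.max()) > cfg.p_remove:
                included.remove(worst)
                changed = True
            else:
                break

    res = _wls_pvalues(y, X_all[included] if included else pd.DataFrame(index=ft.index), w)
    coefs = {"intercept": float(res.params.iloc[0])}
    for i, c in enumerate(included):
        coefs[c] = float(res.params.iloc[i + 1])
    adj = float(res.rsquared_adj) if included else 0.0
    model = AgeModel(
        family=family,
        predictors=included,
        coefficients=coefs,
        adjusted_r2=adj,
        centers={k: v for k, v in centers.items() if k in included},
        quadratic=cfg.quadratic,
        n_rows=len(ft),
        fingerprint=config_fingerprint(
            {"p_enter": cfg.p_enter, "p_remove": cfg.p_remove,
             "quadratic": cfg.quadratic, "candidates": candidates}
        ),
    )
    if not included:
        logger.warning("stepwise: no predictor entered; intercept-only model")
    return model


def fit_family(
    feature_table: pd.DataFrame,
    family: str,
    quadratic: bool = False,
    target: str = "wga",
) -> AgeModel:
    """Fit one named model family with its standard candidate set."""
    if family not in FAMILY_CANDIDATES:
        raise FabasError(f"unknown model family {family!r}")
    cand = [c for c in FAMILY_CANDIDATES[family] if c in feature_table.columns]
    cfg = StepwiseConfig(quadratic=quadratic, candidates=cand)
    return stepwise_fit(feature_table, cfg, target=target, family=family)


def predict_age(model: AgeModel, indices: Dict[str, Optional[float]]) -> Optional[float]:
    """Apply a fitted model to one index vector; the result is the autonomic
    brain age score in weeks. Returns None when a predictor is missing."""
    score = model.coefficients["intercept"]
    for p in model.predictors:
        base = p[:-2] if p.endswith("^2") else p
        x = indices.get(base)
        if x is None or (isinstance(x, float) and np.isnan(x)):
            logger.info("predict_age: missing predictor %r", base)
            return None
        if p.endswith("^2"):
            x = (x - model.centers.get(p, 0.0)) ** 2
        score += model.coefficients[p] * x
    return float(score)


def predict_table(model: AgeModel, feature_table: pd.DataFrame) -> np.ndarray:
    """Vectorized predict_age over the rows of a feature table (NaN where a
    predictor is missing)."""
    out = np.full(len(feature_table), np.nan)
    for i, (_, row) in enumerate(feature_table.iterrows()):
        s = predict_age(model, row.to_dict())
        out[i] = np.nan if s is None else s
    return out


# ----------------------------------------------------------------------
# Normograms


@dataclass
class Normogram:
    """Per-age-bin mean +/- SD of the score; the reference against which an
    individual fetus's deviation from normal maturation is expressed."""

    bins: List[Tuple[int, int]]
    means: List[float]
    sds: List[float]
    ns: List[int]

    def to_dict(self) -> dict:
        return {
            "bins": [list(b) for b in self.bins],
            "means": self.means,
            "sds": self.sds,
            "ns": self.ns,
        }

    def bin_for(self, wga: float) -> Optional[int]:
        week = int(np.floor(wga))
        for i, (lo, hi) in enumerate(self.bins):
            if lo <= week <= hi:
                return i
        return None


def build_normogram(
    scores: Sequence[float],
    ages: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    bins: Sequence[Tuple[int, int]] = tuple(NORMOGRAM_BINS),
) -> Normogram:
    """Weighted per-bin mean and SD of scores; the 21-24 and 37-40 week edge
    bins are merged (small samples at the extremes). Empty bins are omitted
    with a warning."""
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    w = np.ones_like(scores) if weights is None else np.asarray(weights, dtype=float)
    ok = np.isfinite(scores) & np.isfinite(ages)
    scores, ages, w = scores[ok], ages[ok], w[ok]
    out_bins, means, sds, ns = [], [], [], []
    for lo, hi in bins:
        m = (ages >= lo) & (ages < hi + 1)
        n = int(np.sum(m))
        if n == 0:
            logger.warning("normogram: empty bin %d-%d omitted", lo, hi)
            continue
        ww = w[m] / np.sum(w[m])
        mu = float(np.sum(ww * scores[m]))
        if n > 1:
            var = float(np.sum(ww * (scores[m] - mu) ** 2) * n / (n - 1))
            sd = float(np.sqrt(var))
        else:
            sd = 0.0
        out_bins.append((lo, hi))
        means.append(mu)
        sds.append(sd)
        ns.append(n)
    if not out_bins:
        raise FabasError("no scores fall in any normogram bin")
    return Normogram(bins=out_bins, means=means, sds=sds, ns=ns)


def score_deviation(score: float, wga: float, nm: Normogram) -> Optional[float]:
    """z-score of an individual score against its age bin's reference."""
    i = nm.bin_for(wga)
    if i is None:
        raise FabasError(f"no normogram bin covers {wga} weeks")
    if nm.sds[i] == 0:
        return None
    return float((score - nm.means[i]) / nm.sds[i])
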