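"""End-to-end orchestration: recording -> epochs -> events -> STV/LTV ->
normality criteria -> state segments -> index vectors -> optional score.

These functions are the library behind the command line interface; each
returns plain dicts/DataFrames ready for JSON/CSV serialization.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import ctg, indices, model as model_mod, patterns, states
from .core import BeatIntervalSeries, FabasError, SegmentSpec, extract_segment, logger
from .simulate import GroundTruth


def analyze_recording(
    series: BeatIntervalSeries,
    refs: Optional[ctg.ReferencePercentiles] = None,
    age_model: Optional[model_mod.AgeModel] = None,
    normogram: Optional[model_mod.Normogram] = None,
    annotations: Optional[List[Tuple[SegmentSpec, str]]] = None,
) -> dict:
    """Full analysis bundle for one recording."""
    epochs = ctg.epoch_series(series)
    baseline = ctg.estimate_baseline(epochs)
    events = ctg.detect_events(epochs, baseline, "ctg_dawes")
    minutes = ctg.mark_analyzable(epochs, events)
    stv_ms = ctg.stv(epochs, minutes)
    ltv_ms = ctg.ltv(epochs, minutes, baseline)
    episodes = ctg.episodes_of_high_variation(minutes)

    bundle: dict = {
        "recording_id": series.recording_id,
        "wga": series.wga,
        "n_epochs": epochs.n_epochs,
        "stv_ms": stv_ms,
        "ltv_ms": ltv_ms,
        "signal_loss": series.signal_loss_fraction(),
        "episodes_high_variation": [[int(a), int(b)] for a, b in episodes],
        "events": [e.to_dict() for e in events.events],
    }

    if series.wga is not None and series.wga >= 26:
        verdict = ctg.evaluate_dawes_redman(
            series, epochs, baseline, events, episodes,
            wga=series.wga, movement_count=series.movement_count,
            refs=refs, minutes=minutes,
        )
        bundle["dawes_redman"] = verdict.to_dict()
    else:
        bundle["dawes_redman"] = {"applicable": False,
                                  "reason": "criteria defined from 26 WGA upwards"}

    # whole-recording indices
    iv_full = indices.compute_indices(series, "full30")
    bundle["indices"] = {"full30": iv_full.to_dict()}

    # behavioral-state segments
    segs = annotations if annotations is not None else states.select_segments(series)
    bundle["segments"] = []
    for spec, label in segs:
        seg_series = extract_segment(series, spec)
        iv = indices.compute_indices(seg_series, spec.label)
        entry = {
            "start_s": spec.start, "end_s": spec.end, "label": label,
            "indices": iv.to_dict(),
        }
        if spec.label == "quiet":
            ws, variants = patterns.pattern_segmented_variants(
                seg_series, SegmentSpec(0.0, spec.duration, "quiet")
            )
            entry["windows"] = ws.to_dict()
            entry["indices"]["variants"] = variants
        bundle["segments"].append(entry)

    if age_model is not None:
        feats = _bundle_features(bundle, age_model.family)
        score = model_mod.predict_age(age_model, feats) if feats else None
        bundle["score_weeks"] = score
        if score is not None and normogram is not None and series.wga is not None:
            bundle["score_z"] = model_mod.score_deviation(score, series.wga, normogram)
    return bundle


def _bundle_features(bundle: dict, family: str) -> Optional[dict]:
    """Flatten the index vectors of a bundle into the feature dict a model
    family expects, or None when the needed segment is absent."""
    if family == "full30":
        return dict(bundle["indices"]["full30"])
    want = "quiet" if family.startswith("quiet") else "active"
    for seg in bundle.get("segments", []):
        iv = seg["indices"]
        if seg.get("label") in ("HRP_I",) and want == "quiet" or \
           seg.get("label") in ("HRP_II",) and want == "active":
            feats = dict(iv)
            for mode, suffix in (("woDC", "_woDC"), ("basic", "_basic")):
                for k, v in (iv.get("variants", {}).get(mode, {}) or {}).items():
                    if k in patterns.VARIANT_INDICES:
                        feats[k + suffix] = v
            return feats
    return None


def recording_features(
    series: BeatIntervalSeries,
    segment: str = "full30",
) -> Optional[dict]:
    """Feature dict for one recording and one model family's segment type.

    ``segment``: full30, quiet10, active10 or quiet10_patternseg.
    """
    if segment == "full30":
        iv = indices.compute_indices(series, "full30")
        return iv.to_dict()
    want = "quiet" if segment.startswith("quiet") else "active"
    segs = states.select_segments(series)
    for spec, _label in segs:
        if spec.label != want:
            continue
        seg_series = extract_segment(series, spec)
        iv = indices.compute_indices(seg_series, spec.label)
        feats = iv.to_dict()
        if segment == "quiet10_patternseg":
            _ws, variants = patterns.pattern_segmented_variants(
                seg_series, SegmentSpec(0.0, spec.duration, "quiet")
            )
            for mode, suffix in (("woDC", "_woDC"), ("basic", "_basic")):
                for k in patterns.VARIANT_INDICES:
                    feats[k + suffix] = variants[mode][k]
        return feats
    return None


def cohort_feature_table(
    recordings,
    segment: str = "full30",
) -> pd.DataFrame:
    """Feature table (one row per recording) for model fitting.

    ``recordings`` is an iterable of BeatIntervalSeries or
    (series, ground_truth) pairs; rows whose segment is absent are skipped
    with a log message.
    """
    rows = []
    for item in recordings:
        series = item[0] if isinstance(item, tuple) else item
        feats = recording_features(series, segment)
        if feats is None:
            logger.info("no %s segment for %s; row skipped", segment, series.recording_id)
            continue
        row = {"recording_id": series.recording_id, "wga": series.wga}
        for k, v in feats.items():
            if k in ("variants", "missing_reasons", "settings_fingerprint",
                     "segment_label", "n_beats"):
                continue
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)
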