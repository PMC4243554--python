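# fabas

Fetal autonomic brain age scoring from beat-to-beat heart rate variability.

The autonomic nervous system matures measurably over gestation: fetal heart
rate patterns gain fluctuation amplitude, complexity, and structured
acceleration/deceleration patterning between 21 and 40 weeks. `fabas` turns a
beat-to-beat NN-interval recording (as produced by fetal magnetocardiography
at ~1 ms resolution) into

- the CTG-compatible **short/long term variability** (STV/LTV over 3.75 s
  epochs) and a **Dawes–Redman normality verdict** (nine criteria, applicable
  from 26 weeks of gestation),
- five maturation-sensitive **HRV indices** — AMP (20–95 inter-quantile
  distance of the detrended NN series), skewness of the instantaneous heart
  rate, pNN5, ln VLF/LF (0.02–0.08 Hz vs 0.08–0.2 Hz band power), and gMSE3
  (lag-1 auto mutual information of the NN series coarse-grained at scale 3),
- **behavioral-state segmentation** into quiet sleep (HRP I), active sleep
  (HRP II) and active awakeness (HRP III) from written heart-rate-pattern
  rules, with pattern-segmented index variants (windows *without
  decelerations* and *basic rhythm* windows with neither accelerations nor
  decelerations), and
- a fitted **autonomic brain age score**: a stepwise weighted regression of
  gestational age on the indices,

  score = β₀ + Σᵢ βᵢ·HRVᵢ,   selection by partial F test
  (enter while P(F) < 0.05, remove while P(F) > 0.10),
  cases weighted to an approximately uniform age distribution,

  with per-age-bin mean ± SD **normograms** and z-scores for flagging
  deviations from normal maturation.

It is written for researchers working with fetal MCG/ECG beat time series
who want a transparent, scriptable reference implementation of this scoring
pipeline. No clinical claims are made; the Dawes–Redman module is a
CTG-compatible re-implementation for research, not the commercial Oxford
system.

Because no public fetal cohort accompanies the methodology, the package
includes a first-class synthetic-data generator (`fabas.simulate`) producing
seeded 30-min recordings with ground-truth state schedules, event lists and
age-dependent index structure, so the whole pipeline is testable end to end.

## Worked example

Simulate a 32-week recording, write it as CSV, and analyze it:

```python
from fabas.core import write_interval_series
from fabas.simulate import GeneratorConfig, generate_recording

series, truth = generate_recording(GeneratorConfig(wga=32.0, seed=4, movement_count=12))
write_interval_series(series, "rec.csv")
```

```sh
fabas analyze rec.csv --wga 32 --movements 12 --out bundle.json
```

The bundle for this seed contains:

```
stv_ms: 9.03  ltv_ms: 51.55
dawes_redman overall: True
full30 indices: amp_ms 43.061, skewness 1.834, pnn5_percent 28.696,
                ln_vlf_lf 2.262, gmse3 0.913
segments: HRP_I [0, 600) s, HRP_II [960, 1560) s
```

Reading this: the epoch-based short term variability is 9.0 ms and all nine
normality criteria pass; the classifier found a quiet-sleep segment in the
first ten minutes and an active-sleep segment in the second half (the
generator planted quiet over [0, 900) s and active over [900, 1800) s); the
five whole-recording indices are the inputs an age model consumes.

Fitting a model and scoring against it:

```sh
fabas simulate-cohort -n 60 --seed 3 --out cohort/
fabas fit --cohort cohort/ --family full30 --out model.json
fabas normogram --cohort cohort/ --model model.json --out normogram.json
fabas score rec.csv --wga 32 --model model.json --normogram normogram.json
```

`fit` prints the selected predictors and the corrected (adjusted) R² of the
weighted fit; `score` prints the predicted autonomic age in weeks and its
deviation from the age bin's reference in SD units.

Model families: `full30` (whole 30-min recording), `active10` / `quiet10`
(selected 10-min state segments), `quiet10_patternseg` (quiet-segment
indices plus their w/o-DC and basic variants). Models ship unfitted — the
underlying study's cohort is not public — and are fitted on your cohort or
on synthetic ones.

## Layout

| module | contents |
|---|---|
| `fabas.core` | `BeatIntervalSeries` and friends, CSV/JSON I/O, validation |
| `fabas.ctg` | epoching, STV/LTV, baseline, AC/DC detection, Dawes–Redman criteria |
| `fabas.indices` | the five HRV indices |
| `fabas.states` | HRP I/II/III window classification and segment selection |
| `fabas.patterns` | 3-min moving-window pattern segmentation (w/o DC, basic) |
| `fabas.model` | case weights, stepwise WLS, prediction, normograms |
| `fabas.simulate` | seeded synthetic recordings and cohorts with ground truth |
| `fabas.pipeline`, `fabas.cli` | orchestration and the `fabas` command |

See `docs/methods.md` for the model assumptions, estimator conventions and
known limitations.
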