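# Methods

This note records what each stage of the pipeline computes, the conventions
and defaults it uses, and where a published rule was under-specified and a
design choice had to be made. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Input model

The universal input is a sequence of NN intervals (ms) with per-interval
onset times (s) and validity flags. Artifacts are *flagged, never deleted*:
the CTG-compatible rules need the artifact fraction (a one-minute section is
discarded above 50% artifact, and one normality criterion gates on total
signal loss below 30%, which we count as a time fraction). Intervals that
violate positivity, or whose onset times disagree with the interval values
by more than 1 ms inside a valid run, are demoted to invalid with a warning.
All windows are half-open `[start, end)`; an interval belongs to a window
iff its onset does. Invalid beats are omitted from index computation (no
interpolation); a linear-join policy was considered and rejected as a
default because it manufactures spurious short-range correlation for the
complexity index.

## CTG-compatible analysis

Intervals are integrated over fixed 3.75 s epochs (time-weighted mean of
valid intervals overlapping the epoch; 480 epochs per full 30 min). Sixteen
epochs form a minute section; a minute is analyzable iff it overlaps no
large deceleration (lost beats > 20, reusing the smallest bound in the
lost-beat criterion) and is at most 50% artifact.

- **STV** = mean |consecutive epoch difference| over the 15 pairs inside
  each analyzable minute, averaged over analyzable minutes (ms).
- **LTV** = per-minute fluctuation range about the baseline — positive part
  of the maximal deviation above plus positive part below — averaged over
  analyzable minutes. Deviations are computed on the interval scale (ms),
  converting the baseline from bpm at each epoch.

**Baseline.** The original CTG baseline algorithm is not published in a
reproducible form; we use an iterated trimmed moving median: convert epochs
to bpm, trim points further than 10 bpm from the current baseline, take a
3-min centered moving median of the rest, and iterate to convergence (max 5
iterations; non-convergence returns the last iterate with a warning flag).
The *first* trim is against the global median: a purely local first pass can
converge into a deceleration when most of an edge window lies inside one.
The method is pluggable and tagged in the output.

**AC/DC detection** operates on maximal runs of the deviation (epoch heart
rate minus baseline) under three rule sets: `ctg_dawes` (AC: >10 bpm
sustained >15 s; DC: >20 bpm below for >30 s or >10 bpm for >60 s),
`state_classification` (AC: >15 bpm, >15 s), and `pattern_10bpm` (any
>10 bpm excursion, no duration minimum). Duration gates are strict
inequalities on the run length in seconds. `lost beats` is the Riemann sum
of the heart-rate deficit below baseline over the event, divided by 60.

**Episodes of high variation** are not publicly defined; our convention: a
maximal run of ≥6 consecutive minutes in which at least 5 of any 6 have a
fluctuation range above 32 ms. Threshold and run length are configurable;
32 ms is the value conventionally associated with high-variation episodes
in the CTG literature.

**The nine normality criteria** (applicable from 26 completed weeks) are
evaluated independently with evidence strings. Points where the written
rules needed operationalization:

- *Sinusoidal rhythm* (criterion 3): flagged when more than 60% of the
  0.02–0.2 Hz tachogram power falls in a single Welch bin. This runs on the
  4 Hz resampled beat series, not on the 3.75 s epochs, whose 0.27 Hz
  sampling cannot resolve the band.
- *Reference percentiles* (criteria 2, 4, 8): the per-week 3rd/10th LTV
  percentiles and expected LTV ± SD are not published; the package ships an
  editable CSV derived from its own generator (clearly labelled synthetic)
  and a tool to derive a table from any user cohort. A criterion needing a
  missing reference row returns *indeterminate*, which makes the overall
  verdict negative.
- *"LTV within 3 SD of its estimated value"* (criterion 8) uses the overall
  LTV (mean over analyzable minutes); episode-averaged LTV is named only by
  criteria 2 and 4, and tying criterion 8 to episodes would make it fail
  automatically whenever criterion 1 does.
- Movement rates use the recording-level movement count divided by duration;
  per-minute movement times are not part of the input contract.
- Criterion 9 combines the two ending conditions (final epoch not inside a
  deceleration; final minute not artifact-ridden) into one clean-ending
  check.
- Basal heart rate (criterion 7) is the median of the baseline series.

## HRV indices

All estimator settings are fixed defaults, configurable, and hashed into a
fingerprint carried by every output.

| index | convention |
|---|---|
| AMP | 95th − 20th percentile (linear interpolation) of the NN series after subtracting a 60 s centered moving average (edges shrink). The 60 s window removes baseline drift and state transitions without flattening the modulation the index should see. |
| skewness | biased sample skewness g1 = m₃/m₂^{3/2} of the instantaneous heart rate (60000/NN, valid beats only). |
| pNN5 | percentage of adjacent-NN differences strictly greater than 5 ms; pairs spanning an invalid beat are excluded. |
| ln VLF/LF | valid NN series resampled at 4 Hz (cubic), mean-removed (not detrended), Welch periodogram with 150 s Hann segments at 50% overlap; band powers integrated over 0.02–0.08 and 0.08–0.2 Hz. |
| gMSE3 | coarse-grain by non-overlapping means of 3 (multiscale convention), then plug-in auto mutual information at lag 1 with marginal equiprobable (rank) binning, B = ⌊√(M/5)⌋ bins for M lagged pairs. Units: nats. Precondition: ≥300 valid intervals (relaxed to 120 inside 3-min pattern windows, recorded in output). |

The rank-binned MI estimator is exactly invariant under strictly monotone
transformations of its inputs; note that coarse-graining does not commute
with nonlinear maps, so the whole gMSE3 pipeline is only approximately so.
The plug-in estimator has a positive bias of order (B−1)²/2M; calibration is
therefore asserted against a permutation null computed with the same
estimator, not against zero.

## Behavioral-state classification

The published classification is a three-expert consensus; this module is a
transparent rule engine over the written criteria, and every evidence number
is exported so a human can overrule it via an annotation file.

The floating baseline is a 3-min centered moving median of the beat-by-beat
rate. For event detection at beat resolution the deviation series is first
smoothed with an 11 s centered moving average — without it, beat-to-beat
noise splits one excursion into sub-threshold run fragments. Conventions:

- **Bandwidth** = larger of |2.5th| and |97.5th| percentile of the deviation
  outside excluded samples, compared against the ±5 bpm gate. Excluded are
  samples inside sustained >10 bpm excursions (either sign, >15 s): the
  written rules exclude "AC/DC" from the oscillation bandwidth, and
  sub-threshold excursions would otherwise leak into the percentiles.
- **Drift** = largest floating-baseline change over any 180 s span,
  compared against 10 bpm per 3 min.
- **HRP III** "sustained tachycardia" = more than 60 s above 160 bpm outside
  accelerative excursions (configurable).
- Rules are exclusive hits with precedence I, III, II; conflicts yield
  `unclassified`.

Segment selection scans sliding 10-min windows at 1-min steps; per state at
most one segment is kept — the smallest-bandwidth window for quiet sleep,
the largest-bandwidth rule-satisfying window for active sleep (ties to the
earliest). The margin-maximizing choice is our convention; the source
methodology does not say how a segment was chosen when a state lasted
longer than 10 min.

## Pattern segmentation

Within a 600 s quiet segment: eight 180 s windows stepping by 60 s. Each
window gets its own baseline (median heart rate over the window); a single
beat sample more than 10 bpm below it flags `has_dc`, above it `has_ac` (an
optional minimum-excursion duration, default 0 s, guards against lone
artifact samples). Variants are the mean of the per-window index over
qualifying windows — *w/o DC* (no `has_dc`) and *basic* (neither flag) —
for skewness, pNN5, ln VLF/LF and gMSE3; AMP has no pattern-segmented
variant. Per-window computation then averaging (rather than concatenating
windows) keeps windows exchangeable and avoids splicing artifacts at window
joins.

## Age models and normograms

Case weights are inversely proportional to the count in the case's
completed-week bin, normalized to mean one, approximating a uniform age
distribution. Selection is bidirectional stepwise on weighted least squares:
forward-add the candidate with the smallest partial-F p-value while it is
below 0.05, backward-drop any included predictor above 0.10, iterate to a
fixed point. Weights are treated as analytic (variance) weights. Quadratic
models add centered squared terms of each candidate; centering is stored in
the model and applied at prediction. Adjusted ("corrected") R² is reported
from the weighted fit. Rows with any missing candidate are dropped with a
logged count; constant candidates are excluded.

Normogram bins are weekly with 21–24 and 37–40 merged (sparse edges);
per-bin weighted mean and SD of the score, and z = (score − bin mean)/bin SD
for an individual deviation. Empty bins are omitted with a warning.

## Synthetic data

The generator is a test fixture exposing each index's sensitivity, not a
physiological model. A 4 Hz heart-rate process — age-linear baseline
(150 bpm at 21 weeks to 135 at 40), per-state sinusoids at 0.05 and 0.15 Hz,
slow AR drift, and trapezoidal AC/DC bumps — is integrated to beat times;
beat-level AR(1)-plus-white interval noise is added (de-meaned, so duration
is exactly preserved), and artifact spans are flagged. Maturation enters
through smooth monotone maps: white-noise amplitude (pNN5), modulation and
AR amplitude (AMP), AR coefficient 0.75→0.95 in quiet sleep (gMSE3), and
acceleration rate/amplitude (skewness). Event counts per state block are
deterministic (`round(rate × minutes/10)`) with jittered, non-clustering
placement: the active-sleep rule requires at least three accelerations in
*every* 10-min window, which a Poisson count would violate in a third of
blocks — the planted-state recovery tests presuppose margins comfortably
inside the rules.

What the generator does **not** emulate: circadian/maternal influences,
state-transition dynamics (states switch instantaneously on a fixed
schedule), breathing-frequency modulation above 0.2 Hz, realistic artifact
physics (artifacts only flag validity; values stay consistent), or any
validated physiology. Passing tests therefore demonstrate the *pipeline's*
correctness and sensitivity directions, not clinical performance on real
fetuses; the adjusted R² values on synthetic cohorts are far higher than
any real cohort would give, because the generator's maturation maps are
noiseless by construction.

## Problem sizes and numerics

The test suite runs cohorts of 100 recordings across 20 master seeds for
the end-to-end maturation property, 200 recordings for state-label
recovery, 500 replicates for stepwise type-I calibration and 500 series for
the complexity-estimator null — sizes chosen to make the binomial error of
each asserted rate small relative to its margin. The acceptance script uses
an 80-recording cohort. Monotonicity of predicted-age bin means is checked
on predictions pooled across master seeds, since a single cohort's weekly
bin can contain one recording. Degenerate inputs return `None` with a
reason code rather than raising (zero-variance skewness, too-short
segments, zero band power, all-window exclusion); hard errors are reserved
for contract violations (non-monotone times, out-of-range segments,
criteria below 26 weeks).

## Known limitations

- The Dawes–Redman module approximates the published criteria list; the
  commercial system's internal tables and baseline algorithm are not
  public, so agreement with it on real traces is not claimed.
- The HRP classifier reproduces written rules, not expert consensus;
  borderline windows (bandwidth near ±5 bpm) are sensitive to the
  percentile convention.
- gMSE3 estimator details (binning, lag, bin-count rule, units) follow
  common auto-MI practice and are recorded in output metadata; other
  estimator choices shift the absolute values while preserving ordering.
- Whether VLF/LF should be computed on the raw or detrended tachogram is
  unspecified in the source methodology; we use the mean-removed,
  un-detrended series.
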