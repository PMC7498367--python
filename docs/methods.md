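# Methods

This note documents the models, numerical choices and limitations behind
the package, in the order the pipeline runs.

## Trace model and peak quantification

A trace is 96 non-negative fluorescence values (RFU), one per
molecular-weight strip.  The strip → kDa map is log-linear through ladder
anchors (`calibrate_mw`): log10(MW) is piecewise linear in strip index and
extrapolated at the ends; by convention the axis decreases with strip
index (high molecular weight at the gel top), though any strictly
monotone axis is accepted.

Peak detection (`detect_peaks`) scans for strict local maxima, discards
candidates below a prominence threshold (scipy's topographic prominence),
merges maxima closer than `min_separation` strips into the higher one,
and extends each apex to the nearest flanking minima.  The trace noise
level is estimated as the median absolute deviation of the
first-differenced trace divided by √2 (the differencing removes the
smooth band shape; √2 undoes the variance doubling); the SNR of a peak is
its apex height above the local background over this noise.  Defaults:
`min_snr = 3`, `min_prominence = 5` RFU, `min_separation = 3` strips —
the readout platform specifies none of these, so they are exposed in the
configuration.

Quantification (`quantify_peak`) integrates the band above a *local
background* defined as the straight line between the intensities at the
two peak bounds, clipping negative residuals at zero.  This makes the
area exactly invariant to adding a constant to the trace and exactly
proportional to scaling it — both property-tested.  A band counts as
detected when its background-subtracted area exceeds `detection_floor`
(default 50 RFU·strips).

A band is *shifted* when its apex deviates from the antibody's expected
molecular weight by more than 20 % (relative); the tolerance is inclusive
— exactly 20 % passes.  Bands of one antibody are aligned across samples
into signal rows by apex strip (gap > 5 strips starts a new signal);
rows are ranked by median relative shift, so `AB0042#1` is the signal
closest to the expected weight.

## Synthetic cohorts

The generator emulates the paired study design: 25 paired FF/FFPE primary
tumors, five per type (HNSC, LUSC, LUAD, COAD, PAAD), plus an independent
25-sample FFPE validation cohort with the same class structure and fresh
noise.  Latent log2 abundance for sample *s*, antibody *a*:

    log2 A(s, a) = base_a + g(s) · effect_a[type(s)] + u_s + ε(s, a)

with `base_a ~ N(5.85, 0.7²)` (log2 units of peak height),
a per-sample loading effect `u_s ~ N(0, 0.5²)`, per-cell noise
`ε ~ N(0, 0.9²)`, and a grade factor *g* that damps class effects in less
differentiated tumors (G1/G2: 1.0, G2–3: 0.8, G3: 0.6) — which is what
makes correct-class probabilities lower for poorly differentiated cases
downstream.  70 % of concordant antibodies are markers for one random
tumor type with an effect of 1–2.5 log2 units.

Concordant antibodies carry the same latent abundance into FFPE plus a
small extra noise term (sd 0.25 log2); their FFPE amplitude is then
multiplied by a per-antibody attenuation factor `2^−U(0.3, 1.7)`
(≈ 0.31–0.81).  Non-concordant antibodies redraw the FFPE abundance from
an independent stream (own loading effect, own noise), planting a
correlation of ≈ 0.  Traces are baseline (20 RFU) + Gaussian bands in
strip index (sd 1.5 strips) + i.i.d. N(0, 4²) noise, clipped at zero.
A configurable artifact adds a band at a uniform location in 47–53 kDa to
HNSC samples only (150 RFU in FF, 60 in FFPE), mimicking a secondary-
antibody cross-reaction; the three affected antibodies are the natural
input for the manual-exclusion list.

The defaults were chosen once so that the generator realizes the regimes
the downstream stages are designed around: mean detected samples per
antibody ≈ 23 of 25 in FF vs ≈ 18.6 in FFPE, FF log2 intensities higher
than FFPE, and a planted concordant set that the selection screen
recovers with sensitivity ≥ 0.9 at a false-discovery proportion ≤ 0.15
over 25 pairs.  All randomness derives from one seed via SHA-256-hashed
per-(purpose, sample, antibody) substreams, so outputs are byte-identical
regardless of generation order.

What the generator does *not* model: electrophoresis physics, blotting or
bead chemistry, antibody cross-reactivity beyond the single artifact,
correlated antibody panels (each antibody's noise is independent), batch
effects, or heavy-tailed intensity distributions.  Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under the planted model, not performance on real lysates.

## Antibody selection

The screen runs in the order: (1) detection filter on the FFPE matrix —
an antibody survives if it is detected in ≥ 4 samples of one tumor type
or in all samples of that type; (2) per-signal Pearson correlation of
paired log2 FF/FFPE values over *complete pairs* (samples detected in
both preservations), signals with < 3 pairs or zero variance reported as
undefined and excluded from testing; (3) Benjamini–Hochberg step-up
correction across all tested signals, significance at *p*-BH < 0.05;
(4) manual (a-priori) exclusions; (5) per antibody, retention of the
signal with the highest *r* (ties → smaller relative shift, then signal
id); (6) exclusion of shift-flagged and unclear-peak antibodies.  The
complete-pairs choice and the signals-as-family BH scope are documented
decisions where the procedure description leaves room; both are
configurable.  Every antibody receives exactly one disposition, so the
stage counts partition the input panel — an invariant the tests assert.

## Statistics

Clustering: samples are compared by Pearson correlation over their shared
non-missing signals (≥ 3 required), distance 1 − r, average linkage.
A zero-variance profile gets the maximal distance 2 with a warning.
Leaf order is deterministic (smaller subtree first, lexicographic
tie-break).  Merge heights are verified against a naive O(n³)
agglomeration oracle.

Pairwise t-tests mirror R's `pairwise.t.test` default: the standard
deviation is pooled across *all* tumor-type groups (s² = SS_within /
(N − k)), not only the compared pair; Welch's per-pair test is available
behind a flag.  A pair is tested for an antibody only with ≥ 2
non-missing values per group; untestable cells are missing and excluded
from the BH family.  BH scope defaults to one family per tumor-type pair
(across antibodies); a global scope over all pairs is available — the
choice of family is genuinely open and the default is the more
conservative reading of per-pair reporting.

## Classification

Features are the selected panel's log2 signals per sample.  Missing
values are imputed with the per-feature minimum of the *training* data
(a detection-floor surrogate), then features are standardized with
training-fitted statistics; both steps are refitted inside every
cross-validation training split, never on held-out data.  The kernel is
k(x, y) = exp(−σ‖x−y‖²) — sklearn's `gamma` equals this σ, which is the
convention under which the σ grid spanning 10⁻⁵…10 is meaningful for
~100 standardized features.

Nested cross-validation: stratified 5-fold outer splits, 10 repeats; with
five samples per class each outer fold holds exactly one sample per
class.  Hyperparameters are tuned per outer fold on the training portion
only, by mean accuracy over stratified 4-fold × 5-repeat inner splits;
ties break toward smaller C, then smaller σ (prefer the least complex
model, deterministically).  The reported matrix is the mean contingency
table over repeats; overall accuracy is sample-weighted, its SD is across
the ten repeats; per-class accuracy is the row-normalized diagonal.
`nested_cv` optionally logs exactly which row indices each fold's tuning
and fitting saw, making the no-leakage property a testable assertion
rather than a promise.

Class merging sums contingency rows and columns by superclass and
recomputes accuracies per repeat.  The final model selects (C, σ) by
5-fold × 10-repeat CV on the full training set and refits on all samples;
probabilities come from per-pair Platt scaling combined by pairwise
coupling (softmax over decision values available as an alternative).
The grade comparison reports mean correct-class probability per grade
group and a pooled-variance two-sided t-test (p = 1 for degenerate
zero-variance equal-mean input).

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run at the study's design size (300 antibodies,
25 pairs) where the claim depends on it — planted-set recovery uses ten
seeds at full size, null calibration twenty cohorts of 150 antibodies —
and at 120 antibodies with 2 outer × 1 inner CV repeats for the
classifier regime comparisons, where the claim is a relation between
conditions rather than an absolute level.  The acceptance script runs the
full default configuration (300 antibodies, complete CV schedule) on a
single seed.

## Known limitations

* Counts like "102 of 634 antibodies" from the motivating study are not
  reproducible — the underlying patient data are not public; the pipeline
  exercises the same decision rules on planted ground truth instead.
* The detection rule (area above a fixed floor) is a deliberate
  operational simplification; real assays may use per-plate backgrounds.
* Overlapping bands are not deconvolved; two true bands closer than the
  merge separation quantify as one.
* With ~100 correlated tests per tumor-type pair, BH controls FDR per
  family; inference across families is not corrected by default.
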