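# Methods

This note documents the modelling assumptions, parameter defaults and
numerical choices behind `promine`, and what the synthetic experiments do
and do not demonstrate.

## The analysis problem

Each patient contributes a sequence of calendar days. A day carries
once-daily measurements (systolic/diastolic blood pressure in mmHg, SpO2 in
%, weight in kg, ambient temperature in °C, ambient relative humidity in %),
a stream of wearable samples (body humidity and temperature, ECG-beat
parameters — PR interval, QRS duration, QT interval, RR interval, R- and
T-wave amplitudes — an activity label in {lying, sitting, moving}, and an
energy-expenditure intensity), and a patient-reported outcome (PRO): an
ordinal 1–5 rating of how the patient feels *relative to the previous day*.
The pipeline asks (a) how accurately binary good/bad feeling can be
predicted from the objective parameters, and (b) which parameters, in which
direction and at which cut-offs, drive the prediction.

## Feature construction

For each of 9 continuous channels (heart rate is derived as
`60000 / RR interval [ms]`): mean and population SD (divide by n; the
convention is arbitrary but frozen) over the whole day and within each of
the three activities, plus per-activity durations (sample count × sampling
interval; the interval is taken from the config or as the median timestamp
spacing of the day). Derived daily indices: RPP = SBP·HR,
DoP = ((SBP+DBP)/2)·HR (HR is the beat nearest the BP reading when a BP
timestamp is known — within a 30-minute window by default — otherwise the
daily mean, which is also the only option for the timestamp-free daily CSV),
SBP/DBP, skin/ambient temperature and humidity ratios, heart-rate
differences and ratios over the three activity pairs, duration ratios,
activity-time fractions (they sum to 1 over observed time), and the mean
per-sample HR/energy ratio (same-sample pairing).

Change variants subtract the most recent prior value of the same column if
it is at most 3 calendar days old (calendar days, not row adjacency; a
patient's first observed value has no change). Personalized variants divide
by the patient's whole-period mean of the column; that mean uses all of the
patient's days, so in cross-validation it leaks patient-level information
across folds exactly as the original experimental design does — a fold-safe
analysis should treat personalized columns with care. Cross variants
(change-of-personalized and personalized-of-change) are generated by
default and can be disabled (`include_cross_variants=False`).

The canonical enumeration is 99 base features, 297 without cross variants,
495 with them. The enumeration itself — not any particular integer — is the
contract; it is asserted in the tests.

Any formula with a missing operand yields a missing cell (missingness is
monotone through derivations). Division by zero yields a missing cell and a
logged warning, never an exception.

## Class definitions

Nine rules map PRO sequences to {bad, good, excluded} per day. Days rated 1
are always bad and days rated 5 always good. The windowed rules accept a
day rated 2 (symmetrically 4) when at least k of the n calendar days ending
at — and including — that day carry ratings in {1,2} ({4,5}); the "x 2" and
"x 3" run rules require all n. Interpretation choices, switchable where
noted:

* Windows count **calendar** days; unrated or out-of-range days count as
  not-in-set. With `require_full_window=True` a window reaching before the
  patient's first observation never qualifies (default off: the day itself
  plus available history decide).
* The classified day itself must carry the weaker rating (2 or 4) for a
  windowed assignment; rating 1 or 5 qualifies unconditionally.

Bad and good can never collide (their qualifying sets are disjoint), and
looser windows strictly extend stricter ones — both are property-tested
against an exhaustive window-checking reference.

## Feature subsets

* **CFS** maximizes `M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` where r̄_cf is
  the mean absolute feature–class correlation (point-biserial: Pearson
  against a 0/1 encoding) and r̄_ff the mean absolute feature–feature
  Pearson correlation on pairwise-complete observations; undefined
  correlations count as 0. Search is best-first from the empty set,
  stopping after 5 consecutive expansions that fail to improve the best
  merit (tolerance 1e-10). On pools of ≤ 10 features the search provably
  attains the exhaustive optimum in the tests.
* **RelieF** weights are exposed (m sampled instances, k nearest
  hits/misses under a mean-absolute-difference distance on max-min-scaled
  mutually observed features) but no default subset consumes them: the
  selection threshold has no principled default, and CFS is the pipeline's
  automatic selector.
* **Sparsity subsets** keep columns with missing fraction strictly below a
  threshold; the defaults 0.17 and 0.27 are config inputs, not detected
  knees.
* **Expert list**: a documented default of clinically prominent parameters
  (blood pressures, SpO2, weight, ambient temperature/humidity, humidity
  ratio, mean heart rate, mean QRS duration, each with change and
  personalized variants); fully overridable, and unknown names are an
  error, never silently dropped.
* **Activity exclusion** uses column provenance (per-activity aggregates
  and activity-derived indices), not name matching.

## Imputation

All three methods standardize columns (z-score on observed cells) before
distances/decomposition by default and return values on the original scale;
observed cells are bit-identical before and after.

* **kNN** (default k=5): row distance is the mean absolute difference over
  mutually observed standardized features; a missing cell takes the mean of
  the k nearest rows observing that feature, ties broken by row order.
* **Chained equations** (default 10 sweeps): initialize marked cells with
  column means; per sweep, re-estimate each marked cell by ordinary least
  squares of its column on all others, fitted on rows where the target is
  observed; rank-deficient designs fall back to a ridge penalty (1e-6) with
  a warning. This is deliberately single imputation — the behaviour being
  reproduced — not multiple imputation with pooling.
* **SVD-EM**: initialize missing cells with row averages; per iteration,
  take the k eigengenes (rows of Vᵀ) with the largest singular values and
  re-estimate each missing cell (i, j) by regressing row i on the
  eigengenes with position j excluded from the fit; stop when the total
  absolute cell change drops below `tol` (default 0.01, measured on the
  working scale) or at `max_iter`. Default k is the smallest number of
  eigengenes explaining ≥ 90 % of squared singular-value mass, capped
  at 10.

A numerical caveat documented deliberately: column z-scoring is an affine
map, so a rank-r matrix becomes rank ≤ r+1 after standardization. Exact
low-rank completion oracles therefore run with `standardize=False` and
k = rank; with standardization on, k must budget one extra dimension.

The masking benchmark hides observed cells completely at random (re-drawing
if a row would lose all its values), runs each method, and reports RMSE
against the hidden truth overall and per feature.

## Evaluation

Classifiers are scikit-learn implementations with frozen defaults recorded
into every result cell: random forest (100 trees), a pruned CART
(`min_samples_leaf=2`, `ccp_alpha=0.01` — approximating the pruned-C4.5
default of the classical toolkit family; an unpruned tree memorizes noise
and lands far below the baseline on label-independent data), Gaussian naive
Bayes, a linear-kernel SVM on standardized inputs (the classical
SMO-trained classifier normalizes by default), and the majority baseline.
Bit-exact parity with any other toolkit's internals is a non-goal.

Cross-validation is stratified by class (with 3–13 % minority shares,
unstratified folds degenerate; the fold count is reduced with a warning if
the minority class is smaller than the fold count). Each repeat draws a
fresh seeded split; a repeat's accuracy pools held-out predictions over its
folds, and the reported CA is the mean over repeats, in percent. Residual
missing values are mean-filled from the training fold only. Imputation
methods are applied fold-safely by default (method on the training fold;
held-out rows get training-fold column means); `global_imputation=True`
restores whole-table up-front imputation, which leaks across folds but
reproduces the original design. ROC curves pool held-out scores over the
folds of one repeat, with the bad class as positive; AUC is the trapezoid
rule, cross-checked against the pairwise-ranking probability in tests.
Wilcoxon signed-rank comparisons drop zero differences and use the exact
null distribution up to 25 pairs, the normal approximation with continuity
correction above.

## Relation mining and separation analysis

Every internal node of a fitted tree with unequal bad-class proportions in
its two subtrees yields one relation (feature, threshold, direction);
proportions are read from the tree's per-node class counts. The mined trees
are the same pruned CART the evaluation stage reports, one per named subset,
trained on the full labeled dataset. Relations are merged by (underlying
parameter, direction) across those trees; variants (avg/std/chg/pers) are
listed, cut-offs reported as a min–max range, and groups below
`min_occurrences` (default 2) dropped. Clinical annotation of relations
(correct / wrong / novel / unrelated / unknown) is expert input, never
computed.

The separation analysis z-scores features over the included days and
computes, for each day pair, the mean absolute standardized difference over
mutually observed features. Pairs are pooled over the whole cohort (not per
patient). The two populations — (same, same) and (same, good-or-bad) — are
binned into 10 shared equal-width bins, normalized to unit area. Pair
populations above `max_pairs` (default 200 000) are subsampled with the
given seed.

## Synthetic cohort generator

The generator emulates the study conditions: 24 patients by default,
observation lengths uniform on 10–80 days (≈ 45-day mean, ≈ 1080 total
days), PRO marginals fixed to the study's label-frequency table
(30/73/795/148/40 over 1086, i.e. ≈ 73 % feeling-the-same), and per-activity
channel missingness ≥ 60 % (channel-day blanking at 20–35 % combined with
channel-activity-day blanking at 55 %); daily measurements are 8–15 %
missing. Each patient draws parameter baselines from documented plausible
ranges (SBP 95–160, DBP 55–100, SpO2 90–100, weight 50–110 kg, ambient
temperature 15–30 °C, ambient humidity 25–75 %, HR 55–95 bpm, and analogous
ranges for the wearable channels); daily values follow AR(1) drift
(persistence 0.6, innovation SD 8 % of the range width). Because the PRO is
relative to yesterday, the latent wellbeing *change* is a linear
combination of standardized day-to-day parameter changes plus unit-variance
noise; ordinal labels come from quantile thresholds fitted per cohort so
the label marginals match the configuration regardless of effect sizes. The
first day of each patient has no previous day and hence no label. Sensor
streams draw around the daily means with per-activity offsets (heart rate
lying < sitting < moving; energy strongly activity-dependent). Missingness
is completely at random at the level of daily cells, channel-days and
channel-activity-days; informative (MNAR) missingness is out of scope.
Default planted effects point in the directions seen in the mined relation
catalog (humidity and weight up → worse; temperature, SBP, SpO2, QRS up →
better) at modest magnitudes (0.3–0.8 SD per SD of change).

What passing synthetic tests shows: the pipeline recovers planted
change-coupled effects, does not hallucinate effects on null data (with the
naive-Bayes caveat below), and every stage is deterministic under a seed.
What it does not show: performance on real cohorts with MNAR missingness,
label inconsistency between patients, autocorrelated wellbeing, or device
artifacts — none of which the generator emulates.

## Problem sizes and known limitations

* The null-recovery experiment uses 50 patients × 80 days (≈ 1060 labeled
  days under the "1, 2 vs. 4, 5" rule) with 10-fold CV repeated 30 times;
  the planted-effect experiment uses 40 × 80 (≈ 850 labeled days) with 5
  repeats — the observed effect (> 25 CA points over baseline) dwarfs
  repeat noise at that scale.
* On null cohorts, Gaussian naive Bayes sits ~3–4 CA points *below* the
  majority baseline: its single-Gaussian class-conditional model badly fits
  mixture-of-patients feature distributions, so estimation noise tilts its
  decisions. This is a property of the classifier on patient-clustered
  physiological levels, not spurious skill; the tree/forest/SVM classifiers
  stay within 3 points of the baseline.
* Chained-equations imputation is O(sweeps × features × OLS); with several
  hundred columns, prefer the sparse subsets before imputing.
* Personalized features and global up-front imputation leak information
  across CV folds by design (reproducing the original setup); fold-safe
  alternatives are the defaults where a choice exists.
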