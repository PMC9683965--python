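# Methods

`asdbench` implements a three-phase framework for building and selecting
hybrid machine-learning models that grade autism-spectrum-disorder (ASD)
severity (light / medium / intense) from mixed clinical and
sociodemographic tabular data. The selection problem is treated as
multicriteria decision-making (MCDM): candidate models are alternatives,
their evaluation metrics are criteria, and two fuzzy MCDM methods —
FWZIC for criterion weighting and FDOSM for ranking — provide the
decision arithmetic.

## Triangular fuzzy numbers

All fuzzy computation uses triangular fuzzy numbers (TFNs)
`(a, b, c)` with `a ≤ b ≤ c`: membership rises linearly from `a` to 1 at
`b` and falls to 0 at `c`. Arithmetic follows the extension-principle
componentwise rules — addition `(a₁+a₂, b₁+b₂, c₁+c₂)`, subtraction
`(a₁−c₂, b₁−b₂, c₁−a₂)`, product `(a₁a₂, b₁b₂, c₁c₂)`, quotient
`(a₁/c₂, b₁/b₂, c₁/a₂)` — with product and quotient understood as the
standard triangular *approximations* of the exact extension-principle
results; they are taken here as definitions. Crisp values are recovered
by centroid defuzzification `(a+b+c)/3`.

Design choices:

- The library is restricted to non-negative TFNs. Both built-in
  five-term scales live in `[0, 1]`, and on the non-negative cone every
  operation above preserves `a ≤ b ≤ c`; subtraction results leaving the
  cone raise instead of silently producing ill-ordered triples.
- Degenerate edges (`b = a` or `b = c`) get step membership (value 1 at
  the peak), the continuity limit of the linear edge, avoiding 0/0.
- Invariant checks compare floats at 1e-9; all published scale values
  have at most five printed decimals, far above double rounding error.

Both built-in scales — `importance5` (Not important … Very important)
and `difference5` (No difference … Huge difference) — map their five
terms to the same TFN vocabulary `(0,.1,.3), (.1,.3,.5), (.3,.5,.75),
(.5,.75,.9), (.75,.9,1)`. Additional scales can be registered from
config rows `(label, code, a, b, c)`.

## FWZIC criterion weighting

FWZIC (fuzzy-weighted zero-inconsistency) derives feature weights from
*independent* per-expert Likert ratings, so no pairwise-comparison
consistency ratio exists to violate. Pipeline: fuzzify each rating by
dividing its TFN by the expert's fuzzy row sum; average the fuzzified
cells componentwise over experts; centroid-defuzzify per feature; rescale
to unit sum.

- The order *defuzzify, then rescale* is the one deterministic reading
  that guarantees Σw = 1 for every panel; rescaling in fuzzy space first
  would not.
- Ratings must be integers 1–5; fractional or missing ratings are
  rejected rather than rounded, because the scale is defined only on
  integer codes.
- An expert rating *every* feature "Not important" produces a fuzzy row
  sum with zero lower support, making the fuzzification quotient
  undefined; such panels are rejected with a domain error. Any row
  containing at least one rating ≥ 2 is safe.
- Weights are computed per feature-selection technique over that
  technique's surviving set, so a feature's weight depends on which
  other features survived with it.

## Phase 1 — preprocessing

Order is fixed: clean/encode → mean imputation → min–max scaling → SMOTE.
SMOTE's Euclidean distances need complete, commonly scaled columns, which
forces the order.

- Whole-cell `?`, `/`, `-` become missing. Categorical strings are
  encoded by a deterministic codebook (alphabetical within column);
  severity is encoded light=0, medium=1, intense=2.
- Missing cells (including encoded categoricals) are replaced by the
  column mean; a fully missing column is an error.
- Min–max maps each feature to `[0, 1]`; constant columns map to 0 so
  degenerate synthetic inputs stay runnable.
- SMOTE upsamples every class to the majority count: each synthetic row
  is `x + u·(nn − x)`, `u ~ U(0,1)`, with `nn` one of the `k = 5` nearest
  same-class neighbours (`k` is the conventional SMOTE default).
  Originals are kept verbatim; runs are deterministic under a seed.
  Encoded categorical cells are interpolated as reals, i.e. the whole
  table is treated numerically after encoding.

## Phase 2 — feature selection, weighting, hybrid models

Three filter scorers rank features against the class: Pearson χ² of the
feature×class contingency table; information gain
`H(class) − H(class|feature)` in bits; and multiclass ReliefF with
nearest-hit/miss updates, prior-weighted across contrasting classes,
`k = 10` neighbours, all rows sampled. Continuous columns are
discretized for χ²/IG by equal-frequency binning into 4 bins, falling
back to equal-width bins when the mass concentrates on few values (a
situation SMOTE interpolation creates for near-binary columns). The
default selection rule keeps features with positive scores; top-k and
threshold rules are configurable, with ties broken by feature name.
The published feature-set sizes (39/38/41 of 48) are data-dependent and
not recoverable without the original cohort; they are treated as context,
not targets.

The surviving set of each technique is FWZIC-weighted and each selected
column is multiplied by its weight (the published transform has
undefined auxiliary symbols; the implementation uses the plain
"weight × data" reading). Crossing the three techniques with five
classifiers — decision tree, SVM, naive Bayes, KNN, AdaBoost, at library
default hyperparameters, seeded where stochastic — yields the 15 hybrid
alternatives A1–A15. Each is fit on a stratified 66/34 split and scored
on seven criteria: train time and test time (cost), and AUC, accuracy,
F1, precision, recall (benefit). Accuracy/F1/precision/recall are
micro-averaged — for single-label multiclass prediction these four
coincide exactly, which is asserted on every evaluation and explains the
repeated per-row values in the published matrix — and AUC is macro
one-vs-rest on predicted class probabilities.

## Phase 3 — FDOSM ranking

The ideal solution takes each cost column's minimum and each benefit
column's maximum (a configured critical value can override either, for
criteria whose optimum is interior — unused for these seven). Experts
express each cell's distance from the ideal on the five-term difference
scale; terms become TFNs, each alternative's TFNs are averaged, and the
centroid gives its opinion score in `[0.1333, 0.8833]`. Lower is better.
Group decisions average per-expert scores; by linearity of the centroid
the aggregation order is immaterial. Ordinal ranks break ties by
alternative order; dense ranks are also emitted because the published
table lets tied alternatives share a rank.

Human opinion matrices are first-class inputs (one CSV per expert).
`auto_opinions` is an explicitly synthetic surrogate for unattended
runs: the normalized gap `|v − ideal| / (col max − col min)` is binned at
`[0.1, 0.3, 0.55, 0.8]` into the five terms. The edges are an
even-handed partition of the unit gap with a narrower "No difference"
band; they are configurable and no claim is made that they emulate any
particular expert.

### Timing criteria and reproducibility

Wall-clock train/test times are always measured and recorded in the
decision matrix, but they are hardware- and load-dependent: two
identical runs measure different times, and a gap-binned opinion can
flip at a bin edge. The pipeline therefore defaults to ranking on the
five deterministic quality criteria (C3–C7), making the rank report
byte-identical across reruns with the same seed;
`rank_time_criteria=True` restores the full seven-criterion ranking at
the documented cost of run-to-run variation. Supplied human opinion
matrices always cover all seven criteria.

## Synthetic cohort generator

The generator emulates the published cohort description: 538 patients,
48 features with the printed kinds and value ranges, severity counts
241/259/38, and sentinel missing symbols. (One printed numeric range is
reversed in the source table and is read as 85–609.) Signal is planted
as class-conditional shifts: behavioural skill features get severity-
dependent P(yes) (e.g. 0.9/0.5/0.1 across light/medium/intense),
deficit behaviours the reverse, and one numeric feature severity-shifted
means; these defaults make the severity levels strongly separable, in
line with the high published accuracies. Unprintable details default to
uniform category frequencies; lab-test features default to a 5% missing
rate (the published per-feature missing percentages are not printed),
others to 0. Class-conditional independence is a deliberate
simplification — no copulas or feature correlation — so passing tests
demonstrate the framework's mechanics, not clinical realism.

Two caveats the tests make explicit:

- Because SMOTE precedes feature scoring (the published order),
  interpolated cells mark upsampled classes and measurably inflate the
  filter scores of *noise* features; with the default planted effects
  every informative feature still outranks every noise feature across
  seeds, which is the property the recovery test asserts.
- The zero-signal chance-accuracy test uses an already-balanced
  signal-free cohort: with heavy SMOTE upsampling before the split,
  synthetic test rows are near-duplicates of training originals, which
  can raise measured accuracy above chance even without signal. That
  leakage is inherent to balance-then-split and is why the no-signal
  check controls for it.

The expert-panel simulator draws a latent 1–5 importance per feature and
perturbs each expert's copy by ±1 with probability `1 − concordance`
(default 0.8), clipped to the scale.

## Problem sizes and determinism

Default study shape throughout: 538→777 rows, 48 features, 15 models,
4 rating experts, 3 opinion experts. A full synthetic pipeline run takes
a few seconds on one CPU. Every stochastic step (generation, SMOTE,
ReliefF sampling, splitting, stochastic learners, panel simulation)
derives from the run seed, and the end-to-end rank report is
byte-reproducible under the default configuration.

## Known limitations

- The published feature weights and decision-matrix cells cannot be
  reproduced without the original on-request cohort and the experts'
  actual ratings; the package reproduces the *arithmetic* (weighting,
  ideal solution, opinion scores) exactly and treats those tables as
  fixtures.
- Surrogate opinions are a stand-in for human judgement; on the
  published matrix they recover the published top and bottom model
  groups but not the exact published scores.
- TFN product/quotient are triangular approximations; alpha-cut exact
  arithmetic, trapezoidal numbers and other defuzzifiers are out of
  scope.
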