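# Methods

## Data model

A 24-2 exam samples 54 locations on a 6°-spaced grid over the central 24°;
two locations fall on the physiologic blind spot, leaving 52 usable
total-deviation values (TDVs, dB relative to age-normal; negative = loss).
All vectors in the package are 52-dimensional in a frozen canonical order:
row-major, superior row first, x ascending within each row, right-eye
convention (x positive temporal, y positive superior). The ordering itself
is a package convention — any fixed order works, but archetype vectors and
CSV columns depend on it, so it is immutable.

Left-eye fields are expressed in right-eye format by the grid's horizontal
mirror map (x → −x). The 24-2 lattice is not symmetric (the nasal-step
column at x = +27 and the blind-spot column have no active mirror partner),
so the four unpaired locations map to themselves; the map is an involution
and mirroring is idempotent. Records are validated on construction:
TDVs in [−50, +20] dB, reliability rates in [0, 1], VFI in [0, 100].
Elapsed time is days/365.25 from the first included visit; dates are
ISO-8601. Reliability rates are stored as fractions; the CSV reader accepts
a percent dialect.

## Cohort funnel

Selection for longitudinal analyses applies, in this fixed order:

1. **Learning exclusion** — drop each eye's first 2 tests (perimetric
   learning effect).
2. **Reliability** — keep tests with fixation loss ≤ 33%, false negatives
   ≤ 20%, false positives ≤ 20% (inclusive bounds, matching the printed
   "≤" convention of the clinical criteria).
3. **Visit spacing** — greedy forward scan keeping visits whose gap from
   the last kept visit lies in [150, 210] days. Shorter gaps are skipped.
   For longer gaps the default policy also skips (accumulation continues);
   a `terminate` policy that stops the series is available because the
   clinical handling of long gaps is genuinely ambiguous.
4. **Eligibility** — ≥ 2 surviving tests for the MD-change cohort; ≥ 5
   surviving tests *and* ≥ 3 years first-to-last span for the progression
   cohort. Both thresholds are configurable: published cohort descriptions
   are not always internally consistent (e.g. a mean follow-up near 31
   months alongside a 3-year minimum), so nothing is hard-coded.
5. **One eye per patient** — when both eyes qualify, one is chosen
   uniformly at random from a single integer seed, patients processed in
   sorted-ID order so the draw sequence is reproducible.

## Archetypal analysis

Principal-convex-hull formulation: minimize ‖X − W B X‖²_F with rows of
W (n×k) and B (k×n) on the probability simplex. Optimization is
alternating constrained least squares:

- **W-step:** batched FISTA-accelerated projected gradient with step 1/L
  (L = ‖AAᵀ‖₂), warm-started across sweeps; if the accelerated step ever
  fails to decrease the objective it is redone as plain projected gradient,
  which is monotone.
- **B-step:** each row is an exact nonnegative least-squares solve on a
  sum-constraint-augmented system (penalty row weight 10·max|X|, solution
  renormalized to Σ = 1), accepted only if the objective does not increase.

The sweep objective is therefore non-increasing (asserted in tests to 1e-9
slack). Initialization is furthest-sum over data rows; `n_restarts = 5` by
default (heavier fits in the test suite use 1–2 restarts, which the
recovery experiments show is sufficient at these problem sizes), `max_iter
= 500` sweeps, relative-improvement stop at 1e-6. Each archetype's
convex-combination coefficients over training rows are stored as a hull
certificate (rows ≥ 0, Σ = 1 within 1e-6).

Single-field projection (`aa_decompose`) runs projected gradient followed
by an exact active-set KKT polish, so the simplex constraints hold to
machine precision, inactive weights are exactly 0, and the optimum matches
a dense 0.001-step grid search within 1e-3 per coordinate. Reconstruction
error is the mean per-row squared residual; the scree (`select_k`) reports
it on held-out folds of a seeded k-fold split. TDVs enter the fit raw (in
dB, not standardized) — standardization would distort the dB geometry the
archetypes are read in; a config flag is deliberately absent.

## Fuzzy c-means and the hybrid decomposition

Memberships use the standard orientation — the nearer centroid receives the
larger weight — computed in log space for stability at extreme fuzziness:
w_j ∝ d_j^(−2/(P−1)), normalized per row. (Some printed forms of the
membership equation show the distance ratio inverted; the package follows
the standard orientation, which is what the surrounding theory — crisp
limit at P → 1⁺, uniform limit at P → ∞, nearest centroid dominating —
requires.) If a field coincides with one or more centroids, the weight is
split equally among the coincident centroids and is 0 elsewhere (the
continuous limit of the formula).

`P` defaults to 2, the standard FCM choice; it is carried in the
configuration and in serialized outputs. Distance is plain Euclidean on the
52-dim TDV vector, with no location weighting.

The hybrid decomposition evaluates the membership formula once against the
*fixed* fitted archetypes — no centroid iteration. Coefficients are
strictly positive for generic fields, sum to 1 (within 1e-10), and carry no
reconstruction residual, in deliberate contrast to the AA projection whose
residual is positive outside the hull. A full iterative FCM
(`fcm_iterate`, alternating membership and centroid updates from a seeded
random start) is provided for validation only.

## Slopes and progression criteria

All rates of change are closed-form OLS slopes against years from baseline,
with a two-sided t-test on the slope. Degenerate-fit conventions:

- n = 2 (exactly determined line): p = 1, so a 2-visit series can never
  satisfy a p-threshold criterion;
- zero residual variance with n > 2: p = 0 (continuous limit of an
  unbounded t statistic);
- constant series: slope is exactly 0 (the slope is computed from centered
  y, avoiding a ±1e-16 sign that would otherwise interact with the strict
  slope-sign rules below).

Criteria:

- **MD criterion:** slope < 0 and p < 0.05 (both strict).
- **VFI criterion:** same rule on VFI (%/year).
- **PLR criterion:** ≥ 3 of the 52 locations with TDV slope ≤ −1.0 dB/year
  and p < 0.01. The slope bound is inclusive, implemented with a 1e-9
  absolute slack so a decay of exactly −1.0 dB/year counts regardless of
  last-ulp rounding. No spatial-contiguity or hemifield requirement is
  imposed on the 3 points, and raw TDVs are used (no smoothing). No
  multiple-testing correction is applied anywhere; raw p-values are
  reported.

Because each visit's decomposition coefficients sum to exactly 1 and OLS is
linear, each eye's k coefficient slopes sum to 0 (within 1e-8) — used as a
pipeline self-check. `slope_md_relation` reports the Spearman correlation
and the OLS line of MD slope on a coefficient slope across eyes:
diffuse-loss archetypes produce steep lines, focal ones near-horizontal
lines.

## Prediction and diagnostic evaluation

MD-change prediction instances are per-visit deltas from baseline: 16
coefficient differences as features, MD difference as label, one instance
per non-baseline visit. The AA and FCM tables are built from the same
visits so they share row identity. `repeated_eval` draws one random
train/test split per repeat (default fraction 0.70, 30 repeats) applied
identically to both arms — a requirement for the paired t-test across
repeats to be valid — and records test MSE and Pearson correlation.
Regressors: k-NN (k = 5), random forest (500 trees), LightGBM (100 rounds,
learning rate 0.1); hyperparameters are not part of the scientific claim
and are recorded in output metadata.

AUCs use the Mann–Whitney pair-count estimator (ties ½) via midranks;
confidence intervals use the DeLong placement variance at 95%; paired
curves on the same cases are compared with the two-sided DeLong test
(identical score vectors give p = 1 by convention). The estimator equals
exhaustive pair counting exactly, and the DeLong p agrees with a
10⁴-resample stratified bootstrap on toys within 0.02 (both asserted in
tests). Score orientation in `progression_auc_table` defaults to
`"increase"`: a rising coefficient on a defect archetype scores as more
progressive, which is the direction progression takes in both the model and
the generator; `"decrease"` is available for reading the normal pattern's
coefficient, whose share falls as an eye worsens.

## Synthetic cohorts

The generator defines the study conditions the package is validated under.

**Archetype bank.** 16 deterministic patterns built from coordinate-mask
regions of the canonical grid, labelled by their clinical reading (normal;
superior arcuate / nasal step / central-sparing hemifield / altitudinal;
the four inferior counterparts; double arcuate; temporal wedge; ring
scotoma; total loss; central scotoma; temporal hemianopsia; shallow
superior depression). Nominal defect depth is −25 dB — deep enough to
separate patterns, inside the TDV validity range — with per-pattern depth
factors (0.78–1.12) and mild shape shading (eccentricity dip of the normal
field, altitudinal deepening away from the midline, central-scotoma depth
peaking at fixation, nasal breakthrough of the double arcuate). The factors
and shading reflect typical clinical pictures and serve a structural
purpose: they make the 16 patterns affinely independent (verified by rank
in tests), so noise-free mixtures decompose uniquely — without them,
several flat-mask patterns would be exact vector combinations of others and
mixture weights would be unidentifiable. The normal pattern is a mild
physiologic depression (−0.5 to −1.3 dB with eccentricity) rather than
exactly 0 dB, giving the normal archetype a defined direction so
cosine-based recovery matching is meaningful.

**Cross-sectional fields.** Mixing weights are Dirichlet(0.3) — sparse, so
most fields are dominated by few patterns — with 15% of rows placed exactly
at hull corners so every archetype is represented in the sample.
TDV = weights · bank + i.i.d. Gaussian noise (1 dB SD per location,
clipped to [−50, +20]).

**Longitudinal series.** 150 patients × 2 eyes by default, 7 analysis
visits at uniform 150–210-day gaps, 2 extra-noisy learning tests prepended.
Exactly ⌈0.3 · n_eyes⌉ eyes progress (a seeded global draw, so the count is
deterministic bookkeeping): each progressing eye shifts weight toward one
assigned defect archetype at 0.1/year (renormalized), which induces an MD
decline through the defect's depth. About 10% of tests violate the
reliability criteria. All randomness flows from one master seed through
counter-based per-eye streams, so any subset regenerates identically.

**Proxies and what passing tests do not show.** The generator's MD is the
unweighted mean TDV and its VFI is an affine map of MD clipped to
[0, 100]; the instrument's definitions are proprietary and weighted. Noise
is homoscedastic Gaussian per location, with no eccentricity- or
sensitivity-dependent variance and no inter-visit correlation. Passing
tests therefore demonstrate the correctness and direction-of-effect of the
machinery under a faithful structural model of perimetric data, not
quantitative agreement with any clinical cohort — clinical effect sizes,
AUCs and error magnitudes must be re-established on real archives.

## Numerical choices

- Simplex projections (Duchi sort-based) renormalize the row sum, so
  Σw = 1 holds to the last ulp.
- The active-set polish solves the KKT system on the support and
  renormalizes without re-projection, so inactive AA weights are exactly 0
  (the zero/nonzero contrast with FCM memberships is itself a tested
  property).
- The B-step NNLS penalty weight only needs to dominate the data scale
  (10·max|X|); the renormalization plus acceptance guard makes the fit
  insensitive to its exact value.
- Problem sizes in the shipped tests (up to 2,000 fields for archetype
  recovery, 200 eyes for the evaluation protocols) were chosen as the
  smallest at which the tested properties are stable; the library itself
  has no size assumptions beyond n ≥ k.

## Known limitations

- AA fitting is a non-convex problem; restarts mitigate but do not
  eliminate dependence on initialization.
- The mirror map fixes the four asymmetric grid locations in place; a
  left-eye defect at the nasal-step column is therefore not relocated.
- The PLR criterion treats locations independently; cluster-based or
  GPA-style event criteria are out of scope.
- `ArchetypeSet.from_json` restores patterns and metadata but not the
  training-row hull certificate (it stores an identity placeholder).
- The progression AUC table applies one score orientation to all
  archetypes per call; a per-archetype orientation would need two calls.
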