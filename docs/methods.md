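# Methods

## The problem and the model

The pipeline addresses case-control classification from species-level
relative-abundance profiles of faecal shotgun metagenomes, with pancreatic
ductal adenocarcinoma (PDAC) as the target class.  Its distinctive pieces
are (i) a *frozen* normalization that lets a trained model be applied
bit-reproducibly to cohorts it has never seen, (ii) an
*enrichment-constrained* variant of the classifier whose point is
cross-disease specificity rather than in-cohort accuracy, and (iii) a
synthetic-cohort generator that reproduces the statistical structure those
mechanisms rely on, so the whole workflow is testable without patient data.

## Normalization

For each sample the model features `x` (relative abundances) are
transformed as

    L = log10(x + pc),   clr = L − mean(L),   z = (clr − m) / s

with pseudocount `pc = 1e-5` (zeros map to −5 before centring), the clr mean
taken within the sample over the model's feature universe, and `m`, `s` the
per-feature mean and standard deviation (n−1 denominator) of the clr values
across *training* samples.  The tuple (feature list, pc, m, s) is the frozen
parameter record.  Applying it to new data selects exactly the stored
features — species missing from an external profiler's output are imputed
as zero abundance *before* the pseudocount (the only choice that keeps the
transform total), extra species are ignored — and reuses `m`, `s`
unchanged.  Degenerate features (constant in training) get `s = 1` with a
warning so transfer cannot divide by zero.  The clr is centred over the
model feature set, not the full profile; a knob exists because the
alternative convention is defensible too.  Internally the matrix is forced
C-contiguous before the row means so that results do not depend on the
memory layout of the caller's frame — this is what makes refit-vs-frozen
comparisons exactly bit-identical.

## Classifiers

Training uses 10-times-repeated stratified 10-fold cross-validation.
Within each of the 100 training folds, *everything* is refit from the raw
(filtered) table: the normalization, then — for the enrichment-constrained
variant — a filter keeping species whose single-feature AUROC (cases
positive) on the training fold is ≥ 0.5, then an L1-regularised logistic
regression (liblinear).  The regularization cost is chosen per fold by inner
stratified 5-fold AUROC over a fixed grid of 10 log-spaced values in
[1e-2, 1e1], smallest cost on ties (sparser model); the grid and nested
selection are this package's design decision, as no canonical strength
exists for the protocol.  Held-out samples get the fold model's
probability; a sample's CV score is its mean over the 10 repeats.  A
feature's robustness is the fraction of fold models with a nonzero
coefficient.  Training folds are internally sorted by sample ID before
fitting so fold fits — and hence CV scores — are invariant to the order
samples arrive in; liblinear's internal shuffle is pinned for exact refit
reproducibility.

An empty enriched set (possible only through ties, since clr rows sum to
zero within a sample) yields a degenerate fold: an all-zero model emitting
probability 0.5, preserving the 100-model ensemble shape.

For transfer, the ensemble also stores one normalization fitted on the full
training table; an external sample's score is the mean probability over all
100 fold models, each applying its own frozen fold normalization.  External
scoring is deterministic and invariant to sample order and extra features.

Class imbalance is not reweighted (cohorts are near-balanced by design); a
knob exists.

## Fusion, calibration, external evaluation

CA19-9 is coded 1 strictly above 37 U/mL and 0 otherwise, including "not
available" — a missing measurement can only lower a combined score.
Exactly 37 U/mL codes negative (strict inequality; clinical convention).
OR combination = score + code; AND = score × code; both feed rank-based ROC
analysis, so the OR range [0, 2] needs no clipping.

The decision threshold is the smallest observed control score `t` such that
the number of control scores above `t` is within the integer flag budget
`floor(n × (1 − specificity))` (strict `>` both here and when flagging;
integer counting avoids float fuzz at exact boundaries like 1/10).  The
workflow calibrates on the *out-of-fold CV scores* of the training
controls: held-out scores are the unbiased stand-in for how fresh controls
will score.  In-sample re-scores of training controls are systematically
too confident (measured on this generator: mean 0.10 vs 0.19 for held-out
and fresh controls alike) and would inflate every external false-positive
rate.  `calibrate_threshold` itself is score-agnostic.

External cohorts are scored frozen, flagged at the carried threshold, and
reported per (cohort, status group) plus a pooled non-PDAC row per cohort,
since either grouping can be the quantity of interest.  Diagnostics report
Spearman correlations of scores with age and sequencing depth and a
rank-sum test across sex.

## Diversity

Rarefaction draws reads without replacement (multivariate hypergeometric)
to a common depth — default the minimum retained sample depth — and
averages Hill numbers over 100 iterations (q = 0 richness, q = 1
exp-Shannon, q = 2 inverse Simpson; non-increasing in q).  Evenness is
reported as Hill(q)/Hill(0) for q ∈ {1, 2}.  Bray-Curtis uses
Σ|x−y| / Σ(x+y) on raw or square-root counts; an all-zero pair is defined
as distance 0 with a warning.  PERMANOVA partitions squared distances by a
single factor (pseudo-F with the classical within/between decomposition);
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, permuting labels only within
strata when given.  Only the single-factor-plus-strata design is
implemented, matching its use here.

## Univariate screen

Two-sided Wilcoxon rank-sum per species (exact enumeration when both
groups ≤ 10 and tie-free, else normal approximation with tie correction;
constant features give p = 1 by convention), Benjamini-Hochberg correction
across the feature table (one body site at a time, never pooled), the
generalised fold change as the mean over quantiles 0.05–0.95 (step 0.05,
linear-interpolation quantiles) of case-minus-control differences of
log10(x + 1e-5) — the same pseudocount as the normalization, since none is
canonical for the gFC — and single-feature AUROC as the tie-corrected
Mann-Whitney probability.

## The synthetic generator

Species `j` has baseline log10 abundance `mu_j ~ N(−4, 1)` and spread
`sd_j = 0.5`; sample `i` draws `x_ij = 10^(mu_j + sd_j·z)` or a structural
zero with probability 0.2, cases multiply enriched species (default 15, at
4-fold) and depleted species (12, at 0.25-fold), and each sample is closed
to sum 1.  Reference cohort: 60 cases + 60 controls.  Design notes:

- **Marker species are sub-dominant**: their baselines come from a tighter
  stratum `N(−4, 0.4)`.  With markers drawn from the heavy-tailed bulk they
  can carry >15% of total mass, and closure then drags the observed
  generalised fold change of a 4-fold enrichment down to ~0.43 log units;
  sub-dominant markers keep closure a small correction (and are the
  realistic case — known disease markers are not dominant taxa).
- **`sd = 0.5` places the default effects in the strongly separable
  regime** the reference condition represents: at `sd = 1` the 4-fold
  effect is so weak per species (single-feature AUROC ≈ 0.6) that LASSO
  feature selection, not the signal, caps performance near AUROC 0.75 even
  though an oracle given the true markers reaches 0.9.
- External cohorts add a per-cohort per-species batch shift `N(0, 0.25)` on
  the log10 scale.  Other-disease cohorts apply *only* the depletion
  effects — generic dysbiosis — never the enrichment; healthy cohorts
  neither; pdac-like cohorts both.  This is the mechanism by which the
  enrichment-constrained model's external false-positive rate separates
  from the unconstrained model's.
- CA19-9 is Bernoulli with sensitivity 0.80 / specificity 0.75 (the
  reported screening characteristics), optional missingness ("not
  available" codes 0), and serum levels drawn consistent with the flag
  relative to 37 U/mL.
- Age, sex and depth are independent of group by default (matched-cohort
  assumption); an `age_shift` knob reintroduces a score-age association for
  the diagnostic.  Stage probabilities (I–IV) default to
  (0.10, 0.20, 0.30, 0.40), reflecting predominantly late diagnosis.
- One integer seed; every sub-stream (baselines, profiles, metadata, batch
  shifts) derives from it, so cohorts regenerate byte-identically.

What the generator does *not* emulate: phylogenetic correlation between
species, overdispersed count noise at finite sequencing depth (profiles are
continuous relative abundances; counts are derived by rounding only for
diversity analyses), longitudinal structure, and realistic confounder-
microbiome coupling.  Passing tests therefore show that the *pipeline
mechanics* (leakage-free CV, frozen transfer, the specificity mechanism,
calibration) behave as designed under the assumed signal structure — not
that any particular accuracy is attainable on real cohorts.

## Numerical and testing choices

Filtering comparisons are inclusive (≥) on abundance, prevalence and count
boundaries.  The model-feature screen interprets the single 0.001 cut-off
as *maximum* relative abundance (prevalence screening already happens
upstream; a knob exists because mean abundance is a defensible
alternative).  Profile TSVs use the mOTUs dialect: leading `#` lines are
comments except a `#feature_id` header; values serialize via `repr` for
exact round-trips.  DeLong's midrank variance gives AUROC CIs (clipped to
[0, 1]).  Test problem sizes — 20 label-permutation replicates, 500
PERMANOVA null simulations at 199 permutations, 1000-case oracle sweeps —
are chosen so the full battery characterizes calibration tightly while the
suite stays comfortably runnable on a laptop.

## Known limitations

Single-factor PERMANOVA only (no multi-factor marginal effects or dbRDA);
no BIOM I/O; no elastic-net/ridge variants; the fold-model ensemble stores
per-fold normalizations, so model JSON artifacts are large-ish (~100 ×
feature-count floats); the generator's independence assumptions above.
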