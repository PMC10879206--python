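# Methods

## Sequential classify-or-progress pathways

A pathway is an ordered sequence of platforms. All patients start at the
first platform; at each stage a patient whose ensemble confidence clears
the threshold is classified with that platform's majority-vote class,
everyone else is "uncertain" and progresses; the final platform
classifies whoever remains regardless of confidence. "Clears" is
implemented as `confidence >= threshold`, so a threshold of 1.0 means
"classify on unanimity". With the default 50 repeats the attainable
confidences form the grid {2|m/50 − 0.5| : m = 0..50}, on which `>= 0.9`
and `> 0.9` route identically.

## Confidence from repeated cross-validation

Each platform's ensemble is r-repeat k-fold stratified cross-validation
(defaults r = 50, k = 2; k = 2 maximizes model diversity across the
ensemble). Every repeat yields one out-of-sample vote per patient; the
confidence score is 2|p − 0.5| on the majority fraction p, and an exact
50–50 split draws the class uniformly from a dedicated seeded stream,
independent of the fold-randomness stream, so routing is reproducible.

A caveat that matters when interpreting confidences: a patient's feature
vector is fixed, so their r votes are *correlated* across repeats — vote
variability comes only from model variability (fold composition and the
fold-specific selected features). Patients with no signal on a platform
therefore do not converge to confidence ≈ 0 as r grows; a fraction of
them sit far enough from the average decision boundary that most fold
models agree on a (coin-flip) class, yielding high confidence without
accuracy. This is intrinsic to aggregating repeated-CV votes, and it is
why planted-subpopulation stage occupancies run a few points above the
planted fraction in the synthetic experiments.

## Per-platform models

* **Feature selection** ranks features by the absolute two-sample Welch
  t statistic (unequal variances; the choice between pooled and Welch is
  ours and documented, ties break by column order). Constant features
  with equal means score 0; zero-variance features with different means
  score +inf (perfect separators).
* **Feature count tuning** picks, per training fold, the candidate count
  (default grid 10..100 by 10, clipped to the feature number) that
  maximizes balanced accuracy in an inner 2-fold CV on that training
  fold only; exact ties go to the smaller count (parsimony).
* **DLDA** uses per-class means, pooled within-class per-feature
  variances (floored at 1e-8 x the mean positive variance; if all pooled
  variances are zero the floor falls back to the overall spread) and
  empirical class priors. Exact discriminant ties go to the first-listed
  class, deterministically.

For external application the r·k fold-trained models *are* the ensemble:
nothing is refit on the full training cohort, and each external patient
receives r·k votes.

## Cost accounting and ordering selection

A patient's cost is the sum of the costs of the platforms they consumed
(a prefix of the sequence); the cohort total and the raw assay count are
both reported, since either may be the relevant economic axis. Candidate
orderings keep the first `fixed_tiers` platforms pinned (e.g. clinical
first) and permute the rest. Per-platform confidences do not depend on
sequence position, so they are computed once and shared by all
orderings. Rank 1 is the best balanced accuracy and, separately, the
lowest cost; exact ties share average ranks; the score is the weighted
mean of ranks (weights normalized to sum to 1). Tied scores fall back to
lower cost, then lexicographic sequence order. Rank direction and the
average-rank tie policy are our choices, made for symmetry and
stability.

Baselines use the same folds, repeats, selector and classifier as the
pathways: one repeated-CV model per single platform concatenated with
the clinical platform (features prefixed with the platform name to avoid
collisions), and one merged model over all platforms; each pays the full
cost of every platform it uses for every patient.

## Cross-cohort transfer

Per platform: (1) library-size normalization — each sample row rescaled
to sum to 1e6; skippable per platform for intensity data; (2)
restriction to features common to both cohorts; (3) an optional
training-side SD prefilter (e.g. SD > 5 for a high-dimensional count
platform) to keep the pairwise expansion tractable; (4) natural-log
ratios of all C(m, 2) feature pairs with a configurable pseudocount
(default 0 for strictly positive data; use 1 for counts with zeros); (5)
removal of pairs whose *training* log-ratio SD is below 0.1, frozen in a
portable JSON spec that external data consumes verbatim; (6)
patient-level standardization of the retained pairs (each row to mean 0,
variance 1, sample SD with ddof = 1). Standardization is row-local, so
deployment needs no cohort statistics. We drop low-SD pairs first and
standardize over the retained pairs; standardizing before dropping is a
defensible alternative that would change the row statistics slightly.

Multiplying any sample's raw row by a positive constant changes nothing
downstream (the constant cancels in step 1 and again in step 4 when the
pseudocount is 0), which is the property that lets a model trained on
counts score fluorescence intensities.

## Synthetic cohorts

The generator plants the structure the framework is designed around:
each platform separates the classes only for its own disjoint
subpopulation of patients (fractions assigned in platform order; any
remainder is resolved by no platform), with informative-feature class
means +/- Delta/2 x noise SD and everyone else pure noise on that
platform. Defaults are a sparse-biomarker platform: 100 features, 3
informative, unit noise — few true markers among many noise features,
which is both the realistic omics regime and the one in which the
ensemble's fold-varying feature selection provides genuine vote
diversity. Gaussian intensities by default; `distribution="lognormal"`
gives strictly positive count-like data (class shift planted on the log
scale) for the transfer pipeline. External cohorts redraw patients from
the same class-conditional structure, then apply log-uniform per-sample
scale factors, optional per-feature offsets and a configurable feature
overlap fraction.

What passing tests on these cohorts do *not* show: real platforms have
correlated features, batch effects, heavy tails and label noise, none of
which the generator emulates; synthetic separability (Delta = 8 gives
near-perfect subpopulation resolution) is far cleaner than any real
assay.

## Numerical and degenerate-input choices

Metric ratios with empty denominators evaluate to 0. The positive class
is named in the configuration (default: lexicographically larger
label); relabeling the classes swaps sensitivity and specificity and
leaves balanced accuracy unchanged. Missing-data preprocessing drops
features missing in more than 50% of samples and imputes the rest by
the mean of the 5 nearest samples (Euclidean distance on mutually
observed features); the neighbor count is a conventional default, and
the operation is idempotent on complete matrices. Readers never guess
matrix orientation: transposition requires an explicit flag.

## Problem sizes

The test suite and examples run cohorts of 40–200 patients with 10–100
features per platform, 5–50 repeats and 2 folds; the
planted-subpopulation recovery experiment uses the full default
configuration (50 repeats, candidate grid 10..100) on 200 patients over
5 seeds. These sizes were chosen so the complete suite runs in well
under a minute per module while leaving every contract (vote counts,
conservation, reproducibility) exactly exercised.

## Known limitations

* Only two outcome classes; no probability calibration of the ensemble
  votes.
* One platform order for the whole cohort (no per-patient adaptive
  ordering) and no time-to-diagnosis modelling.
* DLDA is the only classifier on the tested surface; the module
  boundaries admit other classifiers but none is wired in.
* No batch correction beyond what log-ratios and patient-level
  standardization absorb.
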