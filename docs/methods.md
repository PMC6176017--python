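# Methods

This note documents the models and procedures implemented in `httimpute`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and the limits of what the test suite demonstrates.

## Qualitative expression classes

All modelling operates on ternary calls rather than expression magnitudes.
A probe's relative expression x (log-ratio versus its matched vehicle
control) is called up-regulated if x > `up_threshold`, down-regulated if
x < `down_threshold`, and unchanged otherwise.  Defaults are ±0.1.  The
inequalities are strict: a value exactly at a threshold is "unchanged",
the conservative reading of a dead zone.  The package performs no
normalisation; inputs are assumed to be log-ratios already, and missing or
non-finite values are rejected rather than imputed.  The threshold scale is
exposed in `CategorizationConfig` because the appropriate dead zone depends
on the platform and preprocessing that produced the ratios.

## Filtering and feature-pool reduction

`median_variance_filter` removes probes whose across-sample variance falls
below the median probe variance — with all variances distinct this keeps
exactly ⌈n/2⌉ probes.  Variance is the population variance (denominator n);
the estimator choice is arbitrary but fixed and documented.

`reduce_features` clusters **probes** (rows), not samples: rows are
z-scored across samples, embedded by PCA, and partitioned by k-means; each
cluster contributes the member probe nearest its centre (Euclidean, in PCA
space).  Open choices, fixed as follows:

* PCA dimensionality: the fewest components capturing 90 % of the variance
  (configurable, `n_components` as an integer or a fraction).
* k selection: the distortion-vs-k curve (k-means inertia on a grid with
  spacing `k_grid_step`, default 500) is min-max normalised on both axes
  and the grid point farthest from the chord joining its endpoints is the
  knee; ties break toward smaller k.  Normalisation is needed because k and
  inertia are on incommensurate scales.
* Clustering: k-means++ with 3 restarts up to 5,000 clusters; above that, a
  mini-batch variant with random init from data points (k-means++ seeding
  is quadratic in k and intractable at k = 10,000), batch size 4,096 and 5
  epochs.  Clusters left empty are re-seeded with the unused probes
  farthest from their assigned centres, so the representative count always
  equals k (or the run fails).
* Determinism: rows are sorted by probe ID before fitting, making the
  result invariant to the row order of the input matrix at a fixed seed.

## Greedy forward selection

`greedy_select` performs a sequential forward search over a candidate pool
(normally the reduction representatives).  Each round, every remaining
candidate is scored by the `n_folds`-fold (default 10) cross-validated
misclassification error of predicting the ternary classes of target probes
from the current selection plus that candidate; the `step_size` (default 5)
best candidates are appended.  Scoring candidates individually and taking
the top 5 keeps the CV objective well defined while matching the
increment-of-five schedule; `step_size=1` gives the exact one-at-a-time
variant.  Ties on equal error break toward the lexicographically smaller
probe ID.  Targets are all non-selected probes; single-class (degenerate)
targets are excluded with a warning, and `target_subsample` (default 200,
re-drawn each round from the seeded RNG) bounds the per-round cost on large
target sets.

Predictors are the integer-encoded classes (−1/0/+1) of the selected
probes — the search, like the rest of the pipeline, is purely qualitative.

**Search scorers.**  Scoring thousands of candidate × fold × target
combinations per round makes per-target refits of full classifiers
intractable for every backend family, so the search uses fast multi-output
models that share one fit across all targets, mapping continuous outputs to
the nearest class:

* SVM-like: a closed-form L2-regularised linear readout (ridge).
* RF-like: a small multi-output random forest (10 trees).
* ANN-like: a fixed random tanh hidden layer with a ridge readout (an
  extreme-learning-machine style network).

The three families therefore still explore the search space differently
(linear margin, axis-aligned partitions, random nonlinear features), which
is what the ≥2-of-3 combination exploits.  The full estimators — SVC with
RBF kernel (C = 1), a 100-tree random forest, and a single-hidden-layer MLP
(64 units, early stopping, initial learning rate 0.01 so early stopping
cannot trigger before any learning on small ternary inputs) — are used for
consensus training and validation, not inside the search loop.

## Combination and consensus prediction

Selections from the three backends are combined by membership in at least
two of the three sets; `overlap_report` tabulates all pairwise and
higher-order intersections plus the exactly-one-set count, satisfying the
inclusion–exclusion identity |≥2-of-3| = |A∩B| + |A∩C| + |B∩C| − 2·|A∩B∩C|.

`train_consensus` fits one classifier per backend per target probe on the
surrogate classes (`mode="per_target"`); a shared multi-output mode
(`mode="multioutput"`, using the search-scorer families at full capacity)
is provided for desk-scale work.  Targets constant in training are stored
as constant predictors — there is nothing to learn.  Prediction is the
majority vote of the three backends per cell; a three-way disagreement is
called "unchanged".  The vote rule is symmetric in the backends, and with
three identical voters it reduces to the single voter.

The predicted whole-genome profile stacks the *measured* surrogate classes
over the predicted target classes before any enrichment comparison, since
surrogate probes are measured by the platform.  This also makes the
self-prediction limit exact: with every probe as a surrogate the predicted
profile equals the actual one and the PSI is 1.

## Enrichment and the Pathway Similarity Index

`enrich` is a standard hypergeometric over-representation test: for a query
of n genes from a background of M, a category with K members in the
background and Q query hits scores p = P(X ≥ Q), with Benjamini–Hochberg
FDR across all tested categories.  Categories are intersected with the
background first; the background defaults to the probes of the analysed
matrix, not the whole ontology.  A category is significant when q <
`fdr_threshold` (default 0.005) **and** Q ≥ `min_query_elements` (default
5).  The default query combines up- and down-regulated genes into a single
list; separate up-only/down-only modes exist.

The PSI between an actual and a predicted enrichment is

    delta = Σ_{i ∈ common} Q_i / Σ_{j ∈ actual significant} Q_j
    PSI   = mean(N_c / N, delta)

where N counts significant pathways in the actual enrichment and N_c those
significant in both.  Q could be counted from either enrichment; counting
both numerator and denominator from the **actual** enrichment is the
default because it bounds delta (and hence PSI) by 1, matching the index's
stated range — the predicted-count convention is available via
`q_source="predicted"`.  PSI is deliberately asymmetric (the actual
enrichment is the reference), is 1 when predicted equals actual, 0 when no
significant pathway is recovered, and is undefined (an error) when the
actual enrichment has no significant pathway; per-sample PSIs aggregate by
arithmetic mean with such samples excluded under a warning.

`y_scramble` establishes the chance baseline: sample labels of the test
surrogate profiles are permuted, decoupling predictors from the target
truth, and the mean PSI is recomputed per permutation.  The identity
permutation reproduces the unscrambled value exactly.

DAG summaries of significant categories plus their ancestors are emitted as
DOT text with `neglog10_q` (colour intensity) and `query_elements` (node
size) attributes; rendering is left to external tools.

## Sample splitting

`split_samples` rounds the train size to the nearest integer (941 samples
at 75 % → 706/235).  When sample metadata with a `compound` column is
present, the default split is **grouped by compound**: whole compounds are
assigned to one side so that no compound appears in train and holdout at
different doses, with the cut chosen to approach the requested fraction;
`stratify=False` restores a plain random split.  Grouped splitting is the
stricter generalisation test — the holdout chemicals are entirely unseen.

## The synthetic compendium

`simulate_compendium` generates the latent-pathway structure the method
presupposes: disjoint pathways of `probes_per_pathway` probes; each
chemical activates `n_active_pathways` (default 4) randomly chosen pathways
with balanced signs (half up, half down), scaled monotonically by dose
(multipliers 0.6/1.0/1.4) and time (0.8/1.0/1.2); a member probe's value is
its loading (uniform 0.8–1.2 × `loading_scale`) times the activation, plus
Gaussian noise.  Defaults: 600 probes, 20 pathways × 25 probes, 30
chemicals × 3 doses × 3 times (270 samples), `loading_scale` 0.5,
`noise_sigma` 0.05.  The chemical count is set so that, even under a
compound-grouped split, every pathway is expected to be activated several
times in training (≈ 4.5 expected activations per pathway from 22–23
training chemicals) — a panel cannot represent, nor a model learn, a
pathway the training chemicals never touch, and diverse chemical coverage
is the method's stated premise.  Balanced signs keep per-sample up/down
proportions comparable across chemicals, mirroring the rationale for the
±0.1 thresholds.

What the generator does **not** emulate: probe-level microarray noise
models, batch effects, overlapping pathway membership, correlated pathway
activation, or platform-specific dynamics.  Passing recovery tests
therefore demonstrates internal consistency of the pipeline under its own
assumptions, not performance on any real compendium.

## Problem sizes used in the checked experiments

* Variance-filter check: 54,675 probes × 2 samples with distinct variances
  → exactly 27,338 retained.
* Reduction check: 27,338 probes × 45 samples, k = 10,000 via mini-batch
  k-means → exactly 10,000 representatives (≈ 40 s).
* Recovery experiment: the generator defaults above, reduction to k = 60
  representatives, greedy budget 40 in steps of 5 with the full
  (non-subsampled) target objective, multioutput consensus, PSI on the
  compound-grouped 25 % holdout, 3 scramble permutations; 8 replicate
  seeds, each required to reach mean PSI ≥ 0.9 with a strictly lower
  scrambled mean.  Observed means range 0.91–1.00 against nulls ≈ 0.3.

## Known limitations

* The greedy search is a local heuristic; it has no escape mechanism from
  local optima, and the selected panel is not guaranteed globally optimal.
* Enrichment significance under the strict default thresholds requires
  categories with enough members in the background; very small simulated
  ontologies can yield no significant pathways, in which case PSI is
  reported as NA rather than extrapolated.
* Multi-output tree models cannot extrapolate to predictor class
  combinations absent from training; consensus voting mitigates but does
  not remove this.
* PSI compares sets of significant pathways; it is insensitive to effect
  directions within pathways and to sub-threshold concordance.
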