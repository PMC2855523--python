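# Methods

## Data model

A TLDA experiment measures each sample on two 384-well cards (panels A
and B) preloaded with 377 and 289 miRNA assays plus controls.  The
in-memory `CtMatrix` keeps one row per (assay, well, panel) so the four
MammU6 endogenous-control replicate wells per card stay distinct until
normalization; "Undetermined" wells (no threshold crossing within the
run) are carried as an explicit boolean mask.  An optional censoring
policy can instead substitute a ceiling CT (default 40 cycles) — both
conventions are common practice; masking is the default because an
imputed 40 is a statement about abundance the instrument did not make.

Assay identity is the full name-with-assay-ID string
(`hsa-miR-204-4373094`); the human-readable name is derived by stripping
the numeric suffix.  This keeps mature and star (miR*) strands distinct
even when their display names collide.

## Relative quantification

ΔCt subtracts the per-sample, per-panel arithmetic mean of the unmasked
control replicate wells.  Whether control replicates should be averaged
per card or pooled across cards is genuinely open; per-card averaging is
used because the control is a card-level loading reference, and the
alternative only matters if the two cards of one sample were loaded
differently — exactly the effect per-card averaging removes.

ΔΔCt references a calibrator sample (the generator marks a PN1-style
nevus sample; a per-batch calibration mode is available for designs with
one calibrator RNA per processing batch, but the global-calibrator mode
is the default since the relative-quantification formula is defined
against a single reference).  Fold change is `2^−ΔΔCt`.  Amplification
efficiency is assumed to be exactly 2 per cycle; no Pfaffl-type
correction is attempted.

Group fold change is the ratio of group geometric-mean RQ, equivalently
`2^−(difference of group-mean ΔCt)`.  This is the only aggregation
consistent with both a log2-FC column and per-class geometric-mean
intensity reporting, and it cancels the calibrator entirely.  "Intensity"
is defined as `2^−ΔCt`, so class geometric means of intensities
reproduce group fold changes as plain ratios.  Fold-change bins label the
magnitude `max(FC, 1/FC)`: (1.2, 1.6], (1.6, 2.0], (2.0, 4.0], > 4.

Masked values are excluded from all means rather than imputed; an assay
whose contrast group has no unmasked value is flagged not-evaluable and
excluded from downstream counting, with the universe size reported.

## Class comparison

Two analysis routes share the ΔCt input:

* **Mode I (relative quantification).** Pooled-variance two-sample
  t-tests on the log2 scale (`−ΔCt`, equal to log2 RQ up to a per-assay
  constant, so the calibrator does not affect the statistic), group fold
  changes, BH-adjusted p-values.  The log2 scale is used because t-tests
  assume additivity; raw FC ratios are strongly right-skewed.
* **Mode II (normalized CT).** Random-variance moderated t-tests, BH
  adjustment, optional per-assay permutation p-values, per-class
  geometric-mean intensities.

**Random variance model.**  Per-assay precisions `1/σ²` are modelled as
Gamma(a, scale b); marginally `a·b·s² ~ F(n, 2a)` for an assay with
pooled variance `s²` on `n` degrees of freedom.  (a, b) are fitted by
maximum likelihood over all assays with positive variance (closed-form
log-likelihood, L-BFGS-B in log-parameter space with an analytic
gradient; a solution pinned at the large-`a` bound is the total-shrinkage
limit reached when variances are essentially equal, and is accepted).
The moderated statistic replaces `s²` by `(n·s² + 2/b)/(n + 2a)` and
refers to a t distribution with `n + 2a` degrees of freedom.  Assays
with zero pooled variance get t = 0, p = 1 and a flag rather than being
dropped, so the multiple-testing universe stays the full assay set.

**Permutation machinery.**  Univariate permutation p-values use the
add-one convention `(1 + k)/(1 + B)`; when the number of distinct label
assignments `C(n, n1)` does not exceed B the test switches to exhaustive
enumeration and reports the exact `k/K` (for 3-vs-3 groups the smallest
attainable two-sided p is 2/20 = 0.1).  The global test counts assays
significant at a stringent level (default 0.001) and reports the plain
proportion of permutations matching or beating the observed count.

**Multivariate selection with confidence-bounded FDP.**  Candidate
cutoffs are the ranked observed p-values.  For each cutoff, label
permutations estimate the distribution of the number of null assays that
would pass; the procedure selects the largest k whose
`confidence`-quantile of that count, divided by k, stays at or below the
false-discovery bound (defaults: 90% confidence, 10% bound).  Setting
confidence to 0 degenerates to the expected-false-count rule.  The prior
hyperparameters of the moderated t are fitted once on the observed
labels and reused across permutations — refitting per permutation
changes selections negligibly at these sample sizes and would dominate
the runtime.

**Four-class F-test.**  One-way ANOVA per assay (e.g. node-positive /
node-negative within each age group).  Classes with a single member
contribute to the between-class term only; degrees of freedom account
for them in the standard way.

## Unsupervised views

Samples are centered by their means and scaled by their centered norms,
then embedded by SVD; with Euclidean distances classical MDS and PCA
coincide, and pairwise distances in the full component space equal the
input distances to machine precision.  The first three components are
reported with their explained-variance fractions.

Hierarchical clustering defaults to the Eisen heat-map convention:
centered Pearson correlation distance with average linkage (Euclidean
available).  A constant profile has no defined correlation; it is
flagged and assigned the maximal distance 2.  The heat-map artifact is
data (matrix, trees, leaf orders, Newick text) — rendering is left to
plotting front-ends.

## Class prediction

Two-class prediction with nested leave-one-out cross-validation: for
every left-out sample, marker selection (moderated t at 0.001 by
default) and classifier fitting are repeated on the remaining samples
only.  Classifier definitions are classical; implementation choices the
definitions leave open: kNN distance is Euclidean on the selected
markers with 3-NN ties broken by the nearest neighbour's label; the SVM
is a linear kernel at unit cost with pinned solver settings; the
Bayesian compound covariate places Gaussian class-conditional densities
with per-class variances on the compound-covariate score and equal class
priors.

An empty in-fold selection falls back to predicting the training
majority class, with the fold counted and flagged.  On a balanced design
this fallback deterministically predicts the *opposite* class of the
left-out sample (training is n−1 vs n), so a run whose folds select
nothing shows error 1.0 and zero sensitivity/specificity everywhere —
worth knowing before reading a performance table of zeros as a broken
classifier.

Significance of the cross-validated error is the add-one proportion of
label permutations whose fully re-run nested LOOCV does at least as
well; permutations that concentrate a class below two members are
counted as non-improving rather than crashing the run.

## Synthetic data generator

The generator is the test bed standing in for instrument exports:
`CT = baseline(assay) + shift(sample) + shift(batch) − effect(assay,
group) + noise`, with control wells sharing the sample and batch shifts
(so ΔCt removes them exactly) and right-censoring above a CT ceiling
applied after noise (so masking correlates with low abundance, as on
real cards).  Defaults mirror the study design: 666 assays split
377/289, four control replicates per card at mean CT 20 (sd 0.15
cycles), 26 samples in groups of 10/10/3/3 run in three batches,
baselines uniform on 22–34 cycles, technical noise 0.5 cycles, sample
offsets 1.0 cycle, batch offsets 0.3 cycles, censoring at 38 cycles.  A
negative-control well per card is emitted near CT 39 and is mostly
censored.  Effects are planted on the −ΔCT scale (one cycle = two-fold);
the study-like preset plants 30 effects whose log2 sizes span all four
fold-change bins.  Everything is reproducible byte-for-byte from the
config seed.

What the generator does **not** emulate: amplification-efficiency
variation between assays, FFPE degradation profiles, correlated miRNA
co-regulation, panel-specific background, or outlier wells.  Passing
tests therefore demonstrate correctness of the algebra and calibration
of the statistics under the assumed additive-Gaussian CT model, not
robustness to every failure mode of archival tissue qPCR.

## Numerical choices and tolerances

* Fold-change estimates at the default design have log2-scale standard
  error ≈ 0.25 (cell noise 0.5, two groups of 10, control-replicate and
  batch terms), so a true 4-fold effect is estimated within [3.0, 5.3]
  in roughly 90% of datasets — recovery tests assert unbiasedness plus
  that coverage, not more.
* Permutation counts use a 1e-12 tie tolerance on |t| comparisons and a
  1e-15 nudge when counting permuted p-values at a cutoff.
* Report-table floats are written with four decimals.
* The exact-agreement oracle tests (t vs an independent implementation,
  BH vs brute-force step-up, ANOVA, classical-MDS double-centering,
  naive agglomerative average linkage) are held to 1e-8 or tighter.

## Problem sizes used in the shipped checks

Calibration and control checks run at the sizes a laptop handles in
minutes: 20,000 null assays for type-I error, 5,000 variances for prior
recovery, 200 replicates of the 26-sample null design and 50 replicates
of the planted 10-vs-10 design (100 permutations each) for the
false-discovery properties, and 200 permutations for the cross-validated
error significance.

## Known limitations

* Two-class prediction only; the multi-class F-test is for comparison,
  not classification.
* No GEO downloader: instrument exports are read from local delimited
  files (long or wide), and the reader's dialect knobs (column
  overrides, undetermined token, assay-to-panel map) exist precisely
  because deposited supplementary formats vary.
* The cluster-significance test against a single multivariate-Gaussian
  null is out of scope.
* The two normalization routes (calibrated RQ vs plain ΔCt) answer
  slightly different questions and are not forced to agree assay-by-assay;
  both are exposed.
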