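# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic validation does and does not
establish about real data.

## Lane quality control

Metrics follow the digital analyzer's default flagging.  Choices that the
platform documentation leaves open were fixed as follows:

* **Imaging** is operationalized as `fov_counted / fov_attempted >= 0.75`
  (the common default; configurable via `QCThresholds.fov_pass_ratio`).
* **Positive-control linearity** is the R² of an ordinary least-squares fit
  of log₂(count) on log₂(concentration in fM) over all six spike-in
  levels.  Counts of zero are floored at 0.5 before the log; a positive set
  with no variance is reported as R² = 0 rather than undefined.
* **Limit of detection** compares the 0.5 fM positive against
  `mean(negatives) + 2·SD(negatives)` with the *sample* SD (n−1):
  negative-control sets are small, and the unbiased estimator is the
  conservative choice.  LOD failure excludes a sample by default
  (`QCThresholds.lod_excludes`); sites that prefer flag-only behaviour can
  switch it off.
* **Correction factors** are `mean over samples of probe-set geometric
  means / sample geometric mean`, for the positive controls (window
  [0.1, 2.0]) and the declared housekeeping probes (window [0.1, 8.0]).
  The QC-stage content factor deliberately uses *all* housekeeping
  candidates: QC precedes reference selection, which later refines which
  genes actually normalize the data.
* **Exclusion rule**: a lane is dropped when a correction factor leaves its
  window, the reference geomean falls under 30 counts, or imaging/LOD fail.
  An out-of-window binding density alone is flagged but tolerated when
  linearity and both factors pass — the saturation metric is forgiven if
  everything quantitative about the lane still behaves.
  A failed linearity flag without a binding-density violation likewise
  flags but does not exclude on its own.

Because the factor denominators are cohort means, one pathological lane
shifts every other lane's factor slightly; the windows are wide enough that
this matters only for grossly aberrant lanes, and the QC report records
all factors so the interaction is auditable.

## Background threshold and probe filter

Each sample's background is `mean + 2·SD` (sample SD) of its negative
controls; the study-level detection threshold doubles the highest
per-sample background.  A probe is excluded when its raw count falls below
that threshold in at least 50% of samples — implemented as
`>= ceil(n/2)`, so exactly half counts as failing on even n.  Filtering
runs on raw counts after sample QC and before normalization.  Housekeeping
probes that fail are flagged but kept: silently removing normalization
candidates would change the content factor without a trace.  Whether the
original workflow used sample or population SD is not documented anywhere
we could find; sample SD is used consistently with the LOD rule.

## Reference-gene selection and normalization

geNorm stability is `M_j = mean_{k≠j} SD_samples(log2 x_j − log2 x_k)`
(SD with n−1).  The least stable gene is eliminated and M recomputed until
two remain; the final pair shares the two-gene-stage M.  Ties in M break
lexicographically by gene label so the elimination order is deterministic.
The top k = 3 genes are used for normalization (configurable).  The
pairwise-variation criterion V(n/n+1) for choosing the *number* of
references is computed and reported but not used for selection, since the
workflow fixes three.  Zero counts among candidates get a 0.5 pseudocount,
applied to the whole candidate block and flagged in the result.

Normalization is two multiplicative steps: the positive-control technical
factor first, then the reference-gene content factor computed on the
technically corrected counts (the conventional order; either step can be
disabled).  After content normalization the reference-gene geometric mean
is identical across samples — an exact invariant the tests assert.  A
subtlety worth knowing: because the factor numerator is the cohort mean of
geomeans, re-running normalization after rescaling one sample's raw column
rescales *all* normalized columns by one common constant; within a single
run, two samples identical up to a scale factor normalize to exactly equal
columns, and all downstream statistics (fold changes, distances on log
ratios, standardized features) are invariant to the common constant.

## Differential expression

Effect size is `log2(median_A / median_B)` on normalized counts; a 0.5
pseudocount enters both medians only when one of them is zero, so
well-expressed genes report the plain ratio.  Significance is a two-sided
Wilcoxon rank-sum test per gene: exact enumeration when both groups have
≤ 12 samples and the gene is untied, otherwise the tie-corrected normal
approximation with continuity correction.  A gene constant across both
groups is assigned p = 1.  P-values are adjusted per comparison with
Benjamini–Yekutieli, which controls FDR under arbitrary dependence —
appropriate for panel content curated to be co-regulated.  Rank-test
p-values are discrete and, with the continuity correction, slightly
conservative; the null-calibration tests therefore check type-I validity at
several levels rather than exact uniformity.  Top-K tables sort by adjusted
p with ties broken by |log₂FC| descending, then symbol.  The cross-panel
retest correlation is the Pearson r of log₂ fold changes over the union of
the two panels' top-20 lists restricted to shared symbols (the union, not
one side's list, so neither panel is privileged).

## Clustering diagnostics

Samples are clustered on log₂(normalized + 1) endogenous values (the
transform is configurable) with the Canberra metric and Ward linkage in the
ward.D2 (squared-dissimilarity) dialect.  Canberra is not Euclidean, so
Ward heights are a heuristic on it — common practice, accepted and
documented rather than hidden.  Hopkins uses `m = max(10, ceil(0.1·n))`
sampled real points and as many uniform points in the per-dimension
bounding box, with the convention that clustered data push H toward 1;
fully degenerate data (all points identical) return H = 1.  The cophenetic
correlation is the Pearson r between original condensed distances and
first-merge heights.  The C-index is computed for each cut k = 2…10 and
minimized; ties go to the smallest k.  Note that for *very* compact,
well-separated groups the C-index is exactly 0 at several cuts (any merge
of entire clusters keeps within-pairs the smallest distances), so the
planted-recovery tests use separation ratios (~10:1 edge:spread) where the
index is strictly minimized at the true k — the regime the statistic is
designed for.

## Classifier

Features are log₂(normalized + 1) endogenous values keyed by gene symbol.
Preprocessing removes near-zero-variance genes (most-common /
second-most-common frequency ratio > 19 *and* distinct-value fraction
< 10%) and then one member of every gene pair with |Pearson r| > 0.9
(the member with the larger mean absolute correlation; ties drop the
lexicographically later symbol).  Genes are standardized to mean 0, SD 1;
the parameters are frozen into the model, and coefficients are reported in
both standardized and raw log-expression units.

The model minimizes `(1/n)·logistic deviance + λ·Σ|β|`.  λ is selected on
a descending geometric grid (25 points from the smallest all-zero λ down
two decades, the usual n < p ratio) by stratified 10-fold cross-validation
with minimum mean deviance — not the 1-SE rule, which the workflow never
claims; ties resolve to the sparser λ.  A `lambda_override` replays a fixed
penalty.  Fits use scikit-learn's saga solver (L1 path with warm starts;
looser tolerance inside CV folds than for the final refit).  When the
penalty shrinks every coefficient to zero the intercept is set to the
analytic prevalence log-odds, where the iterative solver's step size
degenerates.

Evaluation pools out-of-fold probabilities from stratified 10-fold CV, with
standardization and fitting redone inside each training fold — a leakage
test asserts each fold's predictions are reproducible from its training
rows alone.  ROC/AUC come from a threshold sweep on pooled probabilities;
sensitivity/specificity are reported at threshold 0.5 and at the Youden
point.  Cross-panel transfer maps coefficient genes by symbol (probe ids
differ across panels), applies the *frozen* training standardization to the
target panel — re-standardizing on the test panel would leak its label-free
statistics into the decision rule — and errors loudly if any coefficient
gene is missing from the target.

## Synthetic cohorts

The generator emulates the study design: three diagnosis groups (default
32/32/32), a large panel (758 endogenous + 12 housekeeping genes) and a
small AMR-focused subpanel (90 + 6) sharing gene symbols with independent
counts.  Endogenous counts are negative binomial with
`var = µ + 0.08·µ²` and mean
`technical_i · size_i · 2^(baseline_g + shift_{g,group})`: the per-sample
technical factor (log₂ SD 0.1) multiplies every probe including positives,
while the biological RNA-input factor (log₂ SD 0.25) spares the spike-ins,
so positive-control and reference-gene normalization correct distinct
nuisances as on the instrument.  Per-gene baselines are log₂-uniform on
[4, 10] and are a deterministic function of the gene *symbol*, so a
transcript has the same abundance on every panel that assays it — without
this, frozen-standardization transfer across panels would be meaningless.
Genes carrying a planted effect draw baselines from [6, 10]: curated
disease-signature content is chosen to be reliably detectable.
Housekeeping genes get lognormal biological noise at tiered CVs (defaults
0.05–0.3) and no group effect; positives are Poisson around
200 counts/fM (placing the 0.5 fM control near 100 counts, well clear of
background, as on real lanes); negatives are Poisson with mean 5.  QC
failures are injected deterministically per lane and recorded in the
ground truth.  Everything is a pure function of the seed, byte for byte.

What the generator does **not** model: FFPE RNA degradation chemistry,
center or cartridge batch effects beyond scalar size factors, probe
cross-hybridization, and correlated gene-gene biological variation beyond
the planted group shifts.  Passing recovery tests therefore demonstrate
that the pipeline's statistics are implemented correctly and behave as
designed under a faithful noise model — not that real cohorts will yield
comparable effect sizes, DEG counts or AUCs, which are cohort-dependent.

## Problem sizes and numerics

The test suite and the acceptance script run the full design at its study
scale (96 samples, 758-gene panel) for single end-to-end runs, and smaller
presets (30 samples, 60 genes; 90 samples, 500 genes for classifier
recovery) where a loop over many seeds is needed; those sizes keep the
whole suite in the minutes range on one core while leaving every statistic
in its intended regime.  Float comparisons against oracles use 1e-9
absolute tolerance; geNorm and the brute-force reference implementation
agree to that tolerance on all random instances tried.  All randomness
flows from explicit integer seeds; per-stage seeds are derived by hashing
the stage name so any stage reruns in isolation with the stream it would
see in a full pipeline run.

## Known limitations

* RCC parsing targets the sectioned-CSV dialect; RLF binaries and
  PlexSet layouts are out of scope.
* Ward-on-Canberra is a pragmatic pairing, not a theoretically grounded
  minimum-variance method.
* The Wilcoxon/BY combination treats genes as exchangeable test units; no
  gene-level variance moderation (as in limma/DESeq-style models) is
  attempted, matching the workflow being reimplemented.
* The classifier is binary (AMR vs not); the three-way diagnosis problem
  is not modeled.
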