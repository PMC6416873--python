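# Methods

## Scope and data model

`diffgc` analyzes two data modalities: gene × sample expression matrices
(raw counts or normalized values, carried in `ExpressionMatrix` with an
explicit scale tag) and binary gene × sample mutation indicators plus
per-sample total mutation counts over a targeted region
(`MutationMatrix`). Samples carry a cohort label, a histology label, and
optionally a molecular subtype (EBV, MSI, GS, CIN) and an expression
cluster (I/II).

## Normalization

The single-dataset RNA-seq chain is CPM → quantile normalization →
log2(x + pseudocount) → median-centering, in that literal order. Choices
the chain leaves open, and how they are resolved here:

* **Stage order.** Quantile-before-log2 is the default; a `log2_first`
  flag swaps the two stages for sensitivity analysis (log2 is monotone,
  so the quantile ranks are unchanged — only the reference distribution
  differs).
* **Quantile ties.** Tied values receive the mean of the reference values
  at their tied ranks (average ranks interpolated on the reference), the
  common convention. Consequence: on data with ties the "identical sorted
  columns" property and exact idempotence hold only approximately; on
  tie-free (continuous) data both hold to machine precision, and the
  invariant tests use continuous input for that reason.
* **Pseudocount.** Default 1 on the CPM scale.
* **Median-centering** alternates gene-median and sample-median
  subtraction until all row and column medians are within 1e-6 of zero,
  capped at 10 iterations (median polish need not converge exactly; the
  cap is logged when hit).
* **Standardization** uses the sample standard deviation (ddof = 1).
  Constant gene rows map to zero and are logged, never NaN.

Cross-cohort integration: each dataset is z-standardized per gene
independently, datasets are pooled over the (sorted) intersection of
their gene universes with cohort-prefixed sample IDs, and the pooled
matrix is quantile-normalized. The scikit-learn transformers
(`QuantileNormalizer`, `GeneStandardizer`) freeze their reference
distribution / per-gene moments at fit time so external samples are
normalized against the training cohort, not against themselves.

## Differential expression

Gene-wise two-sample Student t-tests with pooled variance
(df = n1 + n2 − 2) on the analysis scale; Welch's correction is available
behind a flag but is not the default, matching the classical
microarray-era convention of this method family. Zero-variance genes get
t = 0, p = 1 rather than NaN. Fold difference is computed on the linear
scale as max(m1, m2)/min(m1, m2) of group means (orientation-free;
log2-scale input is exponentiated first; a tiny pseudo-term guards zero
means). Selection applies raw thresholds — no multiple-testing
correction, since the procedure this reimplements used raw P < 0.05 and
P < 0.001 cutoffs — but a Benjamini–Hochberg column is emitted for
information. Selected genes are ordered by ascending p, ties by
descending |t|, then gene ID, making selection deterministic.

## Clustering

Sample–sample distance is the centered correlation distance
d = 1 − Pearson r over a fixed gene list (range [0, 2]; constant
profiles, whose correlation is undefined, get the maximal distance 2 and
a log warning). Centroid linkage follows the Cluster-3.0 convention: a
cluster is represented by its mean expression profile and inter-cluster
distance is recomputed as 1 − r between centroids after each merge. The
Lance–Williams centroid update is *not* used because it presumes squared
Euclidean distance. Ties on merge distance break to the lexicographically
smallest cluster-index pair, so the dendrogram is deterministic. Centroid
linkage can produce inversions (a merge lower than its predecessor);
these are counted and logged, not hidden. Flat clusters are obtained by
undoing the last k − 1 merges; labels are ordered by descending cluster
size, then smallest member index. k defaults to 2 — the cluster I/II
split was chosen by inspection in the original analysis, and no gap
statistic is implied.

## Subtype prediction (Bayesian compound covariate)

**Panels.** For each subtype s, every gene is t-tested (pooled variance,
p < alpha, default 0.001) against each of the other three subtypes
separately; a gene qualifies only if all three comparisons are
significant *and* the sign of t is consistent across them
(sign-consistency is configurable; requiring it is the stricter and
adopted reading of "significant in all three comparisons"). Candidates
are ranked by the maximum of the three pairwise p-values ascending (most
uniformly significant first), ties by descending mean |t| then gene ID,
and truncated to `top_n` (default 200). The ranking criterion itself was
an open choice; max-p was adopted because it directly orders by the
weakest of the three required comparisons.

**Scores and posteriors.** The one-vs-rest compound covariate score is
c_j = Σ_i t_i x_ij with training t-statistics as weights. Both
class-conditional densities are Normal with class-specific means and a
pooled within-class standard deviation; the posterior is computed in log
space for numerical stability and equals the textbook two-Gaussian Bayes
rule to < 1e-12 (oracle-checked). Priors default to (0.5, 0.5);
degenerate priors (0 or 1) short-circuit to the prior itself.

**Decision tree.** One-vs-rest nodes are evaluated in a configurable
order, default EBV → MSI → GS; the first node whose posterior reaches the
threshold (default 0.5) assigns the label and the remaining subtype (CIN)
catches all fall-throughs, so every sample receives exactly one label. An
empty panel (possible on null data at alpha = 0.001) disables its node —
the posterior is reported as 0 and the tree descends.

**Validation.** `loocv` repeats panel selection and model fitting inside
every fold. This is the critical design point: selecting genes on the
full data first and cross-validating only the model fit would leak the
held-out sample into its own feature panel and inflate accuracy far above
chance on pure-noise data. The no-leakage regression test verifies that
LOOCV accuracy on effect-free fixtures stays within binomial 99% bounds
of the 25% chance rate. Test samples are z-standardized against frozen
training statistics before scoring, since in practice the model is
applied to samples normalized in other batches.

## Mutation statistics

The 2×2 test is the closed-form Pearson chi-square
χ² = N(ad − bc)²/[(a+b)(c+d)(a+c)(b+d)], df = 1, **without** continuity
correction by default: the uncorrected statistic reproduces the cohort's
printed P-values (0.029, 0.028, 0.030) to three decimals, which pins the
convention; Yates' correction is available as an option. Zero marginals
are an error (the test is undefined), not a silent NaN.

Burden is total mutations divided by the targeted region size in Mb; the
region size is a required configuration value since panel footprints
differ. Group comparison offers a tie-corrected two-sided Mann–Whitney
test (default) and an r×2 chi-square over binned mutation counts with
configurable breakpoints (default bins 0–100, 101–500, > 500 — the
binning of the source figure is not stated anywhere, so both flavors are
reported side by side).

MSI-H is called when strictly more than 30% of assayed microsatellite
markers show allelic shifts; the boundary case (exactly 30%) is
non-MSI-H by the strict inequality, and the comparison is done in integer
arithmetic to avoid float boundary artifacts.

## Responder estimation

Checkpoint-inhibitor responders: Σ_s f_s ρ_s with subtype fractions f
(supplied directly or counted from labels) and response rates ρ
defaulting to MSI = EBV = 1.0, CIN = 0.05, GS = 0.12 (reported PD-1
blockade response rates by subtype); the rates are configuration, not
constants. mTOR-inhibitor responders: driver (PIK3CA) mutation frequency
× 0.35, the reported response rate of PIK3CA-mutant tumors to pathway
inhibitors. Percentages round half-away-from-zero (0.0907 → 9%,
0.0385 → 4%); unrounded fractions and the full provenance of every
product are carried in the output. When all driver-mutant tumors fall in
subtypes with response rate 1.0, the mTOR estimate is necessarily
contained in the checkpoint estimate, and the report notes it.

## Synthetic cohorts

The generator emulates the *structure* the analysis assumes, not any real
cohort's distribution:

* per-gene baseline log2-expression ~ Normal(5, 2);
* four disjoint signature blocks (default 200 genes each out of 2,000),
  up-shifted by `signature_log2_effect` (default 2.0) in their subtype
  only — up-shifts only, the simplest structure sufficient for recovery
  testing;
* per-cohort per-gene batch shifts ~ Normal(0, 0.5) on the log2 scale,
  mimicking the cross-platform offsets that per-dataset standardization
  removes;
* counts negative-binomial with dispersion 0.1 (a typical bulk RNA-seq
  value) around library-size-scaled expected fractions, library sizes
  uniform in [0.8M, 1.2M];
* total mutation counts Poisson with per-Mb means 40 (MSI), 10 (EBV),
  5 (GS), 5 (CIN) over a 1 Mb panel — preserving the hypermutated-MSI
  ordering at desk scale rather than any cohort's absolute counts;
* driver mutations Bernoulli with group-dependent frequencies (group keys
  may be subtypes or cluster labels); defaults encode the qualitative
  enrichments: PIK3CA/ARID1A in MSI/EBV, CDH1 in GS, TP53 in CIN;
* ground-truth cluster labels follow the subtype: GS/EBV → cluster I,
  MSI/CIN → cluster II.

Sample sizes default to 30 per subtype per cohort (the recovery analyses)
and 20 per subtype for the no-leakage checks. Randomness flows from one
seed through spawned substreams — one per cohort plus dedicated gene and
mutation streams — so appending a cohort leaves existing cohorts
byte-identical.

What passing tests on this generator do **not** show: robustness to
gene–gene correlation, down-regulated signatures, mixed or mislabeled
histologies, nonlinear batch effects, or the sample-size imbalance of
real cohorts. The generator is a fixture with planted truth, not a claim
about TCGA.

## Numerical and testing choices

* Stochastic test thresholds (panel recovery ≥ 0.90, LOOCV strong-signal
  accuracy ≥ 0.90, clustering ARI ≥ 0.9) were fixed by Monte-Carlo over
  at least 20 generator seeds before being frozen; observed minima were
  0.99, 1.0 and 1.0 respectively, leaving wide margins.
* Calibration checks (null type-I error, no-leakage LOOCV) use binomial
  99% bounds around the nominal rate rather than point equality.
* The centroid-linkage implementation is verified against an independent
  from-scratch agglomerator (scipy-pearsonr distances, full recomputation
  each step) on small fixtures; the posterior against a direct
  Normal-density computation; the chi-square against
  `scipy.stats.chi2_contingency` exhaustively for table totals ≤ 25 and
  on random larger tables.
* Problem sizes in tests and the acceptance script (2,000 genes, 20–30
  samples per subtype, 1,000 simulation replicates) are the package's
  chosen study conditions for desk-scale verification; cohort-scale
  quantities that require the original external data (exact gene lists
  and counts, cluster memberships, PDX posteriors) are out of scope by
  design.

## Known limitations

* Centroid linkage with correlation distance has no monotonicity
  guarantee; dendrogram heights may invert (reported, not repaired).
* The quantile tie convention perturbs exact idempotence on heavily tied
  integer data (see above).
* The decision-tree node order changes borderline calls; it is a
  first-class parameter because the original topology is only shown
  graphically.
* `BCCPClassifier` assumes a shared within-class variance of the
  compound score; strongly heteroscedastic classes would violate it.
* The responder arithmetic is expectation algebra over cited rates; it
  carries no survival modelling and no clinical-validity claim.
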