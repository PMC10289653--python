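# Methods

This note documents the models, parameter choices and numerical
decisions behind each module, what the synthetic data does and does not
emulate, and the known limitations.

## Expression aggregation (`aggregate`)

Counts are normalised per cell by the size factor
s_j = total_j / geomean(totals); the geometric-mean anchor makes the
factors scale-free and keeps the normalised totals' geometric mean equal
to the raw one. This is the documented default of the single-cell
pipelines this procedure descends from; any other library-size
normalisation differs only by a global constant, which the subsequent
rescaling removes. Per cell type the per-gene means are divided by
their sum and multiplied by 10⁶ (scaled TPM), so profiles are
compositions: a gene's scaled TPM changes when *other* genes change.

Bootstrap intervals are **percentile** intervals from resampling each
type's own N cells with replacement (default 1000 replicates). BCa
would correct the small median bias of the ratio statistic but needs
jackknife acceleration per gene × type; at atlas scale the percentile
form is the standard choice and its empirical coverage here is ≈ 0.95
at N = 100 cells (measured in the test suite, 200 replicate
simulations). "Robustly expressed" = 95% lower bound strictly > 0,
which for percentile intervals is equivalent to the gene being detected
in enough cells that no resample is all-zero at the 2.5% quantile.
"Percent expressed" uses raw counts (> 0), i.e. detection, not
normalised abundance.

## Transcriptome coverage (`coverage`)

Down-sampling draws s cells without replacement (a subsample of real
cells, not a read-level thinning), recomputes the type's scaled TPM and
counts genes with positive values; the curve is the mean over
iterations (default 100) at each size. The size grid is 10
geometrically spaced points from 5 to N — the paper-style analyses do
not state a grid, and geometric spacing samples the curve's knee where
the fit is most informative. Sampling is seeded per (type, size) via a
stable CRC so curves are reproducible cell-type by cell-type.

The saturation model is the three-parameter log-logistic
f(x) = d / (1 + exp(b (ln x − ln e))) with b < 0, fitted by bounded
least squares from a 3 × 3 grid of starts (asymptote at 1/1.2/2× the
largest observed mean; e at three quantiles of the grid; b = −1).
This parameterisation makes d the predicted maximum gene count (G_MAX)
and e the cell count at exactly d/2. Coverage = f(N_observed)/d,
clamped to [0, 1]. Noise-free model data is recovered to ≤ 1e-6
relative error; on the default synthetic atlas the fitted G_MAX sits
within 10% of the saturated (all-cells) detected-gene count. Note that
d extrapolates beyond the observed curve, so G_MAX can exceed the
number of annotated genes — it estimates detectable transcripts under
the observed sampling process, not genome content.

## Housekeeping scoring (`housekeeping`)

Skewness is the population moment estimator g₁ = m₃/m₂^{3/2} (no
small-sample correction): the source analyses name a skewness function
without its formula, only the sign and ordering are consumed
downstream, and g₁ is the common default. Genes with a constant
percent-expressed vector, or zero expression everywhere, get missing
scores rather than zeros — both statistics are undefined there.

The Gini coefficient is computed with the sorted-rank identity,
algebraically equal to Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄) (the form used by the R
`ineq::Gini` default, tested to 1e-12 against the double sum). Bracket
edges are inclusive on the right (≤ 0.2 perfect, ≤ 0.3 good, ≤ 0.4
adequate, ≤ 0.5 big gap, > 0.5 severe gap) while ring *candidacy* uses
strict Gc < threshold; the two conventions coexist deliberately —
0.30 is classified "good" but is not a candidate.

Essentiality enrichment is a one-sided (greater) Fisher exact test on
the 2×2 in-set × essential table; the odds ratio reported is the
sample odds ratio ad/bc. Enrichment, not depletion, is the scientific
question, hence one-sided.

## TF activity (`tfactivity`)

Clustering: peaks sorted by apex per chromosome; a gap ≥ 200 bases
starts a new cluster (an exactly-200 gap splits). Distances are
apex-to-apex because only apexes are retained. Filters: > 70 distinct
TFs = HOT site (promiscuous, non-tissue-specific binding), exactly 70
kept; < 2 TFs = likely spurious, removed. Assignment uses the
unstranded distance |mean apex − TSS|; the nearest gene wins iff
d₁ ≤ 2000 and d₂ ≥ 1.5·d₁. Two edge rules: d₁ = 0 assigns outright
(the ratio is undefined at an exact TSS hit) and d₁ = d₂ leaves the
cluster unassigned (ambiguous target).

Signals are rank-normalised to cumulative probabilities rank/N within
each (TF, stage) experiment, average rank for ties, so experiments of
different depth and dynamic range become comparable; the gene × TF
predictor entry is the maximum over all qualifying peaks.

Per cell type, y = log1p(scaled TPM) is regressed on the predictor
matrix with lasso (scikit-learn `LassoCV`), penalty at the minimum of
20-fold cross-validated MSE, fixed fold seed. The log1p response
stabilises the heavy right tail of the TPM scale; `response="raw"` is
exposed for the untransformed variant, and `l1_ratio < 1` switches to
an elastic net. Predictors are left on their natural (0, 1] cumulative
probability scale — all columns share units, so standardisation would
only rescale coefficients. Negative coefficients are clipped to zero
for the activity reading (repression is out of scope) but the raw
coefficients are retained. An association additionally requires the TF
gene to be robustly expressed in that cell type; genes with no
assigned cluster carry no predictor information and are excluded from
the rows.

Dendrograms use Ward variance-minimising linkage on Euclidean
distances over cell-type columns (the "Ward.D2" convention; scipy's
`linkage(..., method="ward")`). Baker's gamma is computed from first
principles: for each leaf pair and each tree, the highest number of
clusters at which the pair still co-clusters; gamma = Spearman
correlation of the two pair-depth vectors (cross-checked against a
cut-tree oracle in the tests).

## Cell-cell communication (`cci`)

The pseudobulk for scoring is the per-type mean of log1p(CPM) per
cell. The score for (pair, sender, receiver) is the geometric mean of
ligand and receptor pseudobulk values; a missing gene scores 0 with a
warning so tensor shapes stay aligned to the input pair list.

The null shuffles cell → cell-type labels, preserving per-type cell
counts, and recomputes the pseudobulk and all scores per permutation;
p = (1 + #{null ≥ observed})/(n_perm + 1) (add-one, so p > 0 always
and min p = 1/(n_perm+1)). Because each cell's CPM denominator is
label-invariant, only the LR gene rows are recomputed per permutation,
making 500–1000 permutations cheap. Raw p < 0.05 thresholds the
tensor, matching the thresholding convention of the upstream analyses;
Benjamini-Hochberg is deliberately not applied by default.

The non-negative CP decomposition is a HALS (hierarchical alternating
least squares) implementation: per mode, each factor column is updated
in closed form and projected to ≥ 0; dead columns are re-seeded with
tiny random values so the requested rank is used. The best of
`n_restarts` random initialisations (uniform on [0.1, 1]) wins by
relative Frobenius error; loading columns are normalised to unit
Euclidean norm per mode with the scale absorbed into per-factor
weights, factors ordered by weight. `rank_scan` warm-starts each rank
from the previous solution padded with a small random column, which
(with HALS's monotone objective) makes the error curve non-increasing;
the suggested rank is the elbow (maximum second difference). The rank
itself remains a user decision — the scan is advisory.

## Synthetic atlas (`simdata`)

The generator realises the study conditions the analyses assume, at
desk scale: 12 cell types × 150 cells, 2,000 genes, 40 TFs, 60 LR
pairs, 3 communication signatures (defaults; all exposed in
`SimConfig`). Counts are negative binomial (Gamma-Poisson) with
variance μ + μ²/θ, θ = 10 — the standard overdispersed model for UMI
counts — with per-cell lognormal library factors (σ = 0.35).

Gene panel: housekeeping genes draw one mean per gene
(loguniform 0.5–4 counts/cell) applied to every type; markers
(20/type) are loguniform 2–6 in their own type and 0.02 elsewhere; TF
genes are lowly expressed (0.15 counts/cell) with strong cross-type
lognormal heterogeneity *unrelated* to the planted hierarchy plus a
weak 0.05 bump where active, making TF expression a deliberately poor
identity proxy, as in the motivating biology; each TF-target gene is
co-bound by two TFs of one cell-type group and responds additively
(baseline 0.3 + scale · Σ weight·signal); background genes carry
per-type lognormal heterogeneity with σ = 1.4, chosen so that their
sample Gini across 12 types stays clearly above the 0.3 housekeeping
threshold. Cell types come in groups of three sharing TFs and target
programs — a planted two-level hierarchy for the dendrogram analyses.

Per-type expected totals are equalised to 1,500 UMI by rescaling the
*background* genes only, so structured genes — housekeeping genes above
all — keep exactly the means drawn for them. This matters: rescaling
every gene would imprint a type-dependent factor on housekeeping genes,
breaking both their expression equality and the exchangeability that
the permutation-test calibration run relies on.

Peaks: one TSS per gene on a jittered grid with ≥ 12 kb spacing, so a
promoter-proximal peak always satisfies the 1.5× next-TSS rule; each
(TF, target) pair gets a peak within ~900 bp of the TSS, < 200 bp from
its co-binder's peak, with raw strength monotone in the planted
binding signal (rank normalisation preserves the order). Decoys: HOT
regions pack 75 distinct TFs at < 200-bp gaps in intergenic deserts;
singleton peaks place one lone real-TF peak near non-target TSSs.
Both are recorded in the truth object.

LR structure: each signature has 2 sender and 2 receiver types
(disjoint across signatures), 8 pairs with dedicated ligand/receptor
genes expressed (mean ≈ 8 counts/cell) only in their sender/receiver
types. Non-signature pairs reuse broadly expressed genes — the
housekeeping pool when present — so their expression is
type-independent and the no-signature configuration is an exact null
for the permutation test; when no housekeeping genes are planted the
pool falls back to background genes. Signature gene rows are redrawn
from the boosted means after the base simulation, reusing the stored
per-cell library factors.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, read-level sampling, gene length effects, strand-aware
promoter geometry, repressive TF action, multi-subunit ligand/receptor
complexes, or spatial constraints on communication. Passing recovery
tests therefore demonstrates correctness of the inference machinery
under the stated generative assumptions, not robustness to these
real-data artefacts.

## Problem sizes and determinism

Test-suite and acceptance-script runs use the default atlas
(2,000 × 1,800), 300–1,000 bootstrap replicates, 60–100 down-sampling
iterations, 500 permutations and 10 rank-scan seeds — sizes chosen so
each stage completes in seconds while recovery margins stay wide.
Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from one top-level seed by stable hashing, and two
pipeline runs with the same configuration are verified hash-identical
file by file (PNG reports included; figure metadata that would embed
software versions is stripped).

## Known limitations

* Compositionality: scaled TPM couples genes within a type; a planted
  boost to one gene slightly depresses all others' scaled TPM. The
  signature-gene boosts shift the affected types' totals by a few
  percent, a mild compositional perturbation accepted as realistic.
* The permutation null conditions on per-type cell counts but not on
  per-cell totals; strongly depth-confounded labels would inflate
  significance (not the case in the generator, where depth is
  label-independent).
* Baker's gamma on 12 leaves has a coarse, tie-heavy depth
  distribution; its magnitude is informative mainly through the
  activity-vs-expression comparison, not as an absolute.
* `LassoCV` selects the penalty at minimum CV error; the 1-SE rule
  would yield sparser activities. The CV MSE per cell type is reported
  so downstream users can judge model confidence, mirroring the
  source convention (lower = more confident).
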