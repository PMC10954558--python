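# Methods

This note documents the models, numerical choices and study conditions
behind `villagefactor`, and what the synthetic-data tests do and do not
establish about real data.

## Synthetic village generator

The generator (`villagefactor.simulate`) emulates a pooled-donor snRNA-seq
study at desk scale. Its defaults define the package's reference study
conditions:

* **Donors.** 40 donors in two 20-donor villages; ages uniform on 22–97
  years; sex and case–control status alternate so pools are balanced.
* **Genotypes.** 200 independent common SNPs, minor-allele frequency
  uniform on (0.1, 0.5), dosages binomial(2, MAF). Linkage is not modelled:
  the demultiplexing likelihood treats sites independently, so correlated
  sites would only change the effective number of informative SNPs.
* **Counts.** Per-nucleus UMI counts are negative binomial with dispersion
  θ = 10 (θ = ∞ gives the Poisson limit) around
  `depth × softmax(log w(gene, cell type) + Σ_k score_k(donor) ·
  loading_k(gene, cell type) [+ outlier perturbation])`,
  with depth log-normal (mean 400 UMIs, log-sd 0.3). Planted program scores
  follow `baseline + slope·(age − mean age) + shift·1[case] + noise`.
* **Doublets.** Each nucleus is a doublet with probability 0.05; the
  partner is an independent uniform draw from the same village (so for 20
  equal donors, 95% of doublets combine two distinct donors). A doublet's
  expected expression is the 50/50 mixture of the two donors' profiles and
  its SNP reads are drawn from either donor with equal probability.
* **Aberrant donors.** An outlier donor receives a multiplicative
  log-normal perturbation (log-sd 1.0) on a random 30% of genes, shared
  across that donor's nuclei and cell types. Because gene proportions are
  renormalized, library size is untouched — the perturbation degrades
  expression conformity without tripping the UMI-count rule, which is the
  failure mode the conformity QC is designed for.
* **Paralog families.** `simulate_umi_records` emits read-level records in
  which family-origin UMIs hit every family member at low mapping quality;
  a configurable rate of uniquely mapping reads emulates the rare
  informative reads real paralogs produce. The generator also returns the
  per-cell counts a collapsed single-copy reference would yield, used as
  the concordance oracle.

For the factor-recovery study a donor-level short-cut exists:
`simulate_factor_matrix` builds the concatenated donor × (gene, cell type)
matrix directly as `scores @ loadings.T + noise` (default 180 donors, 3
cell types, 200 genes per type, one planted program with age slope
−0.02/yr, case shift −0.5, score noise sd 0.3, Gaussian noise scaled to
signal-to-noise ratio 2). This isolates the inference problem from
count-level sampling; the count-level path is exercised separately by the
pseudobulk and QC tests.

**What passing these tests does not show.** The generator has no ambient
RNA, no batch chemistry effects, no cell-type misclassification, and
independent genes given the factors. Real-data performance therefore
depends on upstream cleaning that is out of scope here.

## Donor demultiplexing

Per-nucleus singlet log-likelihood under donor d:
`Σ_obs log P(allele | g_d, ε)` with `P(alt | g, ε) = (1 − 2ε)·g/2 + ε` — a
linear error-contamination model, exact at g ∈ {0, 2} and unbiased at
g = 1 (default ε = 0.01). Multi-read evidence at one SNP is capped at one
observation by default to avoid pseudo-replication from PCR duplicates;
the cap is configurable. Doublets are scored as 50/50 mixtures with
dosage `(g1 + g2)/2` over all donor pairs; a nucleus is called a doublet
when the best pair beats the best singlet by ≥ 5 natural-log units, and
ambiguous when the singlet margin (best − second best) is < 2. Both
margins are explicit configuration: the upstream tools this stands in for
do not publish a numeric confidence rule, so the defaults here are
deliberately conservative and the tests pin their behaviour, not their
optimality. The doublet mixing fraction is fixed at 50/50 rather than
estimated, matching the generator's doublet model.

## Metagene discovery and counting

A UMI with at least one unique-high-quality read belongs to that gene;
unique reads to two different genes mark the UMI inconsistent; otherwise
the UMI is associated with the union of its low-quality hits. "Consistently
co-ambiguous" is operationalized as: a gene set S observed as an
association set with support ≥ 50 UMIs and purity ≥ 0.95, where purity is
the fraction of ambiguous UMIs touching any member of S whose set equals S
exactly. Overlapping candidates resolve deterministically (purity, then
support, then lexicographic order). Ambiguous UMIs that match no family are
counted to a discard bucket rather than fractionally allocated — the data
provide no sound prior for splitting them — which gives the exact
accounting identity `genes + metagenes + discarded = total UMIs` asserted
on every run.

## Pearson residuals and pseudobulk

Residuals are `(x − μ)/sqrt(μ + μ²/θ)` with `μ_gc = depth_c · p_g`. The
per-gene dispersion θ_g is a pooled method-of-moments estimate
(`Σμ² / Σ[(x−μ)² − μ]`), regularized by a rolling median (window 51) over
genes ordered by mean expression; genes below 10⁻⁴ of total counts inherit
the global median θ, and non-overdispersed genes cap at θ = 10⁶
(Poisson-like). This reproduces the intent of kernel-regularized
variance-stabilizing transforms without their exact kernel; the simulation
test checks the property that matters downstream — residual variance near
1 across the expression range. Residuals are clipped to ±√n_cells.

Pseudobulk matrices are plain within-(donor, cell type) sums, in raw-count
or residual mode; donors lacking a cell type yield an absent column that
is recorded, never imputed (such donors are later dropped by the 1,000-UMI
rule or at concatenation).

## Donor conformity QC

Per cell type, donor columns are scaled to 100,000 UMIs and genes kept at
≥ 10 per 100,000 in at least one donor (the filter runs per cell type
before merging, since the per-type expression scales differ); kept rows
from all types are merged, and each donor's conformity score is the median
pairwise Pearson correlation of log10(x+1) expression with the other
donors. log10 uses a +1 pseudocount to keep zeros finite. Scores are
converted to modified z-scores `M = 0.6745 (x − median)/MAD` with unscaled
MAD; exclusion thresholds are |M| > 5 (expression), |M| > 15 (cell-type
proportion conformity, computed with the same machinery on proportion
vectors), and < 1,000 total UMIs in any cell type — all configurable. When
every pairwise correlation is undefined (e.g. identical proportion
vectors), the report carries NaN and flags nothing.

The QC study condition is 40 donors with 2 planted aberrant donors; over
ten seeds the default thresholds recover exactly the planted set with no
false positives. That establishes the statistic separates the generator's
failure mode cleanly; real agonal-state outliers are less stereotyped.

## Latent factor model

Per cell type, genes are ranked by mean raw expression scaled to 100,000
per donor and the top 50% kept; residual-sum matrices are suffixed
(`GENE_celltype`) and column-bound into a donor × feature matrix. Features
are centered but not variance-scaled (residual inputs are already
variance-stabilized; a config switch exists). The Gaussian factor model
with per-feature noise precisions and per-factor ARD precisions is fitted
by coordinate-ascent variational Bayes (hyperpriors Gamma(10⁻³, 10⁻³));
the ELBO is computed every sweep, asserted non-decreasing in tests, and
iteration stops at relative change < 10⁻⁶ (default cap 1000 sweeps).
Initialization is the truncated SVD of the centered matrix, which makes
the fit deterministic; seeded random initialization is available. The
global sign ambiguity is resolved by orienting each factor so its
largest-|loading| feature is positive. Requested k is an upper bound:
surplus factors are shrunk by ARD, measured as each factor's share of
fitted score variance.

Identifiability caveat: factors of (near-)equal strength are recoverable
only up to rotation — this is a property of any Gaussian factor model, not
of the implementation — so recovery tests plant factors with distinct
strengths. PCA mode (exact truncated SVD) serves as the deterministic
subspace oracle.

Donor scores are post-processed exactly as the field does: rank-based
quantile normalization `Φ⁻¹(rank/(n+1))` (a monotone transform, so rank
statistics are unchanged) and age adjustment by OLS residuals on
(intercept, age).

## Association statistics

Spearman rank correlation uses average ranks; p-values are exact by full
permutation enumeration for n ≤ 10 and the t approximation above.
The Wilcoxon rank-sum test reports the rank-sum W of the case group, with
exact enumeration over all rank splits when both groups have ≤ 8 members
and the tie-corrected normal approximation otherwise. The joint regression
is OLS of scores on intercept + age + sex + status (sex coded M = 1,
status case = 1), with listwise deletion of missing rows and an explicit
error naming collinear terms on rank-deficient designs.

## Preranked GSEA

Enrichment scores use the weighted running sum with weight exponent p = 1;
metric ties break by stable input order (documented because loading ties
occur among filtered features), and an exact tie between the positive and
negative extremum resolves to the positive one. The null distribution is
gene-label permutation: same-size random sets from the ranked universe
(default 10,000 draws, shared per set size). P-values and NES are computed
within the sign stratum of the observed ES; FDR q is the sign-stratified
NES-ratio of the original GSEA definition. Default set-size window 10–500.
The leading edge is the run of members up to the extremum. A brute-force
running-sum evaluation at every rank position is the test oracle.

## Consensus NMF

Counts are filtered (cells ≥ 200 genes and ≥ 200 UMIs first, then genes
detected in ≥ 10 cells), scaled per gene to unit variance (switchable),
and factorized `restarts` times (default 20; heavier protocols are
config-reachable) from seeded random initializations for each k in the
scan (default 3–30). Component spectra are L2-normalized; components whose
mean distance to their nearest neighbours (30% of restarts) exceeds 0.3
are dropped as outliers — unless that would leave fewer than k components,
in which case all are kept. Remaining components are clustered by k-means
(10 seeded re-inits, best inertia); consensus spectra are cluster medians,
re-normalized; usages are refit by non-negative least squares and
row-normalized to sum to 1. Stability is the silhouette of the component
clustering, error the relative Frobenius reconstruction error; k is chosen
at maximum stability by default and is user-overridable. Donor program
scores are per-donor means of normalized usages with an optional ±1
orientation per program, so a program whose natural NMF direction opposes
the convention of a companion analysis can be flipped. Explained variance
(`1 − ‖X − WH‖²/‖X − mean‖²`) is reported, never targeted — it is a
property of whatever data are factorized.

## Problem sizes and runtime

All tests and the acceptance script run on one CPU. Chosen sizes — 40-donor
villages with 300 genes and ~2,400 nuclei, 180-donor factor matrices with
600 features, 200–400-cell NMF problems, 10,000 permutations only where the
test is about permutation granularity — keep the full suite around one to
two minutes while leaving each statistical check well-powered; they are the
package's reference conditions, and larger runs are plain configuration
changes.

## Known limitations

* The demultiplexer assumes the genotype panel is error-free and sites are
  independent; it does not model ambient alleles or estimate the doublet
  mixing fraction.
* θ estimation for Pearson residuals is method-of-moments, not a full
  GLM fit; extremely sparse genes fall back to the global median θ.
* The VB factor model assumes Gaussian residual-sum inputs and complete
  matrices; donors missing a cell type must be dropped upstream.
* Consensus NMF stability is a silhouette on pooled components, which can
  be optimistic when restarts converge to the same local optimum.
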