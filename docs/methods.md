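# Methods

## Activity scoring

Genes are ranked within each cell by decreasing log-normalized expression.
Because sparse data leave a large block of tied zeros, ties are broken by a
single random permutation drawn once per run from `tie_seed` and shared by
all cells: equal-expression genes receive an unbiased but reproducible
order, and a stable tie rule (e.g. file order) is avoided because it would
systematically favor early-indexed genes inside the zero block.

For a regulon with m targets present in the matrix, the recovery curve
y(x) = #targets with rank ≤ x is summed over x = 1..T with
T = ⌈top_fraction · n_genes⌉ (default `top_fraction = 0.05`). The score is
this raw area divided by the area of the best possible curve (targets at
ranks 1..min(m, T)), so any set size can reach exactly 1.0 and scores are
comparable across regulon sizes. Scoring therefore depends only on
within-cell ranks and is invariant under any strictly monotone transform of
a cell's expression vector. Regulons with fewer than
`min_regulon_genes_present = 3` targets in the matrix are excluded and
reported, mirroring the smallest regulon size the scoring supports
meaningfully.

## Specificity scores

For regulon R and cell type t, RSS(R, t) = 1 − √JSD(p_R, q_t): p_R is the
activity row normalized to sum 1 over cells, q_t the uniform distribution
over t's member cells, and JSD uses base-2 entropy so both JSD and RSS lie
in [0, 1]. RSS equals 1 exactly when the normalized activity coincides with
the membership indicator, and 0 when their supports are disjoint. Rows
summing to zero have no distribution and are excluded with a report entry.
Master regulators are the top-k regulons per type (default k = 6), ties
broken by name for determinism.

## CSI and module detection

Both CSI variants use strict `<` on the pairwise PCC values, so tied
correlations never count, and the matrix is symmetrized (averaged with its
transpose) first because floating-point correlation matrices are symmetric
only to the last bit. The **literal** variant is a global rank transform:
CSI(A,B) = n/N with N = K(K−1)/2 unordered off-diagonal pairs and n the
number of pairs strictly below PCC(A,B); its values lie on the grid
{0, 1/N, …, (N−1)/N}, and the pair (A,B) itself never counts toward n
(whether it belongs to the comparison universe is ambiguous in the printed
form; including it in N and excluding it from n is the convention here).
The **neighbor** variant is the classical shared-background form,
CSI(A,B) = #{C : PCC(A,C) < PCC(A,B) and PCC(B,C) < PCC(A,B)}/K over all K
regulons. The CSI diagonal is defined as 1 (self-similarity), which enters
the Euclidean row distances used downstream.

Modules are cut from an agglomerative clustering (average linkage by
default; complete and ward available) of the CSI rows at exactly
`n_modules` clusters (default 8), labelled M1..Mk in decreasing size order.
An optional silhouette scan over k = 2..15 is provided as a report and
never applied automatically.

**Which variant to use when.** The literal variant is the default for
fidelity to the printed formula and is verified exactly against exhaustive
enumeration. For module *detection*, however, it has a structural weakness
the benchmark makes visible: between-module correlations are near-tied, so
the global rank transform spreads what is essentially noise across most of
the [0, 1] range, while compressing all within-module pairs into the top of
the grid. On planted 4-module benchmarks (8 regulons/module, activation
fold 8, within-module correlation target 0.8, 2,000 cells × 1,000 genes)
clustering the literal CSI reaches ARI ≥ 0.95 in only about 8 of 20 seeds
regardless of linkage, whereas the neighbor variant recovers the planted
partition exactly (ARI 1.0, 20/20). The module-recovery benchmark and the
acceptance report therefore use `variant="neighbor"`; the choice is recorded
in run metadata either way.

## QC, normalization, markers

A cell is kept iff detected genes ≥ 200 **and** mitochondrial count
fraction ≤ 0.20 — both boundaries inclusive, and "mitochondrial percent" is
the count fraction of `mt-`-prefixed genes (the universal convention), not
a gene-identity fraction. Detected genes means nonzero entries (the Seurat
nFeature convention), not total UMIs. Zero-total cells are dropped and
tallied separately because their mito fraction is undefined.

Normalization is ln(1 + 10⁴ · count/total). The downstream stages consume
only within-cell ranks (activity) and activity scores (RSS, CSI), so a
variance-stabilizing regression model adds nothing here; plain
log-normalization keeps the stack small and exactly testable. HVGs are the
top 3,000 genes by unbiased sample variance of the normalized values, ties
by gene order, zero-variance genes never flagged; activity ranking always
uses *all* genes — HVG selection exists for export and for clustering-type
consumers, not for scoring.

Markers use a one-vs-rest two-sided Wilcoxon rank-sum per type with the
normal approximation and tie correction (no continuity correction; an
exact-enumeration mode exists for small samples), after a pre-filter at
|avg_logFC| ≥ 0.25 computed in the Seurat convention
ln(mean(expm1 x_in)+1) − ln(mean(expm1 x_out)+1), and BH adjustment across
the tested genes of each type. Under null simulations the per-type fraction
of p < 0.05 sits near 0.05 (measured 0.045–0.057 across seeds). GO-style
enrichment is deliberately generic: an upper-tail hypergeometric test
against any user-supplied GMT collection, BH-adjusted.

## Synthetic benchmark generator

The generator emulates, at desk scale, a mouse artery atlas with SMC,
mSMC1–3 (lesion-associated modulated SMC states), fibroblast, macrophage,
endothelial and T cells (default proportions 0.25/0.12/0.10/0.08/0.15/
0.12/0.10/0.08 over 2,000 cells × 1,000 genes). Counts are gamma-Poisson:
gene base means log-normal(μ=−1, σ=1), per-cell depth factors
log-normal(0, 0.5), NB dispersion 0.4, followed by independent Bernoulli
dropout (rate 0.3). Mitochondrial genes (1.3% of the universe, `mt-`
prefix, 6× mean boost) get an extra per-cell log-normal(0, 0.7) scale so
the mito fraction varies across cells; together with the depth spread this
places cells on both sides of both QC thresholds, making the filter tests
non-vacuous.

Each cell type owns `n_regulons_per_type` regulons (default 3) with
disjoint 20-gene target sets drawn from the non-mitochondrial pool
(disjointness keeps planted signals separable and makes the capacity check
exact); `n_shared_regulons` (default 2) are active in every cell. In a
cell of a regulon's home type, target means are multiplied by
`activation_fold^a` with activation level a = 0.8 + 0.15(√ρ·z_module +
√(1−ρ)·w_regulon), z, w ~ U(−1, 1): the module-level latent z is shared by
all regulons of a planted module, giving within-module activation
correlation ρ (`module_correlation`, default 0.8) on top of the shared
home-type indicator that dominates the between-cell variance. The default
module partition is one module per home type plus one for the shared
regulons. The default fold of 4 gives clean master-regulator recovery
while leaving the activity distributions overlapping; fold 1 is the null.

All randomness flows from one `numpy` generator seeded by `config.seed`, so
a fixed seed yields bit-identical count matrices and on-disk fixtures.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, pseudotime trajectories, gene-gene co-expression beyond the planted
regulons, or realistic gene-symbol vocabularies. Passing benchmarks
therefore demonstrate the correctness and statistical behaviour of the
pipeline's computations under a faithful noise model, not performance on
any particular tissue atlas.

## Problem sizes and numerical choices

Benchmark and test sizes were chosen to exercise each property at the
smallest scale where it is statistically meaningful: oracle-equivalence
checks run on 20–50 random instances at tolerances 1e-10 to exact bit
equality; module/master recovery uses 20 simulations of 2,000 × 1,000 with
32 planted regulons; null calibration uses 2,000 genes × 3 seeds. The
rank-uniformity null check tallies one regulon per simulation because
regulons within one simulation share cell-structure noise and their
home-type ranks are correlated — pooling them would overstate the evidence.

Degenerate inputs are rejected loudly: zero cells or genes, non-simplex
type proportions, regulon demand beyond the gene universe, zero-total
cells at normalization, all-absent regulon sets at scoring, single-type
marker runs, and `n_modules` above the regulon count all raise with
context. Ties are everywhere resolved by a stated deterministic rule
(seeded permutation for expression ranks, name order for RSS rankings,
gene order for HVG, first-regulon order for module labels).
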