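# regulonkit

Regulon analytics for single-cell RNA-seq: per-cell regulon activity scoring,
cell-type specificity scores, and regulon module detection, together with a
synthetic benchmark generator that plants recoverable ground truth.

A *regulon* is a transcription factor (TF) together with its inferred target
genes, scored as a unit. Given a UMI count matrix, per-cell type labels, and
regulon definitions (GMT), the pipeline answers two questions that drive
master-regulator analyses such as smooth-muscle-cell (SMC) phenotypic
modulation in atherosclerosis:

1. **Which regulons define each cell type?** Activity of regulon *R* in cell
   *c* is the normalized area under the recovery curve of *R*'s targets over
   the top 5% of *c*'s expression-ranked genes (AUCell-style, rank-based).
   The regulon specificity score is then

   RSS(R, t) = 1 − √JSD(p_R, q_t),

   where p_R is *R*'s activity distribution over cells, q_t the uniform
   indicator distribution of type *t*'s cells, and JSD the Jensen–Shannon
   divergence with base-2 entropy, so RSS ∈ [0, 1] and the top-RSS regulons
   of a type are its candidate master regulators.

2. **Which regulons act together?** From the regulon × regulon Pearson
   correlation (PCC) of activity vectors, a connection specificity index is
   computed — either the global-pair-rank form CSI(A,B) = #{pairs with
   PCC < PCC(A,B)} / #pairs (`variant="literal"`, the default) or the
   classical shared-background form CSI(A,B) = #{C : PCC(A,C) < PCC(A,B) and
   PCC(B,C) < PCC(A,B)} / K (`variant="neighbor"`) — and regulon modules are
   cut from a hierarchical clustering of the CSI rows (Euclidean distance,
   average linkage). Module-by-cell-type mean activity and a top-20-regulon
   Sankey table summarize the result.

Supporting stages: inclusive quality-control filters (≥ 200 detected genes,
mitochondrial count fraction ≤ 20%), log-normalization, variance-ranked
highly-variable-gene selection, one-vs-rest Wilcoxon marker detection with
the Seurat log-fold-change convention (threshold 0.25), and hypergeometric
over-representation of gene lists in GMT collections.

## Worked example

```python
from regulonkit import (SimulationConfig, simulate_counts,
                        PipelineParams, CSIParams, run_pipeline)

cfg = SimulationConfig(seed=7)          # 2,000 cells x 1,000 genes,
                                        # 8 cell types incl. SMC + mSMC1-3
counts, annot, regulons, truth = simulate_counts(cfg)
res = run_pipeline(counts, annot, regulons,
                   PipelineParams(csi=CSIParams(n_modules=9)))

print("QC:", res.qc_report["n_kept"], "of", res.qc_report["n_input"], "cells kept")
print(res.masters[res.masters.cell_type == "SMC"].to_string(index=False))
```

```
QC: 1493 of 2000 cells kept
cell_type  regulon      rss  rank
      SMC Tf002(+) 0.538106     1
      SMC Tf003(+) 0.478125     2
      SMC Tf001(+) 0.449515     3
      SMC Tf026(+) 0.253896     4
      SMC Tf025(+) 0.239962     5
      SMC Tf019(+) 0.197920     6
```

The three regulons planted with home type SMC (`Tf001–Tf003`, activation
fold 4 in SMC cells) occupy the top three ranks; the next entries are the
two everywhere-active "shared" regulons and a background regulon with much
lower RSS. `res.module_by_type` gives the module × cell-type mean-activity
table (e.g. the SMC-planted module averages 0.122 in SMC against ≈ 0.028
elsewhere), `res.sankey` the per-type top-20 regulon → module table, and
`res.markers` the Wilcoxon marker table.

The same stages are exposed as a CLI over the standard on-disk formats
(Matrix Market triplets, GMT, TSV):

```sh
regulonkit simulate --seed 7 --out fixture/
regulonkit run --fixture fixture/ --k 9 --out results/
```

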