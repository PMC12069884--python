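# ntmemory

Transcriptional-memory analysis for nuclear-transfer (NT) versus in-vitro
fertilized (IVF) single-cell RNA-seq experiments.

When a somatic nucleus is transplanted into an enucleated egg, the
resulting cloned embryo often retains transcriptional traces of the donor
cell type: *ON-memory* genes were expressed in the donor and persist
abnormally high in NT cells, while *OFF-memory* genes were low in the donor
and fail to activate in NT cells. This package implements the computational
side of that analysis for people studying reprogramming in cloned embryos
(or any paired perturbed/control single-cell design with a matched bulk
reference):

- **Memory criteria.** A gene *g* is called **ON-memory** when
  `mean RPKM_donor(g) > 1`, `FDR_donor vs IVF(g) < 0.05` (bulk), and
  `log2FC_NT/IVF(g) > 1` with `FDR < 0.05` (single cell); **OFF-memory**
  when `mean RPKM_donor(g) < 20`, `FDR_donor vs IVF(g) < 0.05`, and
  `log2FC_NT/IVF(g) < -1` with `FDR < 0.05`. All comparisons strict; the
  single-cell FDR condition can be toggled.
- **Differential expression.** A per-gene negative-binomial log-linear
  model `log mu = beta_0 + batch + condition + log s_j` with total-count
  size factors, method-of-moments dispersion estimated within design
  groups, and a Wald test on the condition coefficient, BH-corrected.
- **Memory scores.** Per cell, the mean of z-scored (scaled, centered over
  all cells) expression across a memory gene set.
- **Cluster-specific memory and overlaps.** The same criteria applied to
  within-cluster NT-vs-IVF contrasts, with UpSet-style exclusive
  intersection counts across cell states.
- **Germ-layer enrichment** (one-sided Fisher's exact test against the
  DE-tested background, BH across all set x category pairs) and
  **cell-type composition testing** (Wald test on the log-proportion
  difference per cluster, `z = (ln p_NT - ln p_IVF) / sqrt(1/n_NT - 1/N_NT
  + 1/n_IVF - 1/N_IVF)`).
- **Utilities** for 10x-style MTX I/O, strict-threshold cell QC,
  allotetraploid `.L`/`.S` homeolog collapsing, and reciprocal gene-symbol
  mapping.
- **A synthetic-data generator** that plants known ON/OFF-memory structure
  (negative-binomial UMI counts, cluster markers, batch effects, matched
  bulk replicates) so every stage of the pipeline can be validated against
  ground truth.

## Worked example

The `analysis/` scripts run the whole pipeline on the default synthetic
experiment (2,000 genes, 600 cells in 2 conditions x 2 batches x 3
clusters; 100 ON-memory genes planted at log2FC +2, 50 OFF-memory genes at
-2; matched 3v3 bulk donor/IVF replicates):

```sh
python analysis/01_simulate.py              # write results/sim/
python analysis/02_qc.py                    # strict-threshold cell QC
python analysis/03_global_memory.py         # global DE + memory calls + scores
python analysis/04_cluster_memory.py        # per-cluster calls + UpSet overlaps
python analysis/05_enrichment_composition.py
```

`03_global_memory.py` prints:

```
tested genes: 2000 of 2000
global memory calls: 100 ON, 50 OFF
  ON: sensitivity 1.000, false-discovery proportion 0.000
  OFF: sensitivity 1.000, false-discovery proportion 0.000
ON-memory score separation NT-IVF: 1.28 (1.99 score SD)
```

i.e. the classifier recovers every planted memory gene with no false
calls, and NT cells score almost two standard deviations higher than IVF
cells on the ON-memory signature. `05_enrichment_composition.py` then
shows the ON calls enriched in the synthetic "endoderm" annotation and the
OFF calls in "ectoderm" (FDR ~ 0), and flags exactly the two clusters
whose NT proportions were planted to change (one depleted 2-fold, one
doubled) at FDR < 1e-5 while the eight null clusters stay non-significant.

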