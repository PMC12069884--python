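# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `ntmemory`.

## The memory classification

Transcriptional memory is defined by intersecting two independent data
types. The bulk arm asks whether a gene distinguishes the somatic donor
from control IVF material: mean donor RPKM above 1 (ON) or below 20 (OFF),
with donor-vs-IVF FDR < 0.05. The single-cell arm asks whether the gene
misbehaves in NT cells: log2FC(NT/IVF) > +1 for ON, < -1 for OFF. All
comparisons are strict inequalities. The single-cell DE stage is run at
FDR < 0.05; whether that FDR bound is part of the memory criteria proper
or only of the DE stage is ambiguous in the field's usage, so both
behaviors are implemented behind `require_sc_fdr` (default: required —
without it, a noisy fold-change estimate alone could produce a call).
The bulk FDR criterion is non-directional; `bulk_de` reports a signed
log2FC so a directional variant could be imposed downstream, but the
default classification uses FDR only.

Cluster-specific memory applies the identical criteria to a within-cluster
NT-vs-IVF contrast (the only reading consistent with "identified
similarly" for a per-cell-state analysis; a cluster-vs-rest contrast would
answer a different question). Clusters need at least `min_cells = 20`
cells per condition; the batch covariate is kept where estimable within
the cluster and dropped with a logged downgrade otherwise.

## Differential expression

Counts are modeled per gene as NB(mu, alpha) with variance
`mu + alpha * mu^2` and log-linear mean
`log mu = beta_0 + batch + condition + log s_j`.

- **Size factors** are per-cell library size divided by the median library
  size. Median-of-ratios (DESeq2) is ill-defined on sparse single-cell
  data, so simple total-count scaling is used deliberately. A consequence
  worth knowing: when planted (or real) DE is directionally unbalanced,
  the library-size shift partially absorbs it — on the default synthetic
  configuration ON-gene log2FC estimates shrink by ~0.18 toward zero. The
  ±1 memory thresholds sit far enough from the planted ±2 effects that
  classification is unaffected.
- **Dispersion** is a per-gene method-of-moments estimate
  `alpha = max((s^2 - m) / m^2, 1e-8)` on size-factor-scaled counts, with
  the moments taken *within* condition x batch design groups and pooled
  with weights `n_g - 1`. Estimating the moments marginally would count
  true between-group mean differences as dispersion and destroy power
  exactly for the genes of interest (in a 3v3 bulk contrast the OFF-gene
  sensitivity dropped to 0.40 under marginal moments; group-wise moments
  restore it to 1.0). No shrinkage, no Cook's-distance outlier handling,
  no fold-change shrinkage — this is not a DESeq2 clone.
- **Fitting** is IRLS with a 25-iteration cap and relative tolerance 1e-8
  on the coefficients; non-converged genes are flagged untested rather
  than reported with unreliable statistics. With `alpha = 0` the weights
  reduce to the Poisson GLM; the Wald statistics then agree with an
  independently fitted `statsmodels` Poisson GLM to ~1e-7 (the oracle
  must itself be converged tightly, `tol=1e-12`, for the comparison).
- **Testing.** Wald z = condition coefficient / SE from the observed
  information, two-sided normal p, BH step-up over tested genes only.
  Genes are tested when nonzero in >= 10 cells (configurable; >= 2
  replicates for bulk). The BH step-up is implemented directly (five lines
  of numpy) and cross-checked against `statsmodels.multipletests` in the
  test suite.

## Memory scores

Expression is log1p of counts-per-10k (simple library-size normalization
standing in for the Seurat-default normalization used upstream of such
analyses). Each gene in the set is centered and scaled to unit variance
across *all* cells — both conditions jointly — and the per-cell score is
the mean over genes, so the all-cell score mean is 0 by construction.
Genes absent from the matrix or with zero variance are dropped and logged
rather than raising: fixed synthetic panels legitimately contain silent
genes.

## Composition testing

For cluster k with n1 of N1 NT cells and n2 of N2 IVF cells,

    z = (ln(n1/N1) - ln(n2/N2)) / sqrt(1/n1 - 1/N1 + 1/n2 - 1/N2)

the delta-method variance of a log-proportion difference. When either
count is zero, both counts of that cluster get the +1/2 continuity
correction (numerator and variance); applying it only in the degenerate
case keeps z exactly 0 for identical observed proportions. Two-sided
normal p, BH across clusters. The construction is declared here rather
than inferred from any external implementation; its null calibration
(rejection rate 0.03-0.07 at nominal 0.05 over 200 seeded multinomial
replicates of 10 clusters x 1,000 cells/condition) is enforced in the
acceptance suite.

## Enrichment

One-sided Fisher's exact test (hypergeometric upper tail) of each gene set
against each flat annotation category, over a background restricted to
DE-tested genes; categories are intersected with the background, gene sets
must be subsets of it. Odds ratios use the Haldane-Anscombe +0.5
correction when a table cell is zero. BH runs across all set x category
pairs as one family. The p-values agree exactly with brute-force
enumeration over all tables with background <= 12.

## Homeolog collapsing and symbol mapping

Allotetraploid `.L`/`.S` homeolog pairs are collapsed by *arithmetic mean*
(the field's convention for annotation transfer), although summing would
conserve counts: collapsed output is therefore an expression matrix and is
never fed to count-based DE. Suffix recognition is a literal,
case-sensitive trailing `.L`/`.S`. Whether averaging happens on raw or
normalized values is left to the caller; collapsed matrices serve
annotation-support roles only. Reciprocal symbol mapping pairs (a, b) only
when the case-insensitive match is unique in both directions; everything
else is reported unmapped.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes —
it is the package's validation substrate, not a model of any real
dataset.

- **Layout.** `n_clusters` x 2 conditions x `n_batches` equal cell blocks;
  defaults (3 clusters x 50 cells x 2 batches = 600 cells, 300 per
  condition) give the 300-cells-per-condition-in-affected-clusters design
  used throughout the tests. 2,000 genes; 5% ON-memory at log2FC +2, 2.5%
  OFF-memory at -2 (ON genes multiply the NT mean by 4; OFF genes
  attenuate the activated IVF-level mean 4-fold in NT).
- **Noise.** NB with shared dispersion 0.3 (single cell) / 0.05 (bulk),
  typical of UMI and bulk data respectively; per-gene multiplicative batch
  factor with log2 SD 0.25 applied identically to both conditions (so
  condition contrasts are unconfounded in expectation, but a DE method
  ignoring batch pays for it); per-cell lognormal depth factor (ln SD
  0.2). Base means uniform on [0.5, 8] per gene — spanning the
  shallow-coverage regime where NB power actually matters.
- **Cluster markers.** One 20-gene block per cluster boosted 4-fold, so
  cluster labels (which are an *input* to the analysis, never computed
  here) correspond to real expression structure.
- **Bulk.** RPKM is transcriptome-relative, so absolute planted levels
  (donor 30 / IVF 2 RPKM for ON; 2 / 16 for OFF; background lognormal
  around ~7 RPKM) are only meaningful if the 2,000-gene panel is treated
  as a slice of a full transcriptome: counts are generated against a
  nominal 1e7-read library and those nominal library sizes accompany the
  table, to be passed to `bulk_de` so RPKM recovers the planted levels.
  Donor bulk replicate counts and library sizes are not documented for
  the motivating experiments; 3 replicates per group at 1e7 reads is a
  realistic default, chosen once.
- **Determinism.** All randomness flows from one seed through named
  `numpy.random.Generator` streams (truth / single-cell / bulk /
  composition), so each stage is independently and jointly reproducible;
  no global random state is touched.

What the generator does *not* emulate: ambient RNA, doublets, spliced/
unspliced layers, gene-gene correlation beyond the planted blocks, or
batch effects that interact with condition. Passing tests therefore
demonstrate that the statistics do what they claim under the stated model
— not that the model captures every pathology of real data.

## Problem sizes and QC defaults

The default QC thresholds (>6,000 UMIs and >2,000 detected genes, strict)
correspond to full-transcriptome data; the synthetic panel (2,000 genes,
~9k UMIs/cell) uses the scaled-down analog (>2,000 UMIs, >800 genes) in
`analysis/02_qc.py`. The acceptance computations use 5 simulation
replicates of the 600-cell default design, 3 replicates of a 400-cell null
design, 200 multinomial replicates for composition calibration, and a
50-gene fixture for the Poisson oracle — sizes at which every reported
quantity is stable to the third digit while the whole validation completes
in well under a minute.

## Known limitations

- The Wald test is asymptotic; at very small per-group counts it is
  mildly anticonservative, which the calibration bounds (0.03-0.07)
  deliberately expose rather than hide.
- Total-count size factors absorb directionally unbalanced signal (see
  above); a composition-robust normalization is out of scope.
- The composition test treats cells as independent draws; it does not
  model embryo-level (pool) variability.
- Dispersion is estimated per gene without shrinkage, which is noisy for
  genes expressed in few cells; the expression filter is the only guard.
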