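"""ON/OFF-memory gene classification, per-cell memory scores, and overlaps.

An ON-memory gene is expressed in the somatic donor (bulk donor RPKM above
threshold, donor-vs-IVF FDR significant) and persists abnormally high in NT
cells (single-cell log2FC NT/IVF above threshold); an OFF-memory gene is
low in the donor and fails to activate in NT (log2FC below the negative
threshold). All threshold comparisons are strict. Classification can run
globally (all cells) or per cluster (within-cluster NT-vs-IVF contrast).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .de import nb_wald_de
from .exceptions import DesignError
from .io_qc import CountMatrix

__all__ = [
    "MemoryThresholds",
    "classify_memory",
    "cluster_memory",
    "normalize_log1p_cp10k",
    "memory_score",
    "overlap_matrix",
]

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "gene_id",
    "direction",
    "scope",
    "donor_rpkm",
    "bulk_fdr",
    "sc_log2fc",
    "sc_fdr",
]


@dataclass(frozen=True)
class MemoryThresholds:
    """Strict thresholds of the two memory criteria.

    ON: donor RPKM > ``on_min_donor_rpkm``, bulk FDR < ``bulk_fdr_max``,
    single-cell log2FC > ``on_min_log2fc``. OFF: donor RPKM <
    ``off_max_donor_rpkm``, bulk FDR < ``bulk_fdr_max``, single-cell log2FC
    < ``off_max_log2fc``. ``sc_fdr_max`` applies when the single-cell FDR
    condition is enabled.
    """

    on_min_donor_rpkm: float = 1.0
    off_max_donor_rpkm: float = 20.0
    bulk_fdr_max: float = 0.05
    on_min_log2fc: float = 1.0
    off_max_log2fc: float = -1.0
    sc_fdr_max: float = 0.05

    def __post_init__(self) -> None:
        if not self.on_min_log2fc > 0 > self.off_max_log2fc:
            raise ValueError("need on_min_log2fc > 0 > off_max_log2fc")
        if not 0 < self.bulk_fdr_max < 1:
            raise ValueError("bulk_fdr_max must lie in (0, 1)")


def classify_memory(
    de_sc: pd.DataFrame,
    bulk: pd.DataFrame,
    thresholds: MemoryThresholds = MemoryThresholds(),
    scope: str = "global",
    require_sc_fdr: bool = True,
) -> pd.DataFrame:
    """Call ON- and OFF-memory genes from single-cell DE plus bulk statistics.

    Only genes tested in both tables are classifiable; genes absent from
    either side are uncalled and counted in the returned table's
    ``attrs["coverage"]``. ``require_sc_fdr`` additionally demands
    single-cell FDR < ``thresholds.sc_fdr_max`` (the default behavior).

    Returns a call table with one row per called gene (columns
    ``gene_id, direction, scope, donor_rpkm, bulk_fdr, sc_log2fc, sc_fdr``).
    """
    common = de_sc.index.intersection(bulk.index)
    if len(common) == 0:
        raise ValueError("no genes shared between single-cell DE and bulk tables")
    sc = de_sc.loc[common]
    bk = bulk.loc[common]
    usable = sc["tested"].to_numpy() & bk["tested"].to_numpy()

    donor_rpkm = bk["mean_donor_rpkm"].to_numpy()
    bulk_fdr = bk["fdr"].to_numpy()
    sc_lfc = sc["log2fc"].to_numpy()
    sc_fdr = sc["fdr"].to_numpy()

    with np.errstate(invalid="ignore"):
        bulk_ok = usable & (bulk_fdr < thresholds.bulk_fdr_max)
        on = bulk_ok & (donor_rpkm > thresholds.on_min_donor_rpkm) & (
            sc_lfc > thresholds.on_min_log2fc
        )
        off = bulk_ok & (donor_rpkm < thresholds.off_max_donor_rpkm) & (
            sc_lfc < thresholds.off_max_log2fc
        )
        if require_sc_fdr:
            sig = sc_fdr < thresholds.sc_fdr_max
            on &= sig
            off &= sig

    rows = []
    for mask, direction in ((on, "ON"), (off, "OFF")):
        for i in np.flatnonzero(mask):
            rows.append(
                (
                    common[i],
                    direction,
                    scope,
                    donor_rpkm[i],
                    bulk_fdr[i],
                    sc_lfc[i],
                    sc_fdr[i],
                )
            )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    calls.attrs["coverage"] = {
        "n_sc": int(len(de_sc)),
        "n_bulk": int(len(bulk)),
        "n_shared": int(len(common)),
        "n_usable": int(usable.sum()),
        "n_uncalled": int(len(common) - usable.sum()),
    }
    return calls


def cluster_memory(
    m: CountMatrix,
    meta: pd.DataFrame,
    bulk: pd.DataFrame,
    thresholds: MemoryThresholds = MemoryThresholds(),
    min_cells: int = 20,
    contrast: tuple[str, str] = ("NT", "IVF"),
    require_sc_fdr: bool = True,
    **de_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-cluster memory calls via within-cluster NT-vs-IVF DE.

    A cluster is eligible when it holds at least ``min_cells`` cells in each
    condition; others are skipped with a logged reason. The batch covariate
    is retained where estimable within the cluster and dropped (with a
    logged downgrade) otherwise.

    Returns (concatenated call table with scope ``cluster:<label>``,
    per-cluster ON/OFF count table, skipped-cluster reasons).
    """
    meta_idx = meta.set_index("cell_id").loc[list(m.cell_ids)]
    clusters = pd.unique(meta_idx["cluster"])
    calls_all: list[pd.DataFrame] = []
    counts_rows = []
    skipped: dict = {}
    for k in sorted(clusters, key=str):
        cells = np.flatnonzero((meta_idx["cluster"] == k).to_numpy())
        cond = meta_idx["condition"].to_numpy()[cells]
        n_by_cond = {lev: int((cond == lev).sum()) for lev in contrast}
        if min(n_by_cond.values()) < min_cells:
            skipped[k] = f"fewer than {min_cells} cells per condition: {n_by_cond}"
            logger.info("cluster %s skipped: %s", k, skipped[k])
            continue
        sub = m.subset_cells(cells)
        sub_meta = meta_idx.iloc[cells].reset_index()
        try:
            de = nb_wald_de(sub, sub_meta, contrast=contrast, **de_kwargs)
        except DesignError:
            logger.info("cluster %s: batch confounded with condition, dropping covariate", k)
            de = nb_wald_de(sub, sub_meta, contrast=contrast, batch_col=None, **{
                key: v for key, v in de_kwargs.items() if key != "batch_col"
            })
        calls = classify_memory(
            de, bulk, thresholds, scope=f"cluster:{k}", require_sc_fdr=require_sc_fdr
        )
        calls_all.append(calls)
        counts_rows.append(
            (
                k,
                int((calls["direction"] == "ON").sum()),
                int((calls["direction"] == "OFF").sum()),
            )
        )
    if not counts_rows:
        raise DesignError("no cluster has enough cells in both conditions")
    nonempty = [c for c in calls_all if len(c)]
    calls = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=CALL_COLUMNS)
    )
    counts = pd.DataFrame(counts_rows, columns=["cluster", "n_on", "n_off"])
    return calls, counts, skipped


def normalize_log1p_cp10k(m: CountMatrix) -> pd.DataFrame:
    """log1p of counts-per-10k library-size normalization (genes x cells)."""
    Y = m.counts.toarray().astype(float) if sp.issparse(m.counts) else np.asarray(m.counts, float)
    lib = Y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("cells with zero library size present; filter them first")
    return pd.DataFrame(
        np.log1p(Y / lib * 1e4), index=m.gene_ids, columns=m.cell_ids
    )


def memory_score(expr: pd.DataFrame, gene_set: Iterable[str]) -> tuple[pd.Series, list[str]]:
    """Per-cell average of scaled, centered expression over a gene set.

    Each retained gene is z-scored across all cells (both conditions
    jointly); the score is the mean z over retained genes, so the score mean
    over all cells is 0 by construction. Genes absent from ``expr`` or with
    zero variance are dropped and returned (and logged).
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in expr.index]
    dropped = [g for g in gene_set if g not in expr.index]
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd[sd == 0].index.tolist()
    dropped += zero_var
    retained = sd[sd > 0].index
    if len(retained) == 0:
        raise ValueError("no genes with nonzero variance in the gene set")
    if dropped:
        logger.info("memory_score dropped %d gene(s): %s", len(dropped), dropped[:10])
    sub = sub.loc[retained]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[retained], axis=0)
    scores = z.mean(axis=0)
    scores.name = "memory_score"
    return scores, dropped


def overlap_matrix(
    calls_by_cluster: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """UpSet-style exclusive intersections of per-cluster gene sets.

    Returns (boolean gene x cluster membership matrix, exclusive-intersection
    counts for every nonempty observed combination, per-cluster set sizes).
    Exclusive semantics: a gene counts toward exactly the combination of
    clusters it belongs to, no more and no fewer.
    """
    sets = {k: set(v) for k, v in calls_by_cluster.items()}
    if not sets:
        raise ValueError("need at least one cluster")
    clusters = list(sets)
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {k: [g in sets[k] for g in universe] for k in clusters},
        index=pd.Index(universe, name="gene_id"),
    )
    combos: dict[tuple[str, ...], int] = {}
    for _, row in membership.iterrows():
        combo = tuple(k for k in clusters if row[k])
        combos[combo] = combos.get(combo, 0) + 1
    counts = pd.DataFrame(
        {
            "clusters": ["&".join(c) for c in combos],
            "degree": [len(c) for c in combos],
            "n_genes": list(combos.values()),
        }
    ).sort_values(["degree", "clusters"]).reset_index(drop=True)
    totals = pd.Series({k: len(sets[k]) for k in clusters}, name="set_size")
    return membership, counts, totals
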