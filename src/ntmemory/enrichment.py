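"""Germ-layer enrichment of memory gene sets and cluster-composition testing.

Enrichment is a one-sided Fisher's exact test of a gene set against flat
annotation categories (e.g. endoderm/mesoderm/ectoderm marker lists) over a
background of DE-tested genes, with BH correction across all
(set, category) pairs in one family.

The composition test compares per-cluster cell proportions between NT and
IVF with a Wald statistic on the log-proportion difference, using the
delta-method variance Var(ln p_hat) ~ 1/n - 1/N; a +1/2 continuity
correction is applied to both counts of a cluster (in numerator and
variance) only when one of them is zero, so equal observed proportions give
z exactly 0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .exceptions import DesignError

__all__ = ["fisher_enrichment", "composition_test"]


def _one_table(
    gene_set: set, category: set, background: set
) -> tuple[int, int, int, int]:
    """2x2 table (in set x in category) over the background."""
    a = len(gene_set & category)
    b = len(gene_set) - a
    c = len(category) - a
    d = len(background) - len(gene_set) - c
    return a, b, c, d


def fisher_enrichment(
    gene_sets: Union[Iterable[str], Mapping[str, Iterable[str]]],
    categories: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher's exact enrichment of gene set(s) in annotation categories.

    ``gene_sets`` may be a single gene list or a mapping of named lists; BH
    runs across all (set, category) pairs together. Category lists are
    intersected with the background; gene sets must be subsets of the
    background. The odds ratio uses the Haldane-Anscombe +0.5 correction
    when any table cell is zero. ``alternative="greater"`` (default) tests
    enrichment; ``"two-sided"`` is available.
    """
    if not isinstance(gene_sets, Mapping):
        gene_sets = {"set": gene_sets}
    bg = set(background)
    named_sets = {}
    for name, genes in gene_sets.items():
        gs = set(genes)
        if not gs:
            raise ValueError(f"gene set {name!r} is empty")
        stray = sorted(gs - bg)
        if stray:
            raise ValueError(
                f"gene set {name!r} is not contained in the background; "
                f"offenders: {stray[:10]}"
            )
        named_sets[name] = gs

    rows = []
    for set_name, gs in named_sets.items():
        for cat_name, cat_genes in categories.items():
            cat = set(cat_genes) & bg
            a, b, c, d = _one_table(gs, cat, bg)
            if alternative == "greater":
                # hypergeometric upper tail P(X >= a)
                p = float(stats.hypergeom.sf(a - 1, len(bg), len(cat), len(gs)))
            else:
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            if min(a, b, c, d) == 0:
                odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
            else:
                odds = a * d / (b * c)
            rows.append((set_name, cat_name, a, b, c, d, odds, p))
    result = pd.DataFrame(
        rows,
        columns=[
            "gene_set",
            "category",
            "n_set_in_cat",
            "n_set_not_cat",
            "n_bg_in_cat",
            "n_bg_not_cat",
            "odds_ratio",
            "pvalue",
        ],
    )
    result["fdr"] = bh_adjust(result["pvalue"].to_numpy())
    return result


def composition_test(
    meta: pd.DataFrame,
    conditions: tuple[str, str] = ("NT", "IVF"),
    cluster_col: str = "cluster",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Wald test of per-cluster cell-proportion differences between conditions.

    For cluster k with n1 of N1 cells in ``conditions[0]`` and n2 of N2 in
    ``conditions[1]``:

        z = (ln p1 - ln p2) / sqrt(1/n1 - 1/N1 + 1/n2 - 1/N2)

    with the +1/2 continuity correction on both counts when either is zero.
    Two-sided normal p, BH FDR across clusters.
    """
    sub = meta[meta[condition_col].isin(conditions)]
    totals = {c: int((sub[condition_col] == c).sum()) for c in conditions}
    for c, n in totals.items():
        if n == 0:
            raise DesignError(f"condition {c!r} has no cells")
    tab = pd.crosstab(sub[cluster_col], sub[condition_col])
    for c in conditions:
        if c not in tab.columns:
            tab[c] = 0

    rows = []
    for k in tab.index:
        n1, n2 = int(tab.loc[k, conditions[0]]), int(tab.loc[k, conditions[1]])
        N1, N2 = totals[conditions[0]], totals[conditions[1]]
        if n1 == 0 or n2 == 0:
            t1, t2 = n1 + 0.5, n2 + 0.5
        else:
            t1, t2 = float(n1), float(n2)
        p1, p2 = t1 / N1, t2 / N2
        var = 1.0 / t1 - 1.0 / N1 + 1.0 / t2 - 1.0 / N2
        z = (np.log(p1) - np.log(p2)) / np.sqrt(var) if var > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append((k, n1, n2, n1 / N1, n2 / N2, p1 / p2, z, p))
    result = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            f"n_{conditions[0]}",
            f"n_{conditions[1]}",
            f"frac_{conditions[0]}",
            f"frac_{conditions[1]}",
            "fraction_ratio",
            "z",
            "pvalue",
        ],
    )
    ok = result["pvalue"].notna()
    result["fdr"] = np.nan
    result.loc[ok, "fdr"] = bh_adjust(result.loc[ok, "pvalue"].to_numpy())
    return result
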