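"""Core differential-expression statistics.

Negative-binomial Wald differential expression with a batch covariate,
RPKM, Benjamini-Hochberg correction, and the bulk donor-vs-IVF summary the
memory criteria consume.

Model
-----
For gene g and cell/sample j with count ``y_gj``,

    y_gj ~ NB(mu_gj, alpha_g),    Var = mu + alpha * mu^2
    log mu_gj = beta_0 + batch_j . beta_B + condition_j * beta_C + log s_j

where ``s_j`` is a total-count size factor (library size over the median
library size — simple total-count scaling rather than median-of-ratios,
which is ill-defined on sparse single-cell data). ``alpha_g`` is a per-gene
method-of-moments estimate on size-factor-scaled counts, taken within
condition x batch design groups and pooled (floor 1e-8, no shrinkage), so
that true mean differences between groups do not masquerade as dispersion. The Wald statistic is the condition coefficient over its
standard error, referred to the standard normal; BH runs over tested genes
only. Fitting is by iteratively reweighted least squares (cap 25
iterations, relative tolerance 1e-8); non-converged genes are flagged.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .exceptions import DesignError
from .io_qc import CountMatrix

__all__ = ["rpkm", "bh_adjust", "nb_wald_de", "bulk_de", "estimate_dispersion"]

_LN2 = np.log(2.0)
_MAX_ITER = 25
_RTOL = 1e-8
_ALPHA_FLOOR = 1e-8

DE_COLUMNS = [
    "base_mean",
    "log2fc",
    "stat",
    "pvalue",
    "fdr",
    "tested",
    "n_nonzero",
    "converged",
]


def rpkm(
    counts: Union[pd.DataFrame, np.ndarray],
    gene_lengths: Union[pd.Series, np.ndarray],
    library_sizes: Optional[Union[pd.Series, np.ndarray]] = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM[g, s] = counts[g, s] / ((length_g / 1e3) * (libsize_s / 1e6))``.
    Library sizes default to column sums; explicit library sizes support
    panels that are a slice of a larger transcriptome.
    """
    counts = pd.DataFrame(counts)
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise ValueError("gene_lengths length does not match count rows")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        lib = counts.sum(axis=0).to_numpy(dtype=float)
    else:
        lib = np.asarray(library_sizes, dtype=float)
        if lib.shape[0] != counts.shape[1]:
            raise ValueError("library_sizes length does not match count columns")
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    vals = counts.to_numpy(dtype=float) / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, returned in input order.

    ``q_i = min_{j >= i} (p_(j) * m / j)`` clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def estimate_dispersion(
    y: np.ndarray,
    size_factors: np.ndarray,
    groups: Optional[np.ndarray] = None,
) -> float:
    """Method-of-moments NB dispersion on size-factor-scaled counts.

    ``alpha_hat = (s^2 - mu_bar) / mu_bar^2`` floored at 1e-8. When design
    ``groups`` (condition x batch cells) are given, the moments are taken
    within each group and pooled with weights ``n_g - 1``, so planted or
    real mean differences between groups do not inflate the estimate —
    dispersion describes noise around the model mean, not the marginal
    variance.
    """
    yn = y / size_factors
    if groups is None:
        mu = yn.mean()
        if mu <= 0:
            return _ALPHA_FLOOR
        return max((yn.var(ddof=1) - mu) / mu**2, _ALPHA_FLOOR)
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = yn[groups == g]
        if sub.size < 2:
            continue
        mu = sub.mean()
        if mu <= 0:
            continue
        w = sub.size - 1
        num += w * (sub.var(ddof=1) - mu) / mu**2
        den += w
    if den == 0:
        return _ALPHA_FLOOR
    return max(num / den, _ALPHA_FLOOR)


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = _MAX_ITER,
    rtol: float = _RTOL,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit an NB log-linear model; returns (beta, covariance, converged)."""
    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)
    converged = False
    A = None
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        A = X.T @ Xw
        b = Xw.T @ z
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            new, *_ = np.linalg.lstsq(A, b, rcond=None)
        delta = np.max(np.abs(new - beta) / (np.abs(new) + 1.0))
        beta = new
        if delta < rtol:
            converged = True
            break
    # information at the final estimate
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + alpha * mu)
    A = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)
    return beta, cov, converged


def _design_matrix(
    condition: np.ndarray,
    contrast: tuple[str, str],
    batch: Optional[np.ndarray],
) -> tuple[np.ndarray, int]:
    """Intercept + batch indicators (first level dropped) + condition indicator.

    Returns the design and the column index of the condition coefficient.
    """
    n = condition.shape[0]
    cols = [np.ones(n)]
    if batch is not None:
        levels = sorted(pd.unique(batch))
        if len(levels) > 1:
            mixed = any(
                len(set(condition[batch == lev])) == 2 for lev in levels
            )
            if not mixed:
                raise DesignError(
                    "condition is completely confounded with batch: "
                    "no batch contains both conditions"
                )
            for lev in levels[1:]:
                cols.append((batch == lev).astype(float))
    cols.append((condition == contrast[0]).astype(float))
    X = np.column_stack(cols)
    return X, X.shape[1] - 1


def nb_wald_de(
    m: CountMatrix,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("NT", "IVF"),
    batch_col: Optional[str] = "batch",
    min_cells_expressing: int = 10,
    dispersion: Optional[Union[float, np.ndarray]] = None,
    size_factors: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """NB Wald differential expression of ``contrast[0]`` vs ``contrast[1]``.

    Cells outside the two contrast levels are dropped. Genes nonzero in
    fewer than ``min_cells_expressing`` of the remaining cells are flagged
    untested (NaN statistics) and excluded from BH. ``dispersion`` overrides
    the per-gene method-of-moments estimate (0 gives the Poisson limit).

    Returns a DataFrame indexed by gene with columns ``base_mean, log2fc,
    stat, pvalue, fdr, tested, n_nonzero, converged``; positive ``log2fc``
    means higher in ``contrast[0]``.
    """
    meta = meta.set_index("cell_id").loc[list(m.cell_ids)]
    condition = meta["condition"].to_numpy()
    in_contrast = np.isin(condition, list(contrast))
    if not in_contrast.all():
        keep = np.flatnonzero(in_contrast)
        m = m.subset_cells(keep)
        meta = meta.iloc[keep]
        condition = condition[in_contrast]
    for level in contrast:
        if not np.any(condition == level):
            raise DesignError(f"contrast level {level!r} has no cells")

    batch = None
    if batch_col is not None and batch_col in meta.columns:
        batch = meta[batch_col].to_numpy()
        if len(pd.unique(batch)) < 2:
            batch = None
    X, cond_idx = _design_matrix(condition, contrast, batch)

    Y = m.counts.toarray().astype(float) if sp.issparse(m.counts) else np.asarray(m.counts, float)
    lib = Y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("cells with zero library size present; filter them first")
    if size_factors is None:
        size_factors = lib / np.median(lib)
    offset = np.log(size_factors)

    n_genes = m.n_genes
    n_nonzero = (Y > 0).sum(axis=1)
    tested = n_nonzero >= min_cells_expressing
    base_mean = (Y / size_factors).mean(axis=1)

    # design cells for the dispersion moments: condition x batch
    if batch is not None:
        design_groups = np.array(
            [f"{c}|{b}" for c, b in zip(condition, batch)], dtype=object
        )
    else:
        design_groups = condition

    log2fc = np.full(n_genes, np.nan)
    stat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    converged_arr = np.zeros(n_genes, dtype=bool)

    if dispersion is not None and np.ndim(dispersion) > 0:
        disp_arr = np.asarray(dispersion, dtype=float)
    else:
        disp_arr = None

    for g in np.flatnonzero(tested):
        y = Y[g]
        if disp_arr is not None:
            alpha = float(disp_arr[g])
        elif dispersion is not None:
            alpha = float(dispersion)
        else:
            alpha = estimate_dispersion(y, size_factors, design_groups)
        beta, cov, conv = _irls_nb(y, X, offset, alpha)
        converged_arr[g] = conv
        if not conv:
            tested[g] = False  # flagged untested: no reliable statistics
            continue
        se = np.sqrt(max(cov[cond_idx, cond_idx], 0.0))
        log2fc[g] = beta[cond_idx] / _LN2
        if se > 0:
            stat[g] = beta[cond_idx] / se
            pval[g] = 2.0 * stats.norm.sf(abs(stat[g]))

    fdr = np.full(n_genes, np.nan)
    ok = tested & np.isfinite(pval)
    if ok.any():
        fdr[ok] = bh_adjust(pval[ok])

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pval,
            "fdr": fdr,
            "tested": tested,
            "n_nonzero": n_nonzero,
            "converged": converged_arr,
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )


def bulk_de(
    bulk_counts: pd.DataFrame,
    groups: pd.Series,
    gene_lengths: pd.Series,
    library_sizes: Optional[pd.Series] = None,
    contrast: tuple[str, str] = ("donor", "IVF"),
    min_samples_expressing: int = 2,
) -> pd.DataFrame:
    """Bulk donor-vs-IVF statistics feeding the memory criteria.

    Mean donor RPKM over donor replicates, plus NB Wald donor-vs-IVF log2FC,
    p and BH FDR treating replicates as samples (no batch covariate).
    Requires >= 2 replicates per group.

    Returns a DataFrame indexed by gene with columns ``mean_donor_rpkm,
    log2fc, pvalue, fdr, tested``.
    """
    groups = pd.Series(groups)
    for level in contrast:
        if (groups == level).sum() < 2:
            raise DesignError(f"group {level!r} needs >= 2 replicates")
    samples = groups.index
    counts = bulk_counts[samples]
    lengths = pd.Series(gene_lengths).loc[counts.index]

    r = rpkm(
        counts,
        lengths,
        None if library_sizes is None else pd.Series(library_sizes).loc[samples],
    )
    donor_cols = samples[groups == contrast[0]]
    mean_donor_rpkm = r[donor_cols].mean(axis=1)

    matrix = CountMatrix(
        gene_ids=counts.index.to_numpy(),
        cell_ids=samples.to_numpy(),
        counts=counts.to_numpy(),
    )
    meta = pd.DataFrame({"cell_id": samples, "condition": groups.to_numpy()})
    de = nb_wald_de(
        matrix,
        meta,
        contrast=contrast,
        batch_col=None,
        min_cells_expressing=min_samples_expressing,
    )
    out = de[["log2fc", "pvalue", "fdr", "tested"]].copy()
    out.insert(0, "mean_donor_rpkm", mean_donor_rpkm.to_numpy())
    return out
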