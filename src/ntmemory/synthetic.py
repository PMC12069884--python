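"""Synthetic NT/IVF single-cell experiments with planted transcriptional memory.

Generates ground-truth-annotated datasets that mirror the structure the
analysis assumes: two conditions (NT, nuclear transfer; IVF, in-vitro
fertilized control) x two batches of negative-binomially distributed UMI
counts with cluster structure, plus matched bulk donor/IVF replicate counts.

Planted structure
-----------------
* ON-memory genes: high in the somatic donor (bulk), persisting high in NT
  cells of the affected clusters (single-cell mean x 2**on_log2fc in NT).
* OFF-memory genes: low in the donor, activated in IVF but failing to
  activate in NT (the activated base mean is attenuated by 2**off_log2fc in
  NT cells of affected clusters).
* Cluster markers: one marker block per cluster (default 4-fold boost) so
  cluster labels carry biological meaning without running any clustering.

The negative binomial is parameterized by mean ``mu`` and dispersion
``alpha`` with variance ``mu + alpha * mu**2``; ``alpha = 0`` degenerates to
Poisson. All randomness flows from ``SimConfig.seed`` through named
``numpy.random.Generator`` streams (one per stage), never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import json

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import ConfigError
from .io_qc import CountMatrix, write_10x_mtx, write_cell_meta

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_truth",
    "simulate_sc",
    "simulate_bulk",
    "simulate_cluster_meta",
    "write_simulation",
]

ROLE_ON = "on_memory"
ROLE_OFF = "off_memory"
ROLE_MARKER = "cluster_marker"
ROLE_BACKGROUND = "background"

# stream ids: keep simulate_* reproducible independently of call order
_STREAM_TRUTH, _STREAM_SC, _STREAM_BULK = 0, 1, 2


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults encode the standard study conditions used throughout the
    package: 2,000 genes, 100 ON-memory genes planted at log2FC +2, 50
    OFF-memory genes at -2, two batches, and 300 cells per condition in the
    affected (here: all) clusters.
    """

    n_genes: int = 2000
    n_clusters: int = 3
    cells_per_cluster_per_condition_per_batch: int = 50
    n_batches: int = 2
    frac_on_memory: float = 0.05
    frac_off_memory: float = 0.025
    on_log2fc: float = 2.0
    off_log2fc: float = -2.0
    # "global" (all clusters affected) or an explicit tuple of cluster labels
    memory_cluster_assignment: Union[str, Sequence[int]] = "global"
    base_mean_range: tuple[float, float] = (0.5, 8.0)
    dispersion: float = 0.3
    batch_log2fc_sd: float = 0.25
    cell_scale_log_sd: float = 0.2
    markers_per_cluster: int = 20
    marker_log2fc: float = 2.0
    gene_length_range: tuple[int, int] = (500, 5000)
    bulk_replicates: int = 3
    bulk_dispersion: float = 0.05
    bulk_library_size: float = 1e7
    # bulk expression levels in RPKM units relative to the full transcriptome
    on_bulk_rpkm: tuple[float, float] = (30.0, 2.0)   # (donor, IVF)
    off_bulk_rpkm: tuple[float, float] = (2.0, 16.0)  # (donor, IVF)
    background_bulk_rpkm_log_mean: float = 2.0        # lognormal ln-mean (~7.4 RPKM)
    background_bulk_rpkm_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_on_memory < 0 or self.frac_off_memory < 0:
            raise ConfigError("memory fractions must be nonnegative")
        if self.frac_on_memory + self.frac_off_memory >= 1:
            raise ConfigError("frac_on_memory + frac_off_memory must be < 1")
        for name in (
            "n_genes",
            "n_clusters",
            "cells_per_cluster_per_condition_per_batch",
            "n_batches",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.on_log2fc <= 0:
            raise ConfigError("on_log2fc must be positive")
        if self.off_log2fc >= 0:
            raise ConfigError("off_log2fc must be negative")
        if self.dispersion < 0 or self.bulk_dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")
        if self.bulk_replicates < 2:
            raise ConfigError(
                "bulk_replicates must be >= 2 (a dispersion-based test needs replication)"
            )
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ConfigError("base_mean_range must satisfy 0 < min <= max")
        llo, lhi = self.gene_length_range
        if not (0 < llo <= lhi):
            raise ConfigError("gene_length_range must satisfy 0 < min <= max")
        if isinstance(self.memory_cluster_assignment, str):
            if self.memory_cluster_assignment != "global":
                raise ConfigError("memory_cluster_assignment must be 'global' or cluster labels")
        else:
            bad = [k for k in self.memory_cluster_assignment if not 0 <= k < self.n_clusters]
            if bad:
                raise ConfigError(f"memory_cluster_assignment has invalid clusters {bad}")
            object.__setattr__(
                self, "memory_cluster_assignment", tuple(self.memory_cluster_assignment)
            )

    @property
    def affected_clusters(self) -> tuple[int, ...]:
        if self.memory_cluster_assignment == "global":
            return tuple(range(self.n_clusters))
        return tuple(self.memory_cluster_assignment)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class GroundTruth:
    """Per-gene planted structure: role, affected clusters, true effect, length."""

    table: pd.DataFrame  # gene_id, role, affected_clusters, true_log2fc, length_bp,
    #                      base_mean, marker_cluster

    def __post_init__(self) -> None:
        assert self.table["gene_id"].is_unique
        assert self.table["role"].isin(
            [ROLE_ON, ROLE_OFF, ROLE_MARKER, ROLE_BACKGROUND]
        ).all()

    def genes(self, role: str) -> list[str]:
        return self.table.loc[self.table["role"] == role, "gene_id"].tolist()

    @property
    def on_genes(self) -> list[str]:
        return self.genes(ROLE_ON)

    @property
    def off_genes(self) -> list[str]:
        return self.genes(ROLE_OFF)

    def lengths(self) -> pd.Series:
        return self.table.set_index("gene_id")["length_bp"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["affected_clusters"] = out["affected_clusters"].map(
            lambda v: ";".join(map(str, v)) if v else ""
        )
        out.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        counts = self.table["role"].value_counts().to_dict()
        return {"n_genes": int(len(self.table)), "roles": {k: int(v) for k, v in counts.items()}}


def generate_truth(config: SimConfig) -> GroundTruth:
    """Assign gene roles, lengths and base means; deterministic given the seed.

    Exactly ``round(frac_on_memory * n_genes)`` genes are labeled ON-memory
    and ``round(frac_off_memory * n_genes)`` OFF-memory; each cluster gets a
    marker block from the remaining genes; everything else is background.
    """
    rng = config.rng(_STREAM_TRUTH)
    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)], dtype=object)
    n_on = round(config.frac_on_memory * n)
    n_off = round(config.frac_off_memory * n)
    n_marker = config.markers_per_cluster * config.n_clusters
    if n_on + n_off + n_marker > n:
        raise ConfigError("memory + marker genes exceed n_genes")

    perm = rng.permutation(n)
    roles = np.full(n, ROLE_BACKGROUND, dtype=object)
    marker_cluster = np.full(n, -1)
    roles[perm[:n_on]] = ROLE_ON
    roles[perm[n_on : n_on + n_off]] = ROLE_OFF
    pos = n_on + n_off
    for k in range(config.n_clusters):
        block = perm[pos : pos + config.markers_per_cluster]
        roles[block] = ROLE_MARKER
        marker_cluster[block] = k
        pos += config.markers_per_cluster

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )
    base_mean = rng.uniform(*config.base_mean_range, size=n)

    affected = config.affected_clusters
    true_lfc = np.zeros(n)
    true_lfc[roles == ROLE_ON] = config.on_log2fc
    true_lfc[roles == ROLE_OFF] = config.off_log2fc
    affected_col = [
        affected if roles[i] in (ROLE_ON, ROLE_OFF)
        else ((int(marker_cluster[i]),) if roles[i] == ROLE_MARKER else ())
        for i in range(n)
    ]
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": roles,
            "affected_clusters": affected_col,
            "true_log2fc": true_lfc,
            "length_bp": lengths,
            "base_mean": base_mean,
            "marker_cluster": marker_cluster,
        }
    )
    return GroundTruth(table)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + alpha * mu**2 (Poisson when alpha=0)."""
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_sc(truth: GroundTruth, config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the single-cell experiment implied by the ground truth.

    Cells are laid out as batch x cluster x condition blocks of equal size.
    For an ON-memory gene affecting cluster k, the NT mean in that cluster is
    ``base_mean * 2**on_log2fc``; for an OFF-memory gene, the activated IVF
    mean ``base_mean`` is reduced to ``base_mean * 2**off_log2fc`` in NT.
    The per-gene batch effect (log2 SD ``batch_log2fc_sd``) multiplies both
    conditions identically, leaving condition contrasts unconfounded.
    """
    rng = config.rng(_STREAM_SC)
    tab = truth.table
    n = config.n_genes
    base = tab["base_mean"].to_numpy()
    roles = tab["role"].to_numpy()
    marker_cluster = tab["marker_cluster"].to_numpy()
    affected = set(config.affected_clusters)

    batch_factor = 2.0 ** rng.normal(0.0, config.batch_log2fc_sd, size=(n, config.n_batches))

    on_mask = roles == ROLE_ON
    off_mask = roles == ROLE_OFF

    blocks: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    m_cells = config.cells_per_cluster_per_condition_per_batch
    cell_counter = 0
    for b in range(config.n_batches):
        for k in range(config.n_clusters):
            marker_boost = np.where(marker_cluster == k, 2.0 ** config.marker_log2fc, 1.0)
            for cond in ("IVF", "NT"):
                mu = base * marker_boost * batch_factor[:, b]
                if cond == "NT" and k in affected:
                    nt_factor = np.ones(n)
                    nt_factor[on_mask] = 2.0 ** config.on_log2fc
                    nt_factor[off_mask] = 2.0 ** config.off_log2fc
                    mu = mu * nt_factor
                scale = np.exp(rng.normal(0.0, config.cell_scale_log_sd, size=m_cells))
                block = _nb_sample(rng, mu[:, None] * scale[None, :], config.dispersion)
                blocks.append(block)
                for _ in range(m_cells):
                    meta_rows.append((f"cell{cell_counter:05d}", cond, f"batch{b}", k))
                    cell_counter += 1

    counts = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "condition", "batch", "cluster"])
    matrix = CountMatrix(
        gene_ids=tab["gene_id"].to_numpy(),
        cell_ids=meta["cell_id"].to_numpy(),
        counts=sp.csr_matrix(counts),
    )
    return matrix, meta


def simulate_bulk(
    truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Simulate matched bulk donor/IVF replicates.

    Expression levels are planted in RPKM units relative to a full
    transcriptome of nominal library size ``bulk_library_size``, of which
    the simulated gene panel is a slice; the per-replicate nominal library
    sizes are returned so RPKM recovers the planted levels. Donor replicates
    express ON-memory genes high and OFF-memory genes low; IVF the reverse;
    background genes share one level across groups.

    Returns (counts gene x replicate, group labels, gene lengths, library sizes).
    """
    rng = config.rng(_STREAM_BULK)
    tab = truth.table
    n = config.n_genes
    roles = tab["role"].to_numpy()
    lengths = tab["length_bp"].to_numpy().astype(float)

    bg_rpkm = rng.lognormal(
        config.background_bulk_rpkm_log_mean, config.background_bulk_rpkm_log_sd, size=n
    )
    donor_rpkm = bg_rpkm.copy()
    ivf_rpkm = bg_rpkm.copy()
    donor_rpkm[roles == ROLE_ON], ivf_rpkm[roles == ROLE_ON] = config.on_bulk_rpkm
    donor_rpkm[roles == ROLE_OFF], ivf_rpkm[roles == ROLE_OFF] = config.off_bulk_rpkm

    reps = config.bulk_replicates
    columns, groups, libsizes, data = [], [], [], []
    for group, level in (("donor", donor_rpkm), ("IVF", ivf_rpkm)):
        for r in range(reps):
            lib = config.bulk_library_size * rng.lognormal(0.0, 0.1)
            mu = level * (lengths / 1e3) * (lib / 1e6)
            data.append(_nb_sample(rng, mu, config.bulk_dispersion))
            columns.append(f"{group}_{r + 1}")
            groups.append(group)
            libsizes.append(lib)

    counts = pd.DataFrame(
        np.column_stack(data), index=tab["gene_id"].to_numpy(), columns=columns
    )
    groups = pd.Series(groups, index=columns, name="group")
    lengths_s = pd.Series(lengths, index=tab["gene_id"].to_numpy(), name="length_bp")
    libsizes_s = pd.Series(libsizes, index=columns, name="library_size")
    return counts, groups, lengths_s, libsizes_s


def simulate_cluster_meta(
    proportions: dict[str, Sequence[float]],
    n_cells: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial cell-cluster labels per condition, for composition testing.

    ``proportions`` maps condition -> per-cluster probabilities (normalized
    internally); ``n_cells`` maps condition -> number of cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    rows = []
    idx = 0
    for cond, props in proportions.items():
        p = np.asarray(props, dtype=float)
        if np.any(p < 0) or p.sum() <= 0:
            raise ConfigError("proportions must be nonnegative and sum > 0")
        p = p / p.sum()
        draws = rng.multinomial(n_cells[cond], p)
        for k, cnt in enumerate(draws):
            for _ in range(cnt):
                rows.append((f"cell{idx:06d}", cond, "batch0", k))
                idx += 1
    return pd.DataFrame(rows, columns=["cell_id", "condition", "batch", "cluster"])


def write_simulation(
    outdir: str | Path,
    truth: GroundTruth,
    matrix: CountMatrix,
    meta: pd.DataFrame,
    bulk: Optional[tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]] = None,
) -> None:
    """Write the full synthetic experiment as plain-text files.

    Layout: 10x-style MTX triplet under ``sc/``, cell metadata and ground
    truth TSVs, JSON truth summary, and (optionally) bulk counts/groups/
    lengths/library-size TSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_10x_mtx(matrix, outdir / "sc")
    write_cell_meta(meta, outdir / "cell_meta.tsv")
    truth.to_tsv(outdir / "ground_truth.tsv")
    (outdir / "ground_truth_summary.json").write_text(
        json.dumps(truth.summary(), indent=2) + "\n"
    )
    if bulk is not None:
        counts, groups, lengths, libsizes = bulk
        counts.rename_axis("gene_id").to_csv(outdir / "bulk_counts.tsv", sep="\t")
        groups.rename_axis("sample").to_csv(outdir / "bulk_groups.tsv", sep="\t")
        lengths.rename_axis("gene_id").to_csv(outdir / "gene_lengths.tsv", sep="\t")
        libsizes.rename_axis("sample").to_csv(outdir / "bulk_library_sizes.tsv", sep="\t")
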