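"""Memory-gene classification, per-cell scores, and overlap structure."""

import numpy as np
import pandas as pd
import pytest

import ntmemory as nt
from ntmemory.exceptions import DesignError


def _de_table(rows):
    """rows: gene -> (log2fc, fdr)"""
    return pd.DataFrame(
        {
            "log2fc": [v[0] for v in rows.values()],
            "fdr": [v[1] for v in rows.values()],
            "tested": True,
        },
        index=pd.Index(rows.keys(), name="gene_id"),
    )


def _bulk_table(rows):
    """rows: gene -> (mean_donor_rpkm, fdr)"""
    return pd.DataFrame(
        {
            "mean_donor_rpkm": [v[0] for v in rows.values()],
            "fdr": [v[1] for v in rows.values()],
            "tested": True,
        },
        index=pd.Index(rows.keys(), name="gene_id"),
    )


class TestClassify:
    def test_on_and_off_criteria(self):
        de = _de_table({"on": (1.5, 0.001), "off": (-1.5, 0.001), "null": (0.1, 0.9)})
        bulk = _bulk_table({"on": (5, 0.01), "off": (10, 0.01), "null": (5, 0.01)})
        calls = nt.classify_memory(de, bulk)
        by_gene = calls.set_index("gene_id")["direction"]
        assert by_gene["on"] == "ON" and by_gene["off"] == "OFF"
        assert "null" not in by_gene.index

    def test_boundary_log2fc_is_strict(self):
        de = _de_table({"edge": (1.0, 0.001)})
        bulk = _bulk_table({"edge": (5, 0.01)})
        assert nt.classify_memory(de, bulk).empty

    def test_off_requires_low_donor_rpkm(self):
        de = _de_table({"g": (-2.0, 0.001)})
        bulk = _bulk_table({"g": (25, 0.01)})  # donor RPKM 25 not < 20
        assert nt.classify_memory(de, bulk).empty

    def test_sc_fdr_switch(self):
        de = _de_table({"g": (1.5, 0.2)})
        bulk = _bulk_table({"g": (5, 0.01)})
        assert nt.classify_memory(de, bulk, require_sc_fdr=True).empty
        loose = nt.classify_memory(de, bulk, require_sc_fdr=False)
        assert list(loose["gene_id"]) == ["g"]

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="shared"):
            nt.classify_memory(_de_table({"a": (1, 0.1)}), _bulk_table({"b": (1, 0.1)}))

    def test_on_off_disjoint_and_monotone_thresholds(self, default_de):
        de, bulk = default_de
        calls = nt.classify_memory(de, bulk)
        on = set(calls.loc[calls["direction"] == "ON", "gene_id"])
        off = set(calls.loc[calls["direction"] == "OFF", "gene_id"])
        assert not on & off
        stricter = nt.classify_memory(
            de, bulk, nt.MemoryThresholds(on_min_log2fc=1.8)
        )
        on_strict = set(stricter.loc[stricter["direction"] == "ON", "gene_id"])
        assert on_strict <= on

    def test_uncalled_genes_counted_in_coverage(self, default_de):
        de, bulk = default_de
        calls = nt.classify_memory(de, bulk)
        cov = calls.attrs["coverage"]
        assert cov["n_shared"] == cov["n_usable"] + cov["n_uncalled"]


@pytest.fixture(scope="module")
def cluster_run():
    """Memory planted only in cluster 0 of three."""
    cfg = nt.SimConfig(
        seed=5,
        n_genes=800,
        memory_cluster_assignment=(0,),
        cells_per_cluster_per_condition_per_batch=40,
    )
    truth = nt.generate_truth(cfg)
    m, meta = nt.simulate_sc(truth, cfg)
    bulk_stats = nt.bulk_de(*nt.simulate_bulk(truth, cfg))
    return cfg, truth, m, meta, bulk_stats


class TestClusterMemory:

    def test_planted_cluster_has_most_on_calls(self, cluster_run):
        _, _, m, meta, bulk_stats = cluster_run
        _, counts, _ = nt.cluster_memory(m, meta, bulk_stats)
        counts = counts.set_index("cluster")
        assert counts.loc[0, "n_on"] > counts.drop(index=0)["n_on"].max()
        assert counts.loc[0, "n_off"] > counts.drop(index=0)["n_off"].max()

    def test_small_cluster_skipped(self, cluster_run):
        _, _, m, meta, bulk_stats = cluster_run
        # starve cluster 2 of NT cells
        drop = (meta["cluster"] == 2) & (meta["condition"] == "NT")
        keep_idx = np.flatnonzero(~drop.to_numpy())
        sub = m.subset_cells(keep_idx)
        sub_meta = meta.iloc[keep_idx]
        calls, counts, skipped = nt.cluster_memory(sub, sub_meta, bulk_stats)
        assert 2 in skipped
        assert 2 not in set(counts["cluster"])
        assert not (calls["scope"] == "cluster:2").any()

    def test_no_eligible_cluster_errors(self, cluster_run):
        _, _, m, meta, bulk_stats = cluster_run
        with pytest.raises(DesignError):
            nt.cluster_memory(m, meta, bulk_stats, min_cells=10**6)

    def test_identically_planted_clusters_agree(self):
        """Same effect in two clusters: their ON sets overlap strongly."""
        cfg = nt.SimConfig(
            seed=6,
            n_genes=800,
            memory_cluster_assignment=(0, 1),
            cells_per_cluster_per_condition_per_batch=75,
        )
        truth = nt.generate_truth(cfg)
        m, meta = nt.simulate_sc(truth, cfg)
        bulk_stats = nt.bulk_de(*nt.simulate_bulk(truth, cfg))
        calls, _, _ = nt.cluster_memory(m, meta, bulk_stats)
        on0 = set(calls.loc[(calls["scope"] == "cluster:0") & (calls["direction"] == "ON"), "gene_id"])
        on1 = set(calls.loc[(calls["scope"] == "cluster:1") & (calls["direction"] == "ON"), "gene_id"])
        jaccard = len(on0 & on1) / len(on0 | on1)
        assert jaccard >= 0.6


class TestMemoryScore:
    def test_single_gene_score_is_zscore(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(5, 2, size=(1, 200)), index=["g"])
        scores, dropped = nt.memory_score(expr, ["g"])
        assert dropped == []
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert scores.std(ddof=0) == pytest.approx(1.0)

    def test_perfectly_correlated_pair_equals_single_gene(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0, 1, 100)
        expr = pd.DataFrame([g, 3 * g + 7], index=["a", "b"])
        single, _ = nt.memory_score(expr, ["a"])
        pair, _ = nt.memory_score(expr, ["a", "b"])
        assert np.allclose(single, pair)

    def test_invariant_to_gene_order_and_affine_rescaling(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(4, 60)), index=list("abcd"))
        s1, _ = nt.memory_score(expr, ["a", "b", "c"])
        s2, _ = nt.memory_score(expr, ["c", "a", "b"])
        rescaled = expr.copy()
        rescaled.loc["b"] = 10 * rescaled.loc["b"] - 4
        s3, _ = nt.memory_score(rescaled, ["a", "b", "c"])
        assert np.allclose(s1, s2) and np.allclose(s1, s3)

    def test_absent_and_flat_genes_dropped(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["varies", "flat"]
        )
        scores, dropped = nt.memory_score(expr, ["varies", "flat", "ghost"])
        assert set(dropped) == {"flat", "ghost"}
        with pytest.raises(ValueError, match="empty gene set"):
            nt.memory_score(expr, [])
        with pytest.raises(ValueError, match="variance"):
            nt.memory_score(expr, ["flat"])

    def test_nt_cells_score_higher_on_planted_on_genes(self, default_sim):
        cfg, truth, matrix, meta, _ = default_sim
        expr = nt.normalize_log1p_cp10k(matrix)
        scores, _ = nt.memory_score(expr, truth.on_genes)
        is_nt = (meta.set_index("cell_id").loc[scores.index, "condition"] == "NT").to_numpy()
        separation = scores[is_nt].mean() - scores[~is_nt].mean()
        assert separation > 0.5 * scores.std(ddof=0)


class TestOverlap:
    def test_exclusive_semantics(self):
        membership, counts, totals = nt.overlap_matrix({"A": ["g1", "g2"], "B": ["g2"]})
        table = counts.set_index("clusters")["n_genes"].to_dict()
        assert table == {"A": 1, "A&B": 1}
        assert totals["A"] == 2 and totals["B"] == 1
        assert membership.loc["g2"].all()

    def test_single_cluster_degenerate(self):
        _, counts, _ = nt.overlap_matrix({"only": ["x", "y", "z"]})
        assert len(counts) == 1 and counts["n_genes"].iloc[0] == 3

    def test_exclusive_counts_partition_the_union(self, default_de):
        de, bulk = default_de
        calls = nt.classify_memory(de, bulk)
        rng = np.random.default_rng(0)
        genes = calls["gene_id"].tolist()
        sets = {f"k{i}": set(rng.choice(genes, size=30)) for i in range(3)}
        _, counts, _ = nt.overlap_matrix(sets)
        assert counts["n_genes"].sum() == len(set().union(*sets.values()))
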