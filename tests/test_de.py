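"""RPKM, BH correction, and the NB Wald GLM against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ntmemory as nt
from ntmemory.exceptions import DesignError


class TestRPKM:
    def test_definition(self):
        r = nt.rpkm(
            pd.DataFrame({"s": [100, 0]}),
            gene_lengths=[2000, 1000],
            library_sizes=[1e7],
        )
        assert r.loc[0, "s"] == pytest.approx(5.0)
        assert r.loc[1, "s"] == 0.0

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s": [10, 30]})
        a = nt.rpkm(counts, [1000, 1500])
        b = nt.rpkm(2 * counts, [1000, 1500])
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_size_errors(self):
        with pytest.raises(ValueError, match="library sizes"):
            nt.rpkm(pd.DataFrame({"s": [0]}), [1000])


class TestBH:
    def test_step_up_example(self):
        # hand application of q_i = min_{j>=i} p_(j) * m / j
        assert np.allclose(nt.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_empty(self):
        assert nt.bh_adjust([0.3]) == pytest.approx([0.3])
        assert nt.bh_adjust([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            nt.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_statsmodels(self, pvals):
        sm_mt = pytest.importorskip("statsmodels.stats.multitest")
        expected = sm_mt.multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(nt.bh_adjust(pvals), expected)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    def test_invariant_to_input_order(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = nt.bh_adjust(pvals)
        q_perm = nt.bh_adjust([pvals[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)


def _matrix_from_array(arr, conditions, batches=None):
    n_genes, n_cells = arr.shape
    m = nt.CountMatrix(
        gene_ids=np.array([f"g{i}" for i in range(n_genes)]),
        cell_ids=np.array([f"c{j}" for j in range(n_cells)]),
        counts=arr,
    )
    meta = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "condition": conditions,
            "batch": batches if batches is not None else ["b0"] * n_cells,
        }
    )
    return m, meta


class TestNBWald:
    def test_identical_counts_give_null_statistics(self):
        arr = np.full((3, 40), 5)
        m, meta = _matrix_from_array(arr, ["NT"] * 20 + ["IVF"] * 20)
        de = nt.nb_wald_de(m, meta, min_cells_expressing=1)
        assert np.allclose(de["log2fc"], 0.0, atol=1e-8)
        assert np.allclose(de["stat"], 0.0, atol=1e-8)

    def test_low_expression_genes_flagged_untested(self):
        arr = np.zeros((2, 40), dtype=int)
        arr[0] = 5
        arr[1, :3] = 1  # nonzero in 3 cells < threshold 10
        m, meta = _matrix_from_array(arr, ["NT"] * 20 + ["IVF"] * 20)
        de = nt.nb_wald_de(m, meta)
        assert bool(de["tested"].iloc[0]) and not bool(de["tested"].iloc[1])
        assert np.isnan(de["pvalue"].iloc[1]) and np.isnan(de["fdr"].iloc[1])

    def test_complete_confounding_raises(self):
        arr = np.random.default_rng(0).poisson(5, size=(3, 40))
        m, meta = _matrix_from_array(
            arr,
            ["NT"] * 20 + ["IVF"] * 20,
            batches=["b0"] * 20 + ["b1"] * 20,
        )
        with pytest.raises(DesignError, match="confounded"):
            nt.nb_wald_de(m, meta)

    def test_swapping_contrast_negates_log2fc(self, default_sim):
        _, _, matrix, meta, _ = default_sim
        sub = matrix.subset_cells(np.arange(0, matrix.n_cells, 3))
        fwd = nt.nb_wald_de(sub, meta, contrast=("NT", "IVF"))
        rev = nt.nb_wald_de(sub, meta, contrast=("IVF", "NT"))
        t = fwd["tested"] & rev["tested"]
        assert np.allclose(fwd.loc[t, "log2fc"], -rev.loc[t, "log2fc"], atol=1e-6)
        assert np.allclose(fwd.loc[t, "pvalue"], rev.loc[t, "pvalue"], atol=1e-8)

    def test_poisson_limit_matches_statsmodels_glm(self):
        """With dispersion 0 the Wald statistics equal a Poisson-GLM oracle."""
        sm = pytest.importorskip("statsmodels.api")
        cfg = nt.SimConfig(
            seed=7,
            n_genes=50,
            dispersion=0.0,
            markers_per_cluster=5,
            frac_on_memory=0.1,
            frac_off_memory=0.1,
        )
        truth = nt.generate_truth(cfg)
        m, meta = nt.simulate_sc(truth, cfg)
        de = nt.nb_wald_de(m, meta, dispersion=0.0)

        Y = m.counts.toarray().astype(float)
        lib = Y.sum(axis=0)
        offset = np.log(lib / np.median(lib))
        annot = meta.set_index("cell_id").loc[list(m.cell_ids)]
        X = np.column_stack(
            [
                np.ones(m.n_cells),
                (annot["batch"] == "batch1").astype(float),
                (annot["condition"] == "NT").astype(float),
            ]
        )
        for g in range(50):
            fit = sm.GLM(
                Y[g], X, family=sm.families.Poisson(), offset=offset
            ).fit(tol=1e-12)
            z_oracle = fit.params[2] / fit.bse[2]
            assert abs(de["stat"].iloc[g] - z_oracle) < 1e-6

    def test_planted_four_fold_excess_is_recovered(self, default_sim, default_de):
        """ON genes planted at log2FC 2 with 300 cells/condition: the mean
        estimate lands within 0.3 of the plant and the genes reach FDR < 0.05.

        Total-count size factors absorb part of the planted signal (NT
        library sizes are inflated by the ON genes themselves), so a small
        systematic shrinkage toward zero is expected; it stays well inside
        the 0.3 band.
        """
        _, truth, _, _, _ = default_sim
        de, _ = default_de
        est = de.loc[truth.on_genes]
        assert abs((est["log2fc"] - 2.0).mean()) < 0.3
        assert (est["fdr"] < 0.05).mean() >= 0.95


class TestBulkDE:
    def test_mean_donor_rpkm_arithmetic(self):
        counts = pd.DataFrame(
            {
                "donor_1": [10, 50],
                "donor_2": [12, 50],
                "donor_3": [11, 50],
                "IVF_1": [30, 50],
                "IVF_2": [30, 50],
            },
            index=["g1", "g2"],
        )
        groups = pd.Series(
            ["donor", "donor", "donor", "IVF", "IVF"], index=counts.columns
        )
        lengths = pd.Series([1000, 1000], index=counts.index)
        libs = pd.Series(1e6, index=counts.columns)
        stats = nt.bulk_de(counts, groups, lengths, library_sizes=libs)
        assert stats.loc["g1", "mean_donor_rpkm"] == pytest.approx(11.0)

    def test_all_zero_gene_untested(self):
        counts = pd.DataFrame(
            np.array([[0, 0, 0, 0], [9, 11, 10, 12]]),
            index=["dead", "alive"],
            columns=["donor_1", "donor_2", "IVF_1", "IVF_2"],
        )
        groups = pd.Series(["donor", "donor", "IVF", "IVF"], index=counts.columns)
        stats = nt.bulk_de(counts, groups, pd.Series([1000, 1000], index=counts.index))
        assert not bool(stats.loc["dead", "tested"])
        assert np.isnan(stats.loc["dead", "fdr"])

    def test_requires_replication(self):
        counts = pd.DataFrame(
            np.array([[5, 6]]), index=["g"], columns=["donor_1", "IVF_1"]
        )
        groups = pd.Series(["donor", "IVF"], index=counts.columns)
        with pytest.raises(DesignError, match="replicates"):
            nt.bulk_de(counts, groups, pd.Series([1000], index=["g"]))

    def test_planted_donor_high_genes_significant(self, default_sim, default_de):
        _, truth, _, _, _ = default_sim
        _, bulk_stats = default_de
        on = bulk_stats.loc[truth.on_genes]
        assert (on["fdr"] < 0.05).all()
        assert (on["mean_donor_rpkm"] > 1).all()
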