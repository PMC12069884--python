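"""Cluster-specific memory genes and their overlap across cell states.

Re-runs the NT-vs-IVF contrast within each cluster, applies the memory
criteria per cluster, tabulates per-cluster ON/OFF counts, and computes
UpSet-style exclusive intersections of the per-cluster gene sets.
Output: results/clusters/.
"""

import argparse
from pathlib import Path

import pandas as pd

import ntmemory as nt


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--qcdir", type=Path, default=Path("results/qc"))
    ap.add_argument("--outdir", type=Path, default=Path("results/clusters"))
    args = ap.parse_args()

    matrix = nt.read_10x_mtx(args.qcdir / "sc")
    meta = nt.read_cell_meta(args.qcdir / "cell_meta.tsv")
    bulk_counts = pd.read_csv(args.simdir / "bulk_counts.tsv", sep="\t", index_col=0)
    groups = pd.read_csv(args.simdir / "bulk_groups.tsv", sep="\t", index_col=0)["group"]
    lengths = pd.read_csv(args.simdir / "gene_lengths.tsv", sep="\t", index_col=0)["length_bp"]
    libsizes = pd.read_csv(args.simdir / "bulk_library_sizes.tsv", sep="\t", index_col=0)[
        "library_size"
    ]
    bulk_stats = nt.bulk_de(bulk_counts, groups, lengths, library_sizes=libsizes)

    calls, counts, skipped = nt.cluster_memory(matrix, meta, bulk_stats)

    args.outdir.mkdir(parents=True, exist_ok=True)
    calls.to_csv(args.outdir / "memory_calls_clusters.tsv", sep="\t", index=False)
    counts.to_csv(args.outdir / "memory_counts_clusters.tsv", sep="\t", index=False)

    print("per-cluster memory gene counts:")
    print(counts.to_string(index=False))
    if skipped:
        print("skipped clusters:", skipped)

    for direction in ("ON", "OFF"):
        sets = {
            scope.removeprefix("cluster:"): grp["gene_id"]
            for scope, grp in calls[calls["direction"] == direction].groupby("scope")
        }
        if not sets:
            continue
        membership, exclusive, totals = nt.overlap_matrix(sets)
        tag = direction.lower()
        membership.to_csv(args.outdir / f"upset_membership_{tag}.tsv", sep="\t")
        exclusive.to_csv(args.outdir / f"upset_exclusive_{tag}.tsv", sep="\t", index=False)
        shared_all = exclusive.loc[
            exclusive["degree"] == len(sets), "n_genes"
        ].sum()
        print(
            f"{direction}: {int(totals.sum())} calls over {len(sets)} clusters, "
            f"{int(shared_all)} genes shared by all clusters"
        )


if __name__ == "__main__":
    main()
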