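"""Cell-level quality control of the simulated experiment.

Reads the MTX triplet written by 01_simulate.py, computes per-cell totals,
and applies the strict lower-bound filter (UMIs and detected genes). The
thresholds are the synthetic-scale analog of the >6k-UMI / >2k-gene rule
used on real data: the simulated panel has ~2,000 genes and ~9k UMIs per
cell, so the bounds scale down accordingly. Output: results/qc/.
"""

import argparse
from pathlib import Path

import ntmemory as nt


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/qc"))
    ap.add_argument("--min-umi", type=int, default=2000)
    ap.add_argument("--min-genes", type=int, default=800)
    args = ap.parse_args()

    matrix = nt.read_10x_mtx(args.indir / "sc")
    meta = nt.read_cell_meta(args.indir / "cell_meta.tsv")
    thresholds = nt.QCThresholds(min_umi=args.min_umi, min_genes=args.min_genes)
    kept, report = nt.qc_filter(matrix, thresholds, meta=meta)

    args.outdir.mkdir(parents=True, exist_ok=True)
    nt.write_10x_mtx(kept, args.outdir / "sc")
    kept_meta = meta[meta["cell_id"].isin(set(kept.cell_ids))]
    nt.write_cell_meta(kept_meta, args.outdir / "cell_meta.tsv")
    report.per_cell.to_csv(args.outdir / "qc_per_cell.tsv", sep="\t", index=False)

    print(f"cells in: {report.n_in}, kept: {report.n_kept}, discarded: {report.n_discarded}")
    if report.per_batch is not None:
        print(report.per_batch.to_string(index=False))
    if report.warning:
        print("WARNING:", report.warning)


if __name__ == "__main__":
    main()
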