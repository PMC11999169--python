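"""Per-chip log2 fold changes (exercise over sedentary), hit selection at
the |logFC| > 0.2 and >= 15% fold-change thresholds, ternary kinase
direction scores, and the row-normalized heatmap table.

Writes *_log2fc.tsv, *_ternary.tsv and *_heatmap.tsv.
"""

from pathlib import Path

from kinopipe import differential, krsa, qc, simulate

OUT = Path("results/analysis")


def main() -> None:
    for chip in ("stk", "ptk"):
        reads = simulate.read_reads(OUT / f"{chip}_reads.tsv")
        fits = qc.apply_qc(qc.fit_kinetics(reads),
                           min_signal=2.0 * qc.estimate_noise_floor(reads))
        matrix = qc.build_signal_matrix(fits, chip_type=chip.upper())
        fc = differential.log2_fold_change(matrix, "sedentary", "exercise")
        fc.to_csv(OUT / f"{chip}_log2fc.tsv", sep="\t")
        kmap = krsa.read_gmt(OUT / f"{chip}_kinase_map.gmt")
        tern = differential.ternary_score(fc, kmap)
        tern.to_csv(OUT / f"{chip}_ternary.tsv", sep="\t")
        hm = differential.heatmap_matrix(matrix)
        hm.ordered().to_csv(OUT / f"{chip}_heatmap.tsv", sep="\t")
        up = tern[tern["direction"] == "up"].index.tolist()
        print(f"{chip.upper()}: {int(fc['flagged'].sum())} peptides beyond "
              f"|logFC| 0.2, {int(fc['hit15'].sum())} with >=15% change; "
              f"families scored 'up': {up or 'none'}")


if __name__ == "__main__":
    main()
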