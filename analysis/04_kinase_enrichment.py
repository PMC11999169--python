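"""Upstream kinase-family enrichment by random resampling: the >=15%
hit peptides are compared against 2000 random draws of the same size from
the QC-passing universe, giving each family a z-score.

Writes *_krsa.tsv; prints the top families per chip.
"""

from pathlib import Path

from kinopipe import differential, krsa, qc, simulate

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    for offset, chip in enumerate(("stk", "ptk")):
        reads = simulate.read_reads(OUT / f"{chip}_reads.tsv")
        fits = qc.apply_qc(qc.fit_kinetics(reads),
                           min_signal=2.0 * qc.estimate_noise_floor(reads))
        fc = differential.log2_fold_change(
            qc.build_signal_matrix(fits), "sedentary", "exercise")
        kmap = krsa.read_gmt(OUT / f"{chip}_kinase_map.gmt")
        res = krsa.krsa(set(fc.index[fc["hit15"]]), set(fc.index), kmap,
                        n_iter=2000, seed=SEED + offset)
        res.to_csv(OUT / f"{chip}_krsa.tsv", sep="\t")
        top = res.head(3)
        print(f"{chip.upper()}: {int(fc['hit15'].sum())} hit peptides of "
              f"{len(fc)}; top families by |z|:")
        for fam, row in top.iterrows():
            print(f"  {fam:8s} observed {int(row['observed_count']):3d}  "
                  f"z {row['z_score']:+.2f}")


if __name__ == "__main__":
    main()
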