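"""Fit per-spot linear kinetics (intensity vs exposure) and apply QC:
spots with undetectable signal or non-linear growth are removed, and a
peptide must pass in every well to enter the comparison.

Reads results/analysis/*_reads.tsv; writes *_fits.tsv and
*_signal_matrix.tsv.
"""

from pathlib import Path

from kinopipe import qc, simulate

OUT = Path("results/analysis")


def main() -> None:
    for chip in ("stk", "ptk"):
        reads = simulate.read_reads(OUT / f"{chip}_reads.tsv")
        fits = qc.fit_kinetics(reads)
        min_signal = 2.0 * qc.estimate_noise_floor(reads)
        fits = qc.apply_qc(fits, min_signal=min_signal, min_r2=0.90)
        fits.to_csv(OUT / f"{chip}_fits.tsv", sep="\t", index=False)
        matrix = qc.build_signal_matrix(fits, chip_type=chip.upper())
        matrix.values.to_csv(OUT / f"{chip}_signal_matrix.tsv", sep="\t")
        total = reads["peptide_id"].nunique()
        reasons = (fits[~fits["passed_qc"]]
                   .groupby("fail_reason")["peptide_id"].nunique().to_dict())
        print(f"{chip.upper()}: {len(matrix.values)} of {total} peptides passed QC "
              f"(min_signal {min_signal:.2f}, min R^2 0.90); "
              f"failures by reason {reasons}")


if __name__ == "__main__":
    main()
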