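"""Harmonize the internal resampling ranks with two external ranker
tables (standing in for other upstream-kinase tools) into unified
percentile scores and quartile bubble tables.

Writes *_harmonized.tsv and *_bubble.tsv.
"""

from pathlib import Path

import pandas as pd

from kinopipe import harmonize, simulate

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    for offset, chip in enumerate(("stk", "ptk")):
        kr = pd.read_csv(OUT / f"{chip}_krsa.tsv", sep="\t", index_col=0)
        rankers = [harmonize.RankerOutput("krsa",
                                          kr["z_score"].fillna(0.0).to_dict())]
        for j, name in enumerate(("uka_like", "kea_like")):
            ext = simulate.make_external_ranker(name, kr["z_score"],
                                                seed=SEED + 10 * (offset + 1) + j)
            rankers.append(harmonize.RankerOutput(
                name, dict(zip(ext["kinase"], ext["score"]))))
        tab = harmonize.harmonize(rankers)
        tab.to_csv(OUT / f"{chip}_harmonized.tsv", sep="\t")
        harmonize.bubble_table(tab).to_csv(OUT / f"{chip}_bubble.tsv",
                                           sep="\t", index=False)
        best = tab["mean_percentile"].idxmax()
        print(f"{chip.upper()}: top harmonized kinase {best[1]} "
              f"(family {best[0]}, mean percentile "
              f"{tab['mean_percentile'].max():.3f})")


if __name__ == "__main__":
    main()
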