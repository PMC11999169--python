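"""Gene-set over-representation of the forest nodes (hypergeometric, BH
FDR, Enrichr-style combined score) followed by embedding meta-clustering
of the significant terms with most-representative-term selection.

Writes ora.tsv, pathway_clusters.tsv and pathway_cluster_heatmap.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from kinopipe import enrich, pcsf, simulate

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    graph = pcsf.InteractionGraph.from_tsv(OUT / "ppi_edges.tsv")
    forest_nodes = set(json.loads((OUT / "forest_nodes.json").read_text())["nodes"])
    universe = set(graph.nodes)
    prizes = pd.read_csv(OUT / "node_prizes.tsv", sep="\t", index_col=0)["prize"]
    top_prized = sorted(prizes.index[prizes > 0.75].astype(str))
    library = simulate.make_gene_sets(sorted(universe), seed=SEED + 99,
                                      focus=top_prized)

    res = enrich.ora(forest_nodes or universe, library, universe,
                     alpha=0.05, seed=SEED)
    res.to_csv(OUT / "ora.tsv", sep="\t")
    sig = list(res.index[res["significant"]])
    print(f"ORA: {len(res)} terms tested, {len(sig)} significant at FDR < 0.05")

    if sig:
        emb = simulate.make_term_embeddings(sorted(library), seed=SEED + 7)
        clusters = enrich.cluster_terms(sig, emb)
        rows = [(c.cluster_id, m, c.representative_term,
                 round(c.member_similarity[m], 4))
                for c in clusters for m in c.members]
        pd.DataFrame(rows, columns=["cluster_id", "term_id",
                                    "representative_term", "cosine_to_centroid"]
                     ).to_csv(OUT / "pathway_clusters.tsv", sep="\t", index=False)
        scores = res.loc[sig, ["combined_score"]].rename(
            columns={"combined_score": "log_combined_score"})
        scores["log_combined_score"] = np.log1p(
            np.clip(scores["log_combined_score"], 0.0, None))
        heat = enrich.cluster_heatmap_table(clusters, scores)
        heat.to_csv(OUT / "pathway_cluster_heatmap.tsv", sep="\t")
        for c in clusters:
            print(f"  cluster {c.cluster_id}: {len(c.members)} terms, "
                  f"representative {c.representative_term}")


if __name__ == "__main__":
    main()
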