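"""Integrate both chips' harmonized kinase ranks into one interaction
network: prizes from percentile ranks of the mean harmonized percentile,
edge costs from inverse interaction confidence, solved as a
prize-collecting Steiner forest. Reports hidden nodes and hub nodes of
the focal IKK subnetwork.

Writes ppi_edges.tsv, node_prizes.tsv, forest_edges.tsv and
forest_nodes.json.
"""

import json
from pathlib import Path

import pandas as pd

from kinopipe import pcsf, simulate

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    tabs = [pd.read_csv(OUT / f"{c}_harmonized.tsv", sep="\t")
            for c in ("stk", "ptk")]
    merged = (pd.concat(tabs).sort_values("mean_percentile", ascending=False,
                                          kind="stable")
              .drop_duplicates("kinase").set_index("kinase"))
    prize_rank = merged["mean_percentile"].rank(method="average") / len(merged)
    prizes = {str(k): float(v) for k, v in prize_rank.items()}
    pd.DataFrame({"prize": pd.Series(prizes).sort_index()}).to_csv(
        OUT / "node_prizes.tsv", sep="\t")

    edges = simulate.make_ppi_edges(sorted(prizes), seed=SEED)
    edges.to_csv(OUT / "ppi_edges.tsv", sep="\t", index=False)
    graph = pcsf.InteractionGraph.from_frame(edges)
    forest = pcsf.solve_pcsf(graph, prizes, beta=1.0, omega=1.0,
                             mode="heuristic", seed=SEED)
    forest.edge_frame().to_csv(OUT / "forest_edges.tsv", sep="\t", index=False)
    (OUT / "forest_nodes.json").write_text(json.dumps({
        "nodes": forest.nodes, "terminals": forest.terminals,
        "hidden_nodes": forest.hidden_nodes, "n_trees": forest.n_trees,
        "objective": round(forest.objective, 6)}, indent=1) + "\n")
    print(f"forest: {len(forest.nodes)} nodes in {forest.n_trees} tree(s), "
          f"{len(forest.hidden_nodes)} hidden, objective {forest.objective:.3f}")

    ikk = {"IKK", "CHUK", "IKBKB", "IKBKE", "TBK1"} & set(forest.nodes)
    if ikk:
        sub = pcsf.focal_subnetwork(forest, ikk)
        hubs = pcsf.hub_nodes(sub, k=3)
        print(f"focal IKK subnetwork: {sorted(sub.nodes)}; top hubs {hubs}")
    else:
        print("no IKK-family node in the forest")


if __name__ == "__main__":
    main()
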