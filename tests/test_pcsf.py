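"""Steiner forest solver: hand instances, brute-force oracle, forest
invariants, focal subnetworks and hub ranking."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from kinopipe import pcsf
from kinopipe.errors import FormatError


def _graph(edges):
    return pcsf.InteractionGraph.from_frame(
        pd.DataFrame(edges, columns=["protein_a", "protein_b", "confidence"]))


def _random_instance(seed, n=10, p_edge=0.35):
    rng = np.random.default_rng(seed)
    rows = []
    nodes = [f"N{i}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                rows.append((nodes[i], nodes[j], float(rng.uniform(0.05, 1.0))))
    if not rows:
        rows = [(nodes[0], nodes[1], 0.5)]
    g = _graph(rows)
    prizes = {v: float(rng.uniform(0, 2.0)) * (rng.random() < 0.6)
              for v in g.nodes}
    return g, prizes


class TestInteractionGraph:
    def test_duplicate_edges_collapse_to_max(self):
        g = _graph([("A", "B", 0.4), ("B", "A", 0.9)])
        assert g.edges == (("A", "B", 0.9),)

    def test_self_loop_rejected(self):
        with pytest.raises(FormatError, match="self-loop"):
            _graph([("A", "A", 0.5)])

    @pytest.mark.parametrize("conf", [0.0, -0.2, 1.5])
    def test_confidence_range_enforced(self, conf):
        with pytest.raises(FormatError):
            _graph([("A", "B", conf)])

    def test_costs_are_one_minus_confidence(self):
        g = _graph([("A", "B", 1.0), ("B", "C", 0.4)])
        costs = pcsf.assign_costs(g)
        assert costs[("A", "B")] == pytest.approx(0.0)
        assert costs[("B", "C")] == pytest.approx(0.6)

    def test_reciprocal_cost_mode(self):
        g = _graph([("A", "B", 0.5)])
        assert pcsf.assign_costs(g, mode="reciprocal")[("A", "B")] == 2.0


class TestSolvePcsf:
    def test_cheap_edge_joins_two_prized_nodes(self):
        g = _graph([("A", "B", 0.9)])  # cost 0.1
        for mode in ("exact", "heuristic"):
            f = pcsf.solve_pcsf(g, {"A": 1.0, "B": 1.0}, mode=mode)
            assert f.nodes == ["A", "B"]
            assert [tuple(sorted(e)) for e in f.graph.edges] == [("A", "B")]
            assert f.objective == pytest.approx(0.1 + 1.0)  # edge + one tree

    def test_expensive_path_leaves_singletons(self):
        # connecting costs ~3.0 > extra tree charge, so two singleton trees win
        g = _graph([("A", "M1", 1e-6), ("M1", "M2", 1e-6), ("M2", "B", 1e-6)])
        for mode in ("exact", "heuristic"):
            f = pcsf.solve_pcsf(g, {"A": 1.0, "B": 1.0}, mode=mode)
            assert f.nodes == ["A", "B"]
            assert f.n_trees == 2 and f.graph.number_of_edges() == 0

    def test_hidden_node_collected_when_profitable(self):
        # M has no prize but joining A-M-B (cost 0.2) beats two trees
        g = _graph([("A", "M", 0.9), ("M", "B", 0.9)])
        f = pcsf.solve_pcsf(g, {"A": 1.0, "B": 1.0}, mode="exact")
        assert f.hidden_nodes == ["M"]
        assert sorted(f.terminals) == ["A", "B"]

    def test_all_zero_prizes_gives_empty_forest(self):
        g = _graph([("A", "B", 0.5)])
        with pytest.warns(UserWarning, match="prizes"):
            f = pcsf.solve_pcsf(g, {"A": 0.0, "B": 0.0})
        assert f.nodes == [] and f.objective == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_heuristic_never_beats_exact(self, seed):
        g, prizes = _random_instance(seed)
        if all(p <= 0 for p in prizes.values()):
            pytest.skip("degenerate prize draw")
        ex = pcsf.solve_pcsf(g, prizes, mode="exact")
        he = pcsf.solve_pcsf(g, prizes, mode="heuristic")
        assert he.objective >= ex.objective - 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_forest_validity(self, seed):
        g, prizes = _random_instance(seed, n=12)
        if all(p <= 0 for p in prizes.values()):
            pytest.skip("degenerate prize draw")
        f = pcsf.solve_pcsf(g, prizes, mode="heuristic")
        if f.graph.number_of_nodes():
            assert nx.is_forest(f.graph)
        gx = g.to_networkx()
        for a, b in f.graph.edges:
            assert gx.has_edge(a, b)
        assert set(f.terminals) | set(f.hidden_nodes) == set(f.nodes)
        assert set(f.terminals).isdisjoint(f.hidden_nodes)

    def test_exact_terminal_count_monotone_in_beta(self):
        g, prizes = _random_instance(3, n=8)
        counts = []
        for beta in (0.25, 0.5, 1.0, 2.0, 4.0):
            f = pcsf.solve_pcsf(g, prizes, beta=beta, mode="exact")
            counts.append(len(f.terminals))
        assert counts == sorted(counts)

    def test_exact_mode_size_limit(self):
        g = _graph([(f"N{i}", f"N{i+1}", 0.5) for i in range(14)])
        with pytest.raises(ValueError, match="exact"):
            pcsf.solve_pcsf(g, {"N0": 1.0}, mode="exact")


class TestFocalSubnetwork:
    def _forest(self):
        g = _graph([("C", "L1", 0.9), ("C", "L2", 0.9), ("C", "L3", 0.9)])
        return pcsf.solve_pcsf(g, {"C": 1.0, "L1": 1.0, "L2": 1.0, "L3": 1.0},
                               mode="exact")

    def test_star_center_pulls_all_neighbors(self):
        sub = pcsf.focal_subnetwork(self._forest(), {"C"})
        assert sorted(sub.nodes) == ["C", "L1", "L2", "L3"]
        assert sub.nodes["C"]["role"] == "member"
        assert sub.nodes["L1"]["role"] == "neighbor"

    def test_full_cover_returns_whole_forest(self):
        f = self._forest()
        sub = pcsf.focal_subnetwork(f, set(f.nodes))
        assert sorted(sub.nodes) == f.nodes
        assert sub.number_of_edges() == f.graph.number_of_edges()

    def test_disjoint_gene_set_warns_empty(self):
        with pytest.warns(UserWarning, match="no gene-set member"):
            sub = pcsf.focal_subnetwork(self._forest(), {"ZZZ"})
        assert sub.number_of_nodes() == 0

    def test_hub_is_star_center(self):
        sub = pcsf.focal_subnetwork(self._forest(), {"C"})
        assert pcsf.hub_nodes(sub, k=1) == ["C"]

    def test_hub_degree_tie_broken_by_prize(self):
        g = nx.path_graph(["X", "A", "Y", "B", "Z"])
        sub = nx.Graph(g)
        for n in sub.nodes:
            sub.nodes[n]["prize"] = {"A": 0.9, "B": 0.1}.get(n, 0.0)
        # A, Y, B all have degree 2; prize 0.9 > 0.1 > 0 orders A, B, Y
        assert pcsf.hub_nodes(sub, k=3) == ["A", "B", "Y"]

    def test_path_middle_node_is_hub(self):
        sub = nx.path_graph(["a", "m", "b"])
        assert pcsf.hub_nodes(sub, k=1) == ["m"]
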