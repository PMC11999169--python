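"""Prize-collecting Steiner forest over a confidence-weighted PPI graph.

Node prizes come from harmonized kinase percentiles; edge costs are the
inverse of interaction confidence (cost = 1 - confidence by default, so
well-supported edges are nearly free). The solver minimizes

    beta * sum(prize of excluded nodes) + sum(cost of selected edges)
         + omega * (number of trees)

over forests that are subgraphs of the interaction graph. The omega term
is the classic virtual-root construction: a dummy root attached to every
node with edge weight omega turns the forest problem into a rooted
prize-collecting tree problem, and each tree of the forest pays one root
edge. Zero-prize nodes kept because they glue profitable paths together
are the "hidden nodes". Ties between including and excluding a node are
broken toward inclusion.

Two solution modes: a heuristic (minimum spanning tree over the rooted
graph, strong pruning, then cheapest-path re-insertion of dropped prized
nodes) and, for instances of at most 12 nodes, exact enumeration over node
subsets used as the test oracle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .errors import FormatError

_ROOT = "__pcsf_virtual_root__"
_EXACT_MAX_NODES = 12
_TOL = 1e-9


@dataclass(frozen=True)
class InteractionGraph:
    """Undirected PPI graph with confidences in (0, 1].

    Self-loops are rejected; duplicate edges collapse to the maximum
    confidence.
    """

    edges: tuple[tuple[str, str, float], ...]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionGraph":
        best: dict[tuple[str, str], float] = {}
        for row in df.itertuples(index=False):
            a, b, conf = str(row.protein_a), str(row.protein_b), float(row.confidence)
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            if not 0 < conf <= 1:
                raise FormatError(f"confidence {conf} for {a}-{b} outside (0, 1]")
            key = (a, b) if a < b else (b, a)
            best[key] = max(best.get(key, 0.0), conf)
        return cls(tuple((a, b, c) for (a, b), c in sorted(best.items())))

    @classmethod
    def from_tsv(cls, path) -> "InteractionGraph":
        df = pd.read_csv(path, sep="\t")
        need = {"protein_a", "protein_b", "confidence"}
        if not need <= set(df.columns):
            raise FormatError(f"{path}: expected columns {sorted(need)}")
        return cls.from_frame(df)

    @property
    def nodes(self) -> list[str]:
        return sorted({n for a, b, _ in self.edges for n in (a, b)})

    def to_networkx(self, cost_mode: str = "one_minus") -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, conf in self.edges:
            g.add_edge(a, b, confidence=conf, cost=_cost(conf, cost_mode))
        return g


def _cost(confidence: float, mode: str) -> float:
    if mode == "one_minus":
        return 1.0 - confidence
    if mode == "reciprocal":
        return 1.0 / confidence
    raise ValueError(f"unknown cost mode {mode!r}")


def assign_costs(g: InteractionGraph, mode: str = "one_minus") -> dict[tuple[str, str], float]:
    """Edge -> cost map; default cost = 1 - confidence (bounded in [0, 1))."""
    return {(a, b): _cost(c, mode) for a, b, c in g.edges}


@dataclass
class SteinerForest:
    """A solved forest: node/edge selection plus bookkeeping."""

    graph: nx.Graph            # selected nodes and edges (a forest)
    objective: float
    prizes: dict[str, float]
    params: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def terminals(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.prizes.get(n, 0.0) > 0)

    @property
    def hidden_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.prizes.get(n, 0.0) <= 0)

    @property
    def n_trees(self) -> int:
        return nx.number_connected_components(self.graph) if self.graph.nodes else 0

    def edge_frame(self) -> pd.DataFrame:
        rows = [(min(a, b), max(a, b), d["cost"], d.get("confidence", np.nan))
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(sorted(rows),
                            columns=["protein_a", "protein_b", "cost", "confidence"])


def _objective(g: nx.Graph, forest: nx.Graph, prizes: dict[str, float],
               beta: float, omega: float) -> float:
    excluded = sum(p for n, p in prizes.items() if n not in forest.nodes)
    edge_cost = sum(g.edges[e]["cost"] for e in forest.edges)
    n_trees = nx.number_connected_components(forest) if forest.nodes else 0
    return beta * excluded + edge_cost + omega * n_trees


def solve_pcsf(g: InteractionGraph, prizes: dict[str, float], beta: float = 1.0,
               omega: float = 1.0, cost_mode: str = "one_minus",
               mode: str = "auto", seed: int = 0) -> SteinerForest:
    """Solve the prize-collecting Steiner forest problem.

    mode 'exact' enumerates node subsets (instances of <= 12 nodes only),
    'heuristic' runs the virtual-root construction, 'auto' picks exact for
    small instances. Nodes named in `prizes` but absent from the graph are
    ignored with a warning.
    """
    if beta <= 0 or omega <= 0:
        raise ValueError("beta and omega must be positive")
    base = g.to_networkx(cost_mode)
    stray = set(prizes) - set(base.nodes)
    if stray:
        warnings.warn(f"prized nodes absent from graph ignored: {sorted(stray)}")
    prizes = {n: float(prizes.get(n, 0.0)) for n in base.nodes}
    params = {"beta": beta, "omega": omega, "cost_mode": cost_mode, "seed": seed}

    if all(p <= 0 for p in prizes.values()):
        warnings.warn("all prizes are zero; returning empty forest")
        return SteinerForest(nx.Graph(), 0.0, prizes, {**params, "mode": "degenerate"})

    if mode == "auto":
        mode = "exact" if base.number_of_nodes() <= _EXACT_MAX_NODES else "heuristic"
    if mode == "exact":
        forest, obj = _solve_exact(base, prizes, beta, omega)
    elif mode == "heuristic":
        forest, obj = _solve_heuristic(base, prizes, beta, omega)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    _check_forest(base, forest)
    return SteinerForest(forest, obj, prizes, {**params, "mode": mode})


def _check_forest(g: nx.Graph, forest: nx.Graph) -> None:
    assert forest.number_of_nodes() == 0 or nx.is_forest(forest)
    for a, b in forest.edges:
        assert g.has_edge(a, b)


# ---------------------------------------------------------------------------
# Exact mode: subset enumeration with a rooted minimum spanning tree
# ---------------------------------------------------------------------------

def _solve_exact(g: nx.Graph, prizes: dict[str, float], beta: float,
                 omega: float) -> tuple[nx.Graph, float]:
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n > _EXACT_MAX_NODES:
        raise ValueError(f"exact mode supports at most {_EXACT_MAX_NODES} nodes, got {n}")
    idx = {v: i for i, v in enumerate(nodes)}
    # +1 weight shift: csgraph treats 0 as "no edge", but a spanning tree of
    # k+1 nodes always has exactly k edges, so the shift cancels exactly.
    shift = 1.0
    w = np.full((n + 1, n + 1), 0.0)
    for a, b, d in g.edges(data=True):
        i, j = idx[a] + 1, idx[b] + 1
        w[i, j] = w[j, i] = d["cost"] + shift
    for i in range(1, n + 1):
        w[0, i] = w[i, 0] = omega + shift

    total_prize = sum(prizes.values())
    prize_arr = np.array([prizes[v] for v in nodes])
    best_obj = beta * total_prize  # empty selection
    best_subset: tuple[int, ...] = ()
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            sel = np.array([0] + [i + 1 for i in subset])
            sub = w[np.ix_(sel, sel)]
            mst = minimum_spanning_tree(csr_matrix(sub))
            cost = float(mst.sum()) - size * shift
            obj = beta * (total_prize - prize_arr[list(subset)].sum()) + cost
            if obj < best_obj - _TOL or (obj < best_obj + _TOL
                                         and len(subset) > len(best_subset)):
                best_obj, best_subset = obj, subset

    forest = nx.Graph()
    if best_subset:
        sel = np.array([0] + [i + 1 for i in best_subset])
        sub = w[np.ix_(sel, sel)]
        mst = minimum_spanning_tree(csr_matrix(sub)).tocoo()
        forest.add_nodes_from(nodes[i] for i in best_subset)
        for r, c in zip(mst.row, mst.col):
            if r == 0 or c == 0:
                continue  # root edges only mark tree roots
            a = nodes[int(sel[r]) - 1]
            b = nodes[int(sel[c]) - 1]
            forest.add_edge(a, b, **g.edges[a, b])
    return forest, _objective(g, forest, prizes, beta, omega)


# ---------------------------------------------------------------------------
# Heuristic: rooted MST + strong pruning + cheapest-path re-insertion
# ---------------------------------------------------------------------------

def _strong_prune(tree: nx.Graph, prizes: dict[str, float], beta: float,
                  omega: float) -> set[str]:
    """Best subforest of the rooted tree; returns kept (non-root) nodes.

    Bottom-up net value: netval(v) = beta*prize(v) + sum over children of
    max(0, netval(c) - w(v,c)). A child subtree is kept when its net value
    covers the connecting edge (ties kept, provided the subtree holds any
    prize at all).
    """
    order = list(nx.dfs_postorder_nodes(tree, _ROOT))
    parent = dict(nx.dfs_predecessors(tree, _ROOT))
    netval: dict[str, float] = {}
    kept_children: dict[str, list[str]] = {v: [] for v in tree.nodes}
    for v in order:
        if v == _ROOT:
            continue
        val = beta * prizes.get(v, 0.0)
        for c in tree.neighbors(v):
            if parent.get(c) != v:
                continue
            gain = netval[c] - tree.edges[v, c]["weight"]
            if gain >= -_TOL and netval[c] > _TOL:
                val += max(gain, 0.0)
                kept_children[v].append(c)
        netval[v] = val

    kept: set[str] = set()
    stack = []
    for c in tree.neighbors(_ROOT):
        if netval[c] >= omega - _TOL and netval[c] > _TOL:
            stack.append(c)
    while stack:
        v = stack.pop()
        kept.add(v)
        stack.extend(kept_children[v])
    return kept


def _solve_heuristic(g: nx.Graph, prizes: dict[str, float], beta: float,
                     omega: float) -> tuple[nx.Graph, float]:
    """Best of two starts, each polished by local search.

    Start A: minimum spanning tree of the rooted graph, strong-pruned.
    Start B: empty forest (grown greedily by the local search itself).
    """
    rooted = nx.Graph()
    rooted.add_nodes_from(g.nodes)
    for a, b, d in g.edges(data=True):
        rooted.add_edge(a, b, weight=d["cost"])
    for v in g.nodes:
        rooted.add_edge(_ROOT, v, weight=omega)
    mst = nx.minimum_spanning_tree(rooted, weight="weight")
    kept = _strong_prune(mst, prizes, beta, omega)
    cand_a = nx.Graph()
    cand_a.add_nodes_from(kept)
    for a, b in mst.edges:
        if a in kept and b in kept:
            cand_a.add_edge(a, b, **g.edges[a, b])

    best, best_obj = None, np.inf
    for forest in (cand_a, nx.Graph()):
        _local_search(g, forest, prizes, beta, omega)
        obj = _objective(g, forest, prizes, beta, omega)
        # alternate path-based search with node-set flips until neither helps
        for _ in range(10):
            flipped = _flip_search(g, forest, prizes, beta, omega)
            _local_search(g, flipped, prizes, beta, omega)
            new_obj = _objective(g, flipped, prizes, beta, omega)
            if new_obj < obj - _TOL:
                forest, obj = flipped, new_obj
            else:
                break
        better = obj < best_obj - _TOL or (
            obj < best_obj + _TOL and best is not None
            and forest.number_of_nodes() > best.number_of_nodes())
        if best is None or better:
            best, best_obj = forest, obj
    return best, best_obj


def _local_search(g: nx.Graph, forest: nx.Graph, prizes: dict[str, float],
                  beta: float, omega: float) -> None:
    """Improve the forest in place until no move strictly lowers the objective.

    Moves: attach an excluded prized node (as a singleton tree, or via its
    cheapest path into one existing tree, collecting prizes en route);
    merge two trees through a path of non-forest nodes; split off an edge
    costing more than one tree charge omega; drop a whole tree whose
    prizes do not cover its cost. Exact ties favor inclusion (applied once
    at the end).
    """
    guard = 0
    while _one_improving_move(g, forest, prizes, beta, omega):
        guard += 1
        if guard > 20 * max(g.number_of_nodes(), 1):  # pragma: no cover
            warnings.warn("local search hit its iteration guard")
            break
    # tie rule: a prized node worth exactly one tree charge is included
    for v in sorted(g.nodes):
        p = prizes.get(v, 0.0)
        if v not in forest.nodes and p > 0 and beta * p >= omega - _TOL:
            forest.add_node(v)


def _one_improving_move(g: nx.Graph, forest: nx.Graph, prizes: dict[str, float],
                        beta: float, omega: float) -> bool:
    # attach an excluded prized node (singleton tree or cheapest path in)
    excluded = sorted((v for v in g.nodes if v not in forest.nodes
                       and beta * prizes.get(v, 0.0) > 0),
                      key=lambda u: (-prizes.get(u, 0.0), u))
    for v in excluded:
        best_delta = omega - beta * prizes[v]  # singleton option
        best_path = [v]
        lengths, paths = nx.single_source_dijkstra(g, v, weight="cost")
        for target, length in lengths.items():
            if target not in forest.nodes:
                continue
            path = paths[target]
            if sum(u in forest.nodes for u in path) != 1:
                continue  # would close a cycle through the forest
            delta = length - beta * sum(prizes.get(u, 0.0)
                                        for u in path if u not in forest.nodes)
            if delta < best_delta - _TOL:
                best_delta, best_path = delta, path
        if best_delta < -_TOL:
            _add_path(g, forest, best_path)
            return True

    if forest.number_of_nodes() == 0:
        return False
    trees = [set(c) for c in nx.connected_components(forest)]

    # merge two trees through non-forest interior nodes (saves one omega)
    if len(trees) > 1:
        node_tree = {v: i for i, t in enumerate(trees) for v in t}
        forest_nodes = set(forest.nodes)
        for i, tree in enumerate(trees):
            lengths, paths = nx.multi_source_dijkstra(g, tree, weight="cost")
            best_delta, best_path = -_TOL, None
            for target, length in lengths.items():
                j = node_tree.get(target)
                if j is None or j == i:
                    continue
                path = paths[target]
                interior = path[1:-1]
                if any(u in forest_nodes for u in interior):
                    continue
                delta = length - omega - beta * sum(prizes.get(u, 0.0)
                                                    for u in interior)
                if delta < best_delta:
                    best_delta, best_path = delta, path
            if best_path is not None:
                _add_path(g, forest, best_path)
                return True

    # split: removing an edge costing more than omega pays for the new tree
    for a, b, d in sorted(forest.edges(data=True), key=lambda e: -e[2]["cost"]):
        if d["cost"] > omega + _TOL:
            forest.remove_edge(a, b)
            return True

    # drop a tree whose collected prizes do not cover its edges plus omega
    for tree in trees:
        if not tree <= set(forest.nodes):
            continue
        sub = forest.subgraph(tree)
        cost = sum(d["cost"] for _, _, d in sub.edges(data=True)) + omega
        gain = beta * sum(prizes.get(v, 0.0) for v in tree)
        if cost > gain + _TOL:
            forest.remove_nodes_from(tree)
            return True
    return False


def _retree(g: nx.Graph, nodes: set[str], prizes: dict[str, float], beta: float,
            omega: float) -> nx.Graph:
    """Optimal forest for a fixed node set, then strong-pruned.

    For a fixed selection the best forest is the minimum spanning tree of
    the induced subgraph plus a virtual root joined to every node at
    weight omega: each tree of the forest pays exactly one root edge.
    """
    rooted = nx.Graph()
    rooted.add_nodes_from(nodes)
    for a, b, d in g.subgraph(nodes).edges(data=True):
        rooted.add_edge(a, b, weight=d["cost"])
    for v in nodes:
        rooted.add_edge(_ROOT, v, weight=omega)
    forest = nx.Graph()
    if nodes:
        mst = nx.minimum_spanning_tree(rooted, weight="weight")
        kept = _strong_prune(mst, prizes, beta, omega)
        forest.add_nodes_from(kept)
        for a, b in mst.edges:
            if a in kept and b in kept:
                forest.add_edge(a, b, **g.edges[a, b])
    return forest


def _flip_search(g: nx.Graph, forest: nx.Graph, prizes: dict[str, float],
                 beta: float, omega: float) -> nx.Graph:
    """Hill-climb over node sets, scoring each set by its optimal forest.

    Because :func:`_retree` solves the forest exactly for a fixed node
    set, toggling one node in or out and re-treeing evaluates the true
    objective of the neighboring selection; this catches zero-prize
    Steiner nodes whose only value is rewiring the topology.
    """
    current = set(forest.nodes)
    best = _retree(g, current, prizes, beta, omega)
    best_obj = _objective(g, best, prizes, beta, omega)
    if best_obj > _objective(g, forest, prizes, beta, omega) + _TOL:  # pragma: no cover
        best, best_obj = forest, _objective(g, forest, prizes, beta, omega)
    improved = True
    while improved:
        improved = False
        for v in sorted(g.nodes):
            trial = set(best.nodes) ^ {v}
            cand = _retree(g, trial, prizes, beta, omega)
            obj = _objective(g, cand, prizes, beta, omega)
            if obj < best_obj - _TOL:
                best, best_obj = cand, obj
                improved = True
                break
    return best


def _add_path(g: nx.Graph, forest: nx.Graph, path: list[str]) -> None:
    for u in path:
        forest.add_node(u)
    for a, b in zip(path, path[1:]):
        forest.add_edge(a, b, **g.edges[a, b])


# ---------------------------------------------------------------------------
# Forest interrogation
# ---------------------------------------------------------------------------

def focal_subnetwork(forest: SteinerForest, gene_set: set[str]) -> nx.Graph:
    """Induced forest subgraph on gene-set members plus their neighbors.

    Node attribute 'role' is 'member' or 'neighbor'; 'hidden' marks
    zero-prize nodes. Returns an empty graph with a warning when no member
    is present in the forest.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    members = set(gene_set) & set(forest.graph.nodes)
    if not members:
        warnings.warn("no gene-set member present in the forest")
        return nx.Graph()
    nodes = set(members)
    for m in members:
        nodes.update(forest.graph.neighbors(m))
    sub = forest.graph.subgraph(nodes).copy()
    for n in sub.nodes:
        sub.nodes[n]["role"] = "member" if n in members else "neighbor"
        sub.nodes[n]["hidden"] = forest.prizes.get(n, 0.0) <= 0
        sub.nodes[n]["prize"] = forest.prizes.get(n, 0.0)
    return sub


def hub_nodes(subgraph: nx.Graph, k: int = 5) -> list[str]:
    """Top-k nodes by degree; ties by prize (higher first), then name."""
    if subgraph.number_of_nodes() == 0:
        raise ValueError("subgraph is empty")
    ranked = sorted(subgraph.nodes,
                    key=lambda n: (-subgraph.degree[n],
                                   -float(subgraph.nodes[n].get("prize", 0.0)), n))
    return ranked[:k]
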