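"""Gene-set over-representation and embedding-based pathway meta-clustering.

ORA tests each gene set with the one-sided hypergeometric upper tail
against a fixed universe, corrects across terms with Benjamini-Hochberg,
and attaches an Enrichr-style combined score

    combined = -ln(p) * z

where z standardizes the deviation of the term's observed rank (by
p-value) from its expected rank under random queries of the same size.
Significant terms (FDR < alpha) are then meta-clustered on their embedding
vectors with average-linkage agglomerative clustering on cosine distance;
each cluster is summarized by its most representative term (MRT), the
member most cosine-similar to the cluster's mean embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 100


def _hypergeom_p(overlap: int, universe: int, set_size: int, query: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(universe, set_size, query)."""
    return float(hypergeom.sf(overlap - 1, universe, set_size, query))


def ora(query: set[str], library: dict[str, frozenset[str]], universe: set[str],
        alpha: float = DEFAULT_ALPHA, score_mode: str = "combined",
        n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> pd.DataFrame:
    """Over-representation analysis of `query` against a gene-set library.

    Library sets are intersected with the universe; sets with no universe
    overlap are skipped. score_mode 'combined' adds the permutation-based
    z factor; 'neglogp' uses -ln(p) alone (exact, no randomness).

    Returns a DataFrame indexed by term with columns overlap, set_size,
    universe_size, n_query, p_value, fdr, combined_score, significant,
    sorted by ascending p.
    """
    if not query:
        raise ValueError("query is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    n_u, n_q = len(universe), len(query)
    uni = sorted(universe)
    uni_idx = {g: i for i, g in enumerate(uni)}
    terms, k_arr, m_arr, cols = [], [], [], []
    for term in sorted(library):
        members = library[term] & universe
        if not members:
            continue
        terms.append(term)
        k_arr.append(len(members & query))
        m_arr.append(len(members))
        col = np.zeros(n_u, dtype=np.int64)
        for g in members:
            col[uni_idx[g]] = 1
        cols.append(col)
    if not terms:
        raise ValueError("no library set overlaps the universe")
    k_arr = np.asarray(k_arr)
    m_arr = np.asarray(m_arr)
    member = np.column_stack(cols)  # universe x terms
    pvals = hypergeom.sf(k_arr - 1, n_u, m_arr, n_q)

    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    neglogp = -np.log(np.clip(pvals, 1e-300, None))

    if score_mode == "neglogp":
        combined = neglogp
    elif score_mode == "combined":
        z = _rank_deviation_z(member, m_arr, n_u, n_q, pvals, n_perm, seed)
        combined = neglogp * z
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")

    out = pd.DataFrame({
        "overlap": k_arr, "set_size": m_arr,
        "universe_size": n_u, "n_query": n_q,
        "p_value": pvals, "fdr": fdr,
        "combined_score": combined,
        "significant": fdr < alpha,
    }, index=pd.Index(terms, name="term_id"))
    return out.sort_values(["p_value", "term_id"], kind="stable")


def _rank_deviation_z(member: np.ndarray, m_arr: np.ndarray, n_u: int, n_q: int,
                      pvals: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """Standardized deviation of each term's p-value rank from its null rank.

    Random queries of the same size are drawn from the universe; for each,
    terms are re-ranked by hypergeometric p. z > 0 means the term ranks
    better (earlier) than expected under random queries.
    """
    rng = np.random.default_rng(seed)
    obs_rank = pd.Series(pvals).rank(method="average").to_numpy()
    n_terms = member.shape[1]
    perm_ranks = np.empty((n_perm, n_terms))
    for it in range(n_perm):
        draw = rng.choice(n_u, size=n_q, replace=False)
        overlaps = member[draw].sum(axis=0)
        p = hypergeom.sf(overlaps - 1, n_u, m_arr, n_q)
        perm_ranks[it] = pd.Series(p).rank(method="average").to_numpy()
    mean_r = perm_ranks.mean(axis=0)
    sd_r = perm_ranks.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_r > 0, (mean_r - obs_rank) / sd_r, 0.0)
    return z


def cosine_similarity_to(vectors: np.ndarray, center: np.ndarray) -> np.ndarray:
    num = vectors @ center
    den = np.linalg.norm(vectors, axis=1) * np.linalg.norm(center)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(den > 0, num / den, 0.0)
    return sim


@dataclass
class PathwayCluster:
    cluster_id: int
    members: list[str]
    representative_term: str
    member_similarity: dict[str, float] = field(default_factory=dict)
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)


def cluster_terms(term_ids: list[str], embeddings: pd.DataFrame,
                  k: int | None = None,
                  coordinates: pd.DataFrame | None = None) -> list[PathwayCluster]:
    """Meta-cluster pathway terms on their embeddings; pick an MRT each.

    Average-linkage agglomerative clustering on cosine distance. k is
    either fixed or chosen by the largest mean silhouette (cosine) over
    k in [2, min(10, n-1)]; degenerate geometry (all pairwise-identical
    directions) collapses to a single cluster. The MRT is the member most
    cosine-similar to its cluster's mean vector, ties broken
    lexicographically. Terms without an embedding are excluded with a
    warning. 2-D coordinates are presentation-only: taken from
    `coordinates` when given, else classical MDS of cosine distances.
    """
    missing = [t for t in term_ids if t not in embeddings.index]
    if missing:
        warnings.warn(f"terms without embeddings excluded: {sorted(missing)}")
    terms = sorted(t for t in term_ids if t in embeddings.index)
    if not terms:
        raise ValueError("no term has an embedding")
    x = embeddings.loc[terms].to_numpy(float)

    if len(terms) == 1:
        labels = np.zeros(1, dtype=int)
    elif k is not None:
        if not 1 <= k <= len(terms):
            raise ValueError("k out of range")
        labels = (np.arange(len(terms)) if k == len(terms)
                  else AgglomerativeClustering(n_clusters=k, metric="cosine",
                                               linkage="average").fit_predict(x))
    else:
        labels = _auto_k_labels(x)

    coords = _coordinates(terms, x, coordinates)
    clusters: list[PathwayCluster] = []
    for cid in sorted(set(int(l) for l in labels)):
        members = [t for t, l in zip(terms, labels) if int(l) == cid]
        vecs = embeddings.loc[members].to_numpy(float)
        sims = cosine_similarity_to(vecs, vecs.mean(axis=0))
        # highest similarity wins; exact ties go to the lexicographically first term
        best = sorted(range(len(members)), key=lambda i: (-sims[i], members[i]))[0]
        clusters.append(PathwayCluster(
            cluster_id=cid, members=members,
            representative_term=members[best],
            member_similarity={m: float(s) for m, s in zip(members, sims)},
            coordinates={m: coords[m] for m in members},
        ))
    return clusters


def _auto_k_labels(x: np.ndarray) -> np.ndarray:
    n = len(x)
    dirs = x / np.clip(np.linalg.norm(x, axis=1, keepdims=True), 1e-30, None)
    gram = np.clip(dirs @ dirs.T, -1.0, 1.0)
    if np.allclose(gram, 1.0, atol=1e-12):
        return np.zeros(n, dtype=int)  # all directions identical: one cluster
    best_k, best_score, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in range(2, min(10, n - 1) + 1):
        labels = AgglomerativeClustering(n_clusters=k, metric="cosine",
                                         linkage="average").fit_predict(x)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(x, labels, metric="cosine")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels
    return best_labels


def _coordinates(terms: list[str], x: np.ndarray,
                 provided: pd.DataFrame | None) -> dict[str, tuple[float, float]]:
    if provided is not None:
        out = {}
        for t in terms:
            if t in provided.index:
                out[t] = (float(provided.loc[t].iloc[0]), float(provided.loc[t].iloc[1]))
            else:
                out[t] = (np.nan, np.nan)
        return out
    # classical MDS on cosine distances (deterministic eigendecomposition)
    dirs = x / np.clip(np.linalg.norm(x, axis=1, keepdims=True), 1e-30, None)
    d = 1.0 - np.clip(dirs @ dirs.T, -1.0, 1.0)
    n = len(terms)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(n)])
    return {t: (float(coords[i, 0]), float(coords[i, 1])) for i, t in enumerate(terms)}


def cluster_heatmap_table(clusters: list[PathwayCluster],
                          scores: pd.DataFrame) -> pd.DataFrame:
    """Term x comparison score table ordered for the cluster heatmap.

    `scores` holds per-(term, comparison) enrichment scores (log combined
    score), NaN where a term was not tested in a comparison; missing cells
    are masked out of cluster means. Clusters are ordered by descending
    mean score, terms within a cluster by descending mean score.
    """
    rows = []
    for cl in clusters:
        present = [t for t in cl.members if t in scores.index]
        block = scores.loc[present]
        cluster_mean = float(np.nanmean(block.to_numpy(float))) if present else -np.inf
        term_means = block.mean(axis=1, skipna=True)
        for term in present:
            rows.append((cl.cluster_id, cl.representative_term, term,
                         cluster_mean, float(term_means[term])))
    if not rows:
        return pd.DataFrame(columns=["cluster_id", "representative_term", "term_id",
                                     *scores.columns])
    order = pd.DataFrame(rows, columns=["cluster_id", "representative_term",
                                        "term_id", "cluster_mean", "term_mean"])
    order = order.sort_values(["cluster_mean", "cluster_id", "term_mean", "term_id"],
                              ascending=[False, True, False, True], kind="stable")
    out = scores.loc[order["term_id"]].copy()
    out.insert(0, "cluster_id", order["cluster_id"].to_numpy())
    out.insert(1, "representative_term", order["representative_term"].to_numpy())
    return out
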