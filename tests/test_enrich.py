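"""ORA against exhaustive hypergeometric enumeration; term meta-clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from kinopipe import enrich


def _enumerated_upper_tail(overlap, universe, set_size, query):
    """P[X >= overlap] by summing the hypergeometric pmf with exact
    binomial coefficients — independent of scipy."""
    total = 0
    for j in range(overlap, min(set_size, query) + 1):
        total += (math.comb(set_size, j) * math.comb(universe - set_size, query - j))
    return total / math.comb(universe, query)


class TestOra:
    def test_perfect_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(10)}
        term = frozenset(sorted(universe)[:5])
        res = enrich.ora(set(term), {"T": term}, universe, score_mode="neglogp")
        assert res.loc["T", "p_value"] == pytest.approx(1 / 252)

    def test_expected_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(10)}
        term = frozenset(sorted(universe)[:4])
        query = set(sorted(universe)[2:7])  # overlap 2
        res = enrich.ora(query, {"T": term}, universe, score_mode="neglogp")
        assert res.loc["T", "overlap"] == 2
        assert res.loc["T", "p_value"] == pytest.approx(0.7380952, rel=1e-5)

    def test_single_term_fdr_equals_p(self):
        universe = {f"g{i}" for i in range(8)}
        term = frozenset(sorted(universe)[:3])
        res = enrich.ora(set(sorted(universe)[:4]), {"T": term}, universe,
                         score_mode="neglogp")
        assert res.loc["T", "fdr"] == res.loc["T", "p_value"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        n_u = int(rng.integers(6, 16))
        universe = {f"g{i}" for i in range(n_u)}
        genes = sorted(universe)
        library = {}
        for t in range(4):
            size = int(rng.integers(1, n_u))
            library[f"T{t}"] = frozenset(rng.choice(genes, size, replace=False))
        query = set(rng.choice(genes, int(rng.integers(1, n_u)), replace=False))
        res = enrich.ora(query, library, universe, score_mode="neglogp")
        for term, row in res.iterrows():
            expect = _enumerated_upper_tail(int(row["overlap"]), n_u,
                                            int(row["set_size"]), len(query))
            assert row["p_value"] == pytest.approx(expect, rel=1e-10)

    def test_bh_step_up_monotone(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        library = {f"T{t}": frozenset(rng.choice(genes, int(rng.integers(3, 15)),
                                                 replace=False))
                   for t in range(12)}
        res = enrich.ora(set(genes[:8]), library, set(genes), score_mode="neglogp")
        ordered = res.sort_values("p_value")
        assert (np.diff(ordered["fdr"]) >= -1e-12).all()
        assert ((res["fdr"] >= 0) & (res["fdr"] <= 1)).all()

    def test_combined_score_deterministic_under_seed(self):
        genes = [f"g{i}" for i in range(20)]
        library = {"T1": frozenset(genes[:6]), "T2": frozenset(genes[6:14])}
        r1 = enrich.ora(set(genes[:5]), library, set(genes), seed=4)
        r2 = enrich.ora(set(genes[:5]), library, set(genes), seed=4)
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrich.ora(set(), {"T": frozenset({"a"})}, {"a"})


class TestClusterTerms:
    def _bundles(self, n_per=4, dim=6, sep_noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, dim)
        b = -a + rng.normal(0, 0.1, dim)
        rows, names = [], []
        for i in range(n_per):
            rows.append(a + rng.normal(0, sep_noise, dim))
            names.append(f"A{i}")
        for i in range(n_per):
            rows.append(b + rng.normal(0, sep_noise, dim))
            names.append(f"B{i}")
        return pd.DataFrame(rows, index=names)

    def test_two_bundles_split_perfectly(self):
        emb = self._bundles()
        clusters = enrich.cluster_terms(list(emb.index), emb, k=2)
        groups = {frozenset(c.members) for c in clusters}
        assert groups == {frozenset({"A0", "A1", "A2", "A3"}),
                          frozenset({"B0", "B1", "B2", "B3"})}
        for c in clusters:
            vecs = emb.loc[c.members].to_numpy()
            sims = enrich.cosine_similarity_to(vecs, vecs.mean(axis=0))
            assert c.representative_term == c.members[int(np.argmax(sims))]

    def test_auto_k_finds_two_bundles(self):
        emb = self._bundles()
        clusters = enrich.cluster_terms(list(emb.index), emb, k=None)
        assert len(clusters) == 2

    def test_identical_vectors_single_cluster_lexicographic_mrt(self):
        emb = pd.DataFrame([[1.0, 2.0]] * 4, index=["t3", "t1", "t4", "t2"])
        clusters = enrich.cluster_terms(list(emb.index), emb, k=None)
        assert len(clusters) == 1
        assert clusters[0].representative_term == "t1"

    def test_k_equals_n_singletons(self):
        emb = self._bundles(n_per=2)
        clusters = enrich.cluster_terms(list(emb.index), emb, k=4)
        assert all(len(c.members) == 1 for c in clusters)
        assert all(c.representative_term == c.members[0] for c in clusters)

    def test_order_invariance(self):
        emb = self._bundles()
        c1 = enrich.cluster_terms(list(emb.index), emb, k=2)
        c2 = enrich.cluster_terms(list(reversed(emb.index)), emb, k=2)
        assert {frozenset(c.members) for c in c1} == {frozenset(c.members) for c in c2}
        assert {c.representative_term for c in c1} == {c.representative_term for c in c2}

    def test_missing_embedding_excluded_with_warning(self):
        emb = self._bundles(n_per=2)
        with pytest.warns(UserWarning, match="without embeddings"):
            clusters = enrich.cluster_terms(list(emb.index) + ["ghost"], emb, k=2)
        assert all("ghost" not in c.members for c in clusters)


class TestClusterHeatmapTable:
    def test_cluster_blocks_ordered_by_mean_score(self):
        clusters = [enrich.PathwayCluster(0, ["t1", "t2"], "t1"),
                    enrich.PathwayCluster(1, ["t3"], "t3")]
        scores = pd.DataFrame({"cmp1": {"t1": 3.0, "t2": 1.0, "t3": 5.0}})
        out = enrich.cluster_heatmap_table(clusters, scores)
        assert list(out.index) == ["t3", "t1", "t2"]  # cluster means 5.0 > 2.0

    def test_missing_cells_masked_from_cluster_mean(self):
        clusters = [enrich.PathwayCluster(0, ["t1", "t2"], "t1"),
                    enrich.PathwayCluster(1, ["t3"], "t3")]
        scores = pd.DataFrame({"cmp1": {"t1": 4.0, "t2": np.nan, "t3": 3.0}})
        out = enrich.cluster_heatmap_table(clusters, scores)
        # cluster 0 mean is 4.0 (NaN masked), so it outranks cluster 1
        assert list(out.index) == ["t1", "t2", "t3"]
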