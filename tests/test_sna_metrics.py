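"""Descriptives, Jaccard comparison, centralities and influencer selection."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from peerdiffusion.sna_metrics import (
    MetricError,
    SelectionError,
    centrality,
    density,
    jaccard_similarity,
    quota,
    select_influential,
    selection_overlap,
)

from oracles import (
    betweenness_centrality as oracle_betweenness,
    closeness_centrality as oracle_closeness,
    in_degree_centrality as oracle_in_degree,
)


def _dg(n, edges):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


class TestDensity:
    def test_examples(self):
        assert density(_dg(3, [(0, 1), (1, 2)])) == pytest.approx(1 / 3)
        complete = _dg(4, [(i, j) for i in range(4) for j in range(4) if i != j])
        assert density(complete) == 1.0

    def test_undefined_below_two_nodes(self):
        with pytest.raises(MetricError):
            density(_dg(1, []))


class TestJaccard:
    def test_partial_overlap(self):
        a = _dg(3, [(0, 1), (1, 2)])
        b = _dg(3, [(0, 1), (2, 0)])
        assert jaccard_similarity(a, b) == pytest.approx(1 / 3)

    def test_identical_is_one_disjoint_is_zero(self):
        a = _dg(4, [(0, 1), (2, 3), (3, 0)])
        assert jaccard_similarity(a, a.copy()) == 1.0
        b = _dg(4, [(1, 0), (3, 2)])
        assert jaccard_similarity(a, b) == 0.0

    def test_both_empty_is_undefined(self):
        with pytest.raises(MetricError):
            jaccard_similarity(_dg(3, []), _dg(3, []))

    def test_different_node_sets_rejected(self):
        with pytest.raises(MetricError):
            jaccard_similarity(_dg(3, [(0, 1)]), _dg(4, [(0, 1)]))

    @given(st.sets(st.tuples(st.integers(0, 4), st.integers(0, 4)).filter(
        lambda e: e[0] != e[1]), min_size=1, max_size=8),
        st.sets(st.tuples(st.integers(0, 4), st.integers(0, 4)).filter(
            lambda e: e[0] != e[1]), min_size=1, max_size=8))
    def test_symmetry_and_monotone_under_shared_edges(self, ea, eb):
        a, b = _dg(5, ea), _dg(5, eb)
        j = jaccard_similarity(a, b)
        assert j == pytest.approx(jaccard_similarity(b, a))
        # adding one shared new edge never decreases similarity
        missing = [(i, k) for i in range(5) for k in range(5)
                   if i != k and (i, k) not in ea | eb]
        if missing:
            ea2, eb2 = ea | {missing[0]}, eb | {missing[0]}
            assert jaccard_similarity(_dg(5, ea2), _dg(5, eb2)) >= j


class TestCentrality:
    def test_in_star_hub(self):
        g = _dg(4, [(1, 0), (2, 0), (3, 0)])
        assert centrality(g, "in_degree")[0] == 1.0

    def test_path_betweenness(self):
        g = _dg(3, [(0, 1), (1, 2)])
        bc = centrality(g, "betweenness")
        assert bc[1] == pytest.approx(0.5)  # 1 of 2 possible (s,t) pairs, normalized
        assert bc[0] == bc[2] == 0.0

    def test_isolated_node_closeness_zero(self):
        g = _dg(3, [(0, 1)])
        assert centrality(g, "closeness")[2] == 0.0

    def test_unknown_measure(self):
        with pytest.raises(ValueError, match="unknown"):
            centrality(_dg(2, []), "eigenvector")

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracles_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        edges = [(i, j) for i in range(n) for j in range(n)
                 if i != j and rng.random() < 0.35]
        g = _dg(n, edges)
        nodes = list(range(n))
        for got, want in [
            (centrality(g, "in_degree"), oracle_in_degree(nodes, edges)),
            (centrality(g, "betweenness"), oracle_betweenness(nodes, edges)),
            (centrality(g, "closeness"), oracle_closeness(nodes, edges)),
        ]:
            for v in nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-12)


class TestSelection:
    def test_quota_examples(self):
        assert quota(20) == 3
        assert {quota(s) for s in range(15, 30)} == {2, 3, 4}
        assert quota(30) == 5

    def _setup(self, scores, pals, n=None):
        n = n or len(scores)
        g = _dg(n, [])
        return g, {v: scores[v] for v in range(n)}, {v: pals[v] for v in range(n)}

    def test_ties_broken_by_pal(self):
        g, scores, pals = self._setup(
            scores=[0.9] + [0.5] * 19, pals=[1.0] * 20
        )
        scores[1] = scores[2] = 0.8  # two tied candidates for slots 2-3...
        pals[1], pals[2] = 0.8, 1.2
        sel = select_influential(g, scores, pals, "in_degree",
                                 rng=np.random.default_rng(0))
        assert sel.k == 3
        assert set(sel.selected) == {0, 1, 2}
        # force a one-slot contest: three tied, k=3, top spot fixed
        scores[3] = 0.8
        pals[3] = 1.1
        sel = select_influential(g, scores, pals, "in_degree",
                                 rng=np.random.default_rng(0))
        assert 2 in sel.selected and 3 in sel.selected and 1 not in sel.selected
        assert any("PAL" in line for line in sel.tie_log)

    def test_full_tie_is_seed_deterministic(self):
        g, scores, pals = self._setup(scores=[0.5] * 20, pals=[1.0] * 20)
        picks = {
            select_influential(g, scores, pals, "in_degree",
                               rng=np.random.default_rng(42)).selected
            for _ in range(3)
        }
        assert len(picks) == 1
        other = select_influential(g, scores, pals, "in_degree",
                                   rng=np.random.default_rng(43)).selected
        assert isinstance(other, tuple)  # different seed allowed to differ

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        n = 16
        edges = [(i, j) for i in range(n) for j in range(n) if i != j and rng.random() < 0.3]
        g = _dg(n, edges)
        scores = centrality(g, "in_degree")
        pals = {v: float(rng.uniform(0.5, 1.5)) for v in range(n)}
        sel = select_influential(g, scores, pals, "in_degree", rng=np.random.default_rng(1))
        perm = {v: (v * 5 + 3) % n + 100 for v in range(n)}
        g2 = nx.relabel_nodes(g, perm)
        sel2 = select_influential(
            g2, {perm[v]: scores[v] for v in scores}, {perm[v]: pals[v] for v in pals},
            "in_degree", rng=np.random.default_rng(1),
        )
        assert {perm[v] for v in sel.selected} == set(sel2.selected)

    def test_missing_pal_rejected(self):
        g = _dg(16, [])
        with pytest.raises(SelectionError, match="PAL"):
            select_influential(g, {v: 0.0 for v in range(16)},
                               {v: 1.0 for v in range(15)}, "in_degree")


class TestSelectionOverlap:
    def _sel(self, ids, class_id=1):
        from peerdiffusion.sna_metrics import InfluentialSelection
        return InfluentialSelection(class_id, "in_degree", tuple(ids), len(ids))

    def test_identical_and_disjoint_and_partial(self):
        assert selection_overlap(self._sel(range(63)), self._sel(range(63))) == (63, 1.0)
        assert selection_overlap(self._sel([1, 2]), self._sel([3, 4])) == (0, 0.0)
        assert selection_overlap(self._sel([1, 2, 3, 4]), self._sel([3, 4, 5, 6])) == (2, 0.5)

    def test_different_cohorts_rejected(self):
        with pytest.raises(MetricError):
            selection_overlap(self._sel([1], class_id=1), self._sel([1], class_id=2))
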