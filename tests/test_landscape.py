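"""Neighbor graph, graph distances, Leiden clustering and the Ward tree."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from modfuse.harmonize import fuse, harmonize_modality
from modfuse.landscape import (ClusterAssignment, FunctionalLandscape,
                               NeighborGraph, build_graph, embed,
                               graph_distances, leiden_cluster, ward_tree)
from modfuse.matrices import DistanceMatrix, FusedSimilarityMatrix
from modfuse.pipeline import modality_distance_matrices


def fused_from_world(world, weights=None):
    dms = modality_distance_matrices(world)
    harmonized = {m: harmonize_modality(dm) for m, dm in dms.items()}
    names = list(harmonized)
    weights = weights or {m: 1.0 for m in names}
    return fuse([harmonized[m] for m in names], weights, names)


@pytest.fixture(scope="module")
def clean_fused(clean_world):
    return fused_from_world(clean_world)


def block_similarity(n_blocks=2, size=5, within=0.9, between=0.1):
    n = n_blocks * size
    s = np.full((n, n), between)
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        s[sl, sl] = within
    np.fill_diagonal(s, 1.0)
    return FusedSimilarityMatrix([f"g{i}" for i in range(n)], s)


class TestBuildGraph:
    def test_nearest_neighbor_has_weight_one(self, clean_fused):
        g = build_graph(clean_fused, n_neighbors=10, random_state=0)
        d = clean_fused.dissimilarity()
        np.fill_diagonal(d, np.inf)
        a = g.adjacency.toarray()
        for i in range(g.n):
            assert a[i, np.argmin(d[i])] == pytest.approx(1.0)

    def test_symmetric_after_fuzzy_union(self, clean_fused):
        g = build_graph(clean_fused, n_neighbors=10, random_state=0)
        assert abs(g.adjacency - g.adjacency.T).max() < 1e-9

    def test_zero_noise_world_no_cross_cluster_edges(self, clean_world, clean_fused):
        """With between-cluster dissimilarities dominating, all 11-NN lists
        stay inside the planted clusters (cluster size 12, K = 4)."""
        labels = clean_world.planted_labels
        d = clean_fused.dissimilarity()
        np.fill_diagonal(d, np.inf)
        for i in range(len(labels)):  # oracle: check the k-NN lists directly
            nn = np.argsort(d[i])[:11]
            assert (labels[nn] == labels[i]).all()
        g = build_graph(clean_fused, n_neighbors=11, random_state=0)
        coo = sp.triu(g.adjacency, k=1).tocoo()
        assert (labels[coo.row] == labels[coo.col]).all()

    def test_too_many_neighbors_rejected(self, clean_fused):
        with pytest.raises(ValueError, match="n_neighbors"):
            build_graph(clean_fused, n_neighbors=len(clean_fused.ids))


class TestEmbed:
    def test_seeded_determinism_and_shape(self):
        g = build_graph(block_similarity(2, 8), n_neighbors=5, random_state=3)
        e1 = embed(g, n_epochs=50, random_state=42)
        e2 = embed(g, n_epochs=50, random_state=42)
        assert e1.shape == (16, 2)
        assert np.allclose(e1.values, e2.values)
        assert np.isfinite(e1.values).all()

    def test_zero_noise_world_embedding_separates_clusters(self, clean_world, clean_fused):
        g = build_graph(clean_fused, n_neighbors=11, random_state=0)
        coords = embed(g, n_epochs=100, random_state=0).values
        labels = clean_world.planted_labels
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()


class TestGraphDistances:
    def graph_from_edges(self, n, edges):
        a = np.zeros((n, n))
        for i, j, w in edges:
            a[i, j] = a[j, i] = w
        return NeighborGraph([f"v{i}" for i in range(n)], sp.csr_matrix(a))

    def test_unit_adjacency_unit_length(self):
        g = self.graph_from_edges(2, [(0, 1, 1.0)])
        assert graph_distances(g).values[0, 1] == pytest.approx(1.0)

    def test_exp_minus_one_length_two(self):
        g = self.graph_from_edges(2, [(0, 1, math.exp(-1))])
        assert graph_distances(g).values[0, 1] == pytest.approx(2.0)

    def test_six_node_graph_matches_bruteforce_path_enumeration(self, rng):
        n = 6
        edges = [(i, j, float(rng.uniform(0.05, 1.0)))
                 for i, j in itertools.combinations(range(n), 2)
                 if rng.random() < 0.6]
        edges += [(i, (i + 1) % n, float(rng.uniform(0.05, 1.0))) for i in range(n - 1)]
        seen = {}
        for i, j, w in edges:
            seen[(min(i, j), max(i, j))] = w
        g = self.graph_from_edges(n, [(i, j, w) for (i, j), w in seen.items()])
        got = graph_distances(g).values
        # oracle: minimize over all simple paths
        nxg = nx.Graph()
        for (i, j), w in seen.items():
            nxg.add_edge(i, j, length=1.0 - math.log(w))
        for i, j in itertools.combinations(range(n), 2):
            best = min(
                sum(nxg[u][v]["length"] for u, v in zip(path, path[1:]))
                for path in nx.all_simple_paths(nxg, i, j))
            assert got[i, j] == pytest.approx(best)

    def test_triangle_inequality_exact(self, clean_fused):
        g = build_graph(clean_fused, n_neighbors=11, random_state=0)
        d = graph_distances(g).values
        d = np.where(np.isnan(d), np.inf, d)
        n = d.shape[0]
        sub = np.arange(0, n, 3)
        for i in sub:
            for j in sub:
                for k in sub:
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_lowering_adjacency_never_shrinks_distances(self):
        g1 = self.graph_from_edges(4, [(0, 1, 0.9), (1, 2, 0.8), (2, 3, 0.7),
                                       (0, 3, 0.5)])
        d1 = graph_distances(g1).values
        g2 = self.graph_from_edges(4, [(0, 1, 0.9), (1, 2, 0.4), (2, 3, 0.7),
                                       (0, 3, 0.5)])
        d2 = graph_distances(g2).values
        assert (d2 >= d1 - 1e-12).all()

    def test_unreachable_pairs_marked(self):
        g = self.graph_from_edges(4, [(0, 1, 0.9), (2, 3, 0.9)])
        d = graph_distances(g).values
        assert np.isnan(d[0, 2]) and np.isfinite(d[0, 1])


class TestLeiden:
    def test_two_cliques_two_clusters(self):
        g = build_graph(block_similarity(2, 8), n_neighbors=5, random_state=0)
        res = leiden_cluster(g, seed=0)
        assert res.n_clusters == 2
        assert res.modularity > 0.3

    def test_seeded_determinism(self):
        g = build_graph(block_similarity(3, 6), n_neighbors=4, random_state=0)
        r1 = leiden_cluster(g, seed=9)
        r2 = leiden_cluster(g, seed=9)
        assert (r1.labels == r2.labels).all()

    def test_zero_noise_world_perfect_recovery(self, clean_world, clean_fused):
        g = build_graph(clean_fused, n_neighbors=11, random_state=0)
        res = leiden_cluster(g, seed=0)
        assert adjusted_rand_score(clean_world.planted_labels, res.labels) == 1.0


def naive_ward(d):
    """O(n^3) Ward agglomeration via the Lance-Williams update."""
    n = d.shape[0]
    d = d.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, h))
        na, nb = sizes[a], sizes[b]
        new = {}
        for k in active:
            if k in (a, b):
                continue
            nk = sizes[k]
            dak = dist[(min(a, k), max(a, k))]
            dbk = dist[(min(b, k), max(b, k))]
            dab = h
            val = math.sqrt(((na + nk) * dak ** 2 + (nb + nk) * dbk ** 2
                             - nk * dab ** 2) / (na + nb + nk))
            new[k] = val
        active = [k for k in active if k not in (a, b)]
        dist = {(i, j): v for (i, j), v in dist.items()
                if i not in (a, b) and j not in (a, b)}
        for k, v in new.items():
            dist[(min(nxt, k), max(nxt, k))] = v
        sizes[nxt] = na + nb
        active.append(nxt)
        nxt += 1
    return merges


class TestWardTree:
    def make_dm(self, v):
        v = np.asarray(v, dtype=float)
        return DistanceMatrix([chr(65 + i) for i in range(v.shape[0])], v)

    def test_two_entities_cherry(self):
        t = ward_tree(self.make_dm([[0, 2.0], [2.0, 0]]))
        assert t.newick.count(",") == 1
        assert "A" in t.newick and "B" in t.newick and t.newick.endswith(";")

    def test_closest_pair_merges_first(self):
        d = np.array([[0, 0.1, 5, 5], [0.1, 0, 5, 5], [5, 5, 0, 4], [5, 5, 4, 0]])
        t = ward_tree(self.make_dm(d))
        assert set(t.linkage[0, :2].astype(int)) == {0, 1}

    def test_merge_order_matches_naive_ward(self, rng):
        x = rng.normal(size=(8, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        t = ward_tree(self.make_dm(d))
        oracle = naive_ward(d)
        scipy_sets = _merge_sets(t.linkage, 8)
        oracle_sets = _merge_sets(
            np.array([[a, b, h, 0] for a, b, h in oracle]), 8)
        assert scipy_sets == oracle_sets
        for row, (_, _, h) in zip(t.linkage, oracle):
            assert row[2] == pytest.approx(h)

    def test_missing_pairs_rejected(self):
        v = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="complete"):
            ward_tree(DistanceMatrix(["A", "B", "C"], v))

    def test_newick_branch_lengths_are_sqrt_height_differences(self):
        d = np.array([[0, 1.0, 6, 6], [1.0, 0, 6, 6], [6, 6, 0, 2.0], [6, 6, 2.0, 0]])
        t = ward_tree(self.make_dm(d))
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(t.newick), "newick")
        leaf = {cl.name: cl for cl in tree.get_terminals()}
        root_h = math.sqrt(t.linkage[-1, 2])
        for name in "ABCD":
            assert tree.distance(leaf[name]) == pytest.approx(root_h, abs=1e-9)


def _merge_sets(linkage, n):
    """Sequence of frozen leaf sets produced by each merge."""
    clusters = {i: frozenset([i]) for i in range(n)}
    out = []
    for idx, row in enumerate(linkage):
        a, b = int(row[0]), int(row[1])
        merged = clusters[a] | clusters[b]
        clusters[n + idx] = merged
        out.append(merged)
    return out


class TestFunctionalLandscape:
    def test_estimator_fit_sets_attributes(self, clean_world, clean_fused):
        model = FunctionalLandscape(n_neighbors=11, n_epochs=50, random_state=0)
        labels = model.fit_predict(clean_fused)
        assert len(labels) == len(clean_fused.ids)
        assert model.embedding_.shape == (len(labels), 2)
        assert model.modularity_ > 0
        assert adjusted_rand_score(clean_world.planted_labels, model.labels_) == 1.0

    def test_get_params_supports_model_selection(self):
        model = FunctionalLandscape(resolution=0.5)
        assert model.get_params()["resolution"] == 0.5
        model.set_params(n_neighbors=7)
        assert model.n_neighbors == 7
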