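"""Evaluation statistics: silhouette, ANOSIM, AMI, enrichment, F1, skewness."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from modfuse.evaluation import (adjusted_mutual_information, anosim, enrichment,
                                micro_f1_agreement, pair_count, silhouette,
                                skewness)


def euclidean(points):
    p = np.asarray(points, dtype=float)
    return np.linalg.norm(p[:, None] - p[None, :], axis=-1)


class TestSilhouette:
    def test_tight_separated_clusters_score_high(self):
        pts = [[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]]
        per_entity, per_cluster = silhouette(euclidean(pts), [0, 0, 0, 1, 1, 1])
        assert (per_cluster > 0.9).all()

    def test_singleton_cluster_scores_zero(self):
        pts = [[0, 0], [0.1, 0], [5, 5]]
        _, per_cluster = silhouette(euclidean(pts), [0, 0, 1])
        assert per_cluster.loc[1] == 0.0

    def test_equidistant_points_score_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        per_entity, _ = silhouette(d, [0, 0, 1, 1])
        assert np.allclose(per_entity.values, 0.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette(np.zeros((3, 3)), [0, 0, 0])

    def test_cap_policy_scores_disconnected_components(self):
        d = euclidean([[0, 0], [0.1, 0], [9, 9], [9.1, 9]])
        d[0:2, 2:4] = np.nan
        d[2:4, 0:2] = np.nan
        per_entity, _ = silhouette(d, [0, 0, 1, 1], unreachable="cap")
        assert len(per_entity) == 4
        assert (per_entity > 0.9).all()


def anosim_r_bruteforce(d, labels):
    from scipy.stats import rankdata

    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu, ju])
    within = labels[iu] == labels[ju]
    m = len(ranks)
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


class TestAnosim:
    def test_perfect_separation_r_one(self):
        pts = [[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]]
        res = anosim(euclidean(pts), [0, 0, 0, 1, 1, 1], permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_five_point_r_matches_exhaustive_label_permutations(self, rng):
        d = euclidean(rng.normal(size=(5, 2)))
        labels = np.array([0, 0, 1, 1, 1])
        res = anosim(d, labels, permutations=10, seed=0)
        assert res.r == pytest.approx(anosim_r_bruteforce(d, labels))
        # exhaustive permutation distribution: p from all 5! relabelings
        count = sum(
            anosim_r_bruteforce(d, np.array(perm)) >= res.r - 1e-12
            for perm in itertools.permutations(labels))
        exact_p = count / math.factorial(5)
        # the add-one Monte-Carlo estimate must agree within sampling error
        res_big = anosim(d, labels, permutations=2000, seed=1)
        assert res_big.p_value == pytest.approx(exact_p, abs=0.05)

    def test_pvalue_bounds(self):
        pts = [[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]]
        res = anosim(euclidean(pts), [0, 0, 0, 1, 1, 1], permutations=49, seed=2)
        assert 1 / 50 <= res.p_value <= 1.0

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anosim(np.zeros((4, 4)), [0, 0, 0, 0])
        with pytest.raises(ValueError, match="2 members"):
            anosim(np.ones((4, 4)) - np.eye(4), [0, 0, 0, 1])


class TestAMI:
    def test_identical_labelings(self):
        assert adjusted_mutual_information([0, 0, 1, 1], [5, 5, 7, 7]) == pytest.approx(1.0)

    def test_independent_labelings_near_zero(self, rng):
        a = rng.integers(0, 4, size=200)
        b = rng.integers(0, 4, size=200)
        assert abs(adjusted_mutual_information(a, b)) < 0.05

    def test_invariant_to_renaming(self, rng):
        a = rng.integers(0, 3, size=50)
        b = rng.integers(0, 3, size=50)
        assert adjusted_mutual_information(a, b) == pytest.approx(
            adjusted_mutual_information(a, (b + 7) % 11))

    def test_both_single_class_is_one(self):
        assert adjusted_mutual_information([0] * 5, [3] * 5) == 1.0


def hypergeom_tail_bruteforce(k, N, K, n):
    """P(X >= k) by explicit binomial-coefficient enumeration."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


class TestEnrichment:
    def test_hand_example_76_over_15504(self):
        clusters = {f"g{i}": (0 if i < 5 else 1) for i in range(20)}
        props = {f"g{i}": "hit" for i in [0, 1, 2, 3, 7]}  # 4 of 5 inside
        table = enrichment(clusters, props)
        row = table[(table.cluster == 0) & (table.label == "hit")].iloc[0]
        assert row.p_value == pytest.approx(76 / 15504)

    def test_single_carrier_label_omitted(self):
        clusters = {"a": 0, "b": 0, "c": 1, "d": 1}
        table = enrichment(clusters, {"a": "solo", "c": "duo", "d": "duo"})
        assert "solo" not in set(table.label)
        assert "duo" in set(table.label)

    def test_bh_adjustment_step_up(self):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adjusted, [0.03, 0.03, 0.03])

    def test_bh_monotone_and_adjusted_geq_raw(self, rng):
        clusters = {f"g{i}": int(i % 3) for i in range(24)}
        props = {f"g{i}": {f"L{rng.integers(0, 4)}", f"L{rng.integers(0, 4)}"}
                 for i in range(24)}
        table = enrichment(clusters, props)
        assert (table.p_adjusted >= table.p_value - 1e-12).all()
        s = table.sort_values("p_value")
        assert (np.diff(s.p_adjusted.values) >= -1e-12).all()

    def test_p_matches_exhaustive_enumeration_universe_25(self, rng):
        n = 25
        clusters = {f"g{i}": int(rng.integers(0, 3)) for i in range(n)}
        props = {f"g{i}": ("yes" if rng.random() < 0.4 else "no") for i in range(n)}
        table = enrichment(clusters, props)
        for _, row in table.iterrows():
            expected = hypergeom_tail_bruteforce(
                int(row.count_in_cluster), int(row.universe),
                int(row.count_overall), int(row.cluster_size))
            assert row.p_value == pytest.approx(expected, rel=1e-12)

    def test_multilabel_entity_contributes_each_label(self):
        clusters = {"a": 0, "b": 0, "c": 1, "d": 1}
        props = {"a": {"PM", "ER"}, "b": {"PM"}, "c": {"ER"}, "d": {"PM"}}
        table = enrichment(clusters, props)
        assert set(table.label) == {"PM", "ER"}


class TestMicroF1:
    def test_identical_annotations(self):
        ann = {"g1": {"PM"}, "g2": {"ER", "PM"}}
        score = micro_f1_agreement(ann, ann)
        assert score.f1 == 1.0 and score.precision == 1.0

    def test_hand_example_f1_04(self):
        a = {"g1": {"PM", "ER"}, "g2": {"PM"}}
        b = {"g1": {"PM"}, "g2": {"ER"}}
        score = micro_f1_agreement(a, b)
        assert score.precision == pytest.approx(1 / 3)
        assert score.recall == pytest.approx(1 / 2)
        assert score.f1 == pytest.approx(0.4)

    def test_disjoint_zero(self):
        assert micro_f1_agreement({"g": {"PM"}}, {"g": {"ER"}}).f1 == 0.0

    def test_swap_symmetry(self):
        a = {"g1": {"PM", "ER"}, "g2": {"PM"}}
        b = {"g1": {"PM"}, "g2": {"ER"}, "g3": {"NU"}}
        s1, s2 = micro_f1_agreement(a, b), micro_f1_agreement(b, a)
        assert s1.f1 == pytest.approx(s2.f1)
        assert s1.precision == pytest.approx(s2.recall)


class TestSkewness:
    def test_symmetric_zero(self):
        assert skewness([1, 2, 3]) == 0.0

    def test_right_tail_positive(self):
        assert skewness([1, 1, 1, 10]) > 0

    def test_seven_values_match_direct_moments(self):
        x = np.array([2.0, 5, 1, 7, 3, 3, 9])
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        assert skewness(x) == pytest.approx(m3 / m2 ** 1.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            skewness([4, 4, 4])


class TestPairCount:
    @pytest.mark.parametrize("n,expected", [(447, 99681), (2, 1), (4, 6)])
    def test_values(self, n, expected):
        assert pair_count(n) == expected

    def test_matches_enumeration(self):
        assert pair_count(7) == len(list(itertools.combinations(range(7), 2)))
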