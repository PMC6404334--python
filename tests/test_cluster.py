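import math
from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import homogeneity_completeness_v_measure

from gsepd.cluster import (
    derive_term_seed,
    evaluate_terms,
    kmeans2,
    permutation_pvalue,
    v_measure,
)
from gsepd.model import Config, Contrast, GeneSet, GeneSetCollection, SampleTable, ValidationError


# ------------------------------------------------------------------ oracles

def brute_force_min_within_ss(points: np.ndarray) -> float:
    """Exhaustive minimum 2-cluster within-SS over all bipartitions."""
    n = len(points)
    best = math.inf
    for r in range(1, n // 2 + 1):
        for left in combinations(range(n), r):
            mask = np.zeros(n, dtype=bool)
            mask[list(left)] = True
            ss = 0.0
            for part in (points[mask], points[~mask]):
                if len(part):
                    ss += float(((part - part.mean(axis=0)) ** 2).sum())
            best = min(best, ss)
    return best


def brute_force_v(class_labels, cluster_labels, base=math.e):
    """Independent contingency-table entropy computation of (h, c, v)."""

    def H(counts):
        n = sum(counts)
        return -sum((c / n) * math.log(c / n, base) for c in counts if c > 0) if n else 0.0

    classes = sorted(set(class_labels))
    clusters = sorted(set(cluster_labels))
    n = len(class_labels)
    cont = {
        (a, k): sum(1 for x, y in zip(class_labels, cluster_labels) if x == a and y == k)
        for a in classes
        for k in clusters
    }
    h_c = H([sum(cont[a, k] for k in clusters) for a in classes])
    h_k = H([sum(cont[a, k] for a in classes) for k in clusters])
    h_c_k = sum(
        (sum(cont[a, k] for a in classes) / n) * H([cont[a, k] for a in classes])
        for k in clusters
    )
    h_k_c = sum(
        (sum(cont[a, k] for k in clusters) / n) * H([cont[a, k] for k in clusters])
        for a in classes
    )
    h = 1.0 if h_c == 0 else 1 - h_c_k / h_c
    c = 1.0 if h_k == 0 else 1 - h_k_c / h_k
    v = 0.0 if h + c == 0 else 2 * h * c / (h + c)
    return h, c, v


# ------------------------------------------------------------------ k-means

class TestKMeans2:
    def test_separated_blobs_recovered(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        res = kmeans2(pts, seed=0)
        labels = res["labels"]
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert res["within_ss"] == pytest.approx(0.01, abs=1e-12)

    def test_two_points_split_with_zero_ss(self):
        res = kmeans2(np.array([[0.0, 0.0], [3.0, 4.0]]), seed=0)
        assert sorted(res["labels"]) == [0, 1]
        assert res["within_ss"] == 0.0

    def test_identical_points_degenerate(self, caplog):
        res = kmeans2(np.ones((4, 3)), seed=0)
        assert (res["labels"] == 0).all()
        assert res["within_ss"] == 0.0
        assert np.allclose(res["centroids"][0], res["centroids"][1])

    @pytest.mark.parametrize("n,dim", [(5, 1), (6, 2), (8, 3), (8, 1)])
    def test_small_instances_reach_bipartition_optimum(self, n, dim):
        rng = np.random.default_rng(100 * n + dim)
        for rep in range(10):
            pts = rng.normal(size=(n, dim))
            res = kmeans2(pts, seed=rep)
            assert res["within_ss"] == pytest.approx(
                brute_force_min_within_ss(pts), rel=1e-9
            )

    def test_larger_instances_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 4))
        a = kmeans2(pts, seed=5)
        b = kmeans2(pts, seed=5)
        assert np.array_equal(a["labels"], b["labels"])
        assert a["within_ss"] == b["within_ss"]

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            kmeans2(np.zeros((1, 2)), seed=0)


# ---------------------------------------------------------------- V-measure

class TestVMeasure:
    def test_perfect_agreement(self):
        h, c, v = v_measure(["A", "A", "B", "B"], [1, 1, 0, 0])
        assert (h, c, v) == (1.0, 1.0, 1.0)

    def test_independent_labels_give_zero(self):
        h, c, v = v_measure(["A", "A", "B", "B"], [0, 1, 0, 1])
        assert (h, c, v) == (0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        h, c, v = v_measure(["A", "A", "A", "B"], [0, 0, 1, 1])
        assert h == pytest.approx(0.3836885465963443, abs=1e-12)
        assert c == pytest.approx(0.3112781244591328, abs=1e-10)
        assert v == pytest.approx(0.3437110184854507, abs=1e-10)

    def test_matches_brute_force_on_all_6sample_combinations(self):
        """Agrees with an independent contingency-entropy oracle over every
        2^6 x 2^6 label/cluster pair on 6 samples."""
        n = 6
        for lbits in range(2**n):
            labels = [("A", "B")[lbits >> i & 1] for i in range(n)]
            for kbits in range(0, 2**n, 7):  # stride keeps this test quick
                clusters = [kbits >> i & 1 for i in range(n)]
                assert v_measure(labels, clusters) == pytest.approx(
                    brute_force_v(labels, clusters), abs=1e-12
                )

    def test_log_base_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            labels = rng.choice(["A", "B"], size=8)
            clusters = rng.integers(0, 2, size=8)
            assert v_measure(labels, clusters) == pytest.approx(
                brute_force_v(list(labels), list(clusters), base=2), abs=1e-12
            )

    def test_symmetric_under_index_and_label_swaps(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            labels = rng.choice(["A", "B"], size=7)
            clusters = rng.integers(0, 2, size=7)
            v0 = v_measure(labels, clusters)[2]
            assert v_measure(labels, 1 - clusters)[2] == pytest.approx(v0, abs=1e-12)
            swapped = np.where(labels == "A", "B", "A")
            assert v_measure(swapped, clusters)[2] == pytest.approx(v0, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            labels = rng.choice(["A", "B"], size=9)
            clusters = rng.integers(0, 2, size=9)
            assert v_measure(labels, clusters) == pytest.approx(
                homogeneity_completeness_v_measure(labels, clusters), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            v_measure(["A", "B"], [0, 1, 0])


# ---------------------------------------------------- permutation p-value

def enumerate_exact_p(cluster_labels, class_labels, observed_v, strict=False):
    """Oracle: exact exceedance proportion over all distinct assignments."""
    vals = sorted(set(class_labels))
    n = len(class_labels)
    n_a = sum(1 for x in class_labels if x == vals[0])
    e = total = 0
    for pos in combinations(range(n), n_a):
        perm = [vals[1]] * n
        for i in pos:
            perm[i] = vals[0]
        v = brute_force_v(perm, list(cluster_labels))[2]
        total += 1
        if (v > observed_v + 1e-12) if strict else (v >= observed_v - 1e-12):
            e += 1
    return max(e, 1) / total, total


class TestPermutationPvalue:
    @pytest.mark.parametrize(
        "labels,clusters",
        [
            (["A", "A", "B", "B"], [0, 0, 1, 1]),
            (["A", "A", "B", "B"], [0, 1, 1, 1]),
            (["A", "A", "A", "B", "B", "B"], [0, 0, 0, 1, 1, 1]),
            (["A", "A", "A", "B", "B", "B"], [0, 1, 0, 1, 0, 1]),
        ],
    )
    def test_small_designs_match_exhaustive_enumeration(self, labels, clusters):
        """2v2 (6 assignments) and 3v3 (20) resolve exactly, matching an
        independent full enumeration."""
        v_obs = v_measure(labels, clusters)[2]
        p, n_used = permutation_pvalue(clusters, labels, v_obs, Config(), seed=0)
        p_exact, total = enumerate_exact_p(clusters, labels, v_obs)
        assert p == pytest.approx(p_exact, abs=1e-12)
        assert n_used == total

    def test_observed_zero_stops_early_in_sampling_mode(self):
        # 6v6: 924 distinct assignments > budget, so sampling kicks in;
        # v >= 0 always, so exceedances accumulate immediately
        labels = ["A"] * 6 + ["B"] * 6
        clusters = [0, 1] * 6
        p, n_used = permutation_pvalue(clusters, labels, 0.0, Config(), seed=3)
        assert n_used == 10  # early stop at 10 exceedances
        assert p == pytest.approx(1.0)

    def test_no_exceedances_gives_plus_one_floor(self):
        # all-same clusters force every permuted v to 0 < observed 1.0
        labels = ["A"] * 6 + ["B"] * 6
        clusters = [0] * 12
        p, n_used = permutation_pvalue(clusters, labels, 1.0, Config(), seed=0)
        assert n_used == 400
        assert p == pytest.approx(1 / 401, abs=1e-12)

    def test_strict_mode_excludes_ties(self):
        labels = ["A", "A", "B", "B"]
        clusters = [0, 0, 1, 1]
        v_obs = 1.0
        p_ge, _ = permutation_pvalue(clusters, labels, v_obs, Config(), seed=0)
        p_gt, _ = permutation_pvalue(
            clusters, labels, v_obs, Config(strict_exceedance=True), seed=0
        )
        # identity and its complement both reach v=1: ties count only under >=
        assert p_ge == pytest.approx(2 / 6)
        assert p_gt == pytest.approx(1 / 6)  # floored at one exceedance


# ----------------------------------------------------------- evaluate_terms

class TestEvaluateTerms:
    def _study(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(40)]
        cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        data = rng.normal(8, 1, size=(40, 6))
        data[:5, 3:] += 6.0  # first five genes separate the groups
        norm = pd.DataFrame(data, index=genes, columns=cols)
        st = SampleTable(
            pd.DataFrame(
                {"sample_id": cols, "condition": ["A"] * 3 + ["B"] * 3, "short_label": cols}
            )
        )
        coll = GeneSetCollection(
            {
                "T_sep": GeneSet("T_sep", "separating", frozenset(genes[:5])),
                "T_big": GeneSet("T_big", "too big", frozenset(genes)),
                "T_one": GeneSet("T_one", "singleton", frozenset(genes[:1])),
                "T_noise": GeneSet("T_noise", "noise", frozenset(genes[20:25])),
            }
        )
        return norm, st, coll

    def test_size_filters_and_segregation(self):
        norm, st, coll = self._study()
        cfg = Config(m=31, seed=1)
        res = evaluate_terms(["T_sep", "T_big", "T_one", "T_noise"], coll, norm, st, Contrast("A", "B"), cfg)
        res = res.set_index("term_id")
        assert res.loc["T_big", "skip_reason"].startswith("size >= m")
        assert res.loc["T_one", "skip_reason"].startswith("below min_set_size")
        assert res.loc["T_sep", "v"] == pytest.approx(1.0)
        # 3v3 -> exhaustive over 20 assignments; only identity + complement reach v=1
        assert res.loc["T_sep", "p_empirical"] == pytest.approx(2 / 20)

    def test_boundary_size_equal_m_is_skipped(self):
        norm, st, coll = self._study()
        cfg = Config(m=5, min_set_size=2, seed=1)
        res = evaluate_terms(["T_sep"], coll, norm, st, Contrast("A", "B"), cfg).set_index("term_id")
        assert res.loc["T_sep", "skip_reason"].startswith("size >= m")

    def test_term_seed_is_stable_and_bounded(self):
        s1 = derive_term_seed(42, "GO:0001234")
        s2 = derive_term_seed(42, "GO:0001234")
        s3 = derive_term_seed(42, "GO:0001235")
        assert s1 == s2 != s3
        assert 0 <= s1 < 2**31
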