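"""Selection algorithms against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from kcomplex.feature_selection import (
    FeatureMatrix,
    cfs,
    cfs_merit,
    discretize_equal_frequency,
    inconsistency_rate,
    interact,
    relieff,
    relieff_weights,
    select_features,
    sfs,
    symmetrical_uncertainty,
)
from conftest import make_informative_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_inconsistency(Xd, y, subset):
    """Dict-based grouping, written independently of the implementation."""
    groups = {}
    for row, label in zip(Xd[:, list(subset)], y):
        groups.setdefault(tuple(row), []).append(label)
    total = 0
    for labels in groups.values():
        counts = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        total += len(labels) - max(counts.values())
    return total / len(y)


def oracle_entropy(counts):
    n = sum(counts)
    return -sum(c / n * math.log2(c / n) for c in counts if c)


def oracle_sfs_consistency(Xd, y):
    """Brute-force enumeration of every non-empty subset; ties to the
    smaller then lexicographically earlier subset."""
    F = Xd.shape[1]
    best, best_val = None, np.inf
    for size in range(1, F + 1):
        for combo in itertools.combinations(range(F), size):
            v = oracle_inconsistency(Xd, y, combo)
            if v < best_val - 1e-12:
                best, best_val = combo, v
    return best, best_val


def xor_matrix(n=120, seed=3):
    """Two features useless alone, perfect jointly, plus a noise column."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    y = a ^ b
    noise = rng.normal(0, 1, n)
    X = np.column_stack([a.astype(float), b.astype(float), noise])
    return FeatureMatrix(X, y, ["fa", "fb", "fnoise"])


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

class TestReliefF:
    def test_constant_feature_zero_weight(self):
        X, y, names = make_informative_matrix(seed=1)
        X[:, 1] = 5.0
        W = relieff_weights(X, y)
        assert W[1] == 0.0

    def test_label_like_feature_top_ranked(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 100)
        X = np.column_stack([y.astype(float), rng.normal(0, 1, (200, 4))])
        W = relieff_weights(X, y, k_neighbors=10)
        assert np.argmax(W) == 0
        fm = FeatureMatrix(X, y, ["label_copy", "n1", "n2", "n3", "n4"])
        assert relieff(fm).selected == ["label_copy"]

    def test_label_permutation_shrinks_selection(self):
        X, y, names = make_informative_matrix(n=200, seed=6, shift=4.0)
        fm = FeatureMatrix(X, y, names)
        n_real = len(relieff(fm).selected)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        W = relieff_weights(X, y_perm)
        W_real = relieff_weights(X, y)
        # informative structure gone: the top raw weight collapses
        assert W.max() < W_real.max()
        assert n_real >= 1

    def test_single_class_fails(self):
        fm = FeatureMatrix(np.random.default_rng(0).normal(size=(10, 2)),
                           np.zeros(10, int), ["a", "b"])
        with pytest.raises(ValueError):
            relieff(fm)

    def test_deterministic_under_seed(self):
        X, y, names = make_informative_matrix(seed=2)
        fm = FeatureMatrix(X, y, names)
        r1 = relieff(fm, num_samples=50, seed=9)
        r2 = relieff(fm, num_samples=50, seed=9)
        assert r1.scores["weights_raw"] == r2.scores["weights_raw"]


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

class TestCFS:
    def test_merit_hand_values(self):
        rcf = np.array([0.8, 0.8])
        # fully redundant pair: no gain over a singleton
        rff_redundant = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert cfs_merit(rcf, rff_redundant, (0,)) == pytest.approx(0.8)
        assert cfs_merit(rcf, rff_redundant, (0, 1)) == pytest.approx(1.6 / math.sqrt(4))
        # independent pair beats either singleton
        rff_indep = np.eye(2)
        assert cfs_merit(rcf, rff_indep, (0, 1)) == pytest.approx(1.6 / math.sqrt(2))

    def test_prefers_complementary_pair(self):
        rng = np.random.default_rng(8)
        n = 400
        s1 = rng.normal(0, 1, n)
        s2 = rng.normal(0, 1, n)
        y = ((s1 + s2) > 0).astype(int)
        X = np.column_stack([s1, s2, rng.normal(0, 1, n)])
        res = cfs(FeatureMatrix(X, y, ["s1", "s2", "junk"]))
        assert set(res.selected) >= {"s1", "s2"}
        assert "junk" not in res.selected

    def test_zero_variance_feature_warned_not_fatal(self, caplog):
        X, y, names = make_informative_matrix(seed=4)
        X[:, 2] = 1.0
        res = cfs(FeatureMatrix(X, y, names))
        assert names[2] not in res.selected

    def test_column_order_invariant(self):
        X, y, names = make_informative_matrix(seed=10)
        fm = FeatureMatrix(X, y, names)
        perm = [2, 0, 3, 1]
        fm2 = FeatureMatrix(X[:, perm], y, [names[j] for j in perm])
        assert set(cfs(fm).selected) == set(cfs(fm2).selected)


# ---------------------------------------------------------------------------
# inconsistency rate
# ---------------------------------------------------------------------------

class TestInconsistencyRate:
    def test_hand_example(self):
        Xd = np.array([[0], [0], [0], [1]])
        y = np.array([1, 1, 0, 0])
        assert inconsistency_rate(Xd, y) == pytest.approx(0.25)

    def test_perfect_separation_zero(self):
        Xd = np.array([[0], [0], [1], [1]])
        y = np.array([0, 0, 1, 1])
        assert inconsistency_rate(Xd, y) == 0.0

    def test_fifty_fifty_pattern(self):
        Xd = np.zeros((10, 1), int)
        y = np.array([0, 1] * 5)
        assert inconsistency_rate(Xd, y) == 0.5

    def test_oracle_equivalence_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 50))
            F = int(rng.integers(1, 5))
            Xd = rng.integers(0, 3, (n, F))
            y = rng.integers(0, 2, n)
            subset = list(range(F))
            assert inconsistency_rate(Xd, y, subset) == pytest.approx(
                oracle_inconsistency(Xd, y, subset)
            )

    def test_monotone_under_feature_addition(self, rng):
        for _ in range(30):
            Xd = rng.integers(0, 4, (40, 4))
            y = rng.integers(0, 2, 40)
            for k in range(1, 4):
                wide = inconsistency_rate(Xd, y, list(range(k + 1)))
                narrow = inconsistency_rate(Xd, y, list(range(k)))
                assert wide <= narrow + 1e-12


# ---------------------------------------------------------------------------
# SFS
# ---------------------------------------------------------------------------

class TestSFS:
    def test_perfect_feature_singleton(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        X = np.column_stack([y.astype(float), rng.normal(0, 1, (60, 3))])
        res = sfs(FeatureMatrix(X, y, ["perfect", "a", "b", "c"]), "consistency")
        assert res.selected == ["perfect"]
        assert res.scores["measure_value"] == 0.0

    def test_matches_bruteforce_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, F = 40, 4
            Xd_source = rng.integers(0, 3, (n, F)).astype(float)
            y = rng.integers(0, 2, n)
            fm = FeatureMatrix(Xd_source, y, [f"f{j}" for j in range(F)])
            res = sfs(fm, "consistency", bins=10)
            Xd = discretize_equal_frequency(Xd_source, 10)
            best, best_val = oracle_sfs_consistency(Xd, y)
            assert res.scores["measure_value"] == pytest.approx(best_val)
            assert [fm.names[j] for j in best] == res.selected

    def test_xor_pair_found(self):
        fm = xor_matrix()
        res = sfs(fm, "consistency")
        assert res.selected == ["fa", "fb"]

    def test_classifier_error_measure(self):
        X, y, names = make_informative_matrix(n=60, n_noise=2, seed=7, shift=5.0)
        fm = FeatureMatrix(X, y, names)
        res = sfs(fm, "classifier_error", seed=1)
        assert "good" in res.selected
        assert res.scores["measure_value"] < 0.1

    def test_unknown_measure(self):
        fm = xor_matrix()
        with pytest.raises(ValueError, match="measure"):
            sfs(fm, "entropy")

    def test_best_first_fallback_beyond_cap(self, caplog):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        X = np.column_stack([y.astype(float), rng.normal(0, 1, (80, 4))])
        fm = FeatureMatrix(X, y, [f"f{j}" for j in range(5)])
        res = sfs(fm, "consistency", max_exhaustive=3)
        assert res.params["search"] == "best_first"
        assert res.selected == ["f0"]  # perfect feature still found


# ---------------------------------------------------------------------------
# symmetrical uncertainty
# ---------------------------------------------------------------------------

class TestSymmetricalUncertainty:
    def test_identical_is_one(self, rng):
        y = rng.integers(0, 2, 100)
        assert symmetrical_uncertainty(y, y) == pytest.approx(1.0)

    def test_independent_is_zero(self):
        f = np.tile([0, 1], 50)
        y = np.repeat([0, 1], 50)
        assert symmetrical_uncertainty(f, y) == pytest.approx(0.0, abs=1e-12)

    def test_joint_table_oracle(self):
        # joint counts [[2,1],[1,2]], n = 6
        f = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        hf = oracle_entropy([3, 3])
        hy = oracle_entropy([3, 3])
        hfy = oracle_entropy([2, 1, 1, 2])
        expected = 2 * (hf + hy - hfy) / (hf + hy)
        assert symmetrical_uncertainty(f, y) == pytest.approx(expected)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(30):
            f = rng.integers(0, 4, 50)
            y = rng.integers(0, 2, 50)
            su = symmetrical_uncertainty(f, y)
            assert su == pytest.approx(symmetrical_uncertainty(y, f))
            assert 0.0 <= su <= 1.0

    def test_constant_variable_zero(self):
        assert symmetrical_uncertainty(np.zeros(10, int), np.arange(10) % 2) == 0.0


# ---------------------------------------------------------------------------
# INTERACT
# ---------------------------------------------------------------------------

class TestInteract:
    def test_noise_feature_removed(self):
        # a label-consistent feature leaves the noise columns with no
        # consistency contribution: removing them changes the rate by ~0
        rng = np.random.default_rng(9)
        n = 300
        y = rng.integers(0, 2, n)
        X = np.column_stack([y.astype(float), rng.normal(0, 1, (n, 2))])
        names = ["good", "noise0", "noise1"]
        res = interact(FeatureMatrix(X, y, names), bins=5)
        assert res.selected == ["good"]
        assert abs(res.scores["c_contribution"]["noise0"]) <= 1e-4

    def test_xor_pair_retained(self):
        fm = xor_matrix(n=200, seed=13)
        res = interact(fm, bins=5)
        assert {"fa", "fb"} <= set(res.selected)
        assert "fnoise" not in res.selected

    def test_single_informative_feature_kept(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 80)
        fm = FeatureMatrix(y.astype(float).reshape(-1, 1), y, ["only"])
        assert interact(fm).selected == ["only"]

    def test_survivors_in_su_order(self):
        fm = xor_matrix(n=200, seed=13)
        res = interact(fm, bins=5)
        sus = [res.scores["su"][n] for n in res.selected]
        assert sus == sorted(sus, reverse=True)


def test_dispatch_unknown_method():
    fm = xor_matrix()
    with pytest.raises(ValueError, match="unknown selection method"):
        select_features(fm, "mrmr")
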