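"""Discretization, mutual information, mRMR ranking and IFS."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosthr.errors import ParameterError
from phosthr.selection import (
    IfsCurve,
    discretize,
    discretize_matrix,
    ifs,
    mi_matrix,
    mrmr_rank,
    mutual_information,
)

code_vectors = st.lists(st.integers(min_value=0, max_value=2), min_size=4, max_size=40)


class TestDiscretize:
    def test_constant_feature_all_mid(self):
        np.testing.assert_array_equal(discretize([3.0] * 5), [1] * 5)

    def test_hand_computed_cut_points(self):
        # values {-10, 0, 10}: sigma = sqrt(200/3) ~ 8.165, cuts at +/- 8.165
        np.testing.assert_array_equal(discretize([-10.0, 0.0, 10.0]), [0, 1, 2])

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(discretize(x), discretize(3.5 * x - 7.0))

    def test_matrix_form_matches_columnwise(self, rng):
        X = rng.standard_normal((30, 6))
        M = discretize_matrix(X)
        for j in range(6):
            np.testing.assert_array_equal(M[:, j], discretize(X[:, j]))


class TestMutualInformation:
    def test_identity_two_equiprobable_states(self):
        x = [0, 1] * 10
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_uniform_near_zero(self, rng):
        x = rng.integers(0, 2, size=5000)
        y = rng.integers(0, 2, size=5000)
        assert mutual_information(x, y) < 0.01

    def test_printed_joint_table_brute_force(self):
        # joint counts {(0,0):4, (0,1):1, (1,0):1, (1,1):4}
        x = [0] * 5 + [1] * 5
        y = [0, 0, 0, 0, 1, 0, 1, 1, 1, 1]
        n = 10.0
        expected = 0.0
        counts = {(0, 0): 4, (0, 1): 1, (1, 0): 1, (1, 1): 4}
        for (a, b), c in counts.items():
            pxy = c / n
            px = sum(v for k, v in counts.items() if k[0] == a) / n
            py = sum(v for k, v in counts.items() if k[1] == b) / n
            expected += pxy * math.log2(pxy / (px * py))
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ParameterError):
            mutual_information([0, 1], [0, 1, 2])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(code_vectors, code_vectors)
    def test_symmetry_and_nonnegativity(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = xs[:n], ys[:n]
        mi = mutual_information(x, y)
        assert mi >= 0
        assert mi == pytest.approx(mutual_information(y, x))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(code_vectors)
    def test_self_information_is_entropy(self, xs):
        x = np.asarray(xs)
        _, counts = np.unique(x, return_counts=True)
        p = counts / counts.sum()
        entropy = -(p * np.log2(p)).sum()
        assert mutual_information(x, x) == pytest.approx(entropy)

    def test_agrees_with_sklearn_estimator(self, rng):
        from sklearn.metrics import mutual_info_score

        x = rng.integers(0, 3, size=200)
        y = rng.integers(0, 3, size=200)
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / math.log(2)
        )

    def test_mi_matrix_matches_pairwise_calls(self, rng):
        codes = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        M = mi_matrix(codes)
        for i in range(5):
            for j in range(5):
                assert M[i, j] == pytest.approx(
                    mutual_information(codes[:, i], codes[:, j]), abs=1e-10
                )


def _exhaustive_mid_greedy(X, y):
    """Reference mRMR-MID: literal greedy over all remaining features."""
    n_feat = X.shape[1]
    codes = [discretize(X[:, j]) for j in range(n_feat)]
    _, yc = np.unique(y, return_inverse=True)
    rel = [mutual_information(c, yc) for c in codes]
    order = [int(np.argmax(rel))]
    while len(order) < n_feat:
        best_f, best_score = None, -np.inf
        for f in range(n_feat):
            if f in order:
                continue
            red = np.mean([mutual_information(codes[f], codes[s]) for s in order])
            score = rel[f] - red
            if score > best_score:
                best_f, best_score = f, score
        order.append(best_f)
    return order


class TestMrmrRank:
    def test_label_copy_ranks_first(self, rng):
        y = rng.integers(0, 2, size=40)
        X = np.column_stack([rng.standard_normal(40), y.astype(float),
                             rng.standard_normal(40)])
        assert mrmr_rank(X, y).order[0] == 1

    def test_duplicate_of_top_feature_deferred(self, rng):
        # f0 = strong signal, f1 = its copy, f2 = independent weaker signal
        y = np.repeat([0, 1], 30)
        f0 = y + 0.05 * rng.standard_normal(60)
        f2 = y + 0.8 * rng.standard_normal(60)
        X = np.column_stack([f0, f0.copy(), f2, rng.standard_normal(60)])
        order = list(mrmr_rank(X, y).order)
        assert order[0] == 0
        assert order.index(2) < order.index(1)

    @pytest.mark.parametrize("n_feat", [3, 5, 8])
    def test_matches_exhaustive_greedy_oracle(self, rng, n_feat):
        for _ in range(3):
            X = rng.standard_normal((30, n_feat))
            y = rng.integers(0, 2, size=30)
            assert list(mrmr_rank(X, y).order) == _exhaustive_mid_greedy(X, y)

    def test_full_ranking_of_216_features(self, rng):
        X = rng.standard_normal((25, 216))
        y = rng.integers(0, 2, size=25)
        order = mrmr_rank(X, y).order
        assert sorted(order.tolist()) == list(range(216))


class TestIfs:
    def test_one_evaluation_per_prefix(self, rng):
        X = rng.standard_normal((20, 7))
        y = rng.integers(0, 2, size=20)
        calls = []

        def spy(Xs, ys):
            calls.append(Xs.shape[1])
            return 0.5

        curve = ifs(X, y, mrmr_rank(X, y), evaluator=spy)
        assert calls == list(range(1, 8))
        assert len(curve.k) == 7
        assert curve.best_k == 1  # all tie -> smallest prefix

    def test_single_feature_curve(self, rng):
        X = rng.standard_normal((10, 1))
        y = np.repeat([0, 1], 5)
        curve = ifs(X, y, [0], evaluator=lambda Xs, ys: 0.9)
        assert curve.best_k == 1 and len(curve.k) == 1

    def test_prefix_completeness_at_full_width(self, rng):
        X = rng.standard_normal((16, 5))
        y = rng.integers(0, 2, size=16)
        ranking = mrmr_rank(X, y)

        def frac_positive(Xs, ys):  # deterministic stand-in evaluator
            return float(Xs.sum()) % 1.0

        curve = ifs(X, y, ranking, evaluator=frac_positive)
        assert curve.auroc[-1] == pytest.approx(frac_positive(X[:, ranking.order], y))

    def test_informative_features_found_early(self, rng):
        # 5 informative + 50 noise features; best prefix should be small
        # and never worse than using everything
        from phosthr.evaluate import jackknife_auroc

        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 60
            y = np.repeat([0, 1], n // 2)
            informative = np.outer(y, np.ones(5)) + 0.6 * r.standard_normal((n, 5))
            noise = r.standard_normal((n, 50))
            X = np.hstack([informative, noise])
            perm = r.permutation(55)
            X = X[:, perm]
            curve = ifs(X, y, mrmr_rank(X, y), evaluator=jackknife_auroc)
            peak = curve.auroc.max()
            if curve.best_k <= 15 and peak >= curve.auroc[-1]:
                hits += 1
        assert hits >= 4
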