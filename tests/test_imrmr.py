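import dataclasses
import itertools
import math
import warnings
from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from salpvote.dataset_io import ExpressionDataset
from salpvote.imrmr import (
    IMRMRConfig,
    discretize,
    imrmr_select,
    mutual_information,
    pearson_correlation,
    redundancy,
    relevance,
    sweep_alpha,
)


def _dataset(X, y):
    n, p = X.shape
    return ExpressionDataset(X, [f"g{j}" for j in range(p)],
                             [f"s{i}" for i in range(n)], y)


def mi_bits_oracle(a, b):
    """Independent plug-in MI in bits by direct joint-table enumeration."""
    n = len(a)
    joint = Counter(zip(a, b))
    pa, pb = Counter(a), Counter(b)
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / ((pa[x] / n) * (pb[y] / n)))
    return mi


class TestDiscretize:
    def test_equal_frequency_codes(self):
        assert discretize([1, 2, 3, 4, 5, 6], 3).tolist() == [0, 0, 1, 1, 2, 2]

    def test_constant_all_zero(self):
        assert discretize([7.0] * 5, 4).tolist() == [0] * 5

    def test_deterministic(self):
        v = np.random.default_rng(0).normal(size=30)
        np.testing.assert_array_equal(discretize(v, 3), discretize(v, 3))


class TestMutualInformation:
    def test_identical_binary_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_constant_partner_zero(self):
        assert mutual_information([0, 1, 2, 0], [5, 5, 5, 5]) == 0.0

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))
        assert mutual_information(a, b) >= 0

    def test_exhaustive_small_joint_tables(self):
        """Plug-in estimate matches direct enumeration on every 3x3 table, n <= 5."""
        cells = list(itertools.product(range(3), repeat=2))
        for n in range(2, 6):
            for counts in itertools.combinations_with_replacement(range(len(cells)), n):
                a = [cells[k][0] for k in counts]
                b = [cells[k][1] for k in counts]
                assert mutual_information(a, b) == pytest.approx(
                    max(mi_bits_oracle(a, b), 0.0), abs=1e-12
                )

    def test_matches_sklearn_in_bits(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 200)
        b = (a + rng.integers(0, 2, 200)) % 4
        assert mutual_information(a, b) == pytest.approx(
            mutual_info_score(a, b) / math.log(2), abs=1e-10
        )


class TestPearson:
    def test_affine_and_inverse(self):
        a = np.array([1.0, 2, 3, 4])
        assert pearson_correlation(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson_correlation(a, -a) == pytest.approx(-1.0)

    def test_orthogonal_patterns(self):
        assert pearson_correlation([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0)

    def test_constant_input_warns_zero(self):
        with pytest.warns(UserWarning):
            assert pearson_correlation([1, 1, 1], [1, 2, 3]) == 0.0


class TestRelevanceRedundancy:
    def test_alpha_one_collapses_to_mi(self):
        rng = np.random.default_rng(3)
        fi = rng.normal(size=60)
        fc = rng.integers(0, 2, 60)
        assert relevance(fi, fc, alpha=1.0, n_bins=3) == pytest.approx(
            mutual_information(discretize(fi, 3), fc)
        )

    def test_blend_arithmetic(self):
        rng = np.random.default_rng(4)
        fi = rng.normal(size=50)
        fc = rng.integers(0, 3, 50)
        mi = mutual_information(discretize(fi, 3), fc)
        r = abs(pearson_correlation(fi, fc.astype(float)))
        assert relevance(fi, fc, alpha=0.5, n_bins=3) == pytest.approx(0.5 * mi + 0.5 * r)

    def test_independent_noise_low_relevance(self):
        rng = np.random.default_rng(5)
        fi = rng.normal(size=200)
        fc = rng.integers(0, 2, 200)
        assert relevance(fi, fc, alpha=0.5, n_bins=3) < 0.1

    def test_identical_single_partner(self):
        rng = np.random.default_rng(6)
        fi = rng.normal(size=80)
        # Mrd against one identical feature: alpha*H(fi) + (1-alpha)*1
        h = mutual_information(discretize(fi, 3), discretize(fi, 3))  # self-MI = entropy
        assert redundancy(fi, fi.copy(), alpha=0.6, n_bins=3) == pytest.approx(
            0.6 * h + 0.4 * 1.0
        )

    def test_duplicate_raises_redundancy(self):
        rng = np.random.default_rng(7)
        fi = rng.normal(size=100)
        dup_set = np.column_stack([fi + rng.normal(0, 0.05, 100), rng.normal(size=100)])
        indep_set = rng.normal(size=(100, 2))
        assert redundancy(fi, dup_set, 0.5) > redundancy(fi, indep_set, 0.5)

    def test_independent_features_low_redundancy(self):
        rng = np.random.default_rng(8)
        fi = rng.normal(size=400)
        others = rng.normal(size=(400, 5))
        assert redundancy(fi, others, 0.5) < 0.1


class TestSelection:
    def _random_instance(self, seed, n=50, p=20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, n)
        X[:, 0] += y * 2.0
        X[:, 1] += y * 1.5
        return _dataset(X, y)

    def test_oneshot_alpha1_matches_bruteforce_mrmr(self):
        """MI-only scores agree with an independent sklearn-based reimplementation."""
        ds = self._random_instance(9)
        scores = imrmr_select(ds, IMRMRConfig(alpha=1.0, n_bins=3))
        X, y = ds.values, ds.encoded_labels
        p = X.shape[1]
        codes = [discretize(X[:, j], 3) for j in range(p)]
        ln2 = math.log(2)
        rel = np.array([mutual_info_score(c, y) / ln2 for c in codes])
        red = np.array([
            np.mean([mutual_info_score(codes[i], codes[j]) / ln2
                     for j in range(p) if j != i])
            for i in range(p)
        ])
        np.testing.assert_allclose(scores.mre, rel, atol=1e-10)
        np.testing.assert_allclose(scores.mrd, red, atol=1e-10)
        expected_order = np.argsort(-(rel - red), kind="stable")
        expected = [ds.gene_ids[j] for j in expected_order if (rel - red)[j] > 0]
        assert scores.selected_ids == expected[:500]

    def test_greedy_alpha1_matches_classical_mrmr_order(self):
        ds = self._random_instance(10, n=40, p=15)
        got = imrmr_select(ds, IMRMRConfig(alpha=1.0, mode="greedy", max_features=15))
        X, y = ds.values, ds.encoded_labels
        codes = [discretize(X[:, j], 3) for j in range(15)]
        ln2 = math.log(2)
        rel = [mutual_info_score(c, y) / ln2 for c in codes]
        selected, remaining = [], list(range(15))
        while remaining:
            best_j, best_s = None, -np.inf
            for j in remaining:
                red = (np.mean([mutual_info_score(codes[j], codes[k]) / ln2
                                for k in selected]) if selected else 0.0)
                s = rel[j] - red
                if s > best_s:
                    best_j, best_s = j, s
            if selected and best_s <= 0:
                break
            selected.append(best_j)
            remaining.remove(best_j)
        assert got.selected_ids == [ds.gene_ids[j] for j in selected]

    def test_noisy_duplicate_ranks_below_source(self):
        rng = np.random.default_rng(11)
        n = 80
        y = rng.integers(0, 2, n)
        source = rng.normal(size=n) + y * 2.5
        dup = source + rng.normal(0, 0.2, n)
        noise = rng.normal(size=(n, 4))
        ds = _dataset(np.column_stack([source, dup, noise]), y)
        scores = imrmr_select(ds, IMRMRConfig(alpha=0.5))
        assert scores.score[1] < scores.score[0]
        if "g1" in scores.selected_ids:
            assert scores.selected_ids.index("g1") > scores.selected_ids.index("g0")

    def test_score_identity_and_cap(self):
        ds = self._random_instance(12)
        cfg = IMRMRConfig(alpha=0.7, max_features=3)
        scores = imrmr_select(ds, cfg)
        np.testing.assert_allclose(scores.score, scores.mre - scores.mrd, atol=1e-12)
        assert len(scores.selected_ids) <= 3
        assert imrmr_select(ds, cfg).selected_ids == scores.selected_ids  # deterministic


class TestSweepAlpha:
    def test_singleton_grid(self, small_dataset):
        ds, truth = small_dataset
        sub = ds.subset_genes(truth.informative_ids + truth.noise_ids[:5])
        alpha, diag = sweep_alpha(sub, IMRMRConfig(alpha_grid=(0.3,)))
        assert alpha == 0.3 and len(diag) == 1

    def test_constant_evaluator_ties_to_largest_alpha(self, small_dataset):
        ds, truth = small_dataset
        sub = ds.subset_genes(truth.informative_ids + truth.noise_ids[:5])
        alpha, _ = sweep_alpha(sub, IMRMRConfig(alpha_grid=(0.2, 0.5, 0.9)),
                               evaluator=lambda X, y: 0.5)
        assert alpha == 0.9

    def test_nonlinear_signal_prefers_mi(self):
        # symmetric, uncorrelated signal: class decides the magnitude, sign random
        rng = np.random.default_rng(13)
        n = 120
        y = np.repeat([0, 1], n // 2)
        sign = rng.choice([-1.0, 1.0], size=n)
        informative = np.where(y == 1, sign * 3.0, rng.normal(0, 0.5, n))
        X = np.column_stack([informative, rng.normal(size=(n, 3))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert abs(pearson_correlation(informative, y.astype(float))) < 0.25
            alpha, _ = sweep_alpha(_dataset(X, y), IMRMRConfig(max_features=2))
        assert alpha >= 0.5
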