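"""Statistics checked against independent oracles (scipy/sklearn/pingouin or
explicit closed-form arithmetic)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from asgo import psychometrics as psy


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.arange(1.0, 21.0)
        rho, _ = psy.spearman_rho(x, np.exp(x / 5.0))
        assert rho == pytest.approx(1.0)
        rho, _ = psy.spearman_rho(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_example_rank_then_pearson(self):
        # ranks are the values themselves; d = (-1, 1, -1, 1, 0), sum d^2 = 4
        rho, _ = psy.spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(1 - 6 * 4 / (5 * 24))  # = 0.8

    @pytest.mark.parametrize("n", [12, 40, 150])
    def test_matches_scipy_with_ties(self, n):
        rng = np.random.default_rng(n)
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float) + 0.3 * x
        rho, p = psy.spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        # n=5 without ties, rho = 0.8: |rho| >= 0.8 iff sum d^2 <= 4, which
        # happens for 8 of the 120 permutations on each tail -> p = 16/120
        import itertools

        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = psy.spearman_rho(x, y)
        count = 0
        for perm in itertools.permutations(range(1, 6)):
            d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, perm))
            r = 1 - 6 * d2 / (5 * 24)
            count += abs(r) >= abs(rho) - 1e-12
        assert p == pytest.approx(count / 120, abs=1e-12)
        assert p == pytest.approx(16 / 120, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(psy.DegenerateDataError):
            psy.spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @given(
        x=arrays(
            float,
            st.integers(min_value=11, max_value=30),
            elements=st.floats(-50, 50, allow_nan=False),
            unique=True,
        ),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, deadline=None)
    def test_classic_d_squared_formula_without_ties(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.permutation(len(x)).astype(float)
        rho, _ = psy.spearman_rho(x, y)
        rx = sps.rankdata(x)
        d2 = float(((rx - (y + 1)) ** 2).sum())
        n = len(x)
        assert rho == pytest.approx(1 - 6 * d2 / (n * (n * n - 1)), abs=1e-10)


# ---------------------------------------------------------------------------
# Cronbach alpha


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        col = np.array([1.0, 3.0, 2.0, 5.0])
        assert psy.cronbach_alpha(np.column_stack([col] * 4)) == pytest.approx(1.0)

    def test_zero_covariance_two_items(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        assert psy.cronbach_alpha(X) == pytest.approx(0.0)

    def test_hand_matrix_spreadsheet_arithmetic(self):
        # item variances (n-1): 5/3, 13/3, 20/3; total-score variance 106/3
        X = np.array([[1, 2, 3], [2, 4, 5], [3, 5, 7], [4, 7, 9]], dtype=float)
        expected = (3 / 2) * (1 - (5 / 3 + 13 / 3 + 20 / 3) / (106 / 3))
        assert psy.cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5)) + rng.normal(size=(60, 1))
        ref = pingouin.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert psy.cronbach_alpha(X) == pytest.approx(ref, abs=1e-10)

    def test_constant_totals_rejected(self):
        X = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        with pytest.raises(psy.DegenerateDataError):
            psy.cronbach_alpha(X)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_covariance_form_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(5, 40), rng.integers(2, 8)))
        X += rng.normal(size=(X.shape[0], 1))  # shared component
        C = np.cov(X, rowvar=False)
        k = X.shape[1]
        ones = np.ones(k)
        expected = (k / (k - 1)) * (1 - np.trace(C) / float(ones @ C @ ones))
        assert psy.cronbach_alpha(X) == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# ROC / AUC / Youden


def mann_whitney_auc(scores, truth):
    """Pairwise-comparison oracle: (concordant + ties/2) / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos, neg = scores[truth], scores[~truth]
    wins = ties = 0
    for p in pos:
        wins += np.sum(p > neg)
        ties += np.sum(p == neg)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_youden(scores, truth):
    """Brute-force J over every unique-score threshold (and +inf)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    best = (0.0, math.inf)  # (J, threshold); J=0 at the +inf sentinel
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = np.sum(pred & truth) / truth.sum()
        spec = np.sum(~pred & ~truth) / (~truth).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and thr < best[1]):
            best = (j, thr)
    return best[1], best[0]


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        truth = np.array([False, False, False, True, True, True])
        curve = psy.roc_curve(scores, truth)
        assert psy.auc(curve) == pytest.approx(1.0)
        # passes through (FPR 0, TPR 1)
        assert np.any((curve.fpr == 0.0) & (curve.sensitivity == 1.0))
        cutoff, j = psy.youden_optimal_cutoff(curve)
        assert j == pytest.approx(1.0)
        assert 3.0 < cutoff <= 10.0

    def test_degenerate_all_equal_scores(self):
        curve = psy.roc_curve([5.0] * 6, [True, False] * 3)
        assert sorted(curve.fpr) == pytest.approx([0.0, 1.0, 1.0])
        assert psy.auc(curve) == pytest.approx(0.5)
        _, j = psy.youden_optimal_cutoff(curve)
        assert j == pytest.approx(0.0)

    def test_six_point_hand_example_matches_enumeration(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        truth = np.array([False, False, True, False, True, True])
        curve = psy.roc_curve(scores, truth)
        # independent enumeration over thresholds at observed scores
        expected = {(0.0, 1.0)}  # +inf sentinel: sens 0, spec 1
        for thr in scores:
            pred = scores >= thr
            expected.add(
                (
                    float(np.sum(pred & truth) / 3),
                    float(np.sum(~pred & ~truth) / 3),
                )
            )
        expected.add((1.0, 0.0))  # -inf sentinel
        got = set(zip(curve.sensitivity.tolist(), curve.specificity.tolist()))
        assert got == expected

    def test_single_class_rejected(self):
        with pytest.raises(psy.DegenerateDataError):
            psy.roc_curve([1.0, 2.0, 3.0], [True, True, True])

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(size=10_000)
        truth = rng.random(10_000) < 0.5
        assert psy.auc(psy.roc_curve(scores, truth)) == pytest.approx(0.5, abs=0.02)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        truth = rng.random(200) < 0.4
        scores = truth * 1.0 + rng.normal(size=200)
        scores = np.round(scores, 1)  # induce ties
        curve = psy.roc_curve(scores, truth)
        assert psy.auc(curve) == pytest.approx(
            sklearn_metrics.roc_auc_score(truth, scores), abs=1e-12
        )

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=50, deadline=None)
    def test_auc_equals_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        truth = np.zeros(n, dtype=bool)
        truth[: int(rng.integers(1, n))] = True
        rng.shuffle(truth)
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        scores = np.round(rng.normal(size=n) + truth, 1)
        curve = psy.roc_curve(scores, truth)
        assert psy.auc(curve) == pytest.approx(mann_whitney_auc(scores, truth), abs=1e-12)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=50, deadline=None)
    def test_youden_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        scores = np.round(rng.normal(size=n) + 0.8 * truth, 1)
        cutoff, j = psy.youden_optimal_cutoff(psy.roc_curve(scores, truth))
        exp_cutoff, exp_j = exhaustive_youden(scores, truth)
        assert j == pytest.approx(exp_j, abs=1e-12)
        assert cutoff == pytest.approx(exp_cutoff)

    def test_midpoint_threshold_placement(self):
        scores = np.array([10.0, 20.0, 20.0, 30.0])
        truth = np.array([False, False, True, True])
        curve = psy.roc_curve(scores, truth, midpoint=True)
        finite = curve.thresholds[np.isfinite(curve.thresholds)]
        assert set(finite.tolist()) == {31.0, 25.0, 15.0}


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "cells, sens, spec",
        [
            ((130, 126, 82, 454), 130 / 212, 454 / 580),
            ((333, 129, 41, 289), 333 / 374, 289 / 418),
            ((10, 0, 0, 10), 1.0, 1.0),
        ],
    )
    def test_sensitivity_specificity(self, cells, sens, spec):
        table = psy.ConfusionTable(*cells)
        got_sens, got_spec = psy.sensitivity_specificity(table)
        assert got_sens == pytest.approx(sens)
        assert got_spec == pytest.approx(spec)

    def test_empty_margin_rejected(self):
        with pytest.raises(psy.DegenerateDataError):
            psy.sensitivity_specificity(psy.ConfusionTable(0, 5, 0, 5))


# ---------------------------------------------------------------------------
# KMO / Bartlett


def equicorrelation(p, r):
    return (1 - r) * np.eye(p) + r * np.ones((p, p))


def kmo_oracle(R):
    """Independently coded KMO via explicit matrix inversion."""
    S = np.linalg.inv(R)
    p = R.shape[0]
    r2 = q2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            r2 += R[i, j] ** 2
            q2 += (-S[i, j] / math.sqrt(S[i, i] * S[j, j])) ** 2
    return r2 / (r2 + q2)


class TestKmo:
    def test_two_by_two_is_half(self):
        assert psy.kmo(equicorrelation(2, 0.6)) == pytest.approx(0.5)
        assert psy.kmo(equicorrelation(2, -0.3)) == pytest.approx(0.5)

    def test_equicorrelated_hand_inversion(self):
        # R^-1 for p=3, r=0.5 has diagonal 1.5, off-diagonal -0.5
        # => q = 1/3, KMO = (6*0.25)/(6*0.25 + 6/9) = 9/13
        assert psy.kmo(equicorrelation(3, 0.5)) == pytest.approx(9 / 13, abs=1e-12)

    def test_near_singular_rejected(self):
        R = equicorrelation(4, 0.999999999)
        with pytest.raises((psy.DegenerateDataError, np.linalg.LinAlgError)):
            psy.kmo(R)

    def test_identity_rejected(self):
        with pytest.raises(psy.DegenerateDataError):
            psy.kmo(np.eye(5))

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_matches_explicit_inversion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 6)) + 0.6 * rng.normal(size=(50, 1))
        R = np.corrcoef(X, rowvar=False)
        assert psy.kmo(R) == pytest.approx(kmo_oracle(R), abs=1e-10)


class TestBartlett:
    def test_identity_gives_zero(self):
        chi2, df, p = psy.bartlett_sphericity(np.eye(6), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 15
        assert p == pytest.approx(1.0)

    def test_equicorrelated_closed_form_determinant(self):
        # det R = (1-r)^2 (1+2r) for p=3 equicorrelated
        r, n, p = 0.3, 100, 3
        det = (1 - r) ** 2 * (1 + 2 * r)
        expected = -(n - 1 - (2 * p + 5) / 6) * math.log(det)
        chi2, df, _ = psy.bartlett_sphericity(equicorrelation(3, r), n=n)
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert df == 3

    def test_df_for_ten_items(self):
        _, df, _ = psy.bartlett_sphericity(np.eye(10), n=842)
        assert df == 45

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_matches_explicit_determinant_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 5)) + 0.4 * rng.normal(size=(80, 1))
        R = np.corrcoef(X, rowvar=False)
        n = 80
        chi2, df, p = psy.bartlett_sphericity(R, n=n)
        expected = -(n - 1 - (2 * 5 + 5) / 6) * math.log(np.linalg.det(R))
        assert chi2 == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(float(sps.chi2.sf(expected, df)), abs=1e-12)


# ---------------------------------------------------------------------------
# PCA-EFA and varimax


class TestPcaEfa:
    def test_printed_eigenvalue_sequence_retains_two(self):
        eigenvalues = [3.86, 1.08, 0.96, 0.76, 0.72, 0.66, 0.56, 0.52, 0.48, 0.35]
        assert psy.count_kaiser_factors(eigenvalues) == 2

    def test_eigenvalues_sum_to_item_count(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 10)) + 0.5 * rng.normal(size=(200, 1))
        solution = psy.pca_efa(X)
        assert solution.eigenvalues.sum() == pytest.approx(10.0)
        assert solution.cumulative_pct[-1] == pytest.approx(100.0)
        assert np.all(np.diff(solution.eigenvalues) <= 1e-12)

    def test_matches_sklearn_pca_spectrum(self):
        decomposition = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(12)
        X = rng.normal(size=(150, 6)) + rng.normal(size=(150, 1))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = decomposition.PCA().fit(Z)
        assert psy.pca_efa(X).eigenvalues == pytest.approx(ref.explained_variance_, abs=1e-8)

    def test_loadings_reproduce_correlation_matrix(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(100, 5)) + rng.normal(size=(100, 1))
        solution = psy.pca_efa(X, n_factors=5)
        R = np.corrcoef(X, rowvar=False)
        assert solution.loadings @ solution.loadings.T == pytest.approx(R, abs=1e-8)

    def test_constant_item_rejected(self):
        X = np.ones((30, 4))
        X[:, :3] = np.random.default_rng(1).normal(size=(30, 3))
        with pytest.raises(psy.DegenerateDataError):
            psy.pca_efa(X)


def planted_loadings(rng, p=10, k=2, strength=0.8):
    L = np.full((p, k), 0.1)
    for i in range(p):
        L[i, i % k] = strength
    return L


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.9, 0.8, 0.85]
        L[3:, 1] = [0.88, 0.82, 0.9]
        rotated = psy.varimax(L)
        # equal up to column permutation (columns come back ordered by
        # explained variance, signs fixed positive)
        assert any(
            np.allclose(rotated[:, list(perm)], L, atol=1e-8)
            for perm in ((0, 1), (1, 0))
        )

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_communalities_preserved_and_rotation_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(int(rng.integers(5, 12)), int(rng.integers(2, 4)))) * 0.5
        rotated = psy.varimax(L)
        assert (rotated**2).sum(axis=1) == pytest.approx((L**2).sum(axis=1), abs=1e-10)
        R, *_ = np.linalg.lstsq(L, rotated, rcond=None)
        assert R.T @ R == pytest.approx(np.eye(L.shape[1]), abs=1e-8)

    def test_criterion_never_decreases(self):
        rng = np.random.default_rng(21)
        L = rng.normal(size=(10, 3)) * 0.4
        rotated = psy.varimax(L, kaiser_normalize=False)
        sq_in, sq_out = L**2, rotated**2
        assert sq_out.var(axis=0).sum() >= sq_in.var(axis=0).sum() - 1e-12

    def test_recovers_planted_two_block_structure(self):
        rng = np.random.default_rng(33)
        true_L = np.zeros((10, 2))
        true_L[:6, 0], true_L[6:, 1] = 0.8, 0.8
        F = rng.normal(size=(800, 2))
        X = F @ true_L.T + 0.5 * rng.normal(size=(800, 10))
        solution = psy.pca_efa(X, n_factors=2)
        dominant = solution.dominant_factor()
        blocks = np.array([0] * 6 + [1] * 4)
        agreement = max(
            np.mean(dominant == blocks), np.mean(dominant == 1 - blocks)
        )
        assert agreement == 1.0
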