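import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfoscount.metrics import abs_error, fit_counts_regression, match_detections


class TestAbsError:
    def test_identical_series(self):
        report = abs_error([5, 10, 3], [5, 10, 3])
        assert report.abs_errors == (0, 0, 0)
        assert report.mean_abs_error == 0.0

    def test_arithmetic(self):
        report = abs_error([10, 20], [12, 15])
        assert report.abs_errors == (2, 5)
        assert report.mean_abs_error == 3.5

    def test_mean_matches_bruteforce(self, rng):
        ref = rng.integers(0, 100, size=20)
        met = rng.integers(0, 100, size=20)
        report = abs_error(ref, met)
        total = 0
        for r, m in zip(ref, met):
            total += abs(int(r) - int(m))
        assert report.mean_abs_error == pytest.approx(total / 20)

    def test_permutation_invariant_mean(self, rng):
        ref = rng.integers(0, 50, size=12)
        met = rng.integers(0, 50, size=12)
        perm = rng.permutation(12)
        assert abs_error(ref, met).mean_abs_error == pytest.approx(
            abs_error(ref[perm], met[perm]).mean_abs_error
        )

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="not aligned"):
            abs_error([1, 2], [1])


def optimal_matching_size(ref, det, tol):
    """Brute-force maximum one-to-one matching under the distance tolerance.

    Enumerates every injective assignment of the smaller point set into the
    larger one; feasible only for a handful of points.
    """
    ref = np.asarray(ref, float).reshape(-1, 2)
    det = np.asarray(det, float).reshape(-1, 2)
    if len(ref) > len(det):
        ref, det = det, ref
    best = 0
    for perm in itertools.permutations(range(len(det)), len(ref)):
        ok = sum(
            1 for i, j in enumerate(perm) if np.hypot(*(ref[i] - det[j])) <= tol
        )
        best = max(best, ok)
    return best


class TestMatchDetections:
    def test_identical_sets(self):
        pts = [(0, 0), (10, 10), (30, 5)]
        pairs, fp, fn = match_detections(pts, pts, tol=5)
        assert len(pairs) == 3 and fp == 0 and fn == 0

    def test_extra_detection_is_false_positive(self):
        pairs, fp, fn = match_detections([(0, 0)], [(0, 0), (50, 50)], tol=15)
        assert fp == 1 and fn == 0

    def test_missed_reference_is_false_negative(self):
        pairs, fp, fn = match_detections([(0, 0), (50, 50)], [(0, 0)], tol=15)
        assert fp == 0 and fn == 1

    def test_one_to_one_no_double_matching(self):
        # two detections near one reference cell: only one may match
        pairs, fp, fn = match_detections([(0, 0)], [(1, 0), (0, 1)], tol=5)
        assert len(pairs) == 1 and fp == 1 and fn == 0

    def test_matches_bruteforce_on_separated_points(self, rng):
        # far-separated clusters: greedy and optimal matching agree
        for _ in range(20):
            n_ref, n_det = rng.integers(1, 6, size=2)
            ref = [(50 * i + rng.uniform(-3, 3), 50 * i) for i in range(n_ref)]
            det = [(50 * j + rng.uniform(-3, 3), 50 * j) for j in range(n_det)]
            pairs, fp, fn = match_detections(ref, det, tol=10)
            assert len(pairs) == optimal_matching_size(ref, det, 10)
            assert fp == len(det) - len(pairs)
            assert fn == len(ref) - len(pairs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_role_swap_exchanges_fp_and_fn(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0, 100, size=(rng.integers(0, 8), 2))
        det = rng.uniform(0, 100, size=(rng.integers(0, 8), 2))
        _, fp, fn = match_detections(ref, det, tol=12)
        _, fp2, fn2 = match_detections(det, ref, tol=12)
        assert (fp, fn) == (fn2, fp2)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            match_detections([], [], tol=0)


class TestRegression:
    def test_perfect_identity(self):
        fit = fit_counts_regression([1, 2, 3, 4], [1, 2, 3, 4])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_exact_affine_series(self):
        x = np.arange(10.0)
        fit = fit_counts_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.n == 10

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 100, size=25)
        y = 0.9 * x + rng.normal(0, 5, size=25)
        fit = fit_counts_regression(x, y)
        design = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    def test_recovers_slope_with_count_noise(self):
        # parameter-recovery bar: n=15 images, Gaussian count noise sd 3
        rng = np.random.default_rng(7)
        slopes = []
        for _ in range(20):
            x = rng.uniform(5, 100, size=15)
            y = x + rng.normal(0, 3, size=15)
            slopes.append(fit_counts_regression(x, y).slope)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_counts_regression([1, 2], [1, 2])
        with pytest.raises(ValueError, match="zero variance"):
            fit_counts_regression([5, 5, 5], [1, 2, 3])
        with pytest.raises(ValueError, match="not aligned"):
            fit_counts_regression([1, 2, 3], [1, 2])
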