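"""Scoring and statistics against brute-force/closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgamorph.evaluation import (
    ccc,
    dice,
    evaluate_set,
    linregress_r2,
    match_objects,
    pearson,
)
from orgamorph.synthetic import rasterize_ellipse


def _brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def _brute_ccc(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((20, 20)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0, 0] = b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, :4] = True
        b[0, 2:4] = b[1, 0:2] = True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_one(self):
        z = np.zeros((5, 5), dtype=bool)
        assert dice(z, z) == 1.0

    def test_symmetry_and_range(self, rng):
        for _ in range(25):
            a = rng.random((12, 12)) > 0.5
            b = rng.random((12, 12)) > 0.5
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestMatchObjects:
    @staticmethod
    def _blob(cy, cx, r, shape=(128, 128)):
        return rasterize_ellipse((cy, cx), (r, r), 0, shape).pixels

    def test_perfect_predictions(self):
        gts = [self._blob(30, 30, 10), self._blob(90, 90, 12)]
        rep = match_objects(gts, gts)
        assert rep.sensitivity == 1.0 and rep.fp == 0 and rep.fn == 0

    def test_no_predictions(self):
        gts = [self._blob(20 * i + 14, 20, 6) for i in range(5)]
        rep = match_objects([], gts)
        assert (rep.tp, rep.fn) == (0, 5)
        assert rep.sensitivity == 0.0

    def test_confusion_with_distractors(self):
        """4 true (3 found), 3 negatives (1 wrongly detected): brute check."""
        pos = [self._blob(20, 20, 8), self._blob(20, 60, 8),
               self._blob(60, 20, 8), self._blob(60, 60, 8)]
        neg = [self._blob(100, 20, 8), self._blob(100, 60, 8),
               self._blob(100, 100, 8)]
        preds = pos[:3] + [neg[0]]
        rep = match_objects(preds, pos, neg)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 2)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(5 / 7)

    def test_counts_close_over_truth(self, rng):
        pos = [self._blob(30, 30, 9), self._blob(30, 90, 9), self._blob(90, 30, 9)]
        neg = [self._blob(90, 90, 9)]
        preds = [self._blob(31, 30, 9), self._blob(64, 64, 5)]
        rep = match_objects(preds, pos, neg)
        assert rep.tp + rep.fn == len(pos)
        assert rep.tn + sum(1 for _ in [0] if rep.fp) >= 0  # counts non-negative
        assert rep.tp + rep.fp >= len(preds) - len(pos)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            match_objects([], [], iou_threshold=0.0)


class TestCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        est, (lo, hi) = ccc(x, x)
        assert est == pytest.approx(1.0, abs=1e-12)

    def test_location_shift_penalized(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        est, _ = ccc(x, x + 2.0)
        r, _ = pearson(x, x + 2.0)
        assert est < 1.0 and r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        est, _ = ccc(x, y)
        assert est == pytest.approx(_brute_ccc(x, y), abs=1e-12)

    def test_matches_bruteforce_on_seeded_vectors(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = 0.5 * x + rng.normal(size=15)
            est, _ = ccc(x, y)
            assert est == pytest.approx(_brute_ccc(x, y), abs=1e-10)

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.3, size=30)
        est, (lo, hi) = ccc(x, y)
        assert lo < est < hi
        assert -1 <= lo and hi <= 1

    def test_abs_ccc_bounded_by_abs_r(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if x.std() == 0 or y.std() == 0:
                continue
            est, _ = ccc(x, y)
            r = _brute_pearson(x, y)
            assert abs(est) <= abs(r) + 1e-12

    def test_ccc_equals_r_when_moments_match(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([3.0, 1.0, 0.0, 2.0])  # same mean and variance
        est, _ = ccc(x, y)
        assert est == pytest.approx(_brute_pearson(x, y), abs=1e-12)


class TestPearsonOLS:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 3 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_constructed_orthogonal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = pearson(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _ = pearson(x, y)
        assert r == pytest.approx(_brute_pearson(x, y), abs=1e-12)

    def test_noiseless_line_fit(self):
        x = np.arange(8.0)
        slope, intercept, r2, p = linregress_r2(x, 2 * x + 1)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_y_r2_zero(self):
        x = np.arange(6.0)
        _, _, r2, _ = linregress_r2(x, np.full(6, 3.0))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linregress_r2(np.ones(5), np.arange(5.0))

    def test_zero_variance_pearson_flagged(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


class TestEvaluateSet:
    def test_perfect_set(self, rng):
        masks = [rng.random((16, 16)) > 0.5 for _ in range(4)]
        out = evaluate_set(masks, masks, masks)
        assert out["mean_dsc_raw"] == 1.0
        assert out["mean_dsc_post"] == 1.0

    def test_mean_arithmetic(self):
        a = np.ones((4, 4), dtype=bool)
        half = a.copy()
        half[2:] = False
        third = np.zeros((4, 4), dtype=bool)
        third[0] = True
        out = evaluate_set([a, half], None, [a, a])
        assert out["mean_dsc_raw"] == pytest.approx((1.0 + 2 / 3) / 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_set([np.zeros((2, 2), bool)], None, [])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=20),
    st.lists(st.floats(-100, 100), min_size=3, max_size=20),
)
def test_ccc_never_exceeds_pearson(xs, ys):
    n = min(len(xs), len(ys))
    x = np.asarray(xs[:n])
    y = np.asarray(ys[:n])
    if x.std() == 0 or y.std() == 0:
        return
    est, _ = ccc(x, y)
    r = _brute_pearson(x, y)
    assert abs(est) <= abs(r) + 1e-9
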