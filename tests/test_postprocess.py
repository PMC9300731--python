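"""Post-processing and metric oracles: flood fill, pair counting, grid search."""

from collections import deque

import numpy as np
import pytest

from fundusmtl.postprocess import (LogisticClassifier, auc,
                                   center_of_mass, compute_vcdr, dice,
                                   ensemble_classify, evaluate, fit_logistic,
                                   fovea_error, largest_connected_component,
                                   roc_curve)


def flood_fill_largest(mask):
    """Independent oracle: BFS enumeration of 8-connected components."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    best = np.zeros_like(mask)
    best_size = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = []
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                q.append((rr, cc))
                if len(comp) > best_size:
                    best_size = len(comp)
                    best = np.zeros_like(mask)
                    for r, c in comp:
                        best[r, c] = True
    return best


class TestLargestComponent:
    def test_keeps_the_larger_of_two_blobs(self):
        m = np.zeros((12, 12), bool)
        m[1:4, 1:5] = True   # 12 px
        m[8:9, 6:11] = True  # 5 px
        out = largest_connected_component(m)
        assert out.sum() == 12
        assert np.array_equal(out, flood_fill_largest(m))

    def test_matches_flood_fill_on_random_masks(self, rng):
        for _ in range(100):
            m = rng.random((16, 16)) < 0.35
            if not m.any():
                continue
            got = largest_connected_component(m)
            ref = flood_fill_largest(m)
            assert got.sum() == ref.sum()
            assert got.sum() == np.logical_and(got, ref).sum() or np.array_equal(got, ref)
            # subset + idempotence
            assert not np.any(got & ~m)
            assert np.array_equal(largest_connected_component(got), got)

    def test_single_blob_unchanged(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert np.array_equal(largest_connected_component(m), m)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            out = largest_connected_component(np.zeros((4, 4), bool))
        assert not out.any()


class TestCenterOfMass:
    def test_single_pixel(self):
        m = np.zeros((10, 10))
        m[7, 3] = 2.5
        assert center_of_mass(m) == (3.0, 7.0)

    def test_two_equal_masses(self):
        m = np.zeros((3, 11))
        m[0, 0] = m[0, 10] = 1.0
        assert center_of_mass(m) == (5.0, 0.0)

    def test_negative_values_clipped_before_weighting(self):
        m = np.array([[-5.0, 0.0, 1.0]])
        assert center_of_mass(m) == (2.0, 0.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros((4, 4)))


class TestVcdr:
    def test_row_extent_formula(self):
        od = np.zeros((120, 50), bool)
        od[0:100, 10:30] = True
        oc = np.zeros((120, 50), bool)
        oc[10:50, 15:25] = True
        rec = compute_vcdr(od, oc)
        assert (rec.oc_height, rec.od_height, rec.vcdr) == (40, 100, 0.4)

    def test_equal_masks_give_one(self):
        m = np.zeros((20, 20), bool)
        m[3:15, 4:16] = True
        assert compute_vcdr(m, m).vcdr == 1.0

    def test_empty_cup_gives_zero(self):
        od = np.zeros((20, 20), bool)
        od[3:15, 4:16] = True
        assert compute_vcdr(od, np.zeros_like(od)).vcdr == 0.0

    def test_empty_disc_is_flagged_undefined(self):
        rec = compute_vcdr(np.zeros((5, 5), bool), np.zeros((5, 5), bool))
        assert rec.od_empty and np.isnan(rec.vcdr)

    def test_invariant_to_horizontal_translation_and_column_shuffles(self, rng):
        od = np.zeros((30, 30), bool)
        od[5:25, 5:15] = True
        oc = np.zeros((30, 30), bool)
        oc[10:20, 7:13] = True
        base = compute_vcdr(od, oc).vcdr
        assert compute_vcdr(np.roll(od, 9, axis=1), np.roll(oc, 9, axis=1)).vcdr == base
        # widening columns without changing occupied rows preserves vCDR
        od2, oc2 = od.copy(), oc.copy()
        od2[5:25, 20:29] = True
        oc2[10:20, 20:25] = True
        assert compute_vcdr(od2, oc2).vcdr == base


def grid_search_logistic(vcdrs, labels, l2_lambda, lo=-30, hi=30, steps=601):
    """Independent oracle: dense 2-D maximization of the penalized likelihood."""
    v = np.asarray(vcdrs)
    y = np.asarray(labels)
    ws = np.linspace(lo, hi, steps)
    bs = np.linspace(lo, hi, steps)
    best, arg = -np.inf, None
    for w in ws:
        z = np.clip(w * v[None, :] + bs[:, None], -500, 500)
        ll = (y * z - np.log1p(np.exp(z))).sum(axis=1) - l2_lambda / 2 * w**2
        i = ll.argmax()
        if ll[i] > best:
            best, arg = ll[i], (w, bs[i])
    return arg


class TestLogistic:
    def test_matches_grid_search_oracle(self):
        vcdrs = [0.2, 0.3, 0.6, 0.7]
        labels = [0, 0, 1, 1]
        clf = fit_logistic(vcdrs, labels, l2_lambda=1e-3)
        w0, b0 = grid_search_logistic(vcdrs, labels, 1e-3)

        # Newton's optimum must dominate the best grid point
        def pen_ll(w, b):
            z = w * np.asarray(vcdrs) + b
            return float((np.asarray(labels) * z - np.log1p(np.exp(z))).sum()
                         - 1e-3 / 2 * w**2)

        assert pen_ll(clf.weight, clf.bias) >= pen_ll(w0, b0) - 1e-9
        assert abs(clf.weight - w0) < 0.15 and abs(clf.bias - b0) < 0.15

    def test_symmetric_data_crosses_half_at_midpoint(self):
        vstar = 0.5
        vcdrs = [vstar - 0.2, vstar - 0.1, vstar + 0.1, vstar + 0.2]
        clf = fit_logistic(vcdrs, [0, 0, 1, 1])
        assert clf.predict_proba(vstar) == pytest.approx(0.5, abs=1e-9)

    def test_permutation_invariance(self, rng):
        v = rng.random(20)
        y = (v + rng.normal(0, 0.2, 20) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        a = fit_logistic(v, y)
        perm = rng.permutation(20)
        b = fit_logistic(v[perm], y[perm])
        assert a.weight == pytest.approx(b.weight, abs=1e-10)
        assert a.bias == pytest.approx(b.bias, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([0.1, 0.2, 0.3], [1, 1, 1])


class TestEnsemble:
    @pytest.mark.parametrize("fc,lin,prob,label", [
        (0.9, 0.3, 0.6, 1),
        (0.2, 0.2, 0.2, 0),
        (0.5, 0.5, 0.5, 1),  # tie goes positive
    ])
    def test_average_and_threshold(self, fc, lin, prob, label):
        assert ensemble_classify(fc, lin) == (pytest.approx(prob), label)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ensemble_classify(1.2, 0.5)

    def test_monotone_in_each_argument(self, rng):
        for _ in range(50):
            a, b, d = rng.random(3)
            hi = min(1.0, a + d)
            assert ensemble_classify(hi, b)[0] >= ensemble_classify(a, b)[0]


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((6, 6), bool)
        a[1:3, 1:3] = True
        b = np.zeros((6, 6), bool)
        b[4:6, 4:6] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool)
        a[0, :4] = True
        b = np.zeros((4, 4), bool)
        b[0, 2:4] = True
        b[1, 0:2] = True
        assert dice(a, b) == pytest.approx(2 * 2 / 8)

    def test_both_empty_is_agreement(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) == 1.0
        a = z.copy()
        a[0, 0] = True
        assert dice(a, z) == 0.0


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate all (positive, negative) pairs."""
    s = np.asarray(scores)
    pos = s[np.asarray(labels) == 1]
    neg = s[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_and_inverted(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1]) == 0.0

    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pair_counting_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(6, 25))
            s = rng.choice(np.linspace(0, 1, 11), size=n)  # forces ties
            y = (rng.random(n) > 0.6).astype(int)
            if len(np.unique(y)) < 2:
                continue
            a = auc(s, y)
            assert a == pytest.approx(brute_force_auc(s, y), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_agrees_with_trapezoidal_roc_area(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            s = rng.random(n).round(1)
            y = (rng.random(n) > 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            fpr, tpr = roc_curve(s, y)
            assert auc(s, y) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestFoveaError:
    def test_examples_and_symmetry(self):
        assert fovea_error((1, 2), (1, 2)) == 0.0
        assert fovea_error((0, 0), (3, 4)) == 5.0
        assert fovea_error((3, 4), (0, 0)) == 5.0
        assert fovea_error((0, 0), (3, 4), scale=2.0) == 10.0


class _PerfectModel:
    """Stub producing ground truth as predictions (duck-types MultiTaskNet)."""

    def __init__(self, dataset, sigma=1.5):
        from fundusmtl.losses import SaliencyMapSpec, make_fovea_map

        self.ds = dataset
        size = dataset.image_size
        self._fovea = np.stack([
            make_fovea_map(SaliencyMapSpec(x, y, sigma, size, size))
            for x, y in dataset.fovea
        ])

    def forward(self, images, need_maps=True):
        from fundusmtl.model import ForwardOutputs

        idx = [np.flatnonzero([np.array_equal(images[i], im) for im in self.ds.images])[0]
               for i in range(len(images))]
        return ForwardOutputs(
            od_map=self.ds.od_masks[idx].astype(float) * 0.98 + 0.01,
            oc_map=self.ds.oc_masks[idx].astype(float) * 0.98 + 0.01,
            fovea_map=self._fovea[idx],
            glaucoma_prob=self.ds.labels[idx].astype(float) * 0.8 + 0.1,
        )


class TestEvaluate:
    def test_ground_truth_predictions_are_perfect(self, small_dataset):
        model = _PerfectModel(small_dataset)
        clf = LogisticClassifier(weight=40.0, bias=-24.0, l2_lambda=1e-3)  # step near 0.6
        rep = evaluate(model, small_dataset, clf)
        assert rep.dice_od == 1.0 and rep.dice_oc == 1.0
        assert rep.fovea_error < 0.5
        if len(np.unique(small_dataset.labels)) == 2:
            assert rep.auc == 1.0

    def test_shuffling_dataset_gives_identical_aggregates(self, small_dataset, rng):
        model = _PerfectModel(small_dataset)
        rep1 = evaluate(model, small_dataset)
        perm = rng.permutation(len(small_dataset))
        shuffled = small_dataset.subset(perm)
        rep2 = evaluate(_PerfectModel(shuffled), shuffled)
        assert rep1.dice_od == rep2.dice_od
        assert rep1.fovea_error == pytest.approx(rep2.fovea_error, abs=1e-12)
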