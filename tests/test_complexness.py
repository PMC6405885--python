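import warnings

import numpy as np
import pytest

from cnnrf import (
    ComplexnessRecord,
    build_shifted_image_set,
    classify_cell,
    complex_model_similarity,
    complexness_index,
    detect_shifts,
    orthogonal_shift_distance,
    simple_model_similarity,
    zncc,
)
from cnnrf.complexness import ShiftRecord, fraction_shifted_pairs, pairwise_peak_zncc


def _zncc_oracle(a, b, u, v):
    """Independent crop-and-correlate evaluation."""
    ly, lx = b.shape
    x0, x1 = max(0, -u), min(lx, lx - u)
    y0, y1 = max(0, -v), min(ly, ly - v)
    pa = a[y0 + v : y1 + v, x0 + u : x1 + u].ravel()
    pb = b[y0:y1, x0:x1].ravel()
    return np.corrcoef(pa, pb)[0, 1]


class TestZNCC:
    def test_self_at_zero_shift(self):
        img = np.random.default_rng(0).standard_normal((5, 5))
        assert zncc(img, img, 0, 0) == pytest.approx(1.0)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((6, 6))
        b = rng.standard_normal((6, 6))
        base = zncc(a, b, 1, -1)
        assert zncc(3.0 * a + 5.0, b, 1, -1) == pytest.approx(base)
        assert zncc(a, 0.2 * b - 9.0, 1, -1) == pytest.approx(base)

    def test_three_by_three_scalar_oracle(self):
        a = np.array([[1.0, 2, 0], [0, 3, 1], [2, 1, 4]])
        b = np.array([[2.0, 1, 1], [0, 2, 3], [1, 0, 2]])
        assert zncc(a, b, 1, 0) == pytest.approx(_zncc_oracle(a, b, 1, 0))

    @pytest.mark.parametrize("u,v", [(1, 0), (0, 2), (-1, 1), (2, -2)])
    def test_symmetry(self, u, v):
        rng = np.random.default_rng(42)
        a = rng.standard_normal((8, 8))
        b = rng.standard_normal((8, 8))
        assert zncc(a, b, u, v) == pytest.approx(zncc(b, a, -u, -v))

    def test_tiny_overlap_rejected(self):
        img = np.random.default_rng(2).standard_normal((4, 4))
        with pytest.raises(ValueError, match="overlap"):
            zncc(img, img, 3, 3)


class TestDetectShifts:
    def test_identical_noise_images_not_shifted(self):
        # white-noise images decorrelate at any non-zero shift
        img = np.random.default_rng(3).standard_normal((10, 10))
        records = detect_shifts(np.stack([img, img]), zncc_threshold=0.95)
        assert records == []

    def test_exact_translate_detected(self):
        rng = np.random.default_rng(4)
        big = rng.standard_normal((10, 12))
        a = big[:, :10]
        b = big[:, 1:11]  # b(x) = a(x+1): a shifted by u=+1 matches b
        records = detect_shifts(np.stack([a, b]), zncc_threshold=0.95)
        shifts = {r.shift for r in records}
        assert (1, 0) in shifts
        rec = next(r for r in records if r.shift == (1, 0))
        assert rec.zncc == pytest.approx(1.0)

    def test_matches_bruteforce_zncc(self):
        rng = np.random.default_rng(5)
        imgs = rng.standard_normal((4, 8, 8))
        records = detect_shifts(imgs, zncc_threshold=0.2)
        oracle = set()
        for i in range(4):
            for j in range(i + 1, 4):
                for u in range(-4, 5):
                    for v in range(-4, 5):
                        if (u, v) == (0, 0) or (8 - abs(u)) * (8 - abs(v)) < 32:
                            continue
                        if _zncc_oracle(imgs[i], imgs[j], u, v) > 0.2:
                            oracle.add((i, j, u, v))
        got = {(r.pair[0], r.pair[1], *r.shift) for r in records}
        assert got == oracle

    def test_peak_matrix_symmetric(self):
        imgs = np.random.default_rng(6).standard_normal((5, 8, 8))
        peak = pairwise_peak_zncc(imgs)
        np.testing.assert_allclose(peak, peak.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(peak), 1.0)


class TestOrthogonalShift:
    def test_projection_oracle(self):
        # stripes along x (theta=0): orthogonal direction is y
        assert orthogonal_shift_distance([(3, 4)], theta=0.0) == pytest.approx(4.0)
        assert orthogonal_shift_distance([(3, 0)], theta=0.0) == pytest.approx(0.0)

    def test_parallel_shifts_give_zero(self):
        theta = 0.7
        along = (np.cos(theta), np.sin(theta))  # stripe axis
        shifts = [(2 * along[0], 2 * along[1]), (-1 * along[0], -1 * along[1])]
        assert orthogonal_shift_distance(shifts, theta) == pytest.approx(0.0, abs=1e-12)

    def test_empty_list(self):
        assert orthogonal_shift_distance([], theta=1.0) == 0.0


class TestShiftedImageSet:
    def _fake_ensemble(self, n, preds):
        class FakeRF:
            def __init__(self, img, pred):
                self.image = img
                self.predicted_response = pred
                self.activation_fraction = pred

        class FakeEns:
            pass

        ens = FakeEns()
        rng = np.random.default_rng(0)
        ens.rf_images = [FakeRF(rng.standard_normal((6, 6)), p) for p in preds]
        ens.images = np.stack([r.image for r in ens.rf_images])
        return ens

    def test_no_shifts_selects_highest_prediction(self):
        ens = self._fake_ensemble(3, [0.5, 0.9, 0.7])
        assert build_shifted_image_set(ens, [], theta=0.0) == [1]

    def test_chain_closure(self):
        ens = self._fake_ensemble(3, [1.0, 1.0, 1.0])
        shifts = [ShiftRecord((0, 1), (0, 1), 0.96), ShiftRecord((1, 2), (0, 1), 0.96)]
        assert build_shifted_image_set(ens, shifts, theta=0.0) == [0, 1, 2]

    def test_fully_connected_collects_all(self):
        ens = self._fake_ensemble(4, [1.0] * 4)
        shifts = [ShiftRecord((i, j), (1, 0), 0.96) for i in range(4) for j in range(i + 1, 4)]
        assert build_shifted_image_set(ens, shifts, theta=0.0) == [0, 1, 2, 3]

    def test_disconnected_component_excluded(self):
        ens = self._fake_ensemble(5, [1.0] * 5)
        shifts = [ShiftRecord((0, 1), (0, 2), 0.96), ShiftRecord((3, 4), (0, 1), 0.96)]
        # pair (0,1) has the larger orthogonal distance at theta=0 -> seeds the set
        assert build_shifted_image_set(ens, shifts, theta=0.0) == [0, 1]


class TestPredictiveModels:
    def test_single_image_models_identical(self, small_stimuli):
        rng = np.random.default_rng(7)
        rf = rng.standard_normal((10, 10))
        y = rng.random(small_stimuli.n_stim)
        r_s, idx = simple_model_similarity(small_stimuli, y, [rf])
        r_c = complex_model_similarity(small_stimuli, y, [rf])
        assert r_s == pytest.approx(r_c)
        assert idx == 0

    def test_self_consistent_cosine_responses(self, small_stimuli):
        rf = np.random.default_rng(8).standard_normal((10, 10))
        cos = (small_stimuli.flat / np.linalg.norm(small_stimuli.flat, axis=1, keepdims=True)) @ (
            rf.ravel() / np.linalg.norm(rf)
        )
        r_s, idx = simple_model_similarity(small_stimuli, cos, [np.ones((10, 10)), rf])
        assert r_s == pytest.approx(1.0)
        assert idx == 1

    def test_sign_pair_gives_absolute_cosine(self, small_stimuli):
        rf = np.random.default_rng(9).standard_normal((10, 10))
        y = np.random.default_rng(10).random(small_stimuli.n_stim)
        r_c = complex_model_similarity(small_stimuli, y, [rf, -rf])
        sn = small_stimuli.flat / np.linalg.norm(small_stimuli.flat, axis=1, keepdims=True)
        expect = np.abs(sn @ (rf.ravel() / np.linalg.norm(rf)))
        assert r_c == pytest.approx(np.corrcoef(expect, y)[0, 1])

    def test_two_image_three_stimulus_bruteforce(self):
        stim = np.random.default_rng(11).standard_normal((3, 4, 4))
        y = np.array([0.1, 0.8, 0.4])
        rfs = list(np.random.default_rng(12).standard_normal((2, 4, 4)))
        sn = stim.reshape(3, -1) / np.linalg.norm(stim.reshape(3, -1), axis=1, keepdims=True)
        cos = np.stack([sn @ (rf.ravel() / np.linalg.norm(rf)) for rf in rfs], axis=1)
        per_rf = [np.corrcoef(cos[:, i], y)[0, 1] for i in range(2)]
        r_s, idx = simple_model_similarity(stim, y, rfs)
        assert r_s == pytest.approx(max(per_rf))
        assert idx == int(np.argmax(per_rf))
        r_c = complex_model_similarity(stim, y, rfs)
        assert r_c == pytest.approx(np.corrcoef(cos.max(axis=1), y)[0, 1])


class TestClassification:
    def test_boundary_arithmetic(self):
        rec = ComplexnessRecord("c", r_simple=0.3, r_complex=0.6, complexness=complexness_index(0.3, 0.6),
                                gabor_fit_similarity=0.9)
        assert rec.complexness == pytest.approx(0.5)
        assert classify_cell(rec) == "complex_like"

    def test_equal_similarities_classified_simple(self):
        rec = ComplexnessRecord("c", 0.4, 0.4, complexness_index(0.4, 0.4), gabor_fit_similarity=0.9)
        assert rec.complexness == 0.0
        assert classify_cell(rec) == "simple"

    def test_poor_gabor_fit_unclassified(self):
        rec = ComplexnessRecord("c", 0.3, 0.6, 0.5, gabor_fit_similarity=0.5)
        assert classify_cell(rec) == "unclassified"

    def test_negative_similarity_unclassified(self):
        rec = ComplexnessRecord("c", -0.1, 0.4, complexness_index(-0.1, 0.4), gabor_fit_similarity=0.9)
        assert classify_cell(rec) == "unclassified"

    def test_fraction_shifted_pairs_counts_unordered_pairs(self):
        imgs = np.random.default_rng(13).standard_normal((4, 8, 8))
        shifts = [ShiftRecord((0, 1), (1, 0), 0.9), ShiftRecord((0, 1), (2, 0), 0.8),
                  ShiftRecord((2, 3), (0, 1), 0.9)]
        assert fraction_shifted_pairs(imgs, shifts=shifts) == pytest.approx(2 / 6)

    def test_fraction_shifted_pairs_zero_shift_semantics(self):
        # identical noise images match only at (0,0): counted by the
        # default (peak over all shifts) statistic, not by the strict one
        img = np.random.default_rng(14).standard_normal((10, 10))
        pair = np.stack([img, img])
        assert fraction_shifted_pairs(pair, zncc_threshold=0.7) == pytest.approx(1.0)
        assert fraction_shifted_pairs(pair, zncc_threshold=0.7, include_zero_shift=False) == 0.0
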