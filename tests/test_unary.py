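import numpy as np
import pytest

from caudatecut.core import SliceImage
from caudatecut.unary import (
    combine_unary,
    correlogram_bin_masks,
    dense_descriptors,
    extract_correlogram,
    fit_seed_intensity_model,
    intensity_model_from_levels,
    sample_training_pixels,
    supervised_potentials,
    train_pixel_classifier,
    TrainedPixelClassifier,
    unsupervised_potentials,
)

from conftest import make_slice


class TestIntensityModel:
    def test_hand_counted_frequencies(self):
        img = make_slice([[100.0, 100.0], [100.0, 200.0]])
        model = fit_seed_intensity_model(img, np.ones((2, 2), dtype=bool))
        assert model.p_cau[200] == pytest.approx(0.25)
        assert model.p_cau[100] == pytest.approx(0.75)

    def test_floor_and_ceiling(self):
        img = make_slice(np.full((3, 3), 50.0))
        model = fit_seed_intensity_model(img, np.ones((3, 3), dtype=bool), eps=1e-3)
        assert model.p_cau[50] == pytest.approx(1 - 1e-3)
        assert model.p_cau[51] == pytest.approx(1e-3)  # unseen level

    def test_complement_sums_to_one(self):
        img = make_slice([[10.0, 20.0], [30.0, 10.0]])
        model = fit_seed_intensity_model(img, np.ones((2, 2), dtype=bool))
        uu = unsupervised_potentials(img, model)
        p = np.exp(-uu.cau)
        q = np.exp(-uu.back)
        np.testing.assert_allclose(p + q, 1.0)

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            fit_seed_intensity_model(make_slice(np.zeros((3, 3))), np.zeros((3, 3), bool))

    def test_parzen_smoothing_spreads_mass(self):
        m0 = intensity_model_from_levels(np.full(20, 100.0), smooth_sd=0.0)
        m1 = intensity_model_from_levels(np.full(20, 100.0), smooth_sd=3.0)
        assert m0.p_cau[97] == pytest.approx(1e-3)
        assert m1.p_cau[97] > 0.05


class TestUnsupervisedPotentials:
    def test_symmetry_point_ln2(self):
        model = intensity_model_from_levels(np.array([10.0, 20.0]))  # p=0.5 each
        uu = unsupervised_potentials(make_slice([[10, 10], [20, 20]]), model)
        np.testing.assert_allclose(uu.cau, np.log(2), rtol=1e-12)
        np.testing.assert_allclose(uu.back, np.log(2), rtol=1e-12)

    def test_quarter_probability(self):
        model = intensity_model_from_levels(np.array([100.0, 200.0, 200.0, 200.0]))
        uu = unsupervised_potentials(make_slice([[100.0, 100.0], [100.0, 100.0]]), model)
        assert uu.cau[0, 0] == pytest.approx(1.3863, abs=1e-4)
        assert uu.back[0, 0] == pytest.approx(0.2877, abs=1e-4)

    def test_monotone_in_probability(self):
        levels = np.array([100.0] * 3 + [200.0])  # p(100)=0.75 > p(200)=0.25
        model = intensity_model_from_levels(levels)
        uu = unsupervised_potentials(make_slice([[100.0, 200.0], [100.0, 200.0]]), model)
        assert uu.cau[0, 0] < uu.cau[0, 1]


class TestCorrelogram:
    def test_descriptor_length_and_bins(self):
        masks = correlogram_bin_masks(3, 5)
        assert masks.shape[0] == 15
        img = make_slice(np.random.default_rng(0).uniform(0, 255, (35, 35)))
        d = extract_correlogram(img, (17, 17), 3, 5)
        assert d.values.shape == (105,)

    def test_bins_partition_the_disk(self):
        masks = correlogram_bin_masks(3, 5)
        total = masks.sum(axis=0)
        R = 15
        yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
        inside = yy * yy + xx * xx <= R * R
        np.testing.assert_array_equal(total.astype(bool), inside)
        assert total.max() == 1  # disjoint

    def test_uniform_image_gives_zero_descriptor(self):
        img = make_slice(np.full((20, 20), 99.0))
        d = extract_correlogram(img, (10, 10), 2, 3)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_two_bin_toy(self):
        # c=2, r=1: bin 1 = center + dist<=1, bin 2 = 1<dist<=2
        masks = correlogram_bin_masks(2, 1)
        img = np.zeros((9, 9))
        ctr = (4, 4)
        for b, val in ((0, 10.0), (1, 30.0)):
            offs = np.argwhere(masks[b]) - 2
            for dy, dx in offs:
                img[ctr[0] + dy, ctr[1] + dx] = val
        d = extract_correlogram(make_slice(img), ctr, 2, 1)
        assert d.values == pytest.approx([-20.0])

    def test_pairwise_antisymmetry_against_independent_means(self):
        """Descriptor entries equal mean(b_i) - mean(b_j) computed directly
        from the bin masks (interior pixel, no padding involved)."""
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, (31, 31))
        c, r = 2, 3
        masks = correlogram_bin_masks(c, r)
        R = c * r
        ctr = (15, 15)
        patch = img[ctr[0] - R : ctr[0] + R + 1, ctr[1] - R : ctr[1] + R + 1]
        means = [patch[m].mean() for m in masks]
        import itertools

        expected = [means[i] - means[j] for i, j in itertools.combinations(range(c * r), 2)]
        d = extract_correlogram(make_slice(img), ctr, c, r)
        np.testing.assert_allclose(d.values, expected, rtol=1e-10)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            correlogram_bin_masks(1, 1)


class TestTrainingSample:
    @pytest.fixture()
    def gt_fixture(self):
        gt = np.zeros((24, 24), dtype=bool)
        gt[4:9, 4:12] = True  # 40 foreground pixels
        return gt

    def test_balanced_counts(self, gt_fixture):
        img = make_slice(np.zeros((24, 24)))
        pix, lab = sample_training_pixels(img, gt_fixture, seed=0)
        assert (lab == 1).sum() == 40
        assert (lab == 0).sum() == 40

    def test_deterministic(self, gt_fixture):
        img = make_slice(np.zeros((24, 24)))
        a = sample_training_pixels(img, gt_fixture, seed=3)
        b = sample_training_pixels(img, gt_fixture, seed=3)
        np.testing.assert_array_equal(a[0], b[0])

    def test_stratification_proportional(self, gt_fixture):
        img = make_slice(np.zeros((24, 24)))
        pix, lab = sample_training_pixels(img, gt_fixture, seed=0, n_blocks=2)
        bg = pix[lab == 0]
        # quadrant shares proportional to quadrant background counts, +/-1
        bg_mask = ~gt_fixture
        n_fg = 40
        for qy in (0, 1):
            for qx in (0, 1):
                in_q = (
                    (bg[:, 0] >= 12 * qy) & (bg[:, 0] < 12 * (qy + 1))
                    & (bg[:, 1] >= 12 * qx) & (bg[:, 1] < 12 * (qx + 1))
                )
                quota = n_fg * bg_mask[12 * qy : 12 * qy + 12, 12 * qx : 12 * qx + 12].sum() / bg_mask.sum()
                assert abs(in_q.sum() - quota) <= 1

    def test_background_too_small_rejected(self):
        gt = np.ones((6, 6), dtype=bool)
        gt[0, 0] = False
        with pytest.raises(ValueError):
            sample_training_pixels(make_slice(np.zeros((6, 6))), gt, seed=0)


class TestClassifier:
    def test_separable_toy_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 2.0, -2.0)  # widen the margin
        clf = train_pixel_classifier(X, y, 5, 1)
        pred = (clf.margins(X) > 0).astype(int)
        assert (pred == y).all()

    def test_calibrated_probability_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 4))
        y = (X[:, 0] > 0).astype(int)
        clf = train_pixel_classifier(X, y, 2, 2)
        p = clf.predict_proba(100 * rng.standard_normal((50, 4)))
        assert np.all(p > 0) and np.all(p < 1)

    def test_recovers_planted_linear_rule(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(36)
        w /= np.linalg.norm(w)
        X = rng.standard_normal((2000, 36))
        y = (X @ w > 0).astype(int)
        clf = train_pixel_classifier(X, y, 6, 6)
        cos = abs(np.dot(clf.weights / np.linalg.norm(clf.weights), w))
        assert cos >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_pixel_classifier(np.zeros((10, 3)), np.zeros(10), 3, 1)

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = (X[:, 1] > 0).astype(int)
        clf = train_pixel_classifier(X, y, 3, 1)
        clf.save(tmp_path / "clf.json")
        back = TrainedPixelClassifier.load(tmp_path / "clf.json")
        np.testing.assert_allclose(back.predict_proba(X), clf.predict_proba(X))
        assert (back.c, back.r) == (clf.c, clf.r)


class TestSupervisedPotentials:
    def _uninformative_clf(self, n_feat):
        return TrainedPixelClassifier(
            weights=np.zeros(n_feat),
            bias=0.0,
            platt_a=1.0,
            platt_b=0.0,
            feat_mean=np.zeros(n_feat),
            feat_scale=np.ones(n_feat),
            c=2,
            r=1,
        )

    def test_half_probability_gives_ln2(self):
        clf = self._uninformative_clf(1)  # margin 0 -> p = 0.5
        img = make_slice(np.random.default_rng(0).uniform(0, 255, (8, 8)))
        su = supervised_potentials(img, clf)
        np.testing.assert_allclose(su.cau, np.log(2), rtol=1e-12)
        np.testing.assert_allclose(su.back, np.log(2), rtol=1e-12)

    def test_monotone_and_capped(self):
        clf = self._uninformative_clf(1)
        p = np.array([0.2, 0.5, 0.9, 1 - 1e-3])
        su_cau = -np.log(p)
        assert np.all(np.diff(su_cau) < 0)
        assert su_cau[-1] <= -np.log(1 - clf.eps) + 1e-12

    def test_mismatched_geometry_rejected(self):
        clf = self._uninformative_clf(1)
        with pytest.raises(ValueError):
            supervised_potentials(make_slice(np.zeros((6, 6))), clf, c=3, r=2)


class TestCombine:
    def test_additive_identity_and_commutativity(self):
        rng = np.random.default_rng(0)
        from caudatecut.unary import UnaryPotentials

        a = UnaryPotentials(cau=rng.uniform(0, 2, (4, 4)), back=rng.uniform(0, 2, (4, 4)))
        zero = UnaryPotentials(cau=np.zeros((4, 4)), back=np.zeros((4, 4)))
        np.testing.assert_array_equal(combine_unary(a, zero).cau, a.cau)
        ab = combine_unary(a, a)
        np.testing.assert_allclose(ab.cau, 2 * a.cau)
        # worked example: ln2 + (-ln 0.25)
        one = UnaryPotentials(cau=np.full((2, 2), 0.69), back=np.zeros((2, 2)))
        two = UnaryPotentials(cau=np.full((2, 2), 1.39), back=np.zeros((2, 2)))
        assert combine_unary(one, two).cau[0, 0] == pytest.approx(2.08)

    def test_shape_mismatch_rejected(self):
        from caudatecut.unary import UnaryPotentials

        a = UnaryPotentials(cau=np.zeros((3, 3)), back=np.zeros((3, 3)))
        b = UnaryPotentials(cau=np.zeros((4, 4)), back=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            combine_unary(a, b)
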