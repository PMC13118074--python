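import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsiseg._nn import SpectralConvNet
from hsiseg.classify import (SAMClassifier, SpectralCNNClassifier,
                             SpectralForestClassifier, SpectralSVMClassifier,
                             glare_mask, make_classifier, predict_map,
                             sam_classify, sam_similarity_maps)
from hsiseg.dataset import PixelDataset, compute_reference_spectra
from hsiseg.spectra import ReflectanceCube, SpectralGrid

GRID4 = SpectralGrid(np.array([500.0, 550.0, 600.0, 650.0]))


def _refs(healthy, defect):
    from hsiseg.dataset import ReferenceSpectra
    return ReferenceSpectra(np.asarray(healthy, float),
                            np.asarray(defect, float))


def _two_class_data(rng, n=200, bands=81, sep=4.0):
    mu_h = np.linspace(0.2, 0.6, bands)
    mu_d = mu_h - sep * 0.02
    X = np.r_[mu_h + 0.01 * rng.standard_normal((n, bands)),
              mu_d + 0.01 * rng.standard_normal((n, bands))]
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, y


class TestSimilarityMaps:
    def test_pixel_equal_to_reference_scores_one(self):
        h = np.array([0.1, 0.3, 0.5, 0.7])
        cube = ReflectanceCube(np.tile(h, (2, 2, 1)), GRID4)
        maps = sam_similarity_maps(cube, np.ones((2, 2), bool),
                                   _refs(h, h * 0.5))
        assert np.allclose(maps.healthy, 1.0)

    def test_orthogonal_and_half_overlap_closed_forms(self):
        cube_data = np.zeros((1, 2, 3))
        cube_data[0, 0] = [1.0, 0.0, 1.0]      # vs (0,1,0) -> 0
        cube_data[0, 1] = [1.0, 0.0, 1.0]      # vs (1,1,0) -> 0.5
        grid3 = SpectralGrid(np.array([500.0, 600.0, 700.0]))
        cube = ReflectanceCube(cube_data, grid3)
        m_orth = sam_similarity_maps(cube, np.ones((1, 2), bool),
                                     _refs([0, 1, 0], [1, 0, 0]))
        assert m_orth.healthy[0, 0] == pytest.approx(0.0)
        m_half = sam_similarity_maps(cube, np.ones((1, 2), bool),
                                     _refs([1, 1, 0], [1, 0, 0]))
        assert m_half.healthy[0, 1] == pytest.approx(0.5)

    def test_zero_norm_pixel_is_flagged_undefined(self):
        data = np.tile([0.2, 0.2, 0.2, 0.2], (2, 2, 1)).astype(float)
        data[1, 1] = 0.0
        cube = ReflectanceCube(data, GRID4)
        maps = sam_similarity_maps(cube, np.ones((2, 2), bool),
                                   _refs([1, 1, 1, 1], [1, 0, 0, 0]))
        assert not maps.valid[1, 1]
        assert maps.valid.sum() == 3

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=50))
    def test_similarity_is_scale_invariant(self, scale, seed):
        rng = np.random.default_rng(seed)
        spectrum = rng.random(4) + 0.05
        clf = SAMClassifier().fit(
            np.r_[np.tile(rng.random(4) + 0.1, (3, 1)),
                  np.tile(rng.random(4) + 0.1, (3, 1))],
            np.r_[0, 0, 0, 1, 1, 1])
        a = clf.similarity(spectrum[None, :])
        b = clf.similarity((scale * spectrum)[None, :])
        assert a == pytest.approx(b, abs=1e-9)


class TestSAMDecisions:
    def test_uniformly_healthy_map_yields_no_defect(self):
        h = np.array([0.1, 0.3, 0.5, 0.7])
        cube = ReflectanceCube(np.tile(h, (3, 3, 1)), GRID4)
        maps = sam_similarity_maps(cube, np.ones((3, 3), bool),
                                   _refs(h, h[::-1]))
        out = sam_classify(maps, thresholding="fixed", fixed_threshold=0.2)
        assert not (out.values == 2).any()
        assert (out.values == 1).all()

    def test_low_similarity_region_becomes_defect_at_fixed_threshold(self):
        data = np.tile([0.1, 0.3, 0.5, 0.7], (4, 4, 1)).astype(float)
        data[:2, :2] = [0.7, 0.5, 0.3, 0.1]      # region A: dissimilar
        cube = ReflectanceCube(data, GRID4)
        maps = sam_similarity_maps(cube, np.ones((4, 4), bool),
                                   _refs([0.1, 0.3, 0.5, 0.7], [1, 0, 0, 0]))
        sim_a = maps.healthy[0, 0]
        out = sam_classify(maps, thresholding="fixed",
                           fixed_threshold=(sim_a + 1.0) / 2)
        assert (out.values[:2, :2] == 2).all()
        assert (out.values[2:, 2:] == 1).all()

    def test_glare_pixels_are_forced_healthy(self):
        data = np.tile([0.1, 0.3, 0.5, 0.7], (4, 4, 1)).astype(float)
        data[0, 0] = [3.8, 3.9, 4.0, 4.1]        # bright, flat glint
        cube = ReflectanceCube(data, GRID4)
        maps = sam_similarity_maps(cube, np.ones((4, 4), bool),
                                   _refs([0.1, 0.3, 0.5, 0.7], [1, 0, 0, 0]),
                                   glare_percentile=90.0)
        assert maps.glare[0, 0]
        out = sam_classify(maps, thresholding="fixed",
                           fixed_threshold=0.999)
        assert out.values[0, 0] == 1

    def test_fixed_thresholding_without_value_is_an_error(self):
        h = np.array([0.1, 0.3, 0.5, 0.7])
        cube = ReflectanceCube(np.tile(h, (2, 2, 1)), GRID4)
        maps = sam_similarity_maps(cube, np.ones((2, 2), bool),
                                   _refs(h, h[::-1]))
        with pytest.raises(ValueError):
            sam_classify(maps, thresholding="fixed", fixed_threshold=None)

    def test_glare_rule_targets_brightest_flat_pixels(self):
        data = np.full((10, 10, 4), 0.4)
        data[5, 5] = 2.0
        cube = ReflectanceCube(data, GRID4)
        glare = glare_mask(cube, np.ones((10, 10), bool), percentile=98.0,
                           absolute=0.9)
        assert glare[5, 5]
        assert glare.sum() <= 9    # the glint plus its one-pixel dilation


class TestForest:
    def test_separable_classes_are_learned_with_low_oob_error(self, rng):
        X, y = _two_class_data(rng, sep=8.0)
        clf = SpectralForestClassifier(seed=0).fit(X, y)
        assert (clf.predict(X) == y).all()
        assert clf.oob_error_ < 0.05

    def test_seeded_training_is_deterministic(self, rng):
        X, y = _two_class_data(rng, n=80)
        probe = rng.random((30, 81)) * 0.6
        a = SpectralForestClassifier(seed=7).fit(X, y).predict(probe)
        b = SpectralForestClassifier(seed=7).fit(X, y).predict(probe)
        assert np.array_equal(a, b)

    def test_ensemble_reduces_out_of_bag_error(self, rng):
        X, y = _two_class_data(rng, n=300, sep=1.0)
        X += 0.05 * rng.standard_normal(X.shape)
        few = SpectralForestClassifier(n_trees=1, seed=1).fit(X, y)
        many = SpectralForestClassifier(n_trees=100, seed=1).fit(X, y)
        assert many.oob_error_ <= few.oob_error_

    def test_single_class_training_is_an_error(self, rng):
        X = rng.random((10, 5))
        with pytest.raises(ValueError):
            SpectralForestClassifier().fit(X, np.zeros(10, int))


class TestSVM:
    def test_well_separated_gaussians_in_81d(self, rng):
        X, y = _two_class_data(rng, n=400, sep=6.0)
        clf = SpectralSVMClassifier(seed=0).fit(X, y)
        Xt, yt = _two_class_data(np.random.default_rng(99), n=200, sep=6.0)
        assert (clf.predict(Xt) != yt).mean() < 0.02

    def test_duplicating_training_points_leaves_decisions_unchanged(self, rng):
        X, y = _two_class_data(rng, n=60, sep=8.0)
        probe = _two_class_data(np.random.default_rng(1), n=40, sep=8.0)[0]
        base = SpectralSVMClassifier(C=100.0, seed=0).fit(X, y)
        doubled = SpectralSVMClassifier(C=100.0, seed=0).fit(
            np.r_[X, X], np.r_[y, y])
        assert np.allclose(base.decision_function(probe),
                           doubled.decision_function(probe), atol=1e-3)
        assert np.array_equal(base.predict(probe), doubled.predict(probe))

    def test_two_point_boundary_bisects_the_points(self):
        a = np.full(10, 0.2)
        b = np.full(10, 0.8)
        clf = SpectralSVMClassifier(seed=0).fit(np.vstack([a, b]),
                                                np.array([0, 1]))
        midpoint = (a + b) / 2
        margin = np.abs(clf.decision_function(midpoint[None, :]))[0]
        edge = np.abs(clf.decision_function(a[None, :]))[0]
        assert margin < 0.2 * max(edge, 1.0)

    def test_subsample_cap_is_recorded(self, rng):
        X, y = _two_class_data(rng, n=300)
        clf = SpectralSVMClassifier(subsample_cap=100, seed=0).fit(X, y)
        assert clf.n_train_used_ <= 101


class TestCNN:
    def test_parameter_count_matches_hand_derived_sum(self):
        B = 81
        net = SpectralConvNet(n_bands=B, seed=0)
        conv1 = 1 * 8 * 5 + 8
        conv23 = 2 * (8 * 8 * 5 + 8)
        bn = 3 * (8 + 8)
        fc = (8 * 64 + 64) + (64 * 16 + 16) + (16 * 2 + 2)
        assert net.n_parameters == conv1 + conv23 + bn + fc

    def test_trivially_separable_classes_reach_full_accuracy(self, rng):
        X = np.r_[np.full((60, 81), 0.2), np.full((60, 81), 0.8)]
        X += 0.005 * rng.standard_normal(X.shape)
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        clf = SpectralCNNClassifier(epochs=20, seed=0).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_training_is_bit_deterministic(self, rng):
        X, y = _two_class_data(rng, n=50)
        a = SpectralCNNClassifier(epochs=3, seed=5).fit(X, y)
        b = SpectralCNNClassifier(epochs=3, seed=5).fit(X, y)
        assert a.final_loss_ == b.final_loss_

    def test_spectra_shorter_than_the_kernel_are_rejected(self):
        with pytest.raises(ValueError):
            SpectralCNNClassifier().fit(np.random.rand(10, 3),
                                        np.r_[np.zeros(5, int),
                                              np.ones(5, int)])


class TestPredictMap:
    def test_empty_mask_gives_all_zero_map(self, rng):
        X, y = _two_class_data(rng, n=30, bands=4)
        clf = SpectralForestClassifier(n_trees=5, seed=0).fit(X, y)
        cube = ReflectanceCube(rng.random((5, 5, 4)), GRID4)
        out = predict_map(clf, cube, np.zeros((5, 5), bool))
        assert not out.values.any()

    def test_band_mismatch_is_an_error(self, rng):
        X, y = _two_class_data(rng, n=30, bands=6)
        clf = SpectralForestClassifier(n_trees=5, seed=0).fit(X, y)
        cube = ReflectanceCube(rng.random((5, 5, 4)), GRID4)
        with pytest.raises(ValueError):
            predict_map(clf, cube, np.ones((5, 5), bool))

    def test_all_methods_emit_maps_of_identical_shape(self, rng):
        X, y = _two_class_data(rng, n=60, bands=81)
        grid = SpectralGrid(np.arange(450.0, 852.5, 5.0))
        cube = ReflectanceCube(
            np.abs(rng.random((6, 7, 81))) + 0.05, grid)
        mask = np.ones((6, 7), bool)
        shapes = set()
        for method in ("sam", "rf", "svm", "nn"):
            overrides = {"epochs": 2} if method == "nn" else {}
            model = make_classifier(method, seed=0, **overrides).fit(X, y)
            shapes.add(predict_map(model, cube, mask).values.shape)
        assert shapes == {(6, 7)}

    def test_decision_maps_only_mark_masked_pixels(self, rng):
        X, y = _two_class_data(rng, n=40, bands=4)
        clf = SpectralForestClassifier(n_trees=5, seed=0).fit(X, y)
        cube = ReflectanceCube(rng.random((8, 8, 4)), GRID4)
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        out = predict_map(clf, cube, mask)
        assert not out.values[~mask].any()
        assert (out.values[mask] > 0).all()
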