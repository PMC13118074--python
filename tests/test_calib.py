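import numpy as np
import pytest

from hsiseg.calib import (build_object_masks, extract_object_cubes,
                          filter_mask_areas, median_filter_bands,
                          otsu_threshold, reflectance_local,
                          reflectance_simultaneous)
from hsiseg.spectra import (IlluminationSet, ReflectanceCube, SpectralCube,
                            SpectralGrid)

ONE_BAND = SpectralGrid(np.array([750.0]))


def brute_force_otsu(values, nbins=256):
    """Exhaustive search over all bin splits maximizing between-class
    variance; deliberately naive (per-candidate class sums) and carried
    out in exact rational arithmetic over bin-index units."""
    from fractions import Fraction

    v = np.sort(np.asarray(values, dtype=float))
    counts, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.arange(nbins)
    total = int(counts.sum())
    best, best_sigma = None, Fraction(-1)
    for k in range(nbins - 1):
        n0 = int(counts[: k + 1].sum())
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = Fraction(int((counts[: k + 1] * idx[: k + 1]).sum()), n0)
        mu1 = Fraction(int((counts[k + 1:] * idx[k + 1:]).sum()), n1)
        sigma = Fraction(n0 * n1, total * total) * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best = sigma, centers[k]
    return best


class TestMedianFilter:
    def test_constant_band_is_unchanged(self):
        cube = SpectralCube(np.full((6, 6, 1), 3.5), ONE_BAND)
        assert np.array_equal(median_filter_bands(cube).data, cube.data)

    def test_isolated_impulse_is_removed(self):
        data = np.zeros((7, 7, 1))
        data[3, 3, 0] = 100.0
        out = median_filter_bands(SpectralCube(data, ONE_BAND))
        assert out.data[3, 3, 0] == 0.0

    def test_matches_brute_force_sort_and_pick(self, rng):
        band = rng.random((7, 7))
        cube = SpectralCube(band[:, :, None], ONE_BAND)
        out = median_filter_bands(cube).data[:, :, 0]
        padded = np.pad(band, 1, mode="edge")
        for i in range(7):
            for j in range(7):
                window = padded[i:i + 3, j:j + 3].ravel()
                assert out[i, j] == np.sort(window)[4]

    def test_bands_are_filtered_independently(self, rng):
        grid = SpectralGrid(np.array([500.0, 600.0]))
        data = rng.random((9, 9, 2))
        out = median_filter_bands(SpectralCube(data, grid))
        solo = median_filter_bands(
            SpectralCube(data[:, :, :1], ONE_BAND)).data[:, :, 0]
        assert np.array_equal(out.data[:, :, 0], solo)


class TestReflectanceRecovery:
    def test_object_equal_to_reference_gives_unit_reflectance(self, rng):
        ref = SpectralCube(rng.random((5, 5, 1)) + 0.5, ONE_BAND)
        R = reflectance_local(ref, ref)
        assert np.allclose(R.data, 1.0)
        assert R.mode == "local"

    def test_scalar_halving_and_direct_division(self):
        ref = SpectralCube(np.full((2, 2, 1), 240.0), ONE_BAND)
        obj = SpectralCube(np.full((2, 2, 1), 120.0), ONE_BAND)
        assert np.allclose(reflectance_local(obj, ref).data, 0.5)

    def test_zero_reference_marks_pixel_invalid(self):
        ref_data = np.ones((3, 3, 1))
        ref_data[1, 1, 0] = 0.0
        R = reflectance_local(SpectralCube(np.ones((3, 3, 1)), ONE_BAND),
                              SpectralCube(ref_data, ONE_BAND))
        assert R.invalid[1, 1]
        assert R.invalid.sum() == 1

    def test_simultaneous_hand_sum(self):
        grid = ONE_BAND
        objs = [SpectralCube(np.full((1, 1, 1), v), grid) for v in (1.0, 2.0, 3.0)]
        refs = [SpectralCube(np.full((1, 1, 1), 2.0), grid) for _ in range(3)]
        R = reflectance_simultaneous(IlluminationSet(obj=objs, ref=refs))
        assert R.data[0, 0, 0] == pytest.approx(1.0)
        assert R.mode == "simultaneous"

    def test_simultaneous_degenerates_to_local_for_identical_angles(self, rng):
        obj = SpectralCube(rng.random((4, 4, 1)), ONE_BAND)
        ref = SpectralCube(rng.random((4, 4, 1)) + 0.5, ONE_BAND)
        ill = IlluminationSet(obj=[obj] * 3, ref=[ref] * 3)
        assert np.allclose(reflectance_simultaneous(ill).data,
                           reflectance_local(obj, ref).data)

    def test_noiseless_phantom_reflectance_equals_true_volume(self, clean_scene):
        truth, ill = clean_scene
        R = reflectance_simultaneous(ill)
        assert np.allclose(R.data, truth.r_vol, atol=1e-6)


class TestOtsu:
    def test_perfect_bimodality_splits_the_modes(self):
        values = np.r_[np.full(100, 0.1), np.full(100, 0.9)]
        thr = otsu_threshold(values)
        assert 0.1 < thr < 0.9

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(10, 0.4))

    @pytest.mark.parametrize("case", range(20))
    def test_matches_exhaustive_between_class_variance_search(self, case):
        rng = np.random.default_rng(1000 + case)
        # draw from a distribution family indexed by the case number
        kind = case % 3
        if kind == 0:
            values = rng.random(500)
        elif kind == 1:
            values = np.r_[rng.normal(0.2, 0.05, 300), rng.normal(0.7, 0.1, 200)]
        else:
            values = rng.exponential(1.0, 400)
        assert otsu_threshold(values) == brute_force_otsu(values)

    def test_two_gaussian_clusters_are_separated_cleanly(self):
        rng = np.random.default_rng(77)
        lo = rng.normal(0.2, 0.05, 1000)
        hi = rng.normal(0.8, 0.05, 1000)
        thr = otsu_threshold(np.r_[lo, hi])
        misassigned = (lo > thr).sum() + (hi <= thr).sum()
        assert misassigned / 2000 < 0.01


def _disk_frame(radii, centers, shape=(400, 900)):
    """Bright disks on dark background, one 750 nm band."""
    data = np.full(shape + (1,), 0.05)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for r, (cy, cx) in zip(radii, centers):
        data[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r, 0] = 0.8
    return ReflectanceCube(data, ONE_BAND)


class TestObjectMasks:
    def test_area_window_keeps_only_mid_sized_disk(self):
        # disk areas ~5,000 / ~30,000 / ~50,000 px
        R = _disk_frame([40, 98, 126], [(100, 120), (200, 420), (180, 720)])
        masks = build_object_masks(R, 750.0, 20_000, 40_000)
        assert masks.n_objects == 1
        assert 20_000 <= masks.areas[0] <= 40_000
        # the retained component is the middle disk
        ys, xs = np.nonzero(masks.component(0))
        assert abs(ys.mean() - 200) < 3 and abs(xs.mean() - 420) < 3

    def test_frame_without_object_sized_regions_warns(self):
        data = np.full((50, 50, 1), 0.02)
        data[5:8, 5:8, 0] = 0.8        # bright speckles far below min_area
        data[30:33, 40:43, 0] = 0.8
        R = ReflectanceCube(data, ONE_BAND)
        with pytest.warns(UserWarning):
            masks = build_object_masks(R, 750.0, 1000, 2000)
        assert masks.n_objects == 0
        assert not masks.any_mask.any()

    def test_phantom_component_overlaps_true_fruit(self):
        from hsiseg.phantom import PhantomConfig, make_phantom_scene
        truth = make_phantom_scene(PhantomConfig(
            height=220, width=220, n_fruits=1, fruit_radius=90, seed=0))
        R = ReflectanceCube(truth.r_vol, truth.grid)
        masks = build_object_masks(R, 750.0, 20_000, 40_000)
        assert masks.n_objects == 1
        comp = masks.component(0)
        fruit = truth.labels != 0
        iou = (comp & fruit).sum() / (comp | fruit).sum()
        assert iou >= 0.95

    def test_area_filter_is_idempotent(self):
        R = _disk_frame([40, 98, 126], [(100, 120), (200, 420), (180, 720)])
        masks = build_object_masks(R, 750.0, 20_000, 40_000)
        again = filter_mask_areas(masks)
        assert np.array_equal(masks.label_image, again.label_image)
        assert masks.areas == again.areas


class TestObjectExtraction:
    def test_single_component_crop_preserves_area(self):
        R = _disk_frame([98], [(200, 420)])
        masks = build_object_masks(R, 750.0, 20_000, 40_000)
        crops = extract_object_cubes(R, masks)
        assert len(crops) == 1
        assert crops[0].area == masks.areas[0]

    def test_two_components_have_disjoint_footprints(self):
        R = _disk_frame([98, 98], [(200, 220), (200, 650)])
        masks = build_object_masks(R, 750.0, 20_000, 40_000)
        crops = extract_object_cubes(R, masks)
        assert len(crops) == 2
        frames = []
        for crop in crops:
            full = np.zeros((400, 900), dtype=bool)
            r0, c0 = crop.offset
            h, w = crop.mask.shape
            full[r0:r0 + h, c0:c0 + w] = crop.mask
            frames.append(full)
        assert not (frames[0] & frames[1]).any()

    def test_crop_placed_back_reproduces_original_values(self, rng):
        data = rng.random((400, 900, 1)) * 0.05
        yy, xx = np.mgrid[0:400, 0:900]
        disk = (yy - 200) ** 2 + (xx - 420) ** 2 <= 98**2
        data[disk, 0] = 0.5 + 0.3 * rng.random(disk.sum())
        R = ReflectanceCube(data, ONE_BAND)
        masks = build_object_masks(R, 750.0, 20_000, 40_000)
        crop = extract_object_cubes(R, masks)[0]
        r0, c0 = crop.offset
        h, w = crop.mask.shape
        original = R.data[r0:r0 + h, c0:c0 + w]
        assert np.array_equal(crop.cube.data[crop.mask], original[crop.mask])
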