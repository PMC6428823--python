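import numpy as np
import pytest

from nodulescan.image import GrayImage
from nodulescan.phantom import PhantomSpec, generate_slice
from nodulescan.segmentation import (
    DegeneratePartitionError,
    DeParams,
    GaussianMixtureModel,
    GrayHistogram,
    classification_error,
    compute_histogram,
    corner_seeded_region_growing,
    de_optimal_thresholds,
    fill_holes,
    fit_mixture_from_partition,
    iterative_initial_threshold,
    remove_background,
    segment_lungs,
)
from tests.conftest import make_bimodal_hist


class TestHistogram:
    def test_constant_image(self):
        hist = compute_histogram(GrayImage(np.full((4, 4), 7.0)))
        assert hist.levels.tolist() == [7.0]
        assert hist.probs.tolist() == [1.0]

    def test_small_example(self):
        hist = compute_histogram(GrayImage(np.array([[0.0, 0.0], [1.0, 2.0]])))
        assert hist.levels.tolist() == [0.0, 1.0, 2.0]
        assert hist.probs.tolist() == [0.5, 0.25, 0.25]

    def test_mass_sums_to_one(self, rng):
        hist = compute_histogram(GrayImage(rng.normal(0, 300, (32, 32))))
        assert hist.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestMixtureFit:
    def test_two_delta_spikes(self):
        hist = GrayHistogram(levels=[10.0, 200.0], probs=[0.5, 0.5])
        gmm = fit_mixture_from_partition(hist, [100.0])
        assert gmm.weights.tolist() == [0.5, 0.5]
        assert gmm.means.tolist() == [10.0, 200.0]
        assert np.all(gmm.stds <= 1e-5)

    def test_uniform_histogram(self):
        levels = np.arange(256, dtype=float)
        hist = GrayHistogram(levels=levels, probs=np.full(256, 1 / 256))
        gmm = fit_mixture_from_partition(hist, [128.0])
        assert gmm.weights.tolist() == [0.5, 0.5]
        # moments of discrete uniforms over 0..127 and 128..255
        assert gmm.means.tolist() == [63.5, 191.5]

    def test_weights_sum_to_one(self, rng):
        levels, probs = make_bimodal_hist(rng, mu=(50, 120, 200), sigma=(8, 8, 8), weights=(0.3, 0.3, 0.4))
        gmm = fit_mixture_from_partition(GrayHistogram(levels, probs), [85.0, 160.0])
        assert gmm.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_interval_raises(self):
        hist = GrayHistogram(levels=[10.0, 200.0], probs=[0.5, 0.5])
        with pytest.raises(DegeneratePartitionError):
            fit_mixture_from_partition(hist, [250.0])


class TestClassificationError:
    def test_well_separated_classes(self):
        gmm = GaussianMixtureModel([0.5, 0.5], [50.0, 200.0], [5.0, 5.0])
        assert classification_error(gmm, [125.0]) < 1e-10

    def test_identical_classes(self):
        gmm = GaussianMixtureModel([0.5, 0.5], [100.0, 100.0], [10.0, 10.0])
        for t in (50.0, 100.0, 163.0):
            assert classification_error(gmm, [t]) == pytest.approx(0.5, abs=1e-12)

    def test_minimum_at_midpoint_for_equal_sigma(self):
        gmm = GaussianMixtureModel([0.5, 0.5], [80.0, 160.0], [15.0, 15.0])
        ts = np.linspace(81, 159, 391)
        errors = [classification_error(gmm, [t]) for t in ts]
        assert ts[int(np.argmin(errors))] == pytest.approx(120.0, abs=0.5)

    def test_wrong_threshold_count(self):
        gmm = GaussianMixtureModel([0.5, 0.5], [80.0, 160.0], [15.0, 15.0])
        with pytest.raises(ValueError):
            classification_error(gmm, [90.0, 120.0])

    def test_non_increasing_thresholds(self):
        gmm = GaussianMixtureModel([0.3, 0.3, 0.4], [50.0, 100.0, 200.0], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            classification_error(gmm, [120.0, 80.0])


def exhaustive_best_threshold(hist: GrayHistogram) -> int:
    """Brute-force oracle: score every integer threshold."""
    best_t, best_e = None, np.inf
    for t in range(int(hist.levels.min()) + 1, int(hist.levels.max()) + 1):
        try:
            gmm = fit_mixture_from_partition(hist, [float(t)])
        except DegeneratePartitionError:
            continue
        e = classification_error(gmm, [float(t)])
        if e < best_e:
            best_t, best_e = t, e
    return best_t


class TestDeThresholds:
    def test_matches_exhaustive_bimodal(self, rng):
        levels, probs = make_bimodal_hist(rng)
        hist = GrayHistogram(levels, probs)
        tset = de_optimal_thresholds(hist, k=2, seed=3)
        assert abs(tset.thresholds[0] - exhaustive_best_threshold(hist)) <= 3

    def test_deterministic(self, rng):
        levels, probs = make_bimodal_hist(rng)
        hist = GrayHistogram(levels, probs)
        a = de_optimal_thresholds(hist, k=2, seed=42)
        b = de_optimal_thresholds(hist, k=2, seed=42)
        assert np.array_equal(a.thresholds, b.thresholds)
        assert a.total_error == b.total_error

    def test_too_few_levels(self):
        hist = GrayHistogram(levels=[5.0], probs=[1.0])
        with pytest.raises(ValueError):
            de_optimal_thresholds(hist, k=2)

    def test_trimodal_matches_grid_search(self, rng):
        levels, probs = make_bimodal_hist(
            rng, mu=(40, 100, 170), sigma=(8, 8, 8), weights=(0.3, 0.4, 0.3), n_levels=211
        )
        hist = GrayHistogram(levels, probs)
        tset = de_optimal_thresholds(hist, k=3, seed=5)
        # exhaustive 2D oracle
        best, best_e = None, np.inf
        for t1 in range(20, 140):
            for t2 in range(t1 + 1, 200):
                try:
                    gmm = fit_mixture_from_partition(hist, [t1, t2])
                except DegeneratePartitionError:
                    continue
                e = classification_error(gmm, [float(t1), float(t2)])
                if e < best_e:
                    best, best_e = (t1, t2), e
        assert abs(tset.thresholds[0] - best[0]) <= 3
        assert abs(tset.thresholds[1] - best[1]) <= 3


class TestIterativeThreshold:
    def test_two_value_image(self):
        px = np.array([[-1000.0, 0.0], [-1000.0, 0.0]])
        assert iterative_initial_threshold(GrayImage(px)) == pytest.approx(-500.0)

    def test_constant_image_warns(self):
        with pytest.warns(UserWarning):
            t = iterative_initial_threshold(GrayImage(np.full((4, 4), -100.0)))
        assert t == -950.0

    def test_phantom_slice_separates_lung_from_tissue(self, phantom_slice):
        # the fixed point must land above the parenchyma band and below soft
        # tissue, so thresholding at it isolates the dark lung-ish region
        img, truth = phantom_slice
        t = iterative_initial_threshold(img)
        parenchyma = img.pixels[truth.lung_mask & ~truth.nodule_mask & ~truth.vessel_mask]
        assert parenchyma.mean() < t < 40.0


class TestRemoveBackground:
    def test_all_background(self):
        img = GrayImage(np.full((8, 8), 10.0), value_domain="uint8")
        fg = remove_background(img, bg_range=(0, 20))
        assert not fg.any()

    def test_dark_frame_bright_disc(self):
        px = np.zeros((16, 16))
        px[5:11, 5:11] = 200.0
        fg = remove_background(GrayImage(px, value_domain="uint8"), bg_range=(0, 20))
        assert fg[6, 6] and fg[5:11, 5:11].all()
        assert not fg[0, 0] and not fg[15, 15] and not fg[0, 8]

    def test_corner_pixel_in_range_never_foreground(self, rng):
        px = rng.integers(0, 256, (16, 16)).astype(float)
        img = GrayImage(px, value_domain="uint8")
        fg = remove_background(img, bg_range=(px.min(), px.min() + 24))
        for r, c in ((0, 0), (0, 15), (15, 0), (15, 15)):
            if px[r, c] <= px.min() + 24:
                assert not fg[r, c]


class TestMaskOps:
    def test_corner_component_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:3, 0:3] = True  # touches corner
        mask[5:8, 5:8] = True  # interior
        out = corner_seeded_region_growing(mask)
        assert not out[0:3, 0:3].any()
        assert out[5:8, 5:8].all()

    def test_all_false(self):
        assert not corner_seeded_region_growing(np.zeros((5, 5), dtype=bool)).any()

    def test_no_corner_touch_unchanged(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:7, 4:7] = True
        assert np.array_equal(corner_seeded_region_growing(mask), mask)

    def test_ring_fills_to_disc(self):
        from skimage.draw import disk

        mask = np.zeros((20, 20), dtype=bool)
        rr, cc = disk((10, 10), 7)
        mask[rr, cc] = True
        rr, cc = disk((10, 10), 3)
        ring = mask.copy()
        ring[rr, cc] = False
        assert np.array_equal(fill_holes(ring), mask)

    def test_solid_disc_unchanged(self):
        from skimage.draw import disk

        mask = np.zeros((20, 20), dtype=bool)
        rr, cc = disk((10, 10), 6)
        mask[rr, cc] = True
        assert np.array_equal(fill_holes(mask), mask)

    def test_two_rings_two_discs(self):
        from skimage import measure
        from skimage.draw import disk

        ring = np.zeros((20, 40), dtype=bool)
        for cen in ((10, 10), (10, 30)):
            rr, cc = disk(cen, 7)
            ring[rr, cc] = True
            rr, cc = disk(cen, 3)
            ring[rr, cc] = False
        filled = fill_holes(ring)
        assert measure.label(filled).max() == 2
        assert not (filled & ~ring).sum() == 0  # holes actually got filled

    def test_fill_holes_idempotent(self, rng):
        mask = rng.random((32, 32)) > 0.5
        once = fill_holes(mask)
        assert np.array_equal(fill_holes(once), once)


class TestSegmentLungs:
    def test_phantom_dice(self, phantom_slice):
        img, truth = phantom_slice
        mask = segment_lungs(img, seed=0)
        inter = (mask & truth.lung_mask).sum()
        dice = 2 * inter / (mask.sum() + truth.lung_mask.sum())
        assert dice >= 0.95

    def test_dice_across_seeds(self):
        dices = []
        for seed in range(25):
            img, truth = generate_slice(PhantomSpec(seed=seed))
            mask = segment_lungs(img, seed=0)
            inter = (mask & truth.lung_mask).sum()
            dices.append(2 * inter / (mask.sum() + truth.lung_mask.sum()))
        assert min(dices) >= 0.95

    def test_mask_area_fraction(self, phantom_slice):
        img, _ = phantom_slice
        mask = segment_lungs(img, seed=0)
        frac = mask.mean()
        assert 0.05 < frac < 0.6

    def test_solid_body_empty_mask(self):
        px = np.full((64, 64), -1000.0)
        px[8:56, 8:56] = 40.0  # solid soft tissue, no lungs
        with pytest.warns(UserWarning):
            mask = segment_lungs(GrayImage(px), seed=0)
        assert not mask.any()

    def test_rejects_uint8(self, uint8_image):
        with pytest.raises(ValueError):
            segment_lungs(uint8_image)
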