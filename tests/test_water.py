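import numpy as np
import pytest
from scipy import ndimage

from lakefui import water
from lakefui.radiometry import correct_water_leaving
from lakefui.sceneio import QA, Affine
from lakefui.synthetic import LakeSpec, SceneSpec, generate_scene
from tests.conftest import make_scene

SQUARE = np.ones((3, 3), dtype=bool)


def disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestInitialWaterMask:
    def test_all_land_gives_empty_mask(self):
        scene = make_scene({"swir1640": np.full((10, 10), 0.2)})
        assert not water.initial_water_mask(scene).any()

    def test_synthetic_lake_matches_truth(self, single_lake_spec):
        scene, truth = generate_scene(single_lake_spec)
        assert np.array_equal(water.initial_water_mask(scene),
                              truth.water_mask)

    def test_cloud_removes_flagged_half(self, single_lake_spec):
        scene, truth = generate_scene(single_lake_spec)
        half = np.zeros(scene.shape, dtype=bool)
        half[:, :70] = True
        scene.qa[half] |= QA.CLOUD
        expected = truth.water_mask & ~half
        assert np.array_equal(water.initial_water_mask(scene), expected)


class TestConnectedComponents:
    def test_area_floor(self):
        # 120 px at 500 m = 30 km2 kept; 50 px = 12.5 km2 dropped
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:20, 10:22] = True        # 120 px
        mask[60:65, 60:70] = True        # 50 px
        regions = water.connected_components(mask, min_area_km2=25)
        assert len(regions) == 1
        assert regions[0].area_pixels == 120

    def test_empty_mask(self):
        assert water.connected_components(np.zeros((5, 5), bool)) == []

    def test_diagonal_touching_is_one_component(self):
        mask = np.zeros((40, 80), dtype=bool)
        mask[5:15, 5:16] = True
        mask[15:25, 16:27] = True  # touches only at the (14,15)/(15,16) corner
        regions = water.connected_components(mask, min_area_km2=25)
        assert len(regions) == 1

    def test_row_major_ordering_and_ids(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[50:61, 5:16] = True
        mask[5:16, 50:61] = True
        regions = water.connected_components(mask, min_area_km2=25,
                                             scene_id="tileA")
        assert [r.lake_id for r in regions] == ["tileA_1", "tileA_2"]
        first = np.argwhere(regions[0].component_mask)[0]
        assert first[0] < 50  # upper component first


class TestBuildBuffer:
    def test_disc_expansion_within_one_ring(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask |= disc_mask(mask.shape, (40, 40), 5.6)  # ~100 px
        region = water.LakeRegion("x", mask)
        area = mask.sum()
        water.build_buffer(region, factor=1.5)
        expanded = region.buffer_mask.sum()
        # oracle: one extra dilation ring from the last sub-target state
        below = mask.copy()
        while True:
            grown = ndimage.binary_dilation(below, structure=SQUARE)
            if grown.sum() >= 1.5 * area:
                break
            below = grown
        ring = grown.sum() - below.sum()
        assert 1.5 * area <= expanded <= 1.5 * area + ring

    def test_factor_one_is_identity(self):
        mask = disc_mask((40, 40), (20, 20), 6)
        region = water.LakeRegion("x", mask)
        water.build_buffer(region, factor=1.0)
        assert np.array_equal(region.buffer_mask, mask)

    def test_grid_edge_truncation_warns(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:11, 1:11] = True  # can never reach 1.5x on this grid
        region = water.LakeRegion("edge", mask)
        water.build_buffer(region, factor=1.5)
        assert region.buffer_mask.sum() < 1.5 * mask.sum()
        assert any("truncated" in w for w in region.warnings)


class TestFindThreshold:
    def test_valley_in_planted_gap(self):
        # water mode below 0.055, land mode above 0.09: the density gap is
        # (0.055, 0.09) and the threshold must land inside it
        rng = np.random.default_rng(0)
        sample = np.concatenate(
            [rng.uniform(0.0, 0.055, 5000), rng.uniform(0.09, 0.30, 5000)]
        )
        thr, fallback = water.find_threshold(sample)
        assert not fallback
        # brute-force valley oracle over the same binning
        edges = np.arange(0.0, sample.max() + 0.004, 0.002)
        counts, edges = np.histogram(sample, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        win = (centers >= 0.04) & (centers <= 0.12)
        oracle = centers[win][np.argmin(counts[win])]
        assert thr == pytest.approx(oracle)
        assert 0.055 <= thr <= 0.09

    def test_uniform_sample_falls_back_to_midpoint(self):
        rng = np.random.default_rng(1)
        thr, fallback = water.find_threshold(rng.uniform(0, 0.3, 10000))
        assert fallback
        assert thr == pytest.approx(0.08)

    def test_tie_breaks_toward_lower_reflectance(self):
        # two empty window bins at 0.06 and 0.09, equal (zero) counts
        sample = np.concatenate(
            [np.full(100, 0.02), np.full(5, 0.075), np.full(100, 0.2)]
        )
        thr, fallback = water.find_threshold(sample, bin_width=0.01)
        assert not fallback
        assert thr < 0.07

    def test_no_values_on_one_side_falls_back(self):
        thr, fallback = water.find_threshold(np.full(100, 0.02))
        assert fallback and thr == pytest.approx(0.08)


class TestRefineLake:
    def _extract(self, scene):
        initial = water.initial_water_mask(scene)
        regions = water.connected_components(initial)
        assert len(regions) == 1
        return water.build_buffer(regions[0])

    def test_noise_free_equals_truth_eroded(self, single_lake_spec):
        scene, truth = generate_scene(single_lake_spec)
        region = self._extract(scene)
        water.refine_lake(scene, region)
        oracle = ndimage.binary_erosion(truth.water_mask, structure=SQUARE)
        assert np.array_equal(region.refined_mask, oracle)

    def test_fully_clouded_lake_is_unobserved(self, single_lake_spec):
        scene, truth = generate_scene(single_lake_spec)
        scene.qa[truth.water_mask] |= QA.CLOUD
        region = water.LakeRegion("x", truth.water_mask)
        water.build_buffer(region)
        water.refine_lake(scene, region)
        assert not region.refined_mask.any()

    def test_shallow_rim_excluded(self):
        spec = SceneSpec(
            grid_shape=(80, 80),
            lakes=[LakeSpec(shape=("ellipse", (40, 40, 12, 12)),
                            base_fui=5, shallow_margin_pixels=2)],
            seed=3,
        )
        scene, truth = generate_scene(spec)
        region = self._extract(scene)
        water.refine_lake(scene, region)
        interior = ndimage.binary_erosion(truth.water_mask,
                                          structure=SQUARE, iterations=2)
        rim = truth.water_mask & ~interior
        assert not (region.refined_mask & rim).any()
        assert region.refined_mask.sum() > 0

    def test_shallow_threshold_monotonicity(self, single_lake_spec):
        scene, _ = generate_scene(single_lake_spec)
        region = self._extract(scene)
        sizes = []
        for thr in (0.01, 0.04, 0.06, 0.2):
            r = water.LakeRegion("x", region.component_mask,
                                 buffer_mask=region.buffer_mask)
            water.refine_lake(scene, r, shallow_blue_threshold=thr)
            sizes.append(r.refined_mask.sum())
        assert sizes == sorted(sizes)

    def test_refined_subset_of_buffer_and_no_flagged(self, single_lake_spec):
        single_lake_spec.cloud_fraction = 0.2
        scene, _ = generate_scene(single_lake_spec)
        region = self._extract(scene)
        water.refine_lake(scene, region)
        assert not (region.refined_mask & ~region.buffer_mask).any()
        assert not (region.refined_mask
                    & ((scene.qa & QA.BAD) != 0)).any()


class TestNormalWaterMask:
    def test_occurrence_rule(self):
        shape = (4, 4)
        wet = np.zeros(shape, bool)
        wet[1, 1] = True
        dry = np.zeros(shape, bool)
        obs = np.ones(shape, bool)
        refined = [wet] * 10 + [dry] * 10   # 50% occurrence
        nm = water.normal_water_mask(refined, [obs] * 20)
        assert nm.mask[1, 1]
        refined = [wet] * 2 + [dry] * 18    # 10% — ephemeral
        nm = water.normal_water_mask(refined, [obs] * 20)
        assert not nm.mask.any()

    def test_denominator_counts_only_observable_dates(self):
        shape = (3, 3)
        wet = np.zeros(shape, bool)
        wet[1, 1] = True
        dry = np.zeros(shape, bool)
        clouded = np.zeros(shape, bool)
        clear = np.ones(shape, bool)
        # water on 4 of 20 dates, but observable on only 10 -> 40% > 30%
        refined = [wet] * 4 + [dry] * 16
        observable = [clear] * 10 + [clouded] * 10
        nm = water.normal_water_mask(refined, observable)
        assert nm.mask[1, 1]

    def test_centroid_through_affine(self):
        shape = (10, 10)
        mask = np.zeros(shape, bool)
        mask[4, 7] = True
        tr = Affine(30.0, 0.01, 50.0, -0.01)
        nm = water.normal_water_mask([mask], [np.ones(shape, bool)],
                                     transform=tr)
        assert nm.centroid_lon == pytest.approx(30.0 + 7.5 * 0.01)
        assert nm.centroid_lat == pytest.approx(50.0 - 4.5 * 0.01)

    def test_area_from_pixel_count(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True  # 100 px at 500 m -> 25 km2
        nm = water.normal_water_mask([mask], [np.ones((20, 20), bool)])
        assert nm.area_km2 == pytest.approx(25.0)

    def test_invariant_to_date_ordering(self):
        rng = np.random.default_rng(5)
        shape = (8, 8)
        refined = [rng.random(shape) < 0.4 for _ in range(12)]
        observable = [rng.random(shape) < 0.8 for _ in range(12)]
        nm1 = water.normal_water_mask(refined, observable)
        order = rng.permutation(12)
        nm2 = water.normal_water_mask([refined[i] for i in order],
                                      [observable[i] for i in order])
        assert np.array_equal(nm1.mask, nm2.mask)


class TestExtractionIoU:
    def test_refined_dilated_iou_against_truth(self):
        """Noise-free scenes: refined mask (plus the 1-pixel erosion
        allowance) must overlap truth with IoU >= 0.9."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            spec = SceneSpec(
                grid_shape=(100, 140),
                lakes=[LakeSpec(
                    shape=("ellipse",
                           (int(rng.integers(25, 60)),
                            int(rng.integers(30, 100)),
                            int(rng.integers(8, 14)),
                            int(rng.integers(8, 14)))),
                    base_fui=int(rng.integers(1, 17)))],
                residual_level=0.01,
                seed=seed,
            )
            scene, truth = generate_scene(spec)
            region = water.build_buffer(
                water.connected_components(water.initial_water_mask(scene))[0]
            )
            water.refine_lake(scene, region)
            dilated = ndimage.binary_dilation(region.refined_mask,
                                              structure=SQUARE)
            iou = (np.logical_and(dilated, truth.water_mask).sum()
                   / np.logical_or(dilated, truth.water_mask).sum())
            assert iou >= 0.9
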