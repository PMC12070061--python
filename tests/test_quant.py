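"""Intensity quantifications: partitions, colocalization, spots, gels."""

import numpy as np
import pytest

from axonquant.core import ImageScene, PolygonROI
from axonquant.quant import (
    count_spots,
    density_normalized_count,
    gel_band_quant,
    partition_signal,
    per_cell_coloc,
)
from axonquant.synth import GrowthParams, generate_coloc_scene, generate_gel_profile


def _square_roi(x0, y0, side):
    return PolygonROI([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


class TestPartitionSignal:
    def test_all_signal_inside_core(self):
        img = np.zeros((100, 100))
        img[40:60, 40:60] = 80.0
        part = partition_signal(img, _square_roi(30, 30, 40), background=0.0)
        assert part.axon_fraction == 0.0
        assert part.core_fraction == 1.0

    def test_uniform_image_fractions_proportional_to_area(self):
        img = np.full((100, 100), 20.0)
        roi = _square_roi(0, 0, 50)  # quarter of the frame
        part = partition_signal(img, roi, background=0.0)
        from axonquant.core import polygon_mask

        inside_n = polygon_mask(roi, img.shape).sum()
        assert part.core_fraction == pytest.approx(inside_n / img.size, abs=0.01)
        assert part.axon_fraction + part.core_fraction == 1.0

    def test_conservation_on_random_images(self, rng):
        for _ in range(100):
            img = rng.uniform(0, 255, size=(60, 60))
            part = partition_signal(img, _square_roi(10, 15, 30))
            assert part.axon_fraction + part.core_fraction == 1.0
            assert part.core_signal >= 0 and part.axon_signal >= 0

    def test_mean_ratio(self):
        img = np.full((100, 100), 10.0)
        img[:50, :] = 30.0  # top half brighter
        roi = PolygonROI([(0, 0), (99, 0), (99, 49), (0, 49)])
        part = partition_signal(img, roi, background=0.0)
        assert part.axon_to_core_ratio == pytest.approx(10.0 / 30.0, abs=0.02)


class TestPerCellColoc:
    def test_uniform_measure(self):
        mask = np.zeros((64, 64), dtype=np.uint16)
        mask[10:20, 10:20] = 300
        mask[40:50, 40:52] = 300
        meas = np.full((64, 64), 77, dtype=np.uint16)
        scene = ImageScene({"a": mask, "b": meas}, pixel_size_um=1.0)
        recs = per_cell_coloc(scene, "a", "b", threshold=100.0, min_area_px=10)
        assert len(recs) == 2
        assert all(r.mean_measure == pytest.approx(77.0) for r in recs)

    def test_membrane_ring_arithmetic(self):
        mask = np.zeros((64, 64), dtype=np.uint16)
        mask[20:40, 20:40] = 500  # 400-px cell
        meas = np.zeros((64, 64), dtype=np.uint16)
        meas[20:40, 20:30] = 200  # ring covers half the mask
        scene = ImageScene({"a": mask, "b": meas}, pixel_size_um=1.0)
        (rec,) = per_cell_coloc(scene, "a", "b", threshold=100.0, min_area_px=10)
        assert rec.mean_measure == pytest.approx(100.0)

    def test_generator_truth_recovery(self):
        p = GrowthParams(seed=5, noise=(0.0, 3.0))
        scene, truth = generate_coloc_scene(20, 0.5, 3.0, p)
        recs = per_cell_coloc(scene, "GFP", "bCat", threshold=60.0, min_area_px=30)
        assert len(recs) == len(truth.cells)
        got = sorted(r.mean_measure for r in recs)
        want = sorted(c["true_mean_measure"] for c in truth.cells)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=0.05)

    def test_mask_scaling_invariance(self):
        p = GrowthParams(seed=6, noise=(0.0, 0.0))
        scene, truth = generate_coloc_scene(8, 0.5, 2.0, p)
        a = per_cell_coloc(scene, "GFP", "bCat", threshold=60.0, min_area_px=30)
        scaled = ImageScene(
            {"GFP": scene.channel("GFP") * 2, "bCat": scene.channel("bCat")},
            pixel_size_um=scene.pixel_size_um,
        )
        b = per_cell_coloc(scaled, "GFP", "bCat", threshold=120.0, min_area_px=30)
        assert [r.mean_measure for r in a] == [r.mean_measure for r in b]

    def test_insufficient_staining_slice_excluded(self):
        mask = np.zeros((2, 32, 32), dtype=np.uint16)
        mask[:, 5:15, 5:15] = 300
        meas = np.zeros((2, 32, 32), dtype=np.uint16)
        meas[0] = 100  # slice 1 has essentially no staining
        scene = ImageScene({"a": mask, "b": meas}, pixel_size_um=1.0, z_step_um=1.0)
        recs = per_cell_coloc(
            scene, "a", "b", threshold=100.0, min_area_px=10, min_measure_level=50.0
        )
        assert [r.slice_index for r in recs] == [0]

    def test_empty_warns(self):
        scene = ImageScene(
            {"a": np.zeros((32, 32), dtype=np.uint16), "b": np.zeros((32, 32), dtype=np.uint16)},
            pixel_size_um=1.0,
        )
        with pytest.warns(UserWarning, match="no cells"):
            recs = per_cell_coloc(scene, "a", "b", threshold=10.0)
        assert recs == []


class TestDensity:
    def test_simple_division(self):
        assert density_normalized_count(50, 10_000.0) == pytest.approx(0.005)

    def test_zero_count(self):
        assert density_normalized_count(0, 123.0) == 0.0

    def test_doubling_area_halves_density(self):
        d1 = density_normalized_count(7, 1000.0)
        d2 = density_normalized_count(7, 2000.0)
        assert d2 == pytest.approx(d1 / 2)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            density_normalized_count(5, 0.0)


class TestCountSpots:
    def test_blank(self):
        n, c = count_spots(np.zeros((64, 64)), 3.0, 0.1)
        assert n == 0 and len(c) == 0

    def test_well_separated_gaussians(self):
        yy, xx = np.mgrid[0:256, 0:256]
        centers = [(40.0 + 60 * i, 40.0 + 60 * j) for i in range(4) for j in range(3)]
        img = np.zeros((256, 256))
        for cy, cx in centers:
            img += 100 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 3.0**2))
        n, got = count_spots(img, 3.0, threshold=5.0)
        assert n == 12
        for cy, cx in centers:
            assert np.min(np.hypot(got[:, 0] - cx, got[:, 1] - cy)) <= 1.0

    def test_merged_pair_counts_once(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 100 * np.exp(-((yy - 32) ** 2 + (xx - 30) ** 2) / (2 * 3.0**2))
        img += 100 * np.exp(-((yy - 32) ** 2 + (xx - 33) ** 2) / (2 * 3.0**2))
        n, _ = count_spots(img, 3.0, threshold=5.0)
        assert n == 1


class TestGelQuant:
    def test_flat_baseline_single_band(self):
        prof, truth = generate_gel_profile([500.0], [3000.0], 20.0)
        res = gel_band_quant(prof, [(400, 600)])
        assert res["areas"][0] == pytest.approx(3000.0, rel=0.01)

    def test_sloped_baseline_ratio(self):
        prof, truth = generate_gel_profile(
            [300.0, 600.0], [2000.0, 1000.0], 15.0, baseline=(10.0, 0.05), noise_sd=1.0, seed=2
        )
        res = gel_band_quant(prof, [(240, 360), (540, 660)])
        assert res["areas"][0] / res["areas"][1] == pytest.approx(2.0, rel=0.02)

    def test_flat_region_zero_area(self):
        prof = np.full(500, 12.0)
        res = gel_band_quant(prof, [(100, 200)])
        assert res["areas"][0] == 0.0

    def test_linear_baseline_invariance(self):
        prof, _ = generate_gel_profile([250.0], [1500.0], 12.0)
        x = np.arange(len(prof))
        res0 = gel_band_quant(prof, [(180, 320)])
        res1 = gel_band_quant(prof + 7.0 + 0.03 * x, [(180, 320)])
        assert res1["areas"][0] == pytest.approx(res0["areas"][0], rel=1e-6)

    def test_loading_control_normalization(self):
        prof, _ = generate_gel_profile([300.0, 600.0], [2400.0, 800.0], 15.0)
        res = gel_band_quant(prof, [(240, 360), (540, 660)], control_index=1)
        assert res["normalized"][0] == pytest.approx(3.0, rel=0.02)
        assert res["normalized"][1] == pytest.approx(1.0)

    def test_bad_bounds_rejected(self):
        prof = np.zeros(100)
        with pytest.raises(ValueError):
            gel_band_quant(prof, [(50, 150)])
        with pytest.raises(ValueError):
            gel_band_quant(prof, [(30, 60)], [(40, 70)])
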