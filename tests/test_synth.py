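"""The synthetic scene generators and their ground-truth bundles."""

import numpy as np
import pytest

from axonquant.geometry import circle_polyline_crossings, polyline_length
from axonquant.synth import (
    GrowthParams,
    explant_params,
    generate_coloc_scene,
    generate_explant_scene,
    generate_gel_profile,
    generate_nerve_scene,
    generate_neuron_scene,
    sample_neuron_tree,
    true_tip_count,
)
from axonquant.trees import neurite_paths


class TestNeuronTrees:
    def test_no_branching_gives_only_primaries(self):
        p = GrowthParams(seed=1, n_primary=1, branch_prob_per_um=0.0)
        tree = sample_neuron_tree(p)
        paths = neurite_paths(tree)
        assert len(paths) == 1
        assert paths[0]["order"] == 1
        assert len(tree.tips()) == 1

    def test_tips_are_degree_one_nonroot(self):
        for seed in range(10):
            tree = sample_neuron_tree(GrowthParams(seed=seed))
            tree.validate()
            for t in tree.tips():
                assert tree.graph.out_degree(t) == 0
                assert t != tree.root

    def test_per_order_counts_consistent_with_edge_orders(self):
        for seed in range(10):
            tree = sample_neuron_tree(GrowthParams(seed=seed, branch_prob_per_um=0.05))
            paths = neurite_paths(tree)
            # every edge belongs to exactly one neurite path
            edges_in_paths = [e for p in paths for e in p["edges"]]
            assert sorted(edges_in_paths) == sorted(tree.graph.edges())

    def test_branching_process_mean_matches_direct_simulation(self):
        # secondary count expectation: simulate the stated process directly
        # (normal-length neurite, 2 µm steps, Poisson branch events at
        # interior grid points) with 10^5 reps, then compare 1000 trees
        rate, mean, sd, step = 0.02, 50.0, 8.0, 2.0
        rng = np.random.default_rng(999)
        reps = 100_000
        lengths = np.maximum(rng.normal(mean, sd, reps), 0.25 * mean)
        counts = np.zeros(reps)
        for i, length in enumerate(lengths):
            s, nxt, c = 0.0, rng.exponential(1 / rate), 0
            while s < length:
                s += min(step, length - s)
                if s >= nxt and s < length - 1e-9:
                    c += 1
                    nxt += rng.exponential(1 / rate)
            counts[i] = c
        expected = counts.mean()  # per primary neurite

        got = []
        for seed in range(1000):
            p = GrowthParams(
                seed=seed, n_primary=1, branch_prob_per_um=rate,
                segment_len_um=(mean, sd), max_order=2,
            )
            tree = sample_neuron_tree(p)
            got.append(sum(1 for q in neurite_paths(tree) if q["order"] == 2))
        assert np.mean(got) == pytest.approx(expected, rel=0.05)


class TestNeuronScene:
    def test_deterministic_under_seed(self):
        a, ta = generate_neuron_scene(GrowthParams(seed=42))
        b, tb = generate_neuron_scene(GrowthParams(seed=42))
        assert np.array_equal(a.channel("GFP"), b.channel("GFP"))
        assert ta.trees[0].to_json() == tb.trees[0].to_json()

    def test_rendered_intensity_tracks_arclength(self):
        # noise-free: total above-background intensity ~ total arclength
        ratios = []
        for seed in (3, 4, 5):
            p = GrowthParams(seed=seed, noise=(0.0, 0.0), background=0.0)
            scene, truth = generate_neuron_scene(p)
            total = float(scene.channel("GFP").sum())
            ratios.append(total / truth.trees[0].total_length())
        assert max(ratios) / min(ratios) == pytest.approx(1.0, abs=0.02)

    def test_escape_raises_helpful_error(self):
        p = GrowthParams(seed=0, segment_len_um=(4000.0, 10.0), branch_prob_per_um=0.0)
        with pytest.raises(RuntimeError, match="canvas"):
            generate_neuron_scene(p, canvas_px=(128, 128))


class TestExplantScene:
    def test_no_axons_signal_only_in_core(self):
        p = explant_params(0)
        scene, truth = generate_explant_scene(p, n_axons=0)
        img = scene.channel("Tubb3").astype(float)
        outside = img[~truth.core_mask]
        # suprathreshold pixels all inside the (slightly dilated) core
        thr = p.background + 5 * p.noise[1]
        from scipy import ndimage as ndi

        near_core = ndi.binary_dilation(truth.core_mask, iterations=3)
        assert not np.any((img > thr) & ~near_core)
        assert outside.mean() == pytest.approx(p.background, abs=2.0)

    def test_straight_rays_cross_every_ring_once(self):
        p = explant_params(1)
        p = GrowthParams(**{**p.__dict__, "branch_prob_per_um": 0.0, "turn_sd_deg": 0.0})
        scene, truth = generate_explant_scene(
            p, core_radius_um=80.0, n_axons=8, ring_spacing_um=100.0, n_rings=5
        )
        # rays span 80..~780 um from center: all 8 cross rings at 100..500 um
        assert truth.ring_crossings.tolist() == [8, 8, 8, 8, 8]

    def test_truth_ring_counts_match_analytic_oracle(self):
        scene, truth = generate_explant_scene(explant_params(2))
        oracle = circle_polyline_crossings(
            truth.polylines(), truth.extras["center_um"], truth.ring_radii_um
        )
        assert np.array_equal(oracle, truth.ring_crossings)

    def test_region_signal_nonnegative_and_core_dominant(self):
        scene, truth = generate_explant_scene(explant_params(3))
        sig = truth.region_signal["Tubb3"]
        assert sig["core"] > 0 and sig["outside"] > 0
        truth.validate()

    def test_core_too_big_rejected(self):
        with pytest.raises(ValueError, match="core"):
            generate_explant_scene(explant_params(0), core_radius_um=2000.0)


class TestNerveScene:
    def test_single_tip(self):
        p = GrowthParams(seed=0)
        scene, truth = generate_nerve_scene(300.0, [300.0], 40.0, p)
        assert len(truth.tip_points) == 1
        assert truth.tip_points[0]["distance_um"] == 300.0
        for d in (30.0, 150.0, 300.0):
            assert true_tip_count([300.0], d) == 1
        assert true_tip_count([300.0], 301.0) == 0

    def test_truth_counting_intervals(self):
        depths = [200.0, 400.0, 400.0]
        assert true_tip_count(depths, 100.0) == 3
        assert true_tip_count(depths, 200.0) == 3
        assert true_tip_count(depths, 201.0) == 2
        assert true_tip_count(depths, 400.0) == 2
        assert true_tip_count(depths, 401.0) == 0

    def test_close_tips_warn(self):
        p = GrowthParams(seed=0, line_width_um=80.0, psf_sigma_um=0.5)
        with pytest.warns(UserWarning, match="unresolvable"):
            generate_nerve_scene(200.0, [100.0, 110.0], 40.0, p)

    def test_truth_tips_match_skeleton_endpoints(self):
        from skimage.morphology import skeletonize

        p = GrowthParams(seed=5, noise=(0.0, 0.0))
        scene, truth = generate_nerve_scene(
            250.0, [135.0, 255.0, 345.0, 435.0], 30.0, p
        )
        img = scene.channel("Tubb3").astype(float)
        skel = skeletonize(img > 60.0)
        ys, xs = np.nonzero(skel)
        # every truth tip has a skeleton pixel within ~2 px
        for tp in truth.tip_points:
            x, y = tp["pos_um"]
            d = np.hypot(xs - x, ys - y).min()
            assert d <= 2.5


class TestColocScene:
    def test_uniform_measure_channel(self):
        p = GrowthParams(seed=0, noise=(0.0, 0.0))
        scene, truth = generate_coloc_scene(10, 0.5, 1.0, p)
        base = truth.extras["base_level"]
        for c in truth.cells:
            assert c["true_mean_measure"] == pytest.approx(base, abs=1e-9)

    def test_zero_labeled_fraction(self):
        p = GrowthParams(seed=1, noise=(0.0, 0.0))
        scene, truth = generate_coloc_scene(10, 0.0, 3.0, p)
        assert truth.cells == []
        a = scene.channel("GFP").astype(float)
        assert a.max() <= p.background + 1

    def test_truth_means_equal_pixel_average(self):
        p = GrowthParams(seed=2, noise=(0.0, 0.0))
        scene, truth = generate_coloc_scene(20, 0.5, 3.0, p)
        clean_b = truth.extras["clean_measure"]
        px = scene.pixel_size_um
        yy, xx = np.mgrid[0 : clean_b.shape[0], 0 : clean_b.shape[1]]
        for c in truth.cells:
            cx, cy = c["center_um"]
            m = np.hypot(xx * px - cx, yy * px - cy) <= c["radius_um"]
            assert c["true_mean_measure"] == pytest.approx(
                float(clean_b[m].mean()), rel=1e-12
            )


class TestGelProfile:
    def test_single_band_integral(self):
        prof, truth = generate_gel_profile([500.0], [1234.0], 20.0)
        assert float(np.trapezoid(prof)) == pytest.approx(1234.0, rel=0.001)

    def test_two_band_truth_ratio(self):
        _, truth = generate_gel_profile([300.0, 600.0], [2000.0, 1000.0], 15.0)
        assert truth.band_areas[0] / truth.band_areas[1] == pytest.approx(2.0)

    def test_baseline_excluded_from_truth(self):
        _, flat = generate_gel_profile([300.0], [500.0], 10.0, baseline=(0.0, 0.0))
        _, sloped = generate_gel_profile([300.0], [500.0], 10.0, baseline=(20.0, 0.1))
        assert flat.band_areas == sloped.band_areas

    def test_deterministic(self):
        a, _ = generate_gel_profile([300.0], [500.0], 10.0, noise_sd=2.0, seed=9)
        b, _ = generate_gel_profile([300.0], [500.0], 10.0, noise_sd=2.0, seed=9)
        assert np.array_equal(a, b)


def test_polyline_helpers():
    pts = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 10.0]])
    assert polyline_length(pts) == pytest.approx(11.0)
    from axonquant.geometry import resample_polyline

    res = resample_polyline(pts, 0.5)
    assert np.allclose(res[0], pts[0]) and np.allclose(res[-1], pts[-1])
    steps = np.hypot(*np.diff(res, axis=0).T)
    assert steps.max() <= 0.5 + 1e-9
    assert polyline_length(res) == pytest.approx(11.0, rel=1e-6)
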