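import numpy as np
import pytest
from scipy import ndimage

from annosim import (PhantomConfig, ScenarioSpec, SurrogateQuality,
                     SurrogateSegmenter, generate_phantom_dataset,
                     retain_largest_component, simulate_dataset, surrogate_factory)
from annosim.metrics import dice
from annosim.prompts import find_center_slice, jitter_box


def nonempty_slices(mask, label):
    g = np.moveaxis(mask.binary(label), mask.slicing_axis, 0)
    return np.flatnonzero(g.reshape(g.shape[0], -1).any(axis=1))


class TestPhantomGeneration:
    def test_same_config_same_seed_is_bit_identical(self):
        cfg = PhantomConfig(n_volumes=2, grid_shape=(16, 48, 48), seed=5,
                            object_radius_mm=(4.0, 8.0))
        d1 = generate_phantom_dataset(cfg)
        d2 = generate_phantom_dataset(cfg)
        for (v1, m1), (v2, m2) in zip(d1, d2):
            np.testing.assert_array_equal(v1.intensities, v2.intensities)
            np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_fixed_object_count_by_construction(self):
        cfg = PhantomConfig(n_volumes=10, objects_per_volume=(3, 3),
                            grid_shape=(24, 96, 96), object_radius_mm=(4.0, 9.0),
                            seed=3)
        dataset = generate_phantom_dataset(cfg)
        assert sum(m.n_instances for _, m in dataset) == 30

    def test_bone_slice_extent_follows_elongation(self):
        # radius 15 mm stretched 4x along a 1 mm slicing axis: ~120 slices
        cfg = PhantomConfig.bone_default(n_volumes=2, seed=4)
        for _, mask in generate_phantom_dataset(cfg):
            extent = len(nonempty_slices(mask, 1))
            semi_lo = 12.0 * 4 * 0.85  # radius range x elongation x axis wobble
            semi_hi = 15.0 * 4 * 1.15
            assert 2 * semi_lo / cfg.spacing_mm[0] - 2 <= extent
            assert extent <= 2 * semi_hi / cfg.spacing_mm[0] + 2

    def test_contrast_sets_intensity_gap(self):
        cfg = PhantomConfig(n_volumes=1, grid_shape=(16, 48, 48), contrast=0.6,
                            noise_sd=0.0, object_radius_mm=(5.0, 8.0), seed=6)
        vol, mask = generate_phantom_dataset(cfg)[0]
        fg = vol.intensities[mask.labels > 0].mean()
        bg = vol.intensities[mask.labels == 0].mean()
        assert fg - bg == pytest.approx(0.6)

    def test_instances_are_simply_connected_per_slice(self, small_tumor_dataset):
        # no holes and one component: largest-component cleanup is the identity
        for _, mask in small_tumor_dataset:
            for label in mask.instance_labels:
                cleaned = retain_largest_component(mask, label)
                np.testing.assert_array_equal(cleaned.labels, mask.labels)
                for s in nonempty_slices(mask, label):
                    plane = mask.get_slice(s) == label
                    filled = ndimage.binary_fill_holes(plane)
                    np.testing.assert_array_equal(filled, plane)

    def test_instances_span_at_least_two_slices(self, small_tumor_dataset):
        for _, mask in small_tumor_dataset:
            for label in mask.instance_labels:
                assert len(nonempty_slices(mask, label)) >= 2

    def test_infeasible_geometry_raises(self):
        cfg = PhantomConfig(n_volumes=1, grid_shape=(8, 16, 16),
                            spacing_mm=(1.0, 1.0, 1.0),
                            object_radius_mm=(40.0, 50.0), seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_phantom_dataset(cfg)


class TestSurrogateSegmenter:
    def _bound(self, dataset, quality, index=0, label=1):
        vol, mask = dataset[index]
        seg = SurrogateSegmenter(vol, mask.binary(label), quality,
                                 object_key=(index, label))
        return seg, mask

    def test_zero_error_scales_reproduce_ground_truth(self, small_tumor_dataset):
        seg, mask = self._bound(small_tumor_dataset, SurrogateQuality.perfect())
        c = find_center_slice(mask, 1)
        seg.prompt_box(jitter_box(mask.get_slice(c) == 1, mask.inplane_spacing,
                                  np.random.default_rng(0), c))
        for s in nonempty_slices(mask, 1):
            np.testing.assert_array_equal(seg.predict(s), mask.get_slice(s) == 1)

    def test_query_without_prompt_is_hard_error(self, small_tumor_dataset):
        seg, _ = self._bound(small_tumor_dataset, SurrogateQuality(seed=1))
        with pytest.raises(RuntimeError, match="prompt"):
            seg.predict(0)

    def test_dsc_decays_with_distance_from_prompt(self, small_tumor_dataset):
        # Monte-Carlo over >= 50 segmenter seeds: error grows with slice distance
        vol, mask = small_tumor_dataset[0]
        slices = nonempty_slices(mask, 1)
        c = int(slices[len(slices) // 2])
        far = int(slices[-1])
        near_scores, far_scores = [], []
        for seed in range(60):
            q = SurrogateQuality(base_boundary_sd_mm=0.5, drift_per_slice_mm=0.5,
                                 leak_prob=0.0, seed=seed)
            seg = SurrogateSegmenter(vol, mask.binary(1), q)
            seg.prompt_box(jitter_box(mask.get_slice(c) == 1, mask.inplane_spacing,
                                      np.random.default_rng(seed), c))
            near_scores.append(dice(seg.predict(c), mask.get_slice(c) == 1))
            far_scores.append(dice(seg.predict(far), mask.get_slice(far) == 1))
        assert np.mean(near_scores) > np.mean(far_scores)

    def test_mean_dsc_nonincreasing_in_boundary_error_scale(self, small_tumor_dataset):
        vol, mask = small_tumor_dataset[0]
        c = find_center_slice(mask, 1)
        gt2d = mask.get_slice(c) == 1
        means = []
        for scale in (0.0, 1.0, 3.0):
            scores = []
            for seed in range(50):
                q = SurrogateQuality(base_boundary_sd_mm=scale, drift_per_slice_mm=0.0,
                                     leak_prob=0.0, seed=seed)
                seg = SurrogateSegmenter(vol, mask.binary(1), q)
                seg.prompt_box(jitter_box(gt2d, mask.inplane_spacing,
                                          np.random.default_rng(seed), c))
                scores.append(dice(seg.predict(c), gt2d))
            means.append(np.mean(scores))
        assert means[0] >= means[1] >= means[2]
        assert means[0] == 1.0

    def test_mask_reprompt_rebases_the_drift_anchor(self, small_tumor_dataset):
        vol, mask = small_tumor_dataset[0]
        slices = nonempty_slices(mask, 1)
        c, mid = int(slices[0]), int(slices[len(slices) // 2])
        q = SurrogateQuality(base_boundary_sd_mm=0.0, drift_per_slice_mm=1.0,
                             leak_prob=0.0, seed=9)
        seg = SurrogateSegmenter(vol, mask.binary(1), q)
        seg.prompt_mask(mid, mask.get_slice(mid) == 1)
        rebased = seg.predict(mid + 1)
        seg2 = SurrogateSegmenter(vol, mask.binary(1), q)
        seg2.prompt_mask(c, mask.get_slice(c) == 1)
        drifted = seg2.predict(mid + 1)
        gt = mask.get_slice(mid + 1) == 1
        assert dice(rebased, gt) >= dice(drifted, gt)

    def test_reset_makes_predictions_depend_on_post_reset_prompts_only(
            self, small_tumor_dataset):
        vol, mask = small_tumor_dataset[0]
        slices = nonempty_slices(mask, 1)
        a, b = int(slices[0]), int(slices[-1])
        q = SurrogateQuality(seed=5)
        rng = np.random.default_rng(0)
        box_a = jitter_box(mask.get_slice(a) == 1, mask.inplane_spacing, rng, a)
        box_b = jitter_box(mask.get_slice(b) == 1, mask.inplane_spacing, rng, b)
        seg = SurrogateSegmenter(vol, mask.binary(1), q)
        seg.prompt_box(box_a)
        seg.reset_state()
        seg.prompt_box(box_b)
        fresh = SurrogateSegmenter(vol, mask.binary(1), q)
        fresh.prompt_box(box_b)
        for s in slices:
            np.testing.assert_array_equal(seg.predict(s), fresh.predict(s))

    def test_double_reset_equals_single_reset(self, small_tumor_dataset):
        seg, mask = self._bound(small_tumor_dataset, SurrogateQuality(seed=5))
        seg.reset_state()
        seg.reset_state()
        with pytest.raises(RuntimeError):
            seg.predict(0)

    def test_reset_does_not_advance_dataset_stream(self):
        cfg = PhantomConfig(n_volumes=1, grid_shape=(16, 48, 48),
                            object_radius_mm=(4.0, 8.0), seed=8)
        d1 = generate_phantom_dataset(cfg)
        vol, mask = d1[0]
        seg = SurrogateSegmenter(vol, mask.binary(1), SurrogateQuality(seed=1))
        seg.reset_state()
        d2 = generate_phantom_dataset(cfg)
        np.testing.assert_array_equal(d1[0][0].intensities, d2[0][0].intensities)

    def test_leak_blobs_stay_clear_of_the_object(self, small_tumor_dataset):
        vol, mask = small_tumor_dataset[0]
        c = find_center_slice(mask, 1)
        gt2d = mask.get_slice(c) == 1
        sp = np.asarray(mask.inplane_spacing)
        found = 0
        for seed in range(80):
            q = SurrogateQuality(base_boundary_sd_mm=0.0, drift_per_slice_mm=0.0,
                                 leak_prob=1.0, seed=seed)
            seg = SurrogateSegmenter(vol, mask.binary(1), q)
            seg.prompt_mask(c, gt2d)
            pred = seg.predict(c)
            extra = pred & ~gt2d
            if extra.any():
                found += 1
                dist = ndimage.distance_transform_edt(~gt2d, sampling=tuple(sp))
                assert dist[extra].min() >= 5.0
        assert found > 0

    def test_degradation_zero_surrogate_is_exact_oracle(self, small_tumor_dataset,
                                                        perfect_factory):
        summary, assisted, _ = simulate_dataset(
            small_tumor_dataset, perfect_factory,
            ScenarioSpec("tight", 1.0, 1.0), rng=0)
        assert summary.proportion_accepted == 1.0
        for (_, gt), out in zip(small_tumor_dataset, assisted):
            np.testing.assert_array_equal(out.labels, gt.labels)

    def test_quality_validation(self):
        with pytest.raises(ValueError):
            SurrogateQuality(leak_prob=1.5)
        with pytest.raises(ValueError):
            SurrogateQuality(dot_penalty=0.5)
        with pytest.raises(ValueError):
            SurrogateQuality(base_boundary_sd_mm=-1.0)
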