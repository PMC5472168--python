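"""The synthetic scene generator: ground truth, reproducibility, realism knobs."""

import numpy as np
import pytest

from shadecorr.core import correct_image, correct_timelapse, ShadingModel, BaselineSeries
from shadecorr.synthetic import (
    DENSITY_TARGETS,
    make_flatfield,
    simulate_collection,
    simulate_overlap_pairs,
    simulate_timelapse,
)


class TestMakeFlatfield:
    def test_zero_strength_is_uniform(self):
        np.testing.assert_array_equal(make_flatfield(32, 32, 0.0), 1.0)

    def test_mean_one_max_center_min_corner(self):
        S = make_flatfield(64, 64, 0.4)
        assert S.mean() == pytest.approx(1.0, abs=1e-12)
        assert S.min() == min(S[0, 0], S[0, -1], S[-1, 0], S[-1, -1])
        center = S[31:33, 31:33].mean()
        assert center == pytest.approx(S.max(), rel=1e-3)
        assert np.all(S > 0)

    def test_center_corner_ratio_matches_profile(self):
        strength = 0.3
        S = make_flatfield(65, 65, strength)  # odd size: exact center pixel
        ratio = S[32, 32] / S[0, 0]
        assert ratio == pytest.approx(1.0 / (1.0 - strength), rel=1e-12)

    def test_strength_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_flatfield(16, 16, 1.2)


class TestSimulateCollection:
    def test_same_seed_is_bit_identical(self):
        a = simulate_collection(4, shape=(32, 32), seed=5)
        b = simulate_collection(4, shape=(32, 32), seed=5)
        np.testing.assert_array_equal(a.measured_images.frames,
                                      b.measured_images.frames)
        np.testing.assert_array_equal(a.truth_flatfield, b.truth_flatfield)

    def test_noiseless_scene_is_exact_model(self):
        scene = simulate_collection(3, shape=(32, 32), seed=1, noise_sd=0.0)
        np.testing.assert_allclose(
            scene.measured_images.frames,
            scene.true_images.frames * scene.truth_flatfield
            + scene.truth_darkfield,
            rtol=1e-12,
        )

    def test_noise_realization_is_stored(self):
        scene = simulate_collection(3, shape=(32, 32), seed=1, noise_sd=4.0)
        np.testing.assert_allclose(
            scene.measured_images.frames
            - scene.true_images.frames * scene.truth_flatfield
            - scene.truth_darkfield,
            scene.noise,
            atol=1e-12,
        )

    def test_density_levels_are_ordered_and_in_band(self):
        fractions = {}
        for level in ("low", "medium", "high"):
            scene = simulate_collection(6, density_level=level, shape=(64, 64),
                                        seed=3)
            f = scene.foreground_fractions()
            fractions[level] = f.mean()
            assert np.all(f >= DENSITY_TARGETS[level])
            assert np.all(f <= DENSITY_TARGETS[level] + 0.06)
        assert fractions["low"] < fractions["medium"] < fractions["high"]

    def test_spikes_marked_and_bright(self):
        scene = simulate_collection(10, shape=(64, 64), seed=2,
                                    spike_fraction=0.3, noise_sd=0.0)
        spiked = scene.spike_masks.any(axis=(1, 2))
        assert spiked.sum() == 3
        i = np.flatnonzero(spiked)[0]
        inside = scene.true_images.frames[i][scene.spike_masks[i]]
        assert inside.min() > 5 * scene.params["background_level"]

    def test_pipeline_closure_with_truth_model(self):
        scene = simulate_collection(4, shape=(32, 32), seed=8, noise_sd=0.0)
        model = ShadingModel(scene.truth_flatfield, scene.truth_darkfield)
        recovered = np.stack([correct_image(f, model)
                              for f in scene.measured_images.frames])
        np.testing.assert_allclose(recovered, scene.true_images.frames,
                                   rtol=1e-10)


class TestSimulateTimelapse:
    def test_baselines_follow_exponential_formula(self):
        scene = simulate_timelapse(n_frames=20, shape=(32, 32), seed=4,
                                   decay_scale=30.0, baseline_amplitude=80.0,
                                   baseline_floor=5.0)
        i = np.arange(20)
        np.testing.assert_allclose(scene.truth_baselines,
                                   80.0 * np.exp(-i / 30.0) + 5.0, rtol=1e-12)

    def test_constant_baseline_limit(self):
        scene = simulate_timelapse(n_frames=10, shape=(32, 32), seed=4,
                                   constant_baseline=True)
        assert np.ptp(scene.truth_baselines) == 0.0

    def test_brightfield_cells_are_darker_than_background(self):
        scene = simulate_timelapse(n_frames=3, shape=(48, 48), seed=12,
                                   kind="brightfield", noise_sd=0.0)
        frame, mask, b = (scene.true_images.frames[0],
                          scene.foreground_masks[0], scene.truth_baselines[0])
        assert frame[mask].mean() < b

    def test_background_only_movie_corrects_to_zero(self):
        scene = simulate_timelapse(n_frames=6, shape=(32, 32), seed=3,
                                   density_level="low", noise_sd=0.0)
        model = ShadingModel(scene.truth_flatfield, scene.truth_darkfield)
        corrected = correct_timelapse(
            scene.measured_images, model,
            BaselineSeries(scene.truth_baselines, b_norm=0.0))
        bg = ~scene.foreground_masks
        assert np.abs(corrected.frames[bg]).max() < 1e-9

    def test_reproducible(self):
        a = simulate_timelapse(n_frames=5, shape=(32, 32), seed=9)
        b = simulate_timelapse(n_frames=5, shape=(32, 32), seed=9)
        np.testing.assert_array_equal(a.measured_images.frames,
                                      b.measured_images.frames)


class TestOverlapPairs:
    def test_overlap_regions_view_same_specimen(self):
        op = simulate_overlap_pairs(n_pairs=2, shape=(48, 48), overlap=0.5,
                                    seed=7, noise_sd=0.0)
        model = ShadingModel(op.truth_flatfield, op.truth_darkfield)
        corrected = np.stack([correct_image(f, model) for f in op.stack.frames])
        for a, b in op.extract_pairs(corrected):
            np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_pair_count_and_shapes(self):
        op = simulate_overlap_pairs(n_pairs=3, shape=(32, 32), seed=1)
        assert op.stack.n_frames == 6
        pairs = op.extract_pairs(op.stack.frames)
        assert len(pairs) == 3
        assert all(a.shape == b.shape for a, b in pairs)
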