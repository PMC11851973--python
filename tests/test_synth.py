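"""Generator: textures, blending, layouts, and session structure."""

import numpy as np
import pytest

from emosearch.features import fourier_features
from emosearch.synth import (BlockSchedule, ImageSpec, SessionConfig,
                             _bin_representatives, blend_halves, main_quadrant,
                             make_layout, make_texture_image,
                             mirrored_block_order, simulate_session,
                             subquadrant_centers)


class TestTextures:
    def test_flat_spec_yields_constant_image(self):
        img = make_texture_image(ImageSpec(32, 32, {}, mean_luminance=0.5))
        assert np.allclose(img, 0.5)
        assert np.allclose(fourier_features(img).values, 0.0)

    @pytest.mark.parametrize("bin_", [(8, 0), (12, 3), (17, 10), (21, 15)])
    def test_planted_energy_lands_in_target_bin(self, bin_):
        spec = ImageSpec(64, 64, {bin_: 250.0}, seed=5)
        m = fourier_features(make_texture_image(spec)).as_matrix()
        assert m[bin_] / m.sum() >= 0.95
        assert m[bin_] == pytest.approx(250.0, rel=1e-6)

    def test_deterministic_given_seed(self):
        spec = ImageSpec(48, 48, {(10, 2): 9.0, (15, 8): 4.0}, seed=77)
        a = make_texture_image(spec)
        b = make_texture_image(spec)
        assert np.array_equal(a, b)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            ImageSpec(0, 32)

    def test_unrepresentable_bin_raises(self):
        reps = _bin_representatives(32, 32)
        missing = next((f, o) for f in range(24) for o in range(16)
                       if (f, o) not in reps)
        with pytest.raises(ValueError, match="no representable"):
            make_texture_image(ImageSpec(32, 32, {missing: 1.0}))


class TestBlending:
    def test_blend_with_itself_is_identity(self, rng):
        img = rng.random((20, 16))
        assert np.allclose(blend_halves(img, img), img)

    def test_constant_images_follow_cosine_ramp(self):
        h = 11
        a = np.full((h, 5), 0.2)
        b = np.full((h, 5), 0.8)
        out = blend_halves(a, b, match_luminance=False)
        w = 0.5 * (1 + np.cos(np.pi * np.arange(h) / (h - 1)))
        expected = w * 0.2 + (1 - w) * 0.8
        assert np.allclose(out, expected[:, None])
        assert out[0, 0] == pytest.approx(0.2)  # weight 1 at the top row
        assert out[-1, 0] == pytest.approx(0.8)  # weight 0 at the bottom

    def test_output_mean_equals_matched_mean(self, rng):
        a, b = rng.random((30, 30)) + 0.1, rng.random((30, 30)) + 0.4
        out = blend_halves(a, b)
        # per-row weights sum to 1, so each matched row mean is preserved
        target = 0.5 * (a.mean() + b.mean())
        row_means = (a * target / a.mean()).mean(axis=1)
        row_means_b = (b * target / b.mean()).mean(axis=1)
        w = 0.5 * (1 + np.cos(np.pi * np.arange(30) / 29))
        assert np.allclose(out.mean(axis=1),
                           w * row_means + (1 - w) * row_means_b)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            blend_halves(np.zeros((4, 4)), np.zeros((5, 4)))


class TestLayouts:
    def test_target_positions_balanced_within_block(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            schedule = BlockSchedule(32)
            hist = np.zeros(16, dtype=int)
            for _ in range(32):
                layout = make_layout(schedule, r)
                hist[layout.target.sub_quadrant] += 1
            assert list(hist) == [2] * 16

    def test_distractors_split_3_2_2_over_other_quadrants(self, rng):
        layout = make_layout(BlockSchedule(32), rng)
        tq = main_quadrant(layout.target.sub_quadrant)
        quads = [main_quadrant(it.sub_quadrant) for it in layout.distractors]
        assert tq not in quads
        counts = sorted(np.bincount(quads, minlength=4)[q]
                        for q in set(quads))
        assert counts == [2, 2, 3]

    def test_jitter_within_bounds(self, rng):
        centers = subquadrant_centers()
        for _ in range(50):
            layout = make_layout(BlockSchedule(32), rng)
            for it in layout.items:
                cx, cy = centers[it.sub_quadrant]
                assert abs(it.x_deg - cx) <= 1.0
                assert abs(it.y_deg - cy) <= 0.23

    def test_exhausted_schedule_raises(self, rng):
        schedule = BlockSchedule(32)
        for _ in range(32):
            make_layout(schedule, rng)
        with pytest.raises(ValueError, match="exhausted"):
            make_layout(schedule, rng)


class TestSessions:
    def test_default_session_is_12_blocks_of_32(self):
        cfg = SessionConfig(seed=0)
        assert cfg.n_trials == 384
        sd = simulate_session(cfg, render_gaze=False)
        assert len(sd.trials) == 384
        assert sd.trials.block.nunique() == 12
        assert (sd.trials.groupby("block").size() == 32).all()

    def test_block_order_is_mirrored(self):
        order = mirrored_block_order()
        assert len(order) == 12
        assert order == order[::-1]
        assert all(order.count(c) == 4 for c in set(order))
        # counterbalancing permutes which condition plays X/Y/Z
        alt = mirrored_block_order(counterbalance=1)
        assert sorted(alt) == sorted(order) and alt != order

    def test_session_deterministic_given_seed(self):
        cfg = SessionConfig(seed=42, n_blocks=1)
        a = simulate_session(cfg, render_gaze=True)
        b = simulate_session(cfg, render_gaze=True)
        assert a.trials.equals(b.trials)
        assert a.gaze.equals(b.gaze)

    def test_target_emotion_follows_condition(self):
        sd = simulate_session(SessionConfig(seed=7, n_blocks=3),
                              render_gaze=False)
        t = sd.trials
        assert (t.loc[t.condition == "find_angry", "target_emotion"]
                == "angry").all()
        assert (t.loc[t.condition == "find_happy", "target_emotion"]
                == "happy").all()
        assert set(t.loc[t.condition == "find_both", "target_emotion"]) <= \
            {"angry", "happy"}

    def test_ground_truth_carries_planted_quantities(self):
        from emosearch.synth import PlantedEffects

        cfg = SessionConfig(seed=1, n_blocks=1, planted=PlantedEffects(
            emotion_tit_ratio=0.84, task_ratio=1.1))
        sd = simulate_session(cfg, render_gaze=False)
        assert sd.ground_truth["planted"]["emotion_tit_ratio"] == 0.84
        assert sd.ground_truth["planted"]["task_ratio"] == 1.1
        assert len(sd.ground_truth["trials"]) == 32
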