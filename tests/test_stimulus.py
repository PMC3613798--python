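"""Kinematic, geometric and chromatic rules of the dot-field simulator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dotgrouping.stimulus import (
    ConfigurationError,
    GroupMotionState,
    SimConfig,
    StimulusSequence,
    assign_colours,
    displacement_norms,
    frame_displacements,
    generate_sequence,
    grid_positions,
    init_dot_field,
    place_regions,
    region_membership,
    rgb_to_grey_level,
    rng_streams,
    step_groups,
    step_ungrouped,
    wrap_position,
)


def _minimal_image_dev(positions, grid, config):
    """Per-axis deviation from the grid respecting the wrap topology."""
    diff = positions - grid
    w, h = config.field_w_px, config.field_h_px
    diff[:, 0] = (diff[:, 0] + w / 2) % w - w / 2
    diff[:, 1] = (diff[:, 1] + h / 2) % h - h / 2
    return np.abs(diff)


class TestInitDotField:
    def test_default_config_returns_680_dots(self, default_config, rng):
        dots = init_dot_field(default_config, rng)
        assert dots.n_dots == 680

    def test_zero_jitter_reproduces_exact_grid(self, default_config, rng):
        cfg = dataclasses.replace(default_config, jitter_px=0.0)
        dots = init_dot_field(cfg, rng)
        assert np.array_equal(dots.positions, grid_positions(cfg))
        # 34 x 20 cell-centred grid
        assert len(np.unique(dots.positions[:, 0])) == 34
        assert len(np.unique(dots.positions[:, 1])) == 20

    def test_jitter_bounded_by_ten_pixels_across_seeds(self, default_config):
        grid = grid_positions(default_config)
        worst = 0.0
        for seed in range(200):
            dots = init_dot_field(default_config, np.random.default_rng(seed))
            dev = _minimal_image_dev(dots.positions, grid, default_config)
            worst = max(worst, dev.max())
        assert worst <= 10.0
        assert worst > 9.0  # the bound is actually exercised

    def test_inexpressible_grid_raises(self):
        with pytest.raises(ConfigurationError, match="grid"):
            SimConfig(n_dots=681)


class TestColours:
    def test_white_maps_to_255_and_black_to_0(self):
        grey = rgb_to_grey_level(np.array([[255, 255, 255], [0, 0, 0]]))
        assert grey.tolist() == [255, 0]

    def test_grey_level_matches_closed_form_lab_conversion(self):
        # independent oracle: hand-written sRGB -> XYZ -> L* (D65)
        def lab_lightness(rgb):
            c = np.asarray(rgb, dtype=float) / 255.0
            lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
            y = lin @ np.array([0.2126729, 0.7151522, 0.0721750])
            fy = y ** (1 / 3) if y > 0.008856 else (903.3 * y + 16) / 116
            return 116 * fy - 16

        for rgb in [(255, 0, 0), (12, 200, 99), (1, 2, 3), (250, 128, 114)]:
            expected = round(255 * lab_lightness(rgb) / 100)
            assert abs(int(rgb_to_grey_level(np.array([rgb]))[0]) - expected) <= 1

    def test_greyscale_dots_have_equal_channels(self, default_config, rng):
        dots = init_dot_field(default_config, rng)
        dots = assign_colours(dots, "moving_greyscale", rng)
        assert (dots.base_colours[:, 0] == dots.base_colours[:, 1]).all()
        assert (dots.base_colours[:, 1] == dots.base_colours[:, 2]).all()

    def test_colour_condition_spans_rgb_cube(self, default_config, rng):
        dots = assign_colours(init_dot_field(default_config, rng), "moving_colour", rng)
        assert dots.base_colours.min() < 16 and dots.base_colours.max() > 239


class TestPlaceRegions:
    def test_zero_groups_gives_empty_list(self, default_config, rng):
        assert place_regions(0, default_config, rng) == []

    def test_three_regions_satisfy_geometry(self, default_config, rng):
        regions = place_regions(3, default_config, rng)
        assert len(regions) == 3
        for reg in regions:
            assert 50.0 <= reg.centre[0] <= 1024.0 - 50.0
            assert 50.0 <= reg.centre[1] <= 768.0 - 50.0
            assert reg.radius == 50.0
        centres = np.array([r.centre for r in regions])
        d01, d02, d12 = (
            np.hypot(*(centres[i] - centres[j])) for i, j in [(0, 1), (0, 2), (1, 2)]
        )
        assert min(d01, d02, d12) >= 100.0

    def test_constraint_audit_over_1000_seeds(self, default_config):
        violations = 0
        for seed in range(1000):
            regions = place_regions(3, default_config, np.random.default_rng(seed))
            centres = np.array([r.centre for r in regions])
            if (centres < 50.0).any():
                violations += 1
            if (centres[:, 0] > 974.0).any() or (centres[:, 1] > 718.0).any():
                violations += 1
            dists = [
                np.hypot(*(centres[i] - centres[j]))
                for i in range(3)
                for j in range(i + 1, 3)
            ]
            if min(dists) < 100.0:
                violations += 1
        assert violations == 0


class TestStepUngrouped:
    def test_collinear_case_displaces_along_x(self, default_config):
        cfg = dataclasses.replace(default_config, dir_jitter_rad=0.0)
        res = step_ungrouped(
            np.array([[100.0, 100.0]]), np.array([0.0]), cfg, np.random.default_rng(0)
        )
        # raw velocity (1.7 + 1.5, 0) renormalised to 1.7
        np.testing.assert_allclose(res.displacement, [[1.7, 0.0]], atol=1e-12)
        np.testing.assert_allclose(res.positions, [[101.7, 100.0]], atol=1e-12)
        assert res.directions[0] == 0.0

    def test_every_displacement_has_norm_1p7(self, default_config, rng):
        pos = rng.uniform(0, 700, size=(5000, 2))
        dirs = rng.uniform(0, 2 * np.pi, size=5000)
        res = step_ungrouped(pos, dirs, default_config, rng)
        norms = np.hypot(res.displacement[:, 0], res.displacement[:, 1])
        np.testing.assert_allclose(norms, 1.7, rtol=1e-9)

    def test_rightward_bias_gives_positive_mean_x_drift(self, default_config, rng):
        dirs = rng.uniform(0, 2 * np.pi, size=10_000)
        pos = rng.uniform(0, 700, size=(10_000, 2))
        res = step_ungrouped(pos, dirs, default_config, rng)
        assert res.displacement[:, 0].mean() > 0.3


class TestStepGroups:
    def test_all_grouped_dots_share_identical_displacement(self, default_config, rng):
        # two spatial clumps standing in for two groups
        pos = np.vstack(
            [rng.uniform(300, 320, (10, 2)), rng.uniform(500, 520, (10, 2))]
        )
        state, new_pos, disp = step_groups(
            GroupMotionState(1.0), pos, default_config, rng
        )
        # one shared displacement vector, applied bitwise-identically
        assert disp.shape == (2,)
        assert np.array_equal(new_pos, pos + disp)
        np.testing.assert_allclose(np.hypot(*disp), 1.7, rtol=1e-12)

    def test_edge_contact_reverses_direction(self, default_config, rng):
        pos = np.array([[1023.0, 400.0]])  # heading right into the edge
        state, new_pos, disp = step_groups(
            GroupMotionState(0.0), pos, default_config, rng
        )
        assert disp[0] < 0  # now pointing leftward
        assert 0 <= new_pos[0, 0] < default_config.field_w_px

    def test_no_bias_mean_x_statistically_zero(self, default_config):
        # successive frames of one walk are autocorrelated, so sample many
        # independent short walks (uniform initial heading) instead:
        # 250 walks x 20 frames = 5000 frames without edge contact
        rng = np.random.default_rng(5)
        walk_means = []
        for _ in range(250):
            state = GroupMotionState(float(rng.uniform(0, 2 * np.pi)))
            xs = []
            for _ in range(20):
                state, _, disp = step_groups(
                    state, np.array([[512.0, 384.0]]), default_config, rng
                )
                xs.append(disp[0])
            walk_means.append(np.mean(xs))
        assert stats.ttest_1samp(walk_means, 0.0).pvalue > 0.01


class TestWrap:
    def test_wrap_examples(self, default_config):
        out = wrap_position(np.array([[1030.0, 100.0], [100.0, -3.0]]), default_config)
        np.testing.assert_allclose(out, [[6.0, 100.0], [100.0, 765.0]])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.floats(-5000, 5000, allow_nan=False),
        y=st.floats(-5000, 5000, allow_nan=False),
    )
    def test_wrapped_positions_always_in_field(self, x, y):
        cfg = SimConfig()
        out = wrap_position(np.array([[x, y]]), cfg)
        assert 0 <= out[0, 0] < cfg.field_w_px
        assert 0 <= out[0, 1] < cfg.field_h_px


class TestSequences:
    def test_moving_frame_count_and_dot_conservation(self, default_config):
        seq = generate_sequence(default_config)
        assert seq.n_frames == round(5.0 * 50.0) == 250
        assert seq.positions.shape == (250, 680, 2)

    def test_greyscale_burn_in_simulated_but_not_exported(self):
        cfg = SimConfig(condition="moving_greyscale", n_groups=2, seed=3)
        seq = generate_sequence(cfg)
        assert seq.n_frames == 250
        assert seq.n_simulated_frames == 100 + 250

    def test_static_conditions_are_single_frames_without_groups(self):
        for condition in ("static_colour", "static_greyscale"):
            seq = generate_sequence(SimConfig(condition=condition, seed=1))
            assert seq.n_frames == 1
            assert seq.regions == []
            assert (seq.group_ids == -1).all()

    def test_static_with_groups_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SimConfig(condition="static_colour", n_groups=1)

    def test_same_seed_gives_bitwise_identical_sequences(self, default_config):
        assert generate_sequence(default_config) == generate_sequence(default_config)

    def test_different_seed_differs(self, default_config):
        other = dataclasses.replace(default_config, seed=default_config.seed + 1)
        assert generate_sequence(default_config) != generate_sequence(other)

    def test_speed_conserved_in_both_moving_conditions(self):
        for condition in ("moving_colour", "moving_greyscale"):
            seq = generate_sequence(SimConfig(condition=condition, n_groups=2, seed=9))
            np.testing.assert_allclose(displacement_norms(seq), 1.7, rtol=1e-9)

    def test_all_positions_contained_in_field(self, default_config):
        seq = generate_sequence(default_config)
        assert (seq.positions[..., 0] >= 0).all()
        assert (seq.positions[..., 0] < 1024).all()
        assert (seq.positions[..., 1] >= 0).all()
        assert (seq.positions[..., 1] < 768).all()

    def test_grouped_displacements_have_zero_variance_each_frame(self):
        seq = generate_sequence(SimConfig(condition="moving_greyscale", n_groups=3, seed=2))
        grouped = seq.group_ids[0] >= 0
        assert grouped.sum() >= 2
        disp = frame_displacements(seq)[:, grouped, :]
        # a single shared vector is applied each frame; realised steps agree
        # to the last ulp of position arithmetic
        assert np.ptp(disp, axis=1).max() < 1e-9
        np.testing.assert_allclose(
            disp.mean(axis=1), seq.group_displacements[1:], atol=1e-9
        )

    def test_grouped_dots_never_wrap(self):
        seq = generate_sequence(SimConfig(condition="moving_greyscale", n_groups=3, seed=2))
        grouped = seq.group_ids[0] >= 0
        raw = np.abs(np.diff(seq.positions[:, grouped, :], axis=0))
        assert raw.max() < 2.0  # a wrap would jump by ~field size

    def test_colour_reversion_exhaustive(self):
        seq = generate_sequence(SimConfig(condition="moving_colour", n_groups=3, seed=4))
        base = generate_sequence(
            SimConfig(condition="moving_colour", n_groups=0, seed=4)
        )  # same colour stream: base colours match
        for f in range(seq.n_frames):
            member = region_membership(seq.positions[f], seq.regions)
            inside = member >= 0
            assert (seq.colours[f][inside] == seq.group_colour).all()
            assert (seq.colours[f][~inside] == base.colours[f][~inside]).all()

    def test_single_group_colour_across_regions(self):
        seq = generate_sequence(SimConfig(condition="moving_colour", n_groups=3, seed=4))
        inside = seq.group_ids >= 0
        shown = seq.colours[inside]
        assert len(np.unique(shown, axis=0)) == 1

    def test_dot_leaving_region_reverts_exactly(self):
        seq = generate_sequence(SimConfig(condition="moving_colour", n_groups=3, seed=4))
        entered = (seq.group_ids >= 0).any(axis=0) & (seq.group_ids < 0).any(axis=0)
        assert entered.any()  # some dot both enters and leaves a region
        dot = int(np.flatnonzero(entered)[0])
        outside_frames = seq.group_ids[:, dot] < 0
        outside_colours = np.unique(seq.colours[outside_frames, dot, :], axis=0)
        assert len(outside_colours) == 1  # reverts to exactly one base colour

    def test_ungrouped_drift_positive_grouped_centred(self):
        free_seq = generate_sequence(SimConfig(condition="moving_colour", n_groups=0, seed=6))
        free_disp = frame_displacements(free_seq)
        assert free_disp[..., 0].mean() > 0.2  # >= 1.6e5 dot-frames

        # grouped walks are autocorrelated within a sequence; sample one
        # mean per independently seeded sequence
        grp_means = []
        for seed in range(40):
            grp_seq = generate_sequence(
                SimConfig(condition="moving_greyscale", n_groups=3, seed=seed)
            )
            grouped = grp_seq.group_ids[0] >= 0
            grp_means.append(frame_displacements(grp_seq)[:, grouped, :][:, 0, 0].mean())
        assert stats.ttest_1samp(grp_means, 0.0).pvalue > 0.01


def test_rng_streams_are_independent():
    a = rng_streams(0)
    b = rng_streams(0)
    # consuming one stream leaves the others aligned
    a["colours"].uniform(size=100)
    assert np.array_equal(a["positions"].uniform(size=5), b["positions"].uniform(size=5))


def test_sequence_equality_ignores_displacement_log(default_config):
    seq = generate_sequence(default_config)
    clone = StimulusSequence(
        config=seq.config,
        positions=seq.positions.copy(),
        colours=seq.colours.copy(),
        group_ids=seq.group_ids.copy(),
        regions=list(seq.regions),
        group_colour=None if seq.group_colour is None else seq.group_colour.copy(),
        group_displacements=None,
        n_simulated_frames=seq.n_simulated_frames,
    )
    assert seq == clone
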