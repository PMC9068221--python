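"""Collision checks, clearance maps, exhaustive search, adaptation and ranking."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from nasoplan import (
    Anchor,
    Corridor,
    LabelScheme,
    LabelVolume,
    Obstacle,
    Pose,
    SearchGrid,
    ToolSpec,
    adapt_tool_size,
    build_clearance_map,
    check_corridor_bruteforce,
    check_corridor_fast,
    enumerate_poses,
    generate_channel_phantom,
    generate_skull_phantom,
    pose_to_corridor,
    rank_paths,
    search_paths,
    segment_min_forbidden_distance,
    standard_phantom_specs,
    target_anchor,
)
from nasoplan.geometry import rotation_matrix


def feasible_pose_set(result):
    return {p.key() for p in result.feasible_poses}


class TestCollisionChecks:
    def test_forbidden_free_volume_always_feasible(self, all_air_vol, scheme):
        cmap = build_clearance_map(all_air_vol, scheme)
        assert cmap.unbounded
        c = Corridor(tip=(12, 5, 12), axis=(0, 1, 0), radius=3.0, length=15.0)
        assert check_corridor_bruteforce(c, all_air_vol, scheme)
        assert check_corridor_fast(c, cmap, all_air_vol)

    def test_forbidden_center_on_axis_collides(self, scheme):
        labels = np.zeros((9, 9, 9), dtype=np.int16)
        labels[4, 6, 4] = scheme.non_surgical
        vol = LabelVolume(labels, (1.0, 1.0, 1.0))
        cmap = build_clearance_map(vol, scheme)
        c = Corridor(tip=(4, 1, 4), axis=(0, 1, 0), radius=0.4, length=7.0)
        assert not check_corridor_bruteforce(c, vol, scheme)
        assert not check_corridor_fast(c, cmap, vol)

    def test_boundary_distance_exactly_radius_collides(self, scheme):
        """Closed <= convention: a forbidden center at exactly radius collides."""
        labels = np.zeros((9, 9, 9), dtype=np.int16)
        labels[5, 4, 4] = scheme.non_surgical  # 1 mm off the axis
        vol = LabelVolume(labels, (1.0, 1.0, 1.0))
        cmap = build_clearance_map(vol, scheme)
        c = Corridor(tip=(4, 0, 4), axis=(0, 1, 0), radius=1.0, length=8.0)
        assert not check_corridor_bruteforce(c, vol, scheme)
        assert not check_corridor_fast(c, cmap, vol)
        just_under = replace(c, radius=0.999)
        assert check_corridor_bruteforce(just_under, vol, scheme)
        assert check_corridor_fast(just_under, cmap, vol)


class TestClearanceMap:
    def test_sentinel_without_forbidden(self, all_air_vol, scheme):
        cmap = build_clearance_map(all_air_vol, scheme)
        assert np.all(np.isinf(cmap.distances))

    def test_two_point_distance(self, scheme):
        labels = np.zeros((9, 9, 9), dtype=np.int16)
        labels[4, 4, 4] = scheme.non_surgical
        vol = LabelVolume(labels, (1.0, 1.0, 1.0))
        cmap = build_clearance_map(vol, scheme)
        assert cmap.distances[4, 4, 4] == 0.0
        assert cmap.distances[4, 7, 4] == pytest.approx(3.0)

    def test_matches_exhaustive_scan_on_random_phantom(self, scheme):
        """EDT equals the per-voxel brute-force nearest-forbidden scan (anisotropic)."""
        rng = np.random.default_rng(11)
        labels = np.where(rng.random((16, 16, 16)) < 0.05,
                          scheme.non_surgical, scheme.air).astype(np.int16)
        vol = LabelVolume(labels, (0.5, 1.0, 2.0))
        cmap = build_clearance_map(vol, scheme)
        idx = np.array(list(np.ndindex(vol.shape)))
        centers = vol.index_to_world(idx)
        forb = vol.index_to_world(np.argwhere(labels == scheme.non_surgical))
        brute = np.linalg.norm(centers[:, None, :] - forb[None, :, :], axis=2).min(axis=1)
        np.testing.assert_allclose(cmap.distances.ravel(), brute, atol=1e-9)


class TestSearchPaths:
    def test_nothing_forbidden_means_everything_feasible(self, all_air_vol, scheme):
        anchor = target_anchor(all_air_vol, scheme)
        grid = SearchGrid(rot_step=45, spin_step=90, travel_step=5, travel_range=5)
        res = search_paths(all_air_vol, scheme, anchor, ToolSpec(2.9), grid)
        assert res.n_feasible == res.n_poses_total == grid.n_poses

    def test_walled_off_target_has_no_path(self, scheme, coarse_grid):
        spec = standard_phantom_specs()["blocked"]
        vol = generate_skull_phantom(spec, scheme)
        anchor = target_anchor(vol, scheme)
        res = search_paths(vol, scheme, anchor, ToolSpec(2.9), coarse_grid)
        assert res.n_feasible == 0

    def test_fast_and_bruteforce_runs_agree(self, macaque_vol, scheme, coarse_grid):
        """End-to-end oracle: identical pose sets from both collision routes."""
        anchor = target_anchor(macaque_vol, scheme)
        fast = search_paths(macaque_vol, scheme, anchor, ToolSpec(2.4), coarse_grid,
                            use_fast=True)
        brute = search_paths(macaque_vol, scheme, anchor, ToolSpec(2.4), coarse_grid,
                             use_fast=False)
        assert fast.n_feasible == brute.n_feasible
        assert feasible_pose_set(fast) == feasible_pose_set(brute)

    def test_spin_cache_matches_per_pose_evaluation(self, macaque_vol, scheme):
        """The spin-sharing optimization changes no individual pose verdict."""
        anchor = target_anchor(macaque_vol, scheme)
        grid = SearchGrid(rot_step=90, spin_step=90, travel_step=5)
        tool = ToolSpec(2.4)
        res = search_paths(macaque_vol, scheme, anchor, tool, grid)
        expected = set()
        for pose in enumerate_poses(grid):
            try:
                c = pose_to_corridor(pose, anchor, tool, macaque_vol)
            except ValueError:
                continue
            if check_corridor_bruteforce(c, macaque_vol, scheme):
                expected.add(pose.key())
        assert feasible_pose_set(res) == expected
        assert res.n_feasible % grid.n_spin == 0

    def test_radius_monotonicity(self, goat_vol, scheme, coarse_grid):
        """The feasible set shrinks (as a set) when the drill grows."""
        anchor = target_anchor(goat_vol, scheme)
        sets = []
        for d in (2.9, 6.0, 10.0):
            res = search_paths(goat_vol, scheme, anchor, ToolSpec(d), coarse_grid)
            sets.append(feasible_pose_set(res))
        assert sets[2] <= sets[1] <= sets[0]

    def test_obstacle_monotonicity(self, scheme, coarse_grid):
        """Adding forbidden bodies never enlarges the feasible set."""
        base_spec = standard_phantom_specs()["goat_like"]
        tight = replace(standard_phantom_specs()["orbit_flanked"],
                        obstacles=tuple(
                            replace(o, center_mm=(o.center_mm[0] * 0.7 + 20.8 * 0.3,
                                                  o.center_mm[1], o.center_mm[2]))
                            for o in standard_phantom_specs()["orbit_flanked"].obstacles))
        vol0 = generate_channel_phantom(base_spec, scheme)
        vol1 = generate_skull_phantom(tight, scheme)
        anchor = target_anchor(vol0, scheme)
        r0 = search_paths(vol0, scheme, anchor, ToolSpec(2.9), coarse_grid)
        r1 = search_paths(vol1, scheme, anchor, ToolSpec(2.9), coarse_grid)
        assert feasible_pose_set(r1) <= feasible_pose_set(r0)

    def test_mirror_symmetry(self, scheme):
        """Reflecting the scene across x maps pose (rx, ry, rz) to (rx, -ry, -rz)."""
        spec = replace(standard_phantom_specs()["macaque_like"], channel_width=5.0)
        orbit = Obstacle("ellipsoid", center_mm=(33.0, 30.0, 24.0), size_mm=(10, 10, 10))
        vol = generate_skull_phantom(replace(spec, obstacles=(orbit,)), scheme)
        mirrored = LabelVolume(np.ascontiguousarray(vol.labels[::-1]), vol.spacing, vol.origin)
        anchor = target_anchor(vol, scheme)
        manchor = target_anchor(mirrored, scheme)
        cmap = build_clearance_map(vol, scheme)
        mcmap = build_clearance_map(mirrored, scheme)
        tool = ToolSpec(2.9)
        for pose in [Pose(0, 0, 0, 0, 0), Pose(0, 30, 0, 0, 5), Pose(30, 0, -30, 0, 5),
                     Pose(-30, -30, 30, 0, 10), Pose(0, 0, 45, 0, 0), Pose(15, -45, 0, 0, 3)]:
            mirror_pose = Pose(pose.rx, -pose.ry, -pose.rz, pose.spin, pose.depth)
            c = pose_to_corridor(pose, anchor, tool, vol)
            mc = pose_to_corridor(mirror_pose, manchor, tool, mirrored)
            assert check_corridor_fast(c, cmap, vol) == check_corridor_fast(mc, mcmap, mirrored), pose

    def test_anchor_outside_volume_rejected(self, all_air_vol, scheme):
        anchor = Anchor(point=(100.0, 0.0, 0.0), outward=(0, 1, 0))
        with pytest.raises(ValueError, match="anchor"):
            search_paths(all_air_vol, scheme, anchor, ToolSpec(2.9), SearchGrid())


class TestAdaptToolSize:
    def test_feasible_at_start_keeps_diameter(self, goat_vol, scheme, coarse_grid):
        anchor = target_anchor(goat_vol, scheme)
        res = adapt_tool_size(goat_vol, scheme, anchor, ToolSpec(2.9), coarse_grid)
        assert res.adaptation_trace == (2.9,)
        assert res.tool_diameter_used == 2.9
        assert res.feasible

    def test_narrow_channel_steps_down_once(self, macaque_vol, scheme, coarse_grid):
        """2.9 mm fails in the 2.5 mm channel; 2.4 mm is the first fit."""
        anchor = target_anchor(macaque_vol, scheme)
        res = adapt_tool_size(macaque_vol, scheme, anchor, ToolSpec(2.9), coarse_grid)
        assert res.adaptation_trace == (2.9, 2.4)
        assert res.tool_diameter_used == 2.4
        assert res.feasible

    def test_floor_reached_flags_infeasible(self, scheme, coarse_grid):
        vol = generate_skull_phantom(standard_phantom_specs()["blocked"], scheme)
        anchor = target_anchor(vol, scheme)
        tool = ToolSpec(head_diameter=2.9, min_diameter=1.0)
        res = adapt_tool_size(vol, scheme, anchor, tool, coarse_grid)
        assert res.infeasible_at_floor
        assert res.n_feasible == 0
        assert res.adaptation_trace == (2.9, 2.4, 1.9, 1.4)
        diffs = np.diff(res.adaptation_trace)
        np.testing.assert_allclose(diffs, -tool.decrement)

    def test_feasible_count_nondecreasing_along_trace(self, macaque_vol, scheme, coarse_grid):
        anchor = target_anchor(macaque_vol, scheme)
        counts = []
        for d in (2.9, 2.4, 1.9):
            res = search_paths(macaque_vol, scheme, anchor, ToolSpec(d), coarse_grid)
            counts.append(res.n_feasible)
        assert counts == sorted(counts)


class TestRankPaths:
    def test_empty_feasible_set_ranks_empty(self, scheme, coarse_grid):
        vol = generate_skull_phantom(standard_phantom_specs()["blocked"], scheme)
        anchor = target_anchor(vol, scheme)
        cmap = build_clearance_map(vol, scheme)
        res = search_paths(vol, scheme, anchor, ToolSpec(2.9), coarse_grid, cmap=cmap)
        assert rank_paths(res, cmap, vol) == []

    def test_clearances_positive_and_sorted(self, goat_vol, scheme, coarse_grid):
        anchor = target_anchor(goat_vol, scheme)
        cmap = build_clearance_map(goat_vol, scheme)
        res = search_paths(goat_vol, scheme, anchor, ToolSpec(2.9), coarse_grid, cmap=cmap)
        ranked = rank_paths(res, cmap, goat_vol)
        assert len(ranked) == res.n_feasible
        clear = [c for _, c in ranked]
        assert all(c > 0 for c in clear)
        assert clear == sorted(clear, reverse=True)

    def test_single_pose_clearance_value(self, scheme):
        """Clearance equals min forbidden distance minus radius."""
        labels = np.zeros((16, 16, 16), dtype=np.int16)
        labels[2, 8, 8] = scheme.non_surgical
        labels[8, 2, 8] = scheme.target
        vol = LabelVolume(labels, (1.0, 1.0, 1.0))
        scheme_ = scheme
        anchor = target_anchor(vol, scheme_)
        cmap = build_clearance_map(vol, scheme_)
        grid = SearchGrid(rot_step=180, rot_range=180, spin_step=360, travel_step=15)
        res = search_paths(vol, scheme_, anchor, ToolSpec(2.0), grid, cmap=cmap)
        ranked = rank_paths(res, cmap, vol)
        assert len(ranked) == 1
        pose, clearance = ranked[0]
        c = pose_to_corridor(pose, anchor, ToolSpec(2.0), vol)
        assert clearance == pytest.approx(segment_min_forbidden_distance(c, cmap) - 1.0)
        assert clearance > 0

    def test_wider_route_ranks_first(self, scheme):
        """On a Y-shaped scene, poses threading the wide branch outrank the narrow one."""
        shape, sp = (40, 40, 40), 1.0
        labels = np.full(shape, scheme.non_surgical, dtype=np.int16)
        idx = np.array(list(np.ndindex(shape)))
        centers = idx.astype(float) * sp
        apex = np.array([20.0, 3.0, 20.0])
        # narrow branch straight anterior (+y), wide branch at 45 deg in the y-z plane
        d_narrow = np.array([0.0, 1.0, 0.0])
        d_wide = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)

        def dist_to_ray(pts, direction):
            rel = pts - apex
            t = np.clip(rel @ direction, 0.0, None)
            return np.linalg.norm(rel - t[:, None] * direction, axis=1)

        open_mask = (dist_to_ray(centers, d_narrow) <= 2.0) | (dist_to_ray(centers, d_wide) <= 4.5)
        labels[tuple(idx[open_mask].T)] = scheme.surgical_space
        target_mask = np.linalg.norm(centers - apex, axis=1) <= 1.5
        labels[tuple(idx[target_mask].T)] = scheme.target
        vol = LabelVolume(labels, (sp, sp, sp))
        anchor = target_anchor(vol, scheme)
        cmap = build_clearance_map(vol, scheme)
        grid = SearchGrid(rot_step=45, spin_step=360, travel_step=15)
        res = search_paths(vol, scheme, anchor, ToolSpec(2.5), grid, cmap=cmap)
        assert res.feasible
        ranked = rank_paths(res, cmap, vol)
        top_axis = rotation_matrix(ranked[0][0].rx, ranked[0][0].ry, ranked[0][0].rz) @ np.array([0.0, 1.0, 0.0])
        # the best-ranked corridor points down the wide branch, not the narrow one
        assert top_axis @ d_wide > top_axis @ d_narrow
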