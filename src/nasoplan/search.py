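"""Feasibility search over the pose grid, drill-size adaptation, and ranking.

The feasibility rule is the collision-free condition: a corridor is feasible
iff no voxel of its capsule lies in non-surgical space, i.e. no forbidden
voxel center is within ``radius`` mm of the corridor's axis segment (closed
``<=`` convention, shared with the rasterizer).  Two routes implement the
rule:

* :func:`check_corridor_bruteforce` — rasterize the capsule and inspect
  labels; the reference oracle.
* :func:`check_corridor_fast` — exact nearest-forbidden-center distance to the
  axis segment via a KD-tree, with a Euclidean-distance-transform clearance
  map as a conservative prefilter.  It agrees with the oracle on every pose.

Spin is geometrically inert for circular cross-sections, so the search caches
feasibility per (rx, ry, rz, depth) and replicates it across spin values; the
enumerated counts are unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .geometry import (
    Anchor,
    Corridor,
    Pose,
    SearchGrid,
    ToolSpec,
    point_segment_distance,
    pose_to_corridor,
    rasterize_corridor,
    rotation_matrix,
)
from .volume_io import LabelScheme, LabelVolume, forbidden_mask

__all__ = [
    "ClearanceMap",
    "FeasibilityResult",
    "build_clearance_map",
    "check_corridor_bruteforce",
    "check_corridor_fast",
    "segment_min_forbidden_distance",
    "search_paths",
    "adapt_tool_size",
    "rank_paths",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClearanceMap:
    """Per-voxel distance (mm) to the nearest forbidden voxel center.

    ``distances`` is +inf everywhere when the volume has no forbidden voxels
    (the sentinel for "unbounded clearance").  The map also carries the
    forbidden voxel centers and a KD-tree over them for exact segment queries.
    """

    distances: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    forbidden_points: np.ndarray  # (M, 3) world mm; M may be 0
    tree: cKDTree | None

    @property
    def unbounded(self) -> bool:
        return self.tree is None


def build_clearance_map(vol: LabelVolume, scheme: LabelScheme) -> ClearanceMap:
    """Exact anisotropy-aware Euclidean distance transform to forbidden voxels."""
    forb = forbidden_mask(vol, scheme)
    if not forb.any():
        dist = np.full(vol.shape, np.inf)
        return ClearanceMap(dist, vol.spacing, vol.origin,
                            np.empty((0, 3)), None)
    dist = distance_transform_edt(~forb, sampling=vol.spacing)
    pts = vol.index_to_world(np.argwhere(forb))
    return ClearanceMap(dist, vol.spacing, vol.origin, pts, cKDTree(pts))


def check_corridor_bruteforce(c: Corridor, vol: LabelVolume,
                              scheme: LabelScheme) -> bool:
    """Reference oracle: rasterize the capsule and test every voxel's label."""
    idx = rasterize_corridor(c, vol)
    if idx.shape[0] == 0:
        return True
    labels = vol.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    return not np.any(labels == scheme.non_surgical)


def _segment_samples(c: Corridor, h: float) -> np.ndarray:
    """Points along the axis segment at spacing <= h, endpoints included."""
    n = max(int(math.ceil(c.length / h)), 1)
    t = np.linspace(0.0, c.length, n + 1)
    return np.asarray(c.tip) + t[:, None] * np.asarray(c.axis)


def segment_min_forbidden_distance(c: Corridor, cmap: ClearanceMap) -> float:
    """Exact minimum distance from any forbidden voxel center to the axis segment.

    Returns +inf when the volume has no forbidden voxels.  Samples along the
    segment bound the minimum to within half the sample spacing; candidates in
    that band are then resolved with the exact point-to-segment distance.
    """
    if cmap.tree is None:
        return math.inf
    h = 0.5 * min(cmap.spacing)
    samples = _segment_samples(c, h)
    d, _ = cmap.tree.query(samples)
    m = float(d.min())
    # true minimum lies in [m - h/2, m]; any minimizer is within m + h/2 of a sample
    near = samples[d <= m + h / 2.0 + 1e-12]
    cand_lists = cmap.tree.query_ball_point(near, m + h / 2.0 + 1e-12)
    cand = np.unique(np.concatenate([np.asarray(c_, dtype=int) for c_ in cand_lists]))
    dist = point_segment_distance(cmap.forbidden_points[cand], np.asarray(c.tip), c.end)
    return float(dist.min())


def check_corridor_fast(c: Corridor, cmap: ClearanceMap,
                        vol: LabelVolume) -> bool:
    """Exact fast feasibility test; agrees with the brute-force oracle on every pose."""
    if cmap.tree is None:
        return True
    h = 0.5 * min(cmap.spacing)
    samples = _segment_samples(c, h)
    # conservative prefilter from the clearance map (1-Lipschitz bound)
    spacing = np.array(cmap.spacing)
    origin = np.array(cmap.origin)
    idx = np.rint((samples - origin) / spacing).astype(int)
    idx = np.clip(idx, 0, np.array(cmap.distances.shape) - 1)
    centers = idx * spacing + origin
    off = np.linalg.norm(samples - centers, axis=1)
    lower = cmap.distances[idx[:, 0], idx[:, 1], idx[:, 2]] - off
    if float(lower.min()) - h / 2.0 > c.radius:
        return True
    # exact nearest-neighbor pass over forbidden centers
    d, _ = cmap.tree.query(samples)
    m = float(d.min())
    if m <= c.radius:
        return False
    if m - h / 2.0 > c.radius:
        return True
    return segment_min_forbidden_distance(c, cmap) > c.radius


@dataclass(frozen=True)
class FeasibilityResult:
    """Outcome of an exhaustive feasibility search (possibly after adaptation)."""

    grid: SearchGrid
    tool: ToolSpec
    anchor: Anchor
    tool_diameter_used: float
    n_poses_total: int
    n_feasible: int
    feasible_poses: tuple[Pose, ...]
    adaptation_trace: tuple[float, ...]
    infeasible_at_floor: bool = False

    @property
    def feasible_fraction(self) -> float:
        return self.n_feasible / self.n_poses_total if self.n_poses_total else 0.0

    @property
    def feasible(self) -> bool:
        return self.n_feasible > 0


def search_paths(vol: LabelVolume, scheme: LabelScheme, anchor: Anchor,
                 tool: ToolSpec, grid: SearchGrid,
                 cmap: ClearanceMap | None = None,
                 use_fast: bool = True,
                 log_every: int = 50_000) -> FeasibilityResult:
    """Evaluate every pose on the grid and collect the collision-free ones.

    Feasibility is computed once per (rx, ry, rz, depth) combination and
    shared across spin values (circular cross-section); the feasible pose list
    is emitted in lexicographic (rx, ry, rz, spin, depth) order.  Poses whose
    withdrawn tip leaves the volume's physical box are infeasible.
    """
    box_min, box_max = vol.physical_box()
    point = np.asarray(anchor.point)
    if np.any(point < box_min) or np.any(point > box_max):
        raise ValueError("anchor point is outside the volume")
    if cmap is None:
        cmap = build_clearance_map(vol, scheme)
    check = (lambda c: check_corridor_fast(c, cmap, vol)) if use_fast else \
            (lambda c: check_corridor_bruteforce(c, vol, scheme))

    rots = grid.rot_values()
    spins = grid.spin_values()
    depths = grid.travel_values()
    n_spin = len(spins)
    feasible: list[Pose] = []
    n_feasible = 0
    combos_done = 0
    for rx in rots:
        for ry in rots:
            for rz in rots:
                feas_depth = np.zeros(len(depths), dtype=bool)
                for k, depth in enumerate(depths):
                    pose = Pose(float(rx), float(ry), float(rz), 0.0, float(depth))
                    try:
                        corridor = pose_to_corridor(pose, anchor, tool, vol)
                    except ValueError:
                        continue  # tip out of volume -> infeasible
                    feas_depth[k] = check(corridor)
                combos_done += len(depths)
                hits = int(feas_depth.sum())
                if hits:
                    n_feasible += hits * n_spin
                    for spin in spins:
                        for k, depth in enumerate(depths):
                            if feas_depth[k]:
                                feasible.append(Pose(float(rx), float(ry), float(rz),
                                                     float(spin), float(depth)))
                if log_every and combos_done % log_every < len(depths):
                    logger.info("evaluated %d/%d pose combinations, %d feasible poses",
                                combos_done, len(rots) ** 3 * len(depths), n_feasible)
    return FeasibilityResult(
        grid=grid, tool=tool, anchor=anchor,
        tool_diameter_used=tool.head_diameter,
        n_poses_total=grid.n_poses, n_feasible=n_feasible,
        feasible_poses=tuple(feasible),
        adaptation_trace=(tool.head_diameter,),
    )


def adapt_tool_size(vol: LabelVolume, scheme: LabelScheme, anchor: Anchor,
                    tool: ToolSpec, grid: SearchGrid,
                    cmap: ClearanceMap | None = None,
                    use_fast: bool = True) -> FeasibilityResult:
    """Search, shrinking the drill by ``tool.decrement`` mm until a path exists.

    Returns the first feasible result with the full list of attempted
    diameters; if the ``min_diameter`` floor is reached without feasibility,
    the last (empty) result is returned flagged ``infeasible_at_floor``.
    """
    if cmap is None:
        cmap = build_clearance_map(vol, scheme)
    trace: list[float] = []
    k = 0
    while True:
        diameter = round(tool.head_diameter - k * tool.decrement, 9)
        trace.append(diameter)
        attempt = replace(tool, head_diameter=diameter, shaft_diameter=None)
        logger.info("searching with drill diameter %.2f mm", diameter)
        result = search_paths(vol, scheme, anchor, attempt, grid, cmap=cmap,
                              use_fast=use_fast)
        if result.feasible:
            return replace(result, adaptation_trace=tuple(trace))
        k += 1
        if round(tool.head_diameter - k * tool.decrement, 9) < tool.min_diameter - 1e-9:
            return replace(result, adaptation_trace=tuple(trace),
                           infeasible_at_floor=True)


def rank_paths(result: FeasibilityResult, cmap: ClearanceMap,
               vol: LabelVolume) -> list[tuple[Pose, float]]:
    """Feasible poses sorted by decreasing minimal clearance along the corridor.

    Clearance is the minimum forbidden-center-to-axis distance minus the
    corridor radius (inf when nothing is forbidden).  Ties break by smaller
    angular deviation from the canonical outward axis, then by lexicographic
    pose order, so the ranking is fully deterministic.
    """
    anchor = result.anchor
    tool = replace(result.tool, head_diameter=result.tool_diameter_used,
                   shaft_diameter=None)
    outward = np.asarray(anchor.outward)
    clearance_cache: dict[tuple[float, float, float, float], float] = {}
    deviation_cache: dict[tuple[float, float, float], float] = {}
    entries = []
    for pose in result.feasible_poses:
        ckey = (pose.rx, pose.ry, pose.rz, pose.depth)
        if ckey not in clearance_cache:
            corridor = pose_to_corridor(pose, anchor, tool, vol)
            clearance_cache[ckey] = segment_min_forbidden_distance(corridor, cmap) - tool.radius
        rkey = (pose.rx, pose.ry, pose.rz)
        if rkey not in deviation_cache:
            axis = rotation_matrix(*rkey) @ outward
            cosang = float(np.clip(axis @ outward, -1.0, 1.0))
            deviation_cache[rkey] = math.degrees(math.acos(cosang))
        entries.append((pose, clearance_cache[ckey], deviation_cache[rkey]))
    entries.sort(key=lambda e: (-e[1], e[2], e[0].key()))
    return [(pose, clearance) for pose, clearance, _ in entries]
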