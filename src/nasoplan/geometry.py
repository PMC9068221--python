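"""Five-degree-of-freedom pose grid and corridor (capsule) geometry.

A surgical corridor is the straight swept volume of the microdrill moving
along its major axis: a capsule of radius ``head_diameter / 2`` whose tip
rests at (or is withdrawn from) the target contact point and whose shaft runs
outward until it leaves the volume's bounding box.  A pose has exactly five
degrees of freedom anchored at the target: three extrinsic rotations about the
world x, y, z axes, an axial spin about the corridor's own major axis, and an
axial travel (withdrawal) of the tip along that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from .volume_io import LabelScheme, LabelVolume

__all__ = [
    "ToolSpec",
    "SearchGrid",
    "Pose",
    "Anchor",
    "Corridor",
    "target_anchor",
    "enumerate_poses",
    "rotation_matrix",
    "pose_to_corridor",
    "rasterize_corridor",
    "point_segment_distance",
]

POSE_DOF = 5


@dataclass(frozen=True)
class ToolSpec:
    """Microdrill geometry and automatic size-adaptation policy (mm).

    ``head_diameter`` is the burr diameter defining the corridor radius;
    ``decrement`` is how much the planner shrinks the drill when no feasible
    path exists, down to ``min_diameter``.
    """

    head_diameter: float = 2.9
    shaft_diameter: float | None = None
    min_diameter: float = 1.0
    decrement: float = 0.5

    def __post_init__(self) -> None:
        if self.head_diameter <= 0:
            raise ValueError(f"head_diameter must be > 0, got {self.head_diameter}")
        if self.decrement <= 0:
            raise ValueError(f"decrement must be > 0, got {self.decrement}")
        if self.min_diameter <= 0:
            raise ValueError(f"min_diameter must be > 0, got {self.min_diameter}")
        if self.shaft_diameter is None:
            object.__setattr__(self, "shaft_diameter", self.head_diameter)

    @property
    def radius(self) -> float:
        return self.head_diameter / 2.0


def _n_steps(rng: float, step: float, name: str) -> int:
    n = rng / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{name} range {rng} is not an integer multiple of step {step}")
    n = int(round(n))
    if n < 1:
        raise ValueError(f"{name} range/step must give at least one value")
    return n


@dataclass(frozen=True)
class SearchGrid:
    """Discretization of the five pose degrees of freedom.

    Defaults enumerate rotations over a centered 180 deg range at 5 deg per
    world axis, spin over 360 deg at 5 deg, and tip travel over 15 mm at 1 mm:
    (180/5)^3 * (360/5) * (15/1) = 50,388,480 poses.
    """

    rot_step: float = 5.0
    rot_range: float = 180.0
    spin_step: float = 5.0
    spin_range: float = 360.0
    travel_step: float = 1.0
    travel_range: float = 15.0

    def __post_init__(self) -> None:
        _n_steps(self.rot_range, self.rot_step, "rotation")
        _n_steps(self.spin_range, self.spin_step, "spin")
        _n_steps(self.travel_range, self.travel_step, "travel")

    @property
    def n_rot(self) -> int:
        """Number of rotation values per world axis."""
        return _n_steps(self.rot_range, self.rot_step, "rotation")

    @property
    def n_spin(self) -> int:
        return _n_steps(self.spin_range, self.spin_step, "spin")

    @property
    def n_travel(self) -> int:
        return _n_steps(self.travel_range, self.travel_step, "travel")

    @property
    def n_poses(self) -> int:
        """Closed-form pose count: n_rot^3 * n_spin * n_travel."""
        return self.n_rot ** 3 * self.n_spin * self.n_travel

    def rot_values(self) -> np.ndarray:
        """Rotation angles on the centered grid ``step * (k - n//2)``.

        Lies within the half-open interval [-range/2, +range/2) and always
        contains the zero angle, so a range equal to its step yields exactly
        the zero pose.  For the 180/5 default this is -90, -85, ..., +85.
        """
        n = self.n_rot
        return self.rot_step * (np.arange(n) - n // 2)

    def spin_values(self) -> np.ndarray:
        """Spin angles, half-open grid [0, range)."""
        return self.spin_step * np.arange(self.n_spin)

    def travel_values(self) -> np.ndarray:
        """Tip withdrawal depths in mm, half-open grid [0, range)."""
        return self.travel_step * np.arange(self.n_travel)


@dataclass(frozen=True)
class Pose:
    """One discretized tool placement: exactly five degrees of freedom.

    ``rx, ry, rz`` are extrinsic rotations (degrees) about the world axes,
    ``spin`` the rotation about the corridor's own axis (degrees; geometrically
    inert for a circular cross-section but enumerated as a real degree of
    freedom), ``depth`` the tip withdrawal from target contact in mm.
    """

    rx: float
    ry: float
    rz: float
    spin: float
    depth: float

    def key(self) -> tuple[float, float, float, float, float]:
        return (self.rx, self.ry, self.rz, self.spin, self.depth)


@dataclass(frozen=True)
class Anchor:
    """Target contact point and canonical outward (target -> nasal entry) axis."""

    point: tuple[float, float, float]
    outward: tuple[float, float, float]

    def __post_init__(self) -> None:
        point = np.asarray(self.point, dtype=float)
        outward = np.asarray(self.outward, dtype=float)
        norm = float(np.linalg.norm(outward))
        if norm < 1e-12:
            raise ValueError("outward direction is degenerate")
        object.__setattr__(self, "point", tuple(point.tolist()))
        object.__setattr__(self, "outward", tuple((outward / norm).tolist()))


@dataclass(frozen=True)
class Corridor:
    """Realized capsule: tip, unit axis (tip -> entry), radius, in-volume length (mm)."""

    tip: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    length: float

    @property
    def end(self) -> np.ndarray:
        return np.array(self.tip) + self.length * np.array(self.axis)


ANTERIOR = (0.0, 1.0, 0.0)  # +y in canonical RAS axes


def target_anchor(vol: LabelVolume, scheme: LabelScheme,
                  outward: tuple[float, float, float] = ANTERIOR) -> Anchor:
    """Anchor at the centroid of the target-labeled voxel centers.

    ``outward`` is the canonical zero-pose corridor axis, pointing from the
    target toward the nasal entry (anatomical anterior by default).
    """
    idx = np.argwhere(vol.labels == scheme.target)
    if idx.size == 0:
        raise ValueError("target label is empty; cannot anchor the search")
    centroid = vol.index_to_world(idx).mean(axis=0)
    return Anchor(point=tuple(centroid.tolist()), outward=outward)


def enumerate_poses(grid: SearchGrid) -> Iterator[Pose]:
    """Yield the full Cartesian pose grid in lexicographic (rx, ry, rz, spin, depth) order."""
    rots = grid.rot_values()
    spins = grid.spin_values()
    depths = grid.travel_values()
    for rx in rots:
        for ry in rots:
            for rz in rots:
                for spin in spins:
                    for depth in depths:
                        yield Pose(float(rx), float(ry), float(rz), float(spin), float(depth))


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Extrinsic world-axis rotation Rz(rz) @ Ry(ry) @ Rx(rx), angles in degrees."""
    return Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()


def _ray_box_exit(tip: np.ndarray, axis: np.ndarray, box_min: np.ndarray,
                  box_max: np.ndarray) -> float:
    """Distance from ``tip`` along ``axis`` to where the ray leaves the box."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (box_min - tip) / axis
        t2 = (box_max - tip) / axis
    t_far = np.where(np.isnan(t1), np.inf, np.maximum(t1, t2))
    return float(np.min(t_far))


def pose_to_corridor(pose: Pose, anchor: Anchor, tool: ToolSpec,
                     vol: LabelVolume) -> Corridor:
    """Realize a pose as a capsule corridor in world mm.

    The axis is the anchor's outward direction rotated by the pose's extrinsic
    rotations; the tip is the anchor point withdrawn by ``depth`` mm along the
    axis; the corridor runs from the tip to the volume bounding-box exit.
    Raises if the tip leaves the volume's physical box.
    """
    axis = rotation_matrix(pose.rx, pose.ry, pose.rz) @ np.asarray(anchor.outward)
    axis = axis / np.linalg.norm(axis)
    tip = np.asarray(anchor.point) + pose.depth * axis
    box_min, box_max = vol.physical_box()
    if np.any(tip < box_min) or np.any(tip > box_max):
        raise ValueError("tip out of volume")
    length = _ray_box_exit(tip, axis, box_min, box_max)
    return Corridor(tip=tuple(tip.tolist()), axis=tuple(axis.tolist()),
                    radius=tool.radius, length=max(length, 0.0))


def point_segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Euclidean distance from ``points`` (N, 3) to the segment [p0, p1]."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    dd = float(d @ d)
    if dd < 1e-24:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip((points - p0) @ d / dd, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def rasterize_corridor(c: Corridor, vol: LabelVolume) -> np.ndarray:
    """Voxel indices (N, 3) whose centers lie within ``radius`` of the corridor segment.

    Capsule membership uses the closed ``<= radius`` convention, so results
    match the collision rule exactly.  Only the index bounding box of the
    capsule is scanned.
    """
    p0 = np.array(c.tip)
    p1 = c.end
    spacing = np.array(vol.spacing)
    origin = np.array(vol.origin)
    pad = c.radius
    lo_w = np.minimum(p0, p1) - pad
    hi_w = np.maximum(p0, p1) + pad
    lo = np.maximum(np.floor((lo_w - origin) / spacing - 1e-9).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin) / spacing + 1e-9).astype(int),
                    np.array(vol.shape) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = idx * spacing + origin
    dist = point_segment_distance(centers, p0, p1)
    return idx[dist <= c.radius]
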