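"""Seeded synthetic segmented-skull phantoms with exact analytic geometry.

A phantom stands in for a manually segmented cranial CT: a bony (non-surgical)
block pierced by a straight open channel of known width — the drillable
trans-nasal / trans-sphenoidal corridor — terminating in a marked target slab
(the optic-canal wall), surrounded by air.  Obstacle bodies (paired "orbits"
flanking the channel, an anterior "frontal cortex" slab) can be added on top.
Every voxel is classified by closed-form membership of its center, so each
fixture has an exact geometric oracle; optional seeded jitter roughens the
boundaries by perturbing the classification coordinates, never the interior.

The canonical layout runs the channel along anatomical anterior (+y): the
target sits at the posterior end of the channel and the nasal entry opens
anteriorly into air.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume_io import LabelScheme, LabelVolume, forbidden_mask

__all__ = [
    "Obstacle",
    "PhantomSpec",
    "generate_channel_phantom",
    "generate_skull_phantom",
    "measure_channel_width",
    "goat_like_spec",
    "macaque_like_spec",
    "blocked_spec",
    "orbit_flanked_spec",
    "standard_phantom_specs",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Obstacle:
    """Axis-aligned forbidden body: a box or an ellipsoid.

    ``center_mm`` and ``size_mm`` (full extents along x, y, z) are in world mm.
    """

    kind: str  # "box" | "ellipsoid"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("box", "ellipsoid"):
            raise ValueError(f"obstacle kind must be 'box' or 'ellipsoid', got {self.kind!r}")
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("obstacle extents must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rel = (np.asarray(pts, dtype=float) - np.asarray(self.center_mm)) \
            / (np.asarray(self.size_mm) / 2.0)
        if self.kind == "box":
            return np.all(np.abs(rel) <= 1.0, axis=-1)
        return np.sum(rel ** 2, axis=-1) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic segmented skull.

    The non-surgical block spans the full transverse extent over
    ``[block_start, block_start + block_depth]`` mm along ``channel_axis``; a
    circular channel of diameter ``channel_width`` pierces it from
    ``block_start + wall_thickness`` to its anterior face.  The first
    ``target_extent`` mm of the channel are the target slab.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_width: float = 5.0
    channel_axis: str = "y"
    obstacles: tuple[Obstacle, ...] = ()
    target_extent: float = 2.0
    wall_thickness: float = 2.0
    block_start: float = 0.0
    block_depth: float | None = None  # default: 45% of the axis extent
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.channel_axis not in _AXES:
            raise ValueError(f"channel_axis must be one of {sorted(_AXES)}")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be > 0")
        if self.target_extent <= 0:
            raise ValueError("target_extent must be > 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        spacing = self.spacing if not np.isscalar(self.spacing) else (self.spacing,) * 3
        object.__setattr__(self, "spacing", tuple(float(s) for s in spacing))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "obstacles", tuple(self.obstacles))
        ax = _AXES[self.channel_axis]
        trans = [a for a in range(3) if a != ax]
        extent = [self.shape[a] * self.spacing[a] for a in range(3)]
        if any(self.channel_width >= extent[a] for a in trans):
            raise ValueError(f"channel_width {self.channel_width} mm does not fit the "
                             f"transverse extent {min(extent[a] for a in trans)} mm")

    @property
    def axis_index(self) -> int:
        return _AXES[self.channel_axis]

    def resolved_block_depth(self) -> float:
        if self.block_depth is not None:
            return float(self.block_depth)
        ax = self.axis_index
        return 0.45 * self.shape[ax] * self.spacing[ax]


def _voxel_coords(spec: PhantomSpec) -> np.ndarray:
    """(nx, ny, nz, 3) world-mm coordinates used for classification.

    With ``jitter > 0`` each voxel center is perturbed by a seeded uniform
    offset in [-jitter, +jitter] per axis before classification, which can
    only relabel voxels within ``jitter`` mm of an analytic boundary.
    """
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)),
                        indexing="ij")
    coords = np.stack(grids, axis=-1)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.uniform(-spec.jitter, spec.jitter, size=coords.shape)
    return coords


def _channel_center(spec: PhantomSpec) -> np.ndarray:
    """Transverse channel-axis position, snapped to the voxel lattice."""
    center = np.array([(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)])
    for a in range(3):
        center[a] = round(center[a] / spec.spacing[a]) * spec.spacing[a]
    return center


def generate_channel_phantom(spec: PhantomSpec,
                             scheme: LabelScheme | None = None) -> LabelVolume:
    """Bony block pierced by a straight open channel ending in a target slab.

    Deterministic given ``spec.seed``; with ``jitter == 0`` every voxel is
    exactly its closed-form membership.
    """
    scheme = scheme or LabelScheme()
    ax = spec.axis_index
    coords = _voxel_coords(spec)
    y = coords[..., ax]
    center = _channel_center(spec)
    trans_axes = [a for a in range(3) if a != ax]
    r2 = sum((coords[..., a] - center[a]) ** 2 for a in trans_axes)

    b0 = spec.block_start
    b1 = b0 + spec.resolved_block_depth()
    if b1 >= spec.shape[ax] * spec.spacing[ax] - spec.spacing[ax]:
        raise ValueError("block extends past the volume; no anterior air vestibule remains")
    c0 = b0 + spec.wall_thickness
    if c0 + spec.target_extent >= b1:
        raise ValueError("target slab would fall outside the channel")

    labels = np.full(spec.shape, scheme.air, dtype=np.int16)
    # posterior face starts at the physical box boundary (half a voxel below the
    # first center plane) so the analytic surface never sits on voxel centers
    in_block = (y >= b0 - 0.5 * spec.spacing[ax]) & (y <= b1)
    labels[in_block] = scheme.non_surgical
    in_channel = in_block & (y >= c0) & (r2 <= (spec.channel_width / 2.0) ** 2)
    labels[in_channel] = scheme.surgical_space
    in_target = in_channel & (y < c0 + spec.target_extent)
    labels[in_target] = scheme.target

    if not np.any(labels == scheme.surgical_space):
        raise ValueError("channel produced no surgical-space voxels")
    if not np.any(labels == scheme.target):
        raise ValueError("channel produced no target voxels")
    return LabelVolume(labels, spec.spacing)


def generate_skull_phantom(spec: PhantomSpec,
                           scheme: LabelScheme | None = None) -> LabelVolume:
    """Channel phantom plus configured obstacle bodies.

    Obstacles overwrite air and surgical space with non-surgical labels but
    never the target slab.  Raises if they erase the channel entirely.
    """
    scheme = scheme or LabelScheme()
    vol = generate_channel_phantom(spec, scheme)
    if not spec.obstacles:
        return vol
    labels = vol.labels.copy()
    coords = _voxel_coords(spec)
    pts = coords.reshape(-1, 3)
    hit = np.zeros(pts.shape[0], dtype=bool)
    for obs in spec.obstacles:
        hit |= obs.contains(pts)
    hit = hit.reshape(spec.shape)
    writable = labels != scheme.target
    labels[hit & writable] = scheme.non_surgical
    if not np.any(labels == scheme.surgical_space):
        raise ValueError("obstacles erased the entire channel")
    return LabelVolume(labels, spec.spacing)


def measure_channel_width(vol: LabelVolume, scheme: LabelScheme | None = None,
                          channel_axis: str = "y") -> float:
    """Inscribed-disc diameter at mid-channel, via the distance transform.

    Returns twice the maximum distance-to-forbidden over surgical-space voxels
    in the mid-channel cross-section; recovers the analytic channel width to
    within about one voxel.
    """
    from scipy.ndimage import distance_transform_edt

    scheme = scheme or LabelScheme()
    surgical = vol.labels == scheme.surgical_space
    if not surgical.any():
        raise ValueError("no channel: volume has no surgical-space voxels")
    ax = _AXES[channel_axis]
    dist = distance_transform_edt(~forbidden_mask(vol, scheme), sampling=vol.spacing)
    slabs = np.unique(np.argwhere(surgical)[:, ax])
    mid = slabs[len(slabs) // 2]
    sel = [slice(None)] * 3
    sel[ax] = mid
    cross_surgical = surgical[tuple(sel)]
    cross_dist = dist[tuple(sel)]
    return float(2.0 * cross_dist[cross_surgical].max())


# -- standard fixture suite ------------------------------------------------


def goat_like_spec(seed: int = 0, jitter: float = 0.0) -> PhantomSpec:
    """Wide-corridor skull: 13 mm channel at 0.65 mm voxels (goat-like anatomy)."""
    return PhantomSpec(shape=(64, 64, 64), spacing=(0.65, 0.65, 0.65),
                       channel_width=13.0, seed=seed, jitter=jitter)


def macaque_like_spec(seed: int = 0, jitter: float = 0.0) -> PhantomSpec:
    """Narrow-corridor skull: 2.5 mm channel at 1 mm voxels (macaque-like anatomy)."""
    return PhantomSpec(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0),
                       channel_width=2.5, seed=seed, jitter=jitter)


def blocked_spec(seed: int = 0) -> PhantomSpec:
    """Macaque-like skull with an anterior slab fully crossing the corridor."""
    base = macaque_like_spec(seed=seed)
    ext = [n * s for n, s in zip(base.shape, base.spacing)]
    b1 = base.block_start + base.resolved_block_depth()
    slab_y = (b1 + ext[1] - 2.0) / 2.0
    slab = Obstacle("box", center_mm=(ext[0] / 2.0, slab_y, ext[2] / 2.0),
                    size_mm=(ext[0] + 2.0, 3.0, ext[2] + 2.0))
    return replace(base, obstacles=(slab,))


def orbit_flanked_spec(seed: int = 0, clearance: float = 4.0) -> PhantomSpec:
    """Goat-like skull with paired orbit ellipsoids flanking the corridor exit.

    ``clearance`` is the gap (mm) between the channel wall and each orbit
    surface at the channel's exit level.
    """
    base = goat_like_spec(seed=seed)
    ext = [n * s for n, s in zip(base.shape, base.spacing)]
    b1 = base.block_start + base.resolved_block_depth()
    orbit_r = 6.0
    dx = base.channel_width / 2.0 + clearance + orbit_r
    orbits = tuple(
        Obstacle("ellipsoid",
                 center_mm=(ext[0] / 2.0 + side * dx, b1 + 4.0, ext[2] / 2.0),
                 size_mm=(2 * orbit_r, 2 * orbit_r, 2 * orbit_r))
        for side in (-1.0, 1.0)
    )
    return replace(base, obstacles=orbits)


def standard_phantom_specs(seed: int = 0) -> dict[str, PhantomSpec]:
    """The default fixture suite mirroring the species contrasts of interest."""
    return {
        "goat_like": goat_like_spec(seed=seed),
        "macaque_like": macaque_like_spec(seed=seed),
        "blocked": blocked_spec(seed=seed),
        "orbit_flanked": orbit_flanked_spec(seed=seed),
        "jittered": replace(macaque_like_spec(seed=seed, jitter=0.3),
                            channel_width=5.0),
    }
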