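"""Labeled CT volume I/O, validation and resampling.

A planning scene is a 3D integer label volume in which every voxel carries one
of four semantic roles: air (outside the skull), surgical space (the nasal /
sphenoidal corridor the endoscope may occupy), non-surgical space (bone and
soft tissue that must not be touched) and the surgical target (the anterior
wall of the optic canal).  All geometry downstream works in world millimetres
under a voxel-center convention: voxel index ``i`` sits at
``origin + i * spacing`` in canonical RAS axes (x = left->right,
y = posterior->anterior, z = inferior->superior).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "LabelScheme",
    "LabelVolume",
    "read_labelmap",
    "write_labelmap",
    "resample_isotropic",
    "allowed_mask",
    "forbidden_mask",
]


@dataclass(frozen=True)
class LabelScheme:
    """Role -> integer map for the four-label segmentation.

    ``allowed_labels`` is {air, surgical_space, target}: a corridor voxel is
    admissible iff it lies in the open surgical space or in air, and target
    voxels are terminal contact, never an obstacle.  The forbidden set is
    exactly {non_surgical}.
    """

    air: int = 0
    surgical_space: int = 1
    non_surgical: int = 2
    target: int = 3

    def __post_init__(self) -> None:
        vals = self.values()
        if len(set(vals)) != 4:
            raise ValueError(f"label scheme values must be distinct, got {vals}")

    def values(self) -> tuple[int, int, int, int]:
        return (self.air, self.surgical_space, self.non_surgical, self.target)

    @property
    def allowed_labels(self) -> tuple[int, int, int]:
        return (self.air, self.surgical_space, self.target)


@dataclass(frozen=True)
class LabelVolume:
    """3D integer label grid with physical spacing and origin (world mm).

    ``labels`` is indexed ``[x, y, z]`` in canonical RAS order; ``origin`` is
    the world position of the center of voxel (0, 0, 0).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "RAS"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be a 3D array, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {labels.dtype}")
        object.__setattr__(self, "labels", labels)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- coordinate helpers ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World mm coordinates of voxel centers for indices ``idx`` (..., 3)."""
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world points (..., 3); not clipped."""
        rel = (np.asarray(pts, dtype=float) - np.array(self.origin)) / np.array(self.spacing)
        return np.rint(rel).astype(int)

    def physical_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners in mm of the volume's physical extent.

        The box spans half a voxel beyond the outermost voxel centers so that
        the physical extent equals ``shape * spacing``.
        """
        origin = np.array(self.origin)
        spacing = np.array(self.spacing)
        shape = np.array(self.shape)
        return origin - spacing / 2.0, origin + (shape - 0.5) * spacing

    def validate(self, scheme: LabelScheme) -> None:
        """Raise if any voxel carries a label outside the scheme."""
        present = np.unique(self.labels)
        unknown = set(present.tolist()) - set(scheme.values())
        if unknown:
            raise ValueError(f"unknown label value(s) {sorted(unknown)}; scheme is {scheme.values()}")


# -- reading ---------------------------------------------------------------


def _canonicalize(arr: np.ndarray, direction: np.ndarray, spacing: np.ndarray,
                  origin: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reorder/flip ``arr`` (indexed x,y,z) so its direction matrix becomes +I.

    ``direction`` columns are the RAS world directions of the index axes and
    must form a signed permutation (axis-aligned acquisition); oblique
    acquisitions are rejected rather than silently sheared.
    """
    if not np.allclose(np.abs(direction) @ np.ones(3), 1.0, atol=1e-3) or \
            not np.allclose(np.abs(direction).T @ np.ones(3), 1.0, atol=1e-3) or \
            not np.allclose(np.abs(np.abs(direction) - 0.5) , 0.5, atol=1e-3):
        raise ValueError("volume direction matrix is oblique; only axis-aligned label maps are supported")
    perm = np.argmax(np.abs(direction), axis=1)  # world axis w <- index axis perm[w]
    signs = np.sign(direction[np.arange(3), perm])
    out = np.transpose(arr, axes=perm)
    new_spacing = spacing[perm]
    new_origin = np.empty(3)
    for w in range(3):
        j = perm[w]
        if signs[w] < 0:
            out = np.flip(out, axis=w)
            new_origin[w] = origin[w] + direction[w, j] * spacing[j] * (arr.shape[j] - 1)
        else:
            new_origin[w] = origin[w]
    return np.ascontiguousarray(out), new_spacing, new_origin


def _read_nifti(path: str) -> LabelVolume:
    img = nib.as_closest_canonical(nib.load(path))  # RAS+
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-4):
        raise ValueError("NIfTI affine is oblique; only axis-aligned label maps are supported")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.rint(data)):
            raise ValueError("label volume contains non-integer values")
        data = np.rint(data).astype(np.int32)
    spacing = np.diag(rot).astype(float)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing {spacing}")
    return LabelVolume(np.ascontiguousarray(data.astype(np.int16, casting="same_kind")
                                            if data.dtype.itemsize <= 2 else data),
                       tuple(spacing), tuple(affine[:3, 3].astype(float)))


_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


def _read_nrrd(path: str) -> LabelVolume:
    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise ValueError("expected a 3D volume")
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError("label volume contains non-integer values")
        arr = np.rint(arr).astype(np.int32)
    arr = np.transpose(arr, (2, 1, 0))  # -> [x, y, z] index order
    direction_lps = np.array(img.GetDirection()).reshape(3, 3)
    spacing = np.array(img.GetSpacing(), dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing {spacing}")
    # ITK physical space is LPS; convert direction/origin to RAS.
    direction = _LPS_TO_RAS @ direction_lps
    origin = _LPS_TO_RAS @ np.array(img.GetOrigin(), dtype=float)
    out, sp, og = _canonicalize(arr, direction, spacing, origin)
    return LabelVolume(out, tuple(sp), tuple(og))


def read_labelmap(path: str | os.PathLike, scheme: LabelScheme | None = None) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) integer label volume.

    The volume is reoriented to canonical RAS axes.  If ``scheme`` is given,
    every voxel value is validated against it.
    """
    p = str(path)
    if p.endswith((".nii", ".nii.gz")):
        vol = _read_nifti(p)
    elif p.endswith(".nrrd"):
        vol = _read_nrrd(p)
    else:
        raise ValueError(f"unsupported volume format: {p!r} (expected .nii, .nii.gz or .nrrd)")
    if scheme is not None:
        vol.validate(scheme)
    return vol


def write_labelmap(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume as NIfTI or NRRD (format chosen by extension)."""
    p = str(path)
    data = vol.labels.astype(np.int16, casting="same_kind") if vol.labels.dtype.itemsize <= 2 else vol.labels
    if p.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(data, affine), p)
    elif p.endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple((_LPS_TO_RAS @ np.array(vol.origin)).tolist()))
        img.SetDirection(tuple((_LPS_TO_RAS @ np.eye(3)).ravel().tolist()))
        sitk.WriteImage(img, p)
    else:
        raise ValueError(f"unsupported volume format: {p!r}")


# -- resampling and masks --------------------------------------------------


def resample_isotropic(vol: LabelVolume, target_spacing: float | None = None) -> LabelVolume:
    """Nearest-neighbor resample onto an isotropic grid of ``target_spacing`` mm.

    Default target spacing is the smallest input spacing.  Labels stay
    categorical (no interpolation across label values); the physical extent is
    preserved to within one voxel.  Already-conforming volumes are returned
    unchanged.
    """
    if target_spacing is None:
        target_spacing = min(vol.spacing)
    t = float(target_spacing)
    if t <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    spacing = np.array(vol.spacing)
    if np.allclose(spacing, t):
        return vol
    shape = np.array(vol.shape)
    extent = shape * spacing
    new_shape = np.maximum(1, np.rint(extent / t).astype(int))
    box_min = np.array(vol.origin) - spacing / 2.0
    new_origin = box_min + t / 2.0
    # nearest input voxel center for every output voxel center
    src_idx = []
    for ax in range(3):
        centers = new_origin[ax] + np.arange(new_shape[ax]) * t
        rel = np.rint((centers - vol.origin[ax]) / spacing[ax]).astype(int)
        src_idx.append(np.clip(rel, 0, shape[ax] - 1))
    out = vol.labels[np.ix_(src_idx[0], src_idx[1], src_idx[2])]
    return replace(vol, labels=np.ascontiguousarray(out), spacing=(t, t, t),
                   origin=tuple(new_origin))


def allowed_mask(vol: LabelVolume, scheme: LabelScheme) -> np.ndarray:
    """Boolean mask, true where the corridor may pass (air, surgical space, target)."""
    return np.isin(vol.labels, scheme.allowed_labels)


def forbidden_mask(vol: LabelVolume, scheme: LabelScheme) -> np.ndarray:
    """Boolean mask of non-surgical voxels; exact complement of :func:`allowed_mask`."""
    return vol.labels == scheme.non_surgical
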