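"""Voxel-grid geometry, NIfTI I/O, resampling and distance maps.

All spatial quantities in this package live in a world coordinate frame
measured in millimetres (the patient frame of the NIfTI affine, RAS+ by
convention).  Voxel indices are 0-based and refer to voxel *centers*;
the affine mapping index ``i`` to world position is

    x = origin + direction @ (spacing * i)

with ``direction`` an orthogonal 3x3 matrix and ``spacing`` strictly
positive.  Displacements, distances and all reported motions are world
millimetres; this matters because clinical knee acquisitions are
anisotropic (e.g. 0.6 x 0.6 x 0.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DataError,
    DegenerateInputError,
    DimensionalityError,
    GeometryMismatchError,
    InputError,
)

__all__ = [
    "Grid",
    "Volume",
    "LabelMask",
    "GridTransform",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "resample",
    "euclidean_distance_map",
]

@dataclass(frozen=True)
class Grid:
    """Geometry of a voxel lattice: shape, spacing (mm), origin (mm), direction."""

    shape: tuple
    spacing: tuple
    origin: tuple
    direction: tuple  # row-major 3x3, orthogonal

    def __post_init__(self):
        if len(self.shape) != 3:
            raise DimensionalityError(f"grid must be 3D, got shape {self.shape}")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        D = self.direction_matrix
        if not np.allclose(D.T @ D, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthogonal (within 1e-6)")

    @property
    def spacing_array(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_array(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.direction_matrix @ np.diag(self.spacing_array)
        A[:3, 3] = self.origin_array
        return A

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing_array))

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map fractional 0-based indices (..., 3) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * self.spacing_array @ self.direction_matrix.T + self.origin_array

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.origin_array) @ self.direction_matrix / self.spacing_array

    def index_grid(self) -> np.ndarray:
        """Dense (3, *shape) array of voxel indices."""
        return np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij")
        )

    def world_grid(self) -> np.ndarray:
        """Dense (3, *shape) array of voxel-center world coordinates (mm)."""
        idx = self.index_grid().reshape(3, -1).T
        return self.index_to_world(idx).T.reshape((3,) + tuple(self.shape))

    def approx_equal(self, other: "Grid", tol: float = 1e-5) -> bool:
        return (
            tuple(self.shape) == tuple(other.shape)
            and np.allclose(self.spacing_array, other.spacing_array, atol=tol)
            and np.allclose(self.origin_array, other.origin_array, atol=tol)
            and np.allclose(self.direction_matrix, other.direction_matrix, atol=tol)
        )

    @staticmethod
    def from_affine(shape, affine) -> "Grid":
        M = np.asarray(affine, dtype=float)[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        if np.any(spacing <= 0):
            raise ValueError("affine has a zero column")
        D = M / spacing
        return Grid(
            shape=tuple(int(n) for n in shape),
            spacing=tuple(spacing),
            origin=tuple(np.asarray(affine, dtype=float)[:3, 3]),
            direction=tuple(D.ravel()),
        )

    @staticmethod
    def centered(shape, spacing, direction=None) -> "Grid":
        """Grid whose world origin sits at the lattice center."""
        shape = tuple(int(n) for n in shape)
        sp = np.asarray(spacing, dtype=float)
        D = np.eye(3) if direction is None else np.asarray(direction, float).reshape(3, 3)
        center_idx = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        origin = -(D @ (sp * center_idx))
        return Grid(shape=shape, spacing=tuple(sp), origin=tuple(origin),
                    direction=tuple(D.ravel()))


@dataclass
class Volume:
    """A 3D scalar image on a :class:`Grid`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(f"volume data must be 3D, got {self.data.ndim}D")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise GeometryMismatchError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing_array

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    def sample_at_index(self, idx: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate at fractional indices (3, ...); outside the domain -> 0."""
        idx = np.asarray(idx, dtype=float)
        return ndimage.map_coordinates(
            np.asarray(self.data, dtype=float), idx, order=order, mode="constant", cval=0.0
        )

    def sample_at_world(self, xyz: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate at world points (..., 3); outside the domain -> 0."""
        idx = self.grid.world_to_index(xyz)
        return self.sample_at_index(np.moveaxis(idx, -1, 0), order=order)


@dataclass
class LabelMask:
    """A binary mask sharing the grid of a companion :class:`Volume`."""

    data: np.ndarray
    grid: Grid
    label_name: str = "tibia"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(f"mask data must be 3D, got {self.data.ndim}D")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise GeometryMismatchError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise DataError(f"mask values must be 0/1, found {vals[:5]}")
        self.data = self.data.astype(bool)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def foreground_indices(self) -> np.ndarray:
        """(N, 3) integer indices of foreground voxels (C order)."""
        return np.argwhere(self.data)

    def foreground_world(self) -> np.ndarray:
        """(N, 3) world coordinates (mm) of foreground voxel centers."""
        return self.grid.index_to_world(self.foreground_indices())

    def to_volume(self, dtype=float) -> Volume:
        return Volume(self.data.astype(dtype), self.grid)


@dataclass
class GridTransform:
    """A spatial map from template world coordinates to moving world coordinates.

    ``kind`` is ``"rigid"`` (payload: a RigidTransform-like object with an
    ``apply(points)`` method and 6 degrees of freedom) or ``"dense_field"``
    (payload: a DeformationField-like object with per-voxel displacement in
    mm on the template grid).  ``frame`` is the template grid.
    """

    kind: Literal["rigid", "dense_field"]
    payload: object
    frame: Grid

    def __post_init__(self):
        if self.kind not in ("rigid", "dense_field"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "rigid":
            p = getattr(self.payload, "parameters", None)
            if p is None or np.asarray(p).size != 6:
                raise ValueError("rigid payload must expose exactly 6 parameters")

    def map_world(self, xyz: np.ndarray) -> np.ndarray:
        """Apply the transform to world points of shape (..., 3)."""
        if self.kind == "rigid":
            return self.payload.apply(xyz)
        u = self.payload  # DeformationField
        if not u.grid.approx_equal(self.frame):
            raise GeometryMismatchError("deformation field grid differs from frame")
        disp = np.moveaxis(u.sample_at_world(xyz), 0, -1)
        return np.asarray(xyz, dtype=float) + disp


def _as_3d(data: np.ndarray) -> np.ndarray:
    if data.ndim == 3:
        return data
    if data.ndim > 3:
        extra = data.shape[3:]
        if all(n == 1 for n in extra):
            return data.reshape(data.shape[:3])
        raise DimensionalityError(
            f"image has non-singleton extra dimensions {data.shape}"
        )
    raise DimensionalityError(f"image must be 3D, got {data.ndim}D")


def load_volume(path) -> Volume:
    """Load a NIfTI-1 scalar volume.

    A trailing singleton 4th dimension is squeezed; true 4D images and 2D
    images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types
        raise InputError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = _as_3d(np.asanyarray(img.dataobj))
    grid = Grid.from_affine(data.shape, img.affine)
    return Volume(np.asarray(data, dtype=np.float32), grid)


def save_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.grid.affine)
    nib.save(img, str(path))


def _sidecar_path(path) -> Path:
    path = Path(path)
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".yaml")


def load_mask(path, label_name: str = None) -> LabelMask:
    """Load a binary NIfTI label image (stored as uint8).

    If a YAML sidecar written by :func:`save_mask` is present its label
    name takes precedence over the ``label_name`` argument.
    """
    vol = load_volume(path)
    data = np.asarray(vol.data)
    if not np.all(np.isin(np.unique(data), (0, 1))):
        raise DataError(f"label file {path} is not binary")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        import yaml

        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        label_name = meta.get("label", label_name)
    return LabelMask(data.astype(bool), vol.grid,
                     label_name=label_name or "tibia")


def save_mask(mask: LabelMask, path, sidecar: bool = True) -> None:
    """Write a mask as uint8 NIfTI plus a small YAML sidecar naming the label."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
    if sidecar:
        import yaml

        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump({"label": mask.label_name, "values": {0: "background",
                                                                 1: mask.label_name}}, fh)


def resample(
    vol,
    transform: GridTransform,
    interpolation: Literal["trilinear", "nearest"] = "trilinear",
):
    """Pull ``vol`` back onto the transform's template grid.

    The output value at template voxel x is ``vol`` sampled at the warped
    world position ``transform.map_world(x)``; samples outside the moving
    domain are 0.  Masks must use nearest-neighbour interpolation.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    is_mask = isinstance(vol, LabelMask)
    if is_mask and interpolation != "nearest":
        raise ValueError("LabelMask resampling requires interpolation='nearest'")
    order = 0 if interpolation == "nearest" else 1

    frame = transform.frame
    pts = np.moveaxis(frame.world_grid(), 0, -1).reshape(-1, 3)
    warped = transform.map_world(pts)
    idx = vol.grid.world_to_index(warped).T  # (3, N)
    src = vol.data.astype(float) if is_mask else np.asarray(vol.data, dtype=float)
    out = ndimage.map_coordinates(src, idx, order=order, mode="constant", cval=0.0)
    out = out.reshape(tuple(frame.shape))
    if is_mask:
        return LabelMask(out > 0.5, frame, label_name=vol.label_name)
    return Volume(out, frame)


def euclidean_distance_map(mask: LabelMask) -> Volume:
    """Spacing-aware Euclidean distance (mm) to the nearest foreground voxel center.

    Zero on the foreground itself.  This is the shape prior used by the
    deformable registration's distance penalty.
    """
    if mask.n_foreground == 0:
        raise DegenerateInputError("distance map of an empty mask is undefined")
    dist = ndimage.distance_transform_edt(
        ~mask.data, sampling=mask.grid.spacing_array
    )
    return Volume(np.asarray(dist, dtype=float), mask.grid)
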