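"""Core data model: axis-aligned grids, scalar maps, binary masks, NIfTI I/O.

All modalities are compared on a single analysis grid (by convention the
coarser MRSI grid, 3.4 mm isotropic).  Physical positions refer to voxel
*centers* in millimetres; voxel indices are 0-based.  Undefined voxels
(e.g. spectroscopy voxels rejected by quality control) are stored as NaN on
disk and tracked by an explicit boolean domain in memory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DisjointExtentError,
    GridMismatchError,
    VolumeFormatError,
)

UNITS = ("ms", "ratio", "ppm", "unitless")

#: relative tolerance for grid compatibility checks (mm scale)
_GRID_ATOL = 1e-4


@dataclasses.dataclass(frozen=True)
class Grid:
    """A regular axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis (all >= 1).
    voxel_size
        Voxel edge lengths in mm (all > 0).
    origin
        Physical position (mm) of the center of voxel (0, 0, 0).
    orientation
        Axis-alignment code mapping voxel axes to physical axes.  Volumes
        are reoriented to RAS on load; oblique affines are rejected rather
        than silently resliced.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")

    def is_compatible(self, other: "Grid") -> bool:
        """True iff shape, voxel size, origin and orientation all agree."""
        return (
            self.shape == other.shape
            and self.orientation == other.orientation
            and np.allclose(self.voxel_size, other.voxel_size, atol=_GRID_ATOL)
            and np.allclose(self.origin, other.origin, atol=_GRID_ATOL)
        )

    @property
    def affine(self) -> np.ndarray:
        """Voxel-index -> physical-mm affine (RAS, voxel centers)."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers_mm(self) -> np.ndarray:
        """Physical center positions of all voxels, shape (*grid.shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)


def voxel_center_position(grid: Grid, index: Iterable[int]) -> np.ndarray:
    """Physical position (mm) of the center of the voxel at ``index``.

    Raises
    ------
    IndexError
        If the index lies outside the grid.
    """
    idx = tuple(int(i) for i in index)
    if len(idx) != 3:
        raise IndexError(f"index must have three components, got {idx}")
    for i, s in zip(idx, grid.shape):
        if not 0 <= i < s:
            raise IndexError(f"voxel index {idx} out of range for shape {grid.shape}")
    return np.asarray(idx, dtype=float) * np.asarray(grid.voxel_size) + np.asarray(grid.origin)


@dataclasses.dataclass
class ScalarMap:
    """A 3D map of physical values with an explicit defined-voxel domain.

    ``values`` holds NaN wherever ``domain`` is False; all defined values
    are finite.  The unit tag travels with the map through masking and
    resampling.
    """

    grid: Grid
    values: np.ndarray
    unit: str
    domain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        finite = np.isfinite(self.values)
        if self.domain is None:
            self.domain = finite
        else:
            self.domain = np.asarray(self.domain, dtype=bool)
            if self.domain.shape != self.grid.shape:
                raise ValueError("domain shape does not match grid")
            self.domain = self.domain & finite
        self.values = np.where(self.domain, self.values, np.nan)

    @property
    def n_defined(self) -> int:
        return int(self.domain.sum())

    def defined_values(self) -> np.ndarray:
        """All defined voxel values as a flat array."""
        return self.values[self.domain]

    def values_in(self, mask: "BinaryMask") -> np.ndarray:
        """Defined values inside a mask on a compatible grid."""
        _check_compatible(self.grid, mask.grid)
        sel = mask.members & self.domain
        return self.values[sel]

    def copy(self) -> "ScalarMap":
        return ScalarMap(self.grid, self.values.copy(), self.unit, self.domain.copy())


@dataclasses.dataclass
class BinaryMask:
    """A voxel set on a grid."""

    grid: Grid
    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.members.shape != self.grid.shape:
            raise ValueError(
                f"members shape {self.members.shape} does not match grid {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.members.sum())

    @property
    def is_empty(self) -> bool:
        return not self.members.any()

    def union(self, other: "BinaryMask") -> "BinaryMask":
        _check_compatible(self.grid, other.grid)
        return BinaryMask(self.grid, self.members | other.members)

    def intersection(self, other: "BinaryMask") -> "BinaryMask":
        _check_compatible(self.grid, other.grid)
        return BinaryMask(self.grid, self.members & other.members)

    def difference(self, other: "BinaryMask") -> "BinaryMask":
        _check_compatible(self.grid, other.grid)
        return BinaryMask(self.grid, self.members & ~other.members)

    def issubset(self, other: "BinaryMask") -> bool:
        _check_compatible(self.grid, other.grid)
        return bool(np.all(~self.members | other.members))

    __or__ = union
    __and__ = intersection
    __sub__ = difference


def _check_compatible(a: Grid, b: Grid) -> None:
    if not a.is_compatible(b):
        raise GridMismatchError(f"incompatible grids: {a} vs {b}")


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def _grid_from_image(img: nib.Nifti1Image, path: str = "") -> tuple[Grid, np.ndarray]:
    """Reorient to closest canonical (RAS) and extract an axis-aligned grid."""
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path}: expected a single 3D volume, got shape {img.shape}")
    try:
        img = nib.as_closest_canonical(img)
    except Exception as exc:  # pragma: no cover - nibabel-internal failures
        raise VolumeFormatError(f"{path}: cannot interpret header transform: {exc}") from exc
    aff = img.affine
    if not np.all(np.isfinite(aff)) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise VolumeFormatError(f"{path}: non-invertible header transform")
    lin = aff[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off_diag)) > 1e-3 * np.max(np.abs(np.diag(lin))):
        raise VolumeFormatError(
            f"{path}: oblique affine; inputs must be axis-aligned after reorientation"
        )
    voxel_size = tuple(np.diag(lin))
    if any(v <= 0 for v in voxel_size):
        raise VolumeFormatError(f"{path}: non-positive voxel size after canonicalization")
    grid = Grid(tuple(img.shape), voxel_size, tuple(aff[:3, 3]), "RAS")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return grid, data


def read_volume(path: str | Path, expected_unit: str) -> ScalarMap:
    """Read a single 3D NIfTI volume as a ScalarMap.

    Non-finite voxels are marked undefined.  The unit is taken from the
    caller (configuration), never guessed from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid, data = _grid_from_image(img, str(path))
    return ScalarMap(grid, data, expected_unit)


def write_volume(smap: ScalarMap, path: str | Path) -> None:
    """Write a ScalarMap as float32 NIfTI; undefined voxels become NaN."""
    arr = np.where(smap.domain, smap.values, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, smap.grid.affine), str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 0/1 NIfTI volume as a BinaryMask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid, data = _grid_from_image(img, str(path))
    finite = data[np.isfinite(data)]
    if finite.size and not np.all(np.isin(np.round(finite, 6), (0.0, 1.0))):
        raise VolumeFormatError(f"{path}: mask volume contains values other than 0/1")
    return BinaryMask(grid, np.nan_to_num(data) > 0.5)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.members.astype(np.uint8), mask.grid.affine), str(path))


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

_ORDER = {"nearest": 0, "linear": 1}


def _source_coords(source: Grid, target: Grid) -> np.ndarray:
    """Fractional source voxel indices of all target voxel centers (3, N)."""
    centers = target.voxel_centers_mm().reshape(-1, 3)
    coords = (centers - np.asarray(source.origin)) / np.asarray(source.voxel_size)
    return coords.T


def resample_to_grid(smap: ScalarMap, target: Grid, method: str = "linear") -> ScalarMap:
    """Resample a map onto a target grid.

    Undefined voxels propagate: under linear interpolation any target voxel
    that draws weight from an undefined source voxel becomes undefined.
    Target voxels outside the source extent are undefined.  Resampling onto
    a compatible grid is the identity.
    """
    if method not in _ORDER:
        raise ValueError(f"method must be one of {tuple(_ORDER)}, got {method!r}")
    if smap.grid.is_compatible(target):
        return smap.copy()
    if smap.grid.orientation != target.orientation:
        raise GridMismatchError("source and target orientations differ")
    coords = _source_coords(smap.grid, target)
    shape = np.asarray(smap.grid.shape, dtype=float)
    inside = np.all((coords.T >= -0.5) & (coords.T <= shape - 0.5), axis=1)
    if not inside.any():
        raise DisjointExtentError("source and target grids do not overlap in physical space")
    order = _ORDER[method]
    filled = np.nan_to_num(smap.values, nan=0.0)
    vals = ndimage.map_coordinates(filled, coords, order=order, mode="constant", cval=0.0)
    # interpolate the undefined indicator; any contribution marks the target
    # voxel undefined, and outside the source extent counts as undefined
    bad = ndimage.map_coordinates(
        (~smap.domain).astype(np.float64), coords, order=order, mode="constant", cval=1.0
    )
    domain = bad < 1e-9
    out = np.where(domain, vals, np.nan).reshape(target.shape)
    return ScalarMap(target, out, smap.unit, domain.reshape(target.shape))


def resample_mask_to_grid(mask: BinaryMask, target: Grid) -> BinaryMask:
    """Nearest-neighbour mask resampling (preserves binarity)."""
    if mask.grid.is_compatible(target):
        return BinaryMask(target, mask.members.copy())
    if mask.grid.orientation != target.orientation:
        raise GridMismatchError("source and target orientations differ")
    coords = _source_coords(mask.grid, target)
    shape = np.asarray(mask.grid.shape, dtype=float)
    inside = np.all((coords.T >= -0.5) & (coords.T <= shape - 0.5), axis=1)
    if not inside.any():
        raise DisjointExtentError("source and target grids do not overlap in physical space")
    vals = ndimage.map_coordinates(
        mask.members.astype(np.float64), coords, order=0, mode="constant", cval=0.0
    )
    return BinaryMask(target, (vals > 0.5).reshape(target.shape))
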