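"""3-D volume containers, NIfTI I/O and grid resampling.

Everything downstream operates on :class:`Volume3D` (scalar anatomy) and
:class:`LabelVolume` (integer masks) that carry a voxel-to-world affine.
All geometry is computed in world millimetres so that anisotropic grids
(e.g. 0.9375 x 0.9375 x 1.1 mm clinical acquisitions) are handled uniformly.
Voxel indices are 0-based; world coordinates follow the NIfTI affine.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DomainError, FormatError

#: tolerance on affine entries when deciding two grids are "the same"
#: (NIfTI headers are float32, so exact equality is too strict)
GRID_ATOL = 1e-5


@dataclass(frozen=True)
class Grid:
    """A 3-D sampling lattice: array shape plus voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise FormatError("affine is singular (zero determinant)")
        object.__setattr__(self, "affine", aff)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise FormatError(f"grid shape must be 3-D and positive, got {self.shape}")
        if np.any(self.spacing <= 0):
            raise FormatError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    def matches(self, other: "Grid", atol: float = GRID_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices to (N,3) world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def world_corners(self) -> np.ndarray:
        """World coordinates of the 8 grid corners (voxel-center convention)."""
        n = np.array(self.shape) - 1
        corners = np.array(
            [[i * n[0], j * n[1], k * n[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
            dtype=float,
        )
        return self.index_to_world(corners)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.world_corners()
        return c.min(axis=0), c.max(axis=0)


def _validate_volume(data: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D array, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise FormatError("volume contains NaN or Inf values")
    Grid(data.shape, affine)  # delegates affine/spacing checks


@dataclass
class Volume3D:
    """A scalar 3-D image with voxel spacing and voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _validate_volume(self.data, self.affine)

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing

    @property
    def orientation(self) -> tuple[str, str, str]:
        return nib.orientations.aff2axcodes(self.affine)

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.affine.copy())


@dataclass
class LabelVolume:
    """An integer 3-D mask sharing a Volume3D grid.

    Binary masks use values {0, 1}; bilateral hippocampus masks use
    {0 background, 1 left, 2 right}.
    """

    data: np.ndarray
    affine: np.ndarray
    labels: tuple[int, ...] = (0, 1)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.any(self.data != np.round(self.data)):
                raise FormatError("label data must be integer-valued")
            self.data = self.data.astype(np.int16)
        self.affine = np.asarray(self.affine, dtype=float)
        _validate_volume(self.data, self.affine)
        self.labels = tuple(int(v) for v in self.labels)
        present = set(np.unique(self.data).tolist())
        if not present.issubset(set(self.labels)):
            raise FormatError(
                f"label values {sorted(present)} not within declared set {self.labels}"
            )

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing

    def binary(self, label: int | None = None) -> np.ndarray:
        """Boolean foreground array, optionally for a single label value."""
        if label is None:
            return self.data > 0
        return self.data == label

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.affine.copy(), self.labels)


def matching_grids(a, b, atol: float = GRID_ATOL) -> bool:
    """True when two volumes (or grids) share shape and affine within tolerance."""
    ga = a if isinstance(a, Grid) else a.grid
    gb = b if isinstance(b, Grid) else b.grid
    return ga.matches(gb, atol=atol)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume3D:
    """Read a NIfTI file into a :class:`Volume3D`.

    Intensity data are returned unmodified (no scaling beyond the NIfTI
    scl_slope/scl_inter already applied by nibabel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise FormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D data, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: singular affine in header")
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: data contains NaN/Inf")
    return Volume3D(data, affine)


def read_label_volume(path, labels: Sequence[int] | None = None) -> LabelVolume:
    """Read a NIfTI label file; values must lie in the declared label set."""
    vol = read_volume(path)
    data = np.rint(vol.data).astype(np.int16)
    if np.max(np.abs(vol.data - data)) > 1e-3:
        raise FormatError(f"{path}: non-integer values in label file")
    if labels is None:
        labels = tuple(int(v) for v in np.unique(data))
        if 0 not in labels:
            labels = (0,) + labels
    return LabelVolume(data, vol.affine, tuple(labels))


def write_volume(vol: Volume3D | LabelVolume, path) -> None:
    """Write a volume as NIfTI-1; labels are stored with an integer dtype."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def sample_volume(data: np.ndarray, idx: np.ndarray, order: int) -> np.ndarray:
    """Interpolate ``data`` at fractional voxel indices ``idx`` (shape (3, ...)).

    Boundary convention matches ITK's resampler: values are edge-extended up
    to half a voxel beyond the outermost voxel centers and zero outside that
    band, so similarity computed on resampled images agrees with the
    registration engine's.
    """
    out = ndimage.map_coordinates(data, idx, order=order, mode="nearest")
    shape = np.asarray(data.shape, dtype=float)
    inside = np.ones(out.shape, dtype=bool)
    for ax in range(3):
        inside &= (idx[ax] >= -0.5) & (idx[ax] <= shape[ax] - 0.5)
    return np.where(inside, out, 0)

def _overlap_check(source: Grid, target: Grid) -> None:
    slo, shi = source.world_bounds()
    tlo, thi = target.world_bounds()
    if np.any(shi < tlo) or np.any(slo > thi):
        raise DomainError("source and target grids have disjoint world extents")


def _target_index_coords(source: Grid, target: Grid) -> np.ndarray:
    """Source-grid index coordinates of every target voxel, shape (3, *target.shape)."""
    idx = np.indices(target.shape, dtype=float).reshape(3, -1).T
    world = target.index_to_world(idx)
    src_idx = source.world_to_index(world)
    return src_idx.T.reshape((3,) + tuple(target.shape))


def resample(vol: Volume3D | LabelVolume, target_grid: Grid, mode: str = "linear"):
    """Resample a volume onto ``target_grid``.

    Intensities use linear interpolation, labels nearest-neighbour; voxels
    outside the source field of view are filled with 0.
    """
    grid = vol.grid
    if grid.matches(target_grid):
        return vol.copy()
    _overlap_check(grid, target_grid)
    coords = _target_index_coords(grid, target_grid)
    if isinstance(vol, LabelVolume):
        out = sample_volume(vol.data, coords, order=0)
        return LabelVolume(out.astype(vol.data.dtype), target_grid.affine.copy(), vol.labels)
    order = {"linear": 1, "nearest": 0}[mode]
    out = sample_volume(vol.data.astype(np.float32), coords, order=order)
    return Volume3D(out.astype(np.float32), target_grid.affine.copy())
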