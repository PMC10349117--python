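"""Grid-aware volume containers and NIfTI I/O.

All spatial data in the package lives on an explicit :class:`VoxelGrid`
(shape + affine, reference use case MNI152 at 2x2x2 mm).  Mixing grids is
forbidden: every downstream operation calls :func:`assert_same_grid`, and no
resampling is provided — inputs must already share a grid.

Conventions: voxel indices are 0-based; world coordinates follow the NIfTI
affine (world = affine @ [i, j, k, 1]); boolean masks are stored on disk as
unsigned 8-bit 0/1 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "Volume",
    "FunctionalSeries",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "assert_same_grid",
]

_AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two gridded objects do not live on the same voxel grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel grid embedded in world space.

    Parameters
    ----------
    shape
        Number of voxels along each axis (all >= 1).
    affine
        4x4 invertible voxel-to-world transform (mm).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape!r}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return tuple(float(n) for n in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 1.0) -> "VoxelGrid":
        """Identity-oriented grid with isotropic voxels (synthetic phantoms)."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(shape), aff)

    def equals(self, other: "VoxelGrid", atol: float = _AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )


@dataclass
class Volume:
    """A 3D scalar (real or boolean) field over a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def astype_bool(self) -> "Volume":
        return Volume(self.grid, self.values.astype(bool))


@dataclass
class FunctionalSeries:
    """A 4D (space x time) BOLD series with repetition time ``tr`` (seconds)."""

    grid: VoxelGrid
    values: np.ndarray
    tr: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[:3] != self.grid.shape:
            raise ValueError(
                f"series shape {self.values.shape} incompatible with grid {self.grid.shape}"
            )
        if self.values.shape[3] < 2:
            raise ValueError("a functional series needs at least 2 frames")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")

    @property
    def n_t(self) -> int:
        return int(self.values.shape[3])


def read_volume(path: str | Path) -> Volume | FunctionalSeries:
    """Load a NIfTI file as a :class:`Volume` (3D) or :class:`FunctionalSeries` (4D).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the payload is not NIfTI or has more than 4 dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises ImageFileError subclasses
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim > 4:
        raise ValueError(f"{path}: {data.ndim}-dimensional images are not supported")
    if data.ndim < 3:
        raise ValueError(f"{path}: expected a 3D or 4D image, got {data.ndim}D")
    grid = VoxelGrid(tuple(data.shape[:3]), np.asarray(img.affine))
    if data.ndim == 3:
        return Volume(grid, data)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return FunctionalSeries(grid, data, tr=tr)


def write_volume(v: Volume | FunctionalSeries, path: str | Path) -> None:
    """Write a volume or series to NIfTI (.nii / .nii.gz).

    Boolean masks are written as uint8 0/1; integer data round-trips
    bit-exactly, floats to float64 precision.
    """
    path = Path(path)
    data = v.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype in (np.int64, np.uint64):
        data = data.astype(np.int32)  # NIfTI-1 has no portable 64-bit int
    img = nib.Nifti1Image(data, v.grid.affine)
    if isinstance(v, FunctionalSeries):
        zooms = list(img.header.get_zooms())
        zooms[3] = v.tr
        img.header.set_zooms(zooms)
        img.header["xyzt_units"] = 10  # mm + seconds
    nib.save(img, path)


def assert_same_grid(a, b, *, atol: float = _AFFINE_ATOL) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share a grid.

    Accepts any objects carrying a ``grid`` attribute, or bare grids.
    The error message names the differing field (shape or affine).
    """
    ga = a.grid if hasattr(a, "grid") else a
    gb = b.grid if hasattr(b, "grid") else b
    if ga.shape != gb.shape:
        raise GridMismatchError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if not np.allclose(ga.affine, gb.affine, atol=atol, rtol=0.0):
        raise GridMismatchError(
            f"affine mismatch (max abs diff "
            f"{np.max(np.abs(ga.affine - gb.affine)):.3g} > {atol:g})"
        )
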