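"""Volume container, NIfTI I/O and spatial utilities shared by all stages.

Every map in the pipeline — lesion masks, disconnection maps, atlas labels —
lives on a single common template grid, so the container is deliberately thin:
a numpy array plus a :class:`GridSpec` describing voxel geometry and which
axis the inter-hemispheric midline splits.  Coordinates are 0-based voxel
indices internally; world (mm) coordinates appear only at I/O boundaries
through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "Volume",
    "load_volume",
    "save_volume",
    "mirror_lr",
    "spatial_correlation",
    "lesion_frequency_map",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the common template grid.

    Parameters
    ----------
    shape : tuple of 3 int
        Voxels per axis; every entry must be >= 4.
    voxel_size : tuple of 3 float
        Edge length of a voxel in mm per axis, all > 0.
    midline_axis : int
        Index of the axis whose central plane separates the left from the
        right hemisphere.  Lower indices along this axis are treated as
        "left" throughout the package.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    midline_axis: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or len(vs) != 3:
            raise ValueError("GridSpec requires 3-dimensional shape and voxel_size")
        if any(s < 4 for s in shape):
            raise ValueError(f"all grid shape entries must be >= 4, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        if self.midline_axis not in (0, 1, 2):
            raise ValueError("midline_axis must be 0, 1 or 2")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-world affine (no rotation, origin at voxel 0)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (mm^3 / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def contains(self, point: Sequence[float]) -> bool:
        """Whether a continuous voxel-index coordinate lies inside the grid."""
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= -0.5) and np.all(p <= np.array(self.shape) - 0.5))


@dataclass
class Volume:
    """A scalar (3D) or vector/time-series (4D) image on a :class:`GridSpec`.

    The first three axes of ``data`` must match ``grid.shape``; any fourth
    axis carries vector components or timepoints.
    """

    data: np.ndarray
    grid: GridSpec
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.affine is None:
            self.affine = self.grid.affine

    @property
    def is_mask(self) -> bool:
        vals = np.unique(self.data)
        return vals.size <= 2 and np.all(np.isin(vals, (0, 1)))

    def astype(self, dtype) -> "Volume":
        return Volume(self.data.astype(dtype), self.grid, self.affine)


def _grid_from_img(img: nib.Nifti1Image, midline_axis: int) -> GridSpec:
    zooms = img.header.get_zooms()[:3]
    return GridSpec(tuple(img.shape[:3]), tuple(float(z) for z in zooms), midline_axis)


def load_volume(
    path: str | Path,
    expected_grid: GridSpec | None = None,
    midline_axis: int = 0,
) -> Volume:
    """Load a NIfTI volume, optionally validating it against a template grid.

    Raises
    ------
    ValueError
        If the image grid does not match ``expected_grid`` (shape or voxel
        size), or the file is not a readable NIfTI.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
    grid = _grid_from_img(img, midline_axis)
    if expected_grid is not None:
        if grid.shape != expected_grid.shape:
            raise ValueError(
                f"grid mismatch for {path.name}: shape {grid.shape} != "
                f"expected {expected_grid.shape}"
            )
        if not np.allclose(grid.voxel_size, expected_grid.voxel_size, atol=1e-4):
            raise ValueError(
                f"grid mismatch for {path.name}: voxel size {grid.voxel_size} != "
                f"expected {expected_grid.voxel_size}"
            )
        grid = expected_grid
    data = np.asanyarray(img.dataobj)
    return Volume(data, grid, np.asarray(img.affine))


def save_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; masks should be uint8, maps float32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.grid.voxel_size + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))
    return path


def mirror_lr(volume: Volume) -> Volume:
    """Reflect a volume about the midline plane of its grid.

    On an axis of length ``N`` index ``i`` maps to ``N - 1 - i`` (pure flip,
    no interpolation): volumes are assumed template-aligned.  Applying the
    operation twice returns the input.
    """
    axis = volume.grid.midline_axis
    return Volume(np.flip(volume.data, axis=axis).copy(), volume.grid, volume.affine)


def spatial_correlation(map_a: Volume, map_b: Volume, mask: Volume) -> float:
    """Pearson spatial correlation between two maps over a voxel mask.

    Raises
    ------
    ValueError
        On grid mismatch, fewer than 3 in-mask voxels, or zero variance of
        either map within the mask (correlation undefined).
    """
    if map_a.grid != map_b.grid or map_a.grid != mask.grid:
        raise ValueError("maps and mask must share a grid")
    m = mask.data.astype(bool)
    if m.sum() < 3:
        raise ValueError("mask must contain at least 3 voxels")
    a = np.asarray(map_a.data, dtype=float)[m]
    b = np.asarray(map_b.data, dtype=float)[m]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("spatial correlation undefined: zero variance within mask")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def lesion_frequency_map(masks: Sequence[Volume]) -> Volume:
    """Per-voxel fraction of patients whose lesion covers that voxel."""
    if len(masks) == 0:
        raise ValueError("need at least one lesion mask")
    grid = masks[0].grid
    acc = np.zeros(grid.shape, dtype=float)
    for mk in masks:
        if mk.grid != grid:
            raise ValueError("all lesion masks must share a grid")
        acc += np.asarray(mk.data, dtype=float) > 0
    return Volume(acc / len(masks), grid)
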