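"""Shared template grid for voxel-wise lesion mapping.

All per-patient lesion masks and all output maps live on one common 3D
grid in a standard template space (MNI-like, RAS+ orientation: +x is the
patient's right, so negative world x is the left hemisphere). The grid is
defined once and every mask is validated against it — voxel-wise statistics
are only meaningful when every patient indexes the same anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TemplateGrid", "GridMismatchError", "make_grid"]

#: element-wise tolerance (mm) when comparing affines from file headers
AFFINE_TOL = 1e-3


class GridMismatchError(ValueError):
    """An image's geometry does not match the analysis grid."""


@dataclass(frozen=True)
class TemplateGrid:
    """Immutable 3D grid: shape, voxel-to-world affine and voxel volume.

    ``voxel_volume`` (mm^3) defaults to |det| of the affine's 3x3 linear
    part but may be overridden, e.g. when volumes should be reported with
    a calibration constant that differs from the nominal grid spacing.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)
    voxel_volume: float = 0.0

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        affine = affine.copy()
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if self.voxel_volume == 0.0:
            object.__setattr__(
                self, "voxel_volume", abs(float(np.linalg.det(affine[:3, :3])))
            )
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel edge lengths (mm) along each axis."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world coordinates (mm, RAS+)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_x(self) -> np.ndarray:
        """World x coordinate of every voxel, as a 3D array over the grid."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx)[:, 0].reshape(self.shape)

    def matches(self, shape, affine, tol: float = AFFINE_TOL) -> bool:
        return tuple(shape) == self.shape and np.allclose(
            np.asarray(affine, dtype=float), self.affine, atol=tol
        )

    def require_match(self, shape, affine, what: str = "image") -> None:
        if not self.matches(shape, affine):
            raise GridMismatchError(
                f"{what} geometry (shape={tuple(shape)}) does not match the "
                f"analysis grid (shape={self.shape})"
            )


def make_grid(
    shape,
    spacing,
    voxel_volume_override: float | None = None,
) -> TemplateGrid:
    """Build a centred RAS+ template grid.

    The affine is diagonal with the given spacings and translates the grid
    so its centre sits at the world origin; with an odd number of voxels
    along x the mid-sagittal plane is exactly at world x = 0.

    Parameters
    ----------
    shape : three positive ints
        Voxels per axis.
    spacing : three positive floats
        Voxel edge lengths in mm.
    voxel_volume_override : float, optional
        Use this single-voxel volume (mm^3) for all volume computations
        instead of the product of the spacings.
    """
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be 3 positive integers, got {shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive lengths, got {spacing}")
    if voxel_volume_override is not None and voxel_volume_override <= 0:
        raise ValueError("voxel_volume_override must be positive")

    affine = np.eye(4)
    for i in range(3):
        affine[i, i] = spacing[i]
        affine[i, 3] = -spacing[i] * (shape[i] - 1) / 2.0
    return TemplateGrid(
        shape=shape,
        affine=affine,
        voxel_volume=float(voxel_volume_override or 0.0),
    )
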