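"""Volume geometry: voxel grids, affines, tissue masks and stat maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeGrid", "StatMap", "default_grid"]


@dataclass
class VolumeGrid:
    """A 3-D voxel grid with an affine voxel->mm map and tissue masks.

    ``gray_mask`` marks gray matter; ``sensorimotor_mask`` marks sensorimotor
    cortex. The two may overlap; analyses that exclude sensorimotor voxels use
    ``gray AND NOT sensorimotor`` (:meth:`analysis_mask`).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    gray_mask: np.ndarray
    sensorimotor_mask: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        for name in ("gray_mask", "sensorimotor_mask"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.shape != self.shape:
                raise ValueError(f"{name} shape {m.shape} != grid shape {self.shape}")
            setattr(self, name, m)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length per axis in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def analysis_mask(self) -> np.ndarray:
        """Gray matter excluding sensorimotor cortex."""
        return self.gray_mask & ~self.sensorimotor_mask

    def voxel_coordinates_mm(self) -> np.ndarray:
        """World (mm) coordinates of every voxel center, shape (*grid, 3)."""
        idx = np.indices(self.shape).reshape(3, -1)
        homog = np.vstack([idx, np.ones(idx.shape[1])])
        mm = (self.affine @ homog)[:3].T
        return mm.reshape(self.shape + (3,))

    def same_geometry(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class StatMap:
    """Voxelwise scalar field (beta, t or p) on a :class:`VolumeGrid`."""

    values: np.ndarray
    grid: VolumeGrid
    kind: str = "beta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in ("beta", "t", "p"):
            raise ValueError(f"kind must be beta|t|p, got {self.kind!r}")

    def masked(self, mask: np.ndarray) -> np.ndarray:
        """Flat vector of values inside ``mask``."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape mismatch")
        return self.values[mask]


def default_grid(
    shape: tuple[int, int, int] = (10, 12, 10), voxel_mm: float = 4.0
) -> VolumeGrid:
    """Small MNI-like grid with an ellipsoidal gray mask.

    The affine centers the grid on the origin so mm coordinates span both
    hemispheres (x > 0 is right). The sensorimotor mask is a dorsal band —
    a coarse stand-in for pre/postcentral cortex.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0

    idx = np.indices(shape).astype(float)
    center = (np.array(shape) - 1) / 2.0
    semi = np.maximum(np.array(shape) / 2.0 - 0.5, 1.0)
    r2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    gray = r2 <= 1.0

    z = idx[2]
    sensorimotor = gray & (z >= shape[2] - 3) & (np.abs(idx[1] - center[1]) <= 2)
    return VolumeGrid(shape=shape, affine=affine, gray_mask=gray,
                      sensorimotor_mask=sensorimotor)
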