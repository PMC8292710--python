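"""Core volumetric containers shared by every stage.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``: axis 0 is cranio-caudal with index 0 at
  the superior end, axis 1 anterior-posterior, axis 2 left-right.
* ``spacing`` and ``origin`` are in millimetres, ordered like the axes.
* Physical coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing``.
* Displacement fields store millimetre vectors (component order ``z, y, x``)
  on the exhale grid and map exhale coordinates to inhale coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ImageGrid:
    """A 3D scalar volume (HU or Gy[RBE]) with physical geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ImageGrid | DisplacementField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "ImageGrid":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def voxel_coordinates(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape ``(3, nz, ny, nx)``."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"))

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert physical coordinates (3, ...) to fractional voxel indices."""
        pts = np.asarray(points, dtype=np.float64)
        spacing = np.asarray(self.spacing).reshape((3,) + (1,) * (pts.ndim - 1))
        origin = np.asarray(self.origin).reshape((3,) + (1,) * (pts.ndim - 1))
        return (pts - origin) / spacing

    def sample(
        self, points: np.ndarray, *, fill: float = -1000.0, order: int = 1
    ) -> np.ndarray:
        """Interpolate the volume at physical ``points`` of shape ``(3, ...)``.

        Trilinear by default; out-of-grid samples return ``fill``.
        """
        idx = self.physical_to_index(points)
        return ndimage.map_coordinates(
            self.data, idx, order=order, mode="constant", cval=fill
        )


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel exhale-to-inhale 3-vectors (mm) on the exhale grid."""

    vectors: np.ndarray  # (3, nz, ny, nx), component order (z, y, x)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    convention: str = "exhale_to_inhale"

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=np.float64)
        if vec.ndim != 4 or vec.shape[0] != 3:
            raise ValueError(f"expected vectors of shape (3, nz, ny, nx), got {vec.shape}")
        if not np.all(np.isfinite(vec)):
            raise ValueError("displacement field contains non-finite values")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def same_geometry(self, other: "ImageGrid | DisplacementField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def scaled(self, factor: float) -> "DisplacementField":
        return replace(self, vectors=self.vectors * float(factor))

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=0))

    def displaced_coordinates(self) -> np.ndarray:
        """``x + u(x)`` for every exhale voxel, shape ``(3, nz, ny, nx)``."""
        grid = ImageGrid(np.zeros(self.shape), self.spacing, self.origin)
        return grid.voxel_coordinates() + self.vectors

    def jacobian_determinant(self) -> np.ndarray:
        """``det(I + grad u)`` by central finite differences (mm-consistent)."""
        grad = np.empty((3, 3) + self.shape)
        for comp in range(3):
            for axis in range(3):
                grad[comp, axis] = np.gradient(
                    self.vectors[comp], self.spacing[axis], axis=axis
                )
        jac = grad + np.eye(3).reshape(3, 3, 1, 1, 1)
        jac = np.moveaxis(jac, (0, 1), (-2, -1))
        return np.linalg.det(jac)


def jacobian_from_gradient(grad_u: np.ndarray) -> np.ndarray:
    """Determinant of ``I + grad_u`` where ``grad_u`` has shape ``(3, 3, ...)``."""
    jac = grad_u + np.eye(3).reshape((3, 3) + (1,) * (grad_u.ndim - 2))
    jac = np.moveaxis(jac, (0, 1), (-2, -1))
    return np.linalg.det(jac)
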