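"""Core in-memory containers: images, label maps, deformation fields, affines.

Conventions used throughout the package:

* arrays are row-major 2-D, index ``(row, col)``, pixel-centered;
* the physical coordinate of index ``(r, c)`` is ``origin + (r, c) * spacing``
  in millimetres;
* deformation fields are *backward* maps sampled on the fixed grid with
  displacements in **pixels** of that grid: ``output(p) = moving(p + u(p))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ImageGrid",
    "LabelMap",
    "DeformationField",
    "AffineTransform",
    "MODALITIES",
]

MODALITIES = ("CT", "TEE", "CT_LIKE", "TEE_LIKE")


def _as_pair(v) -> Tuple[float, float]:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size == 1:
        a = np.array([a[0], a[0]])
    if a.size != 2:
        raise ValueError(f"expected a scalar or pair, got shape {a.shape}")
    return (float(a[0]), float(a[1]))


@dataclass
class ImageGrid:
    """A 2-D scalar image with physical spacing, origin and a modality tag."""

    pixels: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)
    origin: Tuple[float, float] = (0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"ImageGrid requires a 2-D array, got ndim={self.pixels.ndim}")
        self.spacing = _as_pair(self.spacing)
        self.origin = _as_pair(self.origin)
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageGrid pixels must be finite")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, modality: str | None = None) -> "ImageGrid":
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64),
                       modality=modality if modality is not None else self.modality)

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class LabelMap:
    """An integer segmentation map on the same grid model as :class:`ImageGrid`.

    Label 0 is background by convention.
    """

    labels: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("LabelMap requires integer labels")
            lab = np.round(lab).astype(np.int32)
        if lab.ndim != 2:
            raise ValueError(f"LabelMap requires a 2-D array, got ndim={lab.ndim}")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab.astype(np.int32)
        self.spacing = _as_pair(self.spacing)
        self.origin = _as_pair(self.origin)
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def label_values(self) -> np.ndarray:
        return np.unique(self.labels)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))


@dataclass
class DeformationField:
    """Dense backward-mapping displacement on a fixed grid.

    ``displacement`` has shape ``(H, W, 2)`` with channels ``(d_row, d_col)``
    in pixel units of the fixed grid.
    """

    displacement: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=np.float64)
        if d.ndim != 3 or d.shape[2] != 2:
            raise ValueError(f"displacement must have shape (H, W, 2), got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacement must be finite")
        self.displacement = d
        self.spacing = _as_pair(self.spacing)
        self.origin = _as_pair(self.origin)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.displacement.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.displacement ** 2, axis=2))

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    @classmethod
    def zero(cls, shape, spacing=(1.0, 1.0), origin=(0.0, 0.0)) -> "DeformationField":
        return cls(np.zeros((shape[0], shape[1], 2)), spacing, origin)


@dataclass
class AffineTransform:
    """A 2-D affine map acting on physical (mm) coordinates: x -> A x + t."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=np.float64).reshape(2, 2)
        self.translation = _as_pair(self.translation)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 2) array of physical coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + np.asarray(self.translation)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, tuple(-inv @ np.asarray(self.translation)))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_params(cls, tx: float, ty: float, rotation: float = 0.0,
                    scale_r: float = 1.0, scale_c: float = 1.0, shear: float = 0.0,
                    center=(0.0, 0.0)) -> "AffineTransform":
        """Build from translation (mm), rotation (radians), axis scales and shear,
        rotating/scaling about ``center`` (mm)."""
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        sc = np.array([[scale_r, 0.0], [0.0, scale_c]])
        sh = np.array([[1.0, shear], [0.0, 1.0]])
        lin = rot @ sc @ sh
        center = np.asarray(center, dtype=float)
        t = np.asarray([tx, ty]) + center - lin @ center
        return cls(lin, tuple(t))
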