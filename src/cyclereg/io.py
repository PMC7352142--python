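"""Image and deformation-field I/O plus preprocessing.

Supported formats are NIfTI-1 (``.nii``, ``.nii.gz``) and 8/16-bit grayscale
PNG.  PNG files carry no physical metadata and are assigned a spacing of
1.0 mm per pixel, so downstream distance metrics are then in pixel units.
Deformation fields serialize as 2-channel NIfTI with displacements in pixels
of the fixed grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from typing import List

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import DeformationField, ImageGrid, LabelMap

__all__ = [
    "PatchSet",
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "resample",
    "crop_or_pad",
    "normalize_intensity",
    "extract_patches",
]

_NIFTI_EXT = (".nii", ".nii.gz")


@dataclass
class PatchSet:
    """A bag of equally sized square patches drawn from one modality."""

    patches: List[ImageGrid] = dc_field(default_factory=list)
    modality: str = "CT"
    seed: int = 0

    def __len__(self) -> int:
        return len(self.patches)

    def as_array(self) -> np.ndarray:
        """Stack into an (N, H, W) array."""
        return np.stack([p.pixels for p in self.patches]) if self.patches else \
            np.zeros((0, 0, 0))


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _nifti_affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing[0]
    aff[1, 1] = spacing[1]
    aff[0, 3] = origin[0]
    aff[1, 3] = origin[1]
    return aff


def _grid_from_nifti(img: nib.Nifti1Image):
    aff = img.affine
    spacing = (float(abs(aff[0, 0])), float(abs(aff[1, 1])))
    origin = (float(aff[0, 3]), float(aff[1, 3]))
    return spacing, origin


def read_image(path: str):
    """Read a NIfTI or PNG file as an :class:`ImageGrid` or :class:`LabelMap`.

    Integer-typed NIfTI volumes load as :class:`LabelMap`; everything else,
    including PNG (rescaled so full-range 8-bit is [0, 1]), loads as
    :class:`ImageGrid`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2-D slice, got shape {data.shape}")
        spacing, origin = _grid_from_nifti(img)
        descrip = img.header["descrip"].item().decode("ascii", "ignore")
        modality = "CT"
        for m in ("TEE_LIKE", "CT_LIKE", "TEE", "CT"):
            if f"modality={m}" in descrip:
                modality = m
                break
        if np.issubdtype(data.dtype, np.integer) and "kind=label" in descrip:
            return LabelMap(data.astype(np.int32), spacing, origin)
        if np.issubdtype(data.dtype, np.integer) and "kind=image" not in descrip:
            return LabelMap(data.astype(np.int32), spacing, origin)
        return ImageGrid(data.astype(np.float64), spacing, origin, modality)
    # PNG path
    try:
        data = iio.imread(path)
    except Exception as e:  # pragma: no cover - imageio error text varies
        raise ValueError(f"{path}: unreadable image file ({e})") from e
    if data.ndim == 3:
        if data.shape[2] == 1:
            data = data[:, :, 0]
        else:
            raise ValueError(f"{path}: expected grayscale PNG, got shape {data.shape}")
    if data.dtype == np.uint8:
        scale = 255.0
    elif data.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"{path}: unsupported PNG dtype {data.dtype}")
    return ImageGrid(data.astype(np.float64) / scale, (1.0, 1.0), (0.0, 0.0), "CT")


def write_image(img, path: str) -> None:
    """Write an :class:`ImageGrid` or :class:`LabelMap` to NIfTI or PNG."""
    if _is_nifti(path):
        if isinstance(img, LabelMap):
            data, descrip = img.labels.astype(np.int32), "kind=label"
        else:
            data, descrip = img.pixels.astype(np.float64), f"kind=image modality={img.modality}"
        nii = nib.Nifti1Image(data, _nifti_affine(img.spacing, img.origin))
        nii.header["descrip"] = descrip.encode("ascii")
        nii.to_filename(path)
        return
    if isinstance(img, LabelMap):
        iio.imwrite(path, img.labels.astype(np.uint8))
    else:
        arr = np.clip(img.pixels, 0.0, 1.0)
        iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def write_field(field: DeformationField, path: str) -> None:
    """Serialize a deformation field as a 2-channel NIfTI (pixel units)."""
    if not _is_nifti(path):
        raise ValueError("deformation fields serialize as NIfTI only")
    nii = nib.Nifti1Image(field.displacement.astype(np.float64),
                          _nifti_affine(field.spacing, field.origin))
    nii.header["descrip"] = b"kind=field units=px"
    nii.to_filename(path)


def read_field(path: str) -> DeformationField:
    img = nib.load(path)
    data = np.squeeze(np.asanyarray(img.dataobj)).astype(np.float64)
    if data.ndim != 3 or data.shape[2] != 2:
        raise ValueError(f"{path}: expected an (H, W, 2) field, got shape {data.shape}")
    spacing, origin = _grid_from_nifti(img)
    return DeformationField(data, spacing, origin)


def resample(img, target_spacing, interp: str | None = None):
    """Resample to ``target_spacing`` (mm), preserving physical extent.

    Images default to anti-aliased linear interpolation, label maps to
    nearest-neighbour.  New size = round(old_size * old_spacing / target).
    """
    ts = np.asarray(target_spacing, dtype=float).reshape(-1)
    if ts.size == 1:
        ts = np.array([ts[0], ts[0]])
    if np.any(ts <= 0):
        raise ValueError(f"target spacing must be positive, got {tuple(ts)}")
    is_label = isinstance(img, LabelMap)
    if interp is None:
        interp = "nearest" if is_label else "linear"
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    data = img.labels.astype(np.float64) if is_label else img.pixels
    old_sp = np.asarray(img.spacing)
    old_shape = np.asarray(data.shape)
    new_shape = np.maximum(1, np.round(old_shape * old_sp / ts).astype(int))
    ratio = ts / old_sp  # >1 means downsampling
    src = data
    if interp == "linear":
        sigma = np.where(ratio > 1.0, ratio / 2.0, 0.0)
        if np.any(sigma > 0):
            src = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")
    rr, cc = np.meshgrid(np.arange(new_shape[0]), np.arange(new_shape[1]), indexing="ij")
    coords = np.stack([rr * ratio[0], cc * ratio[1]])
    order = 0 if interp == "nearest" else 1
    out = ndimage.map_coordinates(src, coords, order=order, mode="nearest")
    if is_label:
        return LabelMap(np.round(out).astype(np.int32), tuple(ts), img.origin)
    return ImageGrid(out, tuple(ts), img.origin, img.modality)


def crop_or_pad(img, size):
    """Center-crop or symmetrically zero-pad to ``size`` pixels.

    The origin is updated so retained pixels keep their physical coordinates.
    """
    size = np.asarray(size, dtype=int).reshape(-1)
    if size.size == 1:
        size = np.array([size[0], size[0]])
    if np.any(size < 1):
        raise ValueError("target size must be >= 1")
    is_label = isinstance(img, LabelMap)
    data = img.labels if is_label else img.pixels
    out = np.zeros(tuple(size), dtype=data.dtype)
    origin = np.asarray(img.origin, dtype=float)
    src_start, dst_start, length = [], [], []
    for ax in range(2):
        old, new = data.shape[ax], size[ax]
        if new <= old:
            s = (old - new) // 2
            src_start.append(s); dst_start.append(0); length.append(new)
            origin[ax] += s * img.spacing[ax]
        else:
            p = (new - old) // 2
            src_start.append(0); dst_start.append(p); length.append(old)
            origin[ax] -= p * img.spacing[ax]
    out[dst_start[0]:dst_start[0] + length[0], dst_start[1]:dst_start[1] + length[1]] = \
        data[src_start[0]:src_start[0] + length[0], src_start[1]:src_start[1] + length[1]]
    if is_label:
        return LabelMap(out, img.spacing, tuple(origin))
    return ImageGrid(out, img.spacing, tuple(origin), img.modality)


def normalize_intensity(img: ImageGrid, mode: str = "unit") -> ImageGrid:
    """Min-max normalize to [0, 1] (``unit``) or [-1, 1] (``symmetric``).

    A constant image maps to the mid-point of the target range (0.5 or 0.0)
    by convention rather than raising.
    """
    if mode not in ("unit", "symmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    if hi - lo < 1e-12:
        mid = 0.5 if mode == "unit" else 0.0
        return img.with_pixels(np.full_like(img.pixels, mid))
    unit = (img.pixels - lo) / (hi - lo)
    return img.with_pixels(unit if mode == "unit" else 2.0 * unit - 1.0)


def extract_patches(img: ImageGrid, size: int, n: int, seed: int) -> PatchSet:
    """Draw ``n`` square patches at uniformly random top-left corners."""
    H, W = img.shape
    if size > min(H, W):
        raise ValueError(f"patch size {size} exceeds image size {(H, W)}")
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n):
        r = int(rng.integers(0, H - size + 1))
        c = int(rng.integers(0, W - size + 1))
        sub = img.pixels[r:r + size, c:c + size]
        origin = (img.origin[0] + r * img.spacing[0], img.origin[1] + c * img.spacing[1])
        patches.append(ImageGrid(sub.copy(), img.spacing, origin, img.modality))
    return PatchSet(patches, img.modality, seed)
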