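"""Synthetic bimodal cardiac phantoms with ground-truth deformations.

Real paired CT/TEE data is scarce and private, so this module fabricates the
study conditions: one anatomy (elliptical chambers inside a myocardial ring)
rendered twice with disjoint appearance statistics —

* a CT-like render: piecewise-constant bright tissue classes, Gaussian blur
  and additive Gaussian noise;
* a TEE-like render: a fan-shaped field of view from the top transducer
  position, per-tissue echogenicity attenuated with depth, multiplicative
  Rayleigh speckle and log compression (the standard B-mode amplitude
  model) — zero outside the fan;

plus a smooth random diffeomorphic displacement between the two domains, so
registration error can be measured against a known truth.

Everything is a pure function of :class:`PhantomParams`, including its seed:
identical parameters give bit-identical cases.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import DeformationField, ImageGrid, LabelMap
from .registration import warp

__all__ = ["PhantomParams", "PhantomCase", "make_anatomy", "render_ct",
           "render_tee", "make_deformation", "make_paired_case"]

# per-label base intensities; chambers are contrast-bright in CT and
# anechoic (dark) in TEE, the myocardium is mid-gray in CT and echogenic
_CT_BASE = {0: 0.05, 1: 0.55}
_CT_CHAMBER = (0.85, 0.75, 0.90, 0.80)
_TEE_BASE = {0: 0.25, 1: 0.65}
_TEE_CHAMBER = (0.05, 0.08, 0.06, 0.07)
_LOG_GAIN = 30.0


@dataclass
class PhantomParams:
    """Parameters of one synthetic paired case.

    ``ct_noise_sigma`` is an intensity fraction, ``speckle_shape`` the
    Rayleigh scale (0 disables speckle), ``fan_angle`` the full aperture in
    degrees, ``attenuation_rate`` per millimetre, ``max_disp`` the peak
    displacement magnitude in pixels and ``field_smoothness`` the Gaussian
    sigma (pixels) of the random field.  The seed fully determines output.
    """

    image_size: int = 256
    n_chambers: int = 4
    ct_noise_sigma: float = 0.03
    ct_blur_sigma: float = 1.0
    speckle_shape: float = 1.0
    fan_angle: float = 75.0
    attenuation_rate: float = 0.008
    max_disp: float = 8.0
    field_smoothness: float = 16.0
    spacing: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (2 <= self.n_chambers <= 4):
            raise ValueError("n_chambers must be in 2..4")
        if not (0.0 < self.fan_angle <= 180.0):
            raise ValueError("fan_angle must lie in (0, 180]")
        if self.max_disp < 0:
            raise ValueError("max_disp must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class PhantomCase:
    """A paired pseudo-CT / pseudo-TEE case with ground truth.

    ``true_field`` is a backward map on the TEE (fixed) grid pointing into
    CT-domain coordinates; ``anatomy_tee`` is exactly ``anatomy_ct`` warped
    by it with nearest-neighbour interpolation.
    """

    anatomy_ct: LabelMap
    image_ct: ImageGrid
    true_field: DeformationField
    anatomy_tee: LabelMap
    image_tee: ImageGrid
    seed: int


def _rng(params: PhantomParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def _render_rng(params: PhantomParams, stream: int,
                anatomy: LabelMap) -> np.random.Generator:
    """Noise stream for a render, keyed on the anatomy content.

    Rendering the same anatomy twice gives bit-identical noise, but renders
    of *different* anatomies (e.g. the CT-domain and TEE-domain label maps
    of one case) get independent speckle/noise realizations — as in real
    acquisitions, where the noise pattern is not shared across modalities.
    """
    crc = zlib.crc32(anatomy.labels.tobytes()) & 0x7FFFFFFF
    return np.random.default_rng([params.seed, stream, crc])


def _ellipse_mask(shape, center, semi_axes, angle) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    x = ca * dr + sa * dc
    y = -sa * dr + ca * dc
    return (x / semi_axes[0]) ** 2 + (y / semi_axes[1]) ** 2 <= 1.0


def _try_anatomy(params: PhantomParams, rng: np.random.Generator) -> LabelMap | None:
    size = params.image_size
    shape = (size, size)
    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    heart_c = (size / 2 + jit(-0.03, 0.03) * size, size / 2 + jit(-0.03, 0.03) * size)
    a = 0.34 * size * jit(0.92, 1.08)
    b = 0.38 * size * jit(0.92, 1.08)
    heart_rot = jit(-0.3, 0.3)
    heart = _ellipse_mask(shape, heart_c, (a, b), heart_rot)

    labels = np.zeros(shape, dtype=np.int32)
    labels[heart] = 1  # myocardium; chambers carve into it
    n = params.n_chambers
    # chambers sit on an elliptical ring at half the heart axes
    base_angle = jit(0.0, 2 * np.pi)
    chamber_frac = {2: 0.30, 3: 0.26, 4: 0.22}[n]
    interior = ndimage.binary_erosion(heart, iterations=max(2, size // 64))
    chamber_masks = []
    for k in range(n):
        theta = base_angle + 2 * np.pi * k / n + jit(-0.1, 0.1)
        center = (heart_c[0] + 0.48 * a * np.cos(theta),
                  heart_c[1] + 0.48 * b * np.sin(theta))
        sa_ = chamber_frac * a * jit(0.85, 1.05)
        sb_ = chamber_frac * b * jit(0.85, 1.05)
        mask = _ellipse_mask(shape, center, (sa_, sb_), jit(-0.5, 0.5))
        chamber_masks.append(mask)

    floor = 0.01 * size * size
    for i, mask in enumerate(chamber_masks):
        if np.any(mask & ~interior):          # chamber must keep the ring closed
            return None
        for other in chamber_masks[:i]:
            if np.any(mask & other):          # chambers must stay disjoint
                return None
        labels[mask] = 2 + i
    for lab in range(1, n + 2):
        if np.count_nonzero(labels == lab) < floor:
            return None
    return LabelMap(labels, (params.spacing, params.spacing))


def make_anatomy(params: PhantomParams) -> LabelMap:
    """Build the label map: background 0, myocardial ring 1, chambers 2+.

    Retries with a perturbed seed (up to 10 attempts) when the random
    geometry degenerates — chambers overlapping, breaking the ring, or any
    structure falling below 1% of the pixels.
    """
    for attempt in range(10):
        rng = np.random.default_rng([params.seed, 0, attempt])
        anatomy = _try_anatomy(params, rng)
        if anatomy is not None:
            return anatomy
    raise RuntimeError("phantom geometry degenerate after 10 attempts; "
                       "loosen PhantomParams")


def _base_image(anatomy: LabelMap, table, chamber_table) -> np.ndarray:
    out = np.zeros(anatomy.shape, dtype=np.float64)
    for lab in anatomy.label_values():
        if lab in table:
            val = table[lab]
        else:
            val = chamber_table[(lab - 2) % len(chamber_table)]
        out[anatomy.labels == lab] = val
    return out


def render_ct(anatomy: LabelMap, params: PhantomParams) -> ImageGrid:
    """Render the CT appearance: per-label constants, blur, additive noise."""
    img = _base_image(anatomy, _CT_BASE, _CT_CHAMBER)
    if params.ct_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.ct_blur_sigma, mode="nearest")
    if params.ct_noise_sigma > 0:
        img = img + _render_rng(params, 1, anatomy).normal(
            0.0, params.ct_noise_sigma, img.shape)
    return ImageGrid(np.clip(img, 0.0, 1.0), anatomy.spacing, anatomy.origin, "CT")


def _fan_mask_and_depth(shape, fan_angle, spacing):
    H, W = shape
    vertex = (-2.0, (W - 1) / 2.0)
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    dr, dc = rr - vertex[0], cc - vertex[1]
    depth_px = np.sqrt(dr ** 2 + dc ** 2)
    angle = np.abs(np.arctan2(dc, dr))          # from the downward axis
    half = np.deg2rad(fan_angle / 2.0)
    mask = (angle <= half) & (depth_px <= 0.98 * H)
    return mask, depth_px * spacing


def render_tee(anatomy: LabelMap, params: PhantomParams) -> ImageGrid:
    """Render the B-mode TEE appearance inside a fan-shaped field of view.

    Inside the fan the signal is per-label echogenicity, attenuated as
    exp(-attenuation_rate * depth_mm), multiplied by unit-mean Rayleigh
    speckle, log-compressed and min-max rescaled over the fan; pixels
    outside the fan are exactly zero.
    """
    base = _base_image(anatomy, _TEE_BASE, _TEE_CHAMBER)
    mask, depth_mm = _fan_mask_and_depth(anatomy.shape, params.fan_angle,
                                         params.spacing)
    sig = base * np.exp(-params.attenuation_rate * depth_mm)
    if params.speckle_shape > 0:
        speckle = _render_rng(params, 2, anatomy).rayleigh(
            params.speckle_shape, anatomy.shape)
        speckle /= params.speckle_shape * np.sqrt(np.pi / 2.0)  # unit mean
        sig = sig * speckle
    sig = np.log1p(_LOG_GAIN * sig) / np.log1p(_LOG_GAIN)
    inside = sig[mask]
    lo, hi = float(inside.min()), float(inside.max())
    out = np.zeros_like(sig)
    if hi - lo > 1e-12:
        out[mask] = (sig[mask] - lo) / (hi - lo)
    return ImageGrid(out, anatomy.spacing, anatomy.origin, "TEE")


def make_deformation(params: PhantomParams) -> DeformationField:
    """Smooth random backward displacement with max magnitude ``max_disp``.

    Each channel is Gaussian-smoothed white noise (sigma
    ``field_smoothness``), rescaled so the peak per-pixel magnitude equals
    ``max_disp`` exactly.  The finite-difference Jacobian determinant of the
    map p + u(p) must stay positive at every pixel; otherwise ``max_disp``
    is halved (up to 5 times) before giving up.
    """
    size = params.image_size
    sp = (params.spacing, params.spacing)
    if params.max_disp == 0:
        return DeformationField.zero((size, size), sp)
    rng = _rng(params, 3)
    noise = rng.normal(0.0, 1.0, (size, size, 2))
    u = np.stack([ndimage.gaussian_filter(noise[:, :, i], params.field_smoothness,
                                          mode="nearest") for i in range(2)],
                 axis=-1)
    mag = np.sqrt((u ** 2).sum(axis=-1)).max()
    if mag < 1e-12:
        return DeformationField.zero((size, size), sp)
    u *= 0.5 * params.max_disp / mag
    # a global offset (different probe/scanner geometry) on top of the local
    # deformation, so every structure is genuinely displaced
    theta = rng.uniform(0.0, 2 * np.pi)
    u += 0.5 * params.max_disp * np.array([np.cos(theta), np.sin(theta)])
    u *= params.max_disp / np.sqrt((u ** 2).sum(axis=-1)).max()
    target = params.max_disp
    for _ in range(6):
        dr0, dc0 = np.gradient(u[:, :, 0])
        dr1, dc1 = np.gradient(u[:, :, 1])
        jac = (1.0 + dr0) * (1.0 + dc1) - dc0 * dr1
        if jac.min() > 0:
            return DeformationField(u, sp)
        target /= 2.0
        u = u * (target / np.sqrt((u ** 2).sum(axis=-1)).max())
    raise RuntimeError("could not produce a locally invertible field; "
                       "increase field_smoothness or reduce max_disp")


def make_paired_case(params: PhantomParams) -> PhantomCase:
    """Assemble the full paired case with ground truth.

    The TEE anatomy is the CT anatomy warped by the true field (nearest
    neighbour), and the TEE image is rendered from that warped anatomy, so
    the ground-truth correspondence between the two domains is exact.
    """
    anatomy_ct = make_anatomy(params)
    image_ct = render_ct(anatomy_ct, params)
    true_field = make_deformation(params)
    anatomy_tee = warp(anatomy_ct, true_field, "nearest")
    image_tee = render_tee(anatomy_tee, params)
    return PhantomCase(anatomy_ct, image_ct, true_field, anatomy_tee,
                       image_tee, params.seed)
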