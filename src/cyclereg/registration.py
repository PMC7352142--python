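"""Grid (affine) and nongrid (Demons, Powell-FFD) registration and warping.

All registrations minimize a similarity cost (lower is better).  Deformable
outputs are dense backward-mapping :class:`~cyclereg.grids.DeformationField`
objects on the fixed grid; out-of-domain samples use edge-value extension,
which avoids ringing at the hard zeros of the ultrasound fan mask.

The affine stage plays the role of a FLIRT-style grid registration: Powell's
derivative-free method over translation, rotation, anisotropic scale and
shear, coarse-to-fine over an image pyramid.  The two nongrid methods are
the classic Thirion Demons iteration with Gaussian field regularization and
a cubic B-spline free-form deformation whose control displacements are
optimized by Powell's method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .grids import AffineTransform, DeformationField, ImageGrid, LabelMap

__all__ = [
    "RegistrationConfig",
    "similarity",
    "warp",
    "average_fields",
    "field_from_affine",
    "compose_affine_field",
    "affine_register",
    "demons_register",
    "ffd_register",
]


@dataclass
class RegistrationConfig:
    """Tunable parameters for all three registration stages.

    ``metric`` applies to the affine and FFD objective; Demons is driven by
    intensity differences (SSD-like) by construction and uses the metric only
    for its acceptance trace.  ``image_smooth_sigma`` is a Gaussian prefilter
    (pixels) applied to both images before Demons, which stabilises the
    update on speckled ultrasound-like inputs.
    """

    metric: str = "NCC"
    demons_sigma: float = 2.0
    demons_iterations: int = 100
    demons_step_cap: float = 2.0
    pyramid_levels: int = 3
    powell_xtol: float = 1e-3
    powell_ftol: float = 1e-6
    powell_maxfev: int = 600
    ffd_grid_spacing: float = 32.0
    image_smooth_sigma: float = 1.0

    def __post_init__(self):
        if self.metric not in ("SSD", "NCC", "MI"):
            raise ValueError(f"unknown metric {self.metric!r}")
        for name in ("demons_sigma", "demons_iterations", "demons_step_cap",
                     "pyramid_levels", "powell_xtol", "powell_ftol",
                     "ffd_grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------

def similarity(fixed: ImageGrid, moving: ImageGrid, metric: str = "SSD") -> float:
    """Similarity cost between two images on the same grid; lower is better.

    SSD: mean squared difference.  NCC: negative normalized cross-correlation.
    MI: negative mutual information from a 32-bin joint histogram.
    """
    f = fixed.pixels if isinstance(fixed, ImageGrid) else np.asarray(fixed, float)
    m = moving.pixels if isinstance(moving, ImageGrid) else np.asarray(moving, float)
    if f.shape != m.shape:
        raise ValueError(f"shape mismatch {f.shape} vs {m.shape}")
    if metric == "SSD":
        return float(np.mean((f - m) ** 2))
    if metric == "NCC":
        fz = f - f.mean()
        mz = m - m.mean()
        denom = np.sqrt((fz ** 2).sum() * (mz ** 2).sum())
        if denom < 1e-12:
            return 0.0
        return float(-(fz * mz).sum() / denom)
    if metric == "MI":
        hist, _, _ = np.histogram2d(f.ravel(), m.ravel(), bins=32)
        pxy = hist / hist.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nz = pxy > 0
        mi = np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz]))
        return float(-mi)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# warping and field algebra
# ---------------------------------------------------------------------------

def _sample(data: np.ndarray, coords_r: np.ndarray, coords_c: np.ndarray,
            order: int) -> np.ndarray:
    return ndimage.map_coordinates(data, [coords_r, coords_c], order=order,
                                   mode="nearest")


def warp(img, field: DeformationField, interp: str | None = None):
    """Backward-warp an image or label map by a deformation field.

    ``output(p) = moving(p + u(p))`` with edge-value extension; label maps
    use nearest-neighbour interpolation.
    """
    is_label = isinstance(img, LabelMap)
    grid_ok = (img.shape == field.shape
               and np.allclose(img.spacing, field.spacing))
    if not grid_ok:
        raise ValueError(f"field grid {field.shape} does not match image grid {img.shape}")
    if interp is None:
        interp = "nearest" if is_label else "linear"
    order = 0 if interp == "nearest" else 1
    H, W = img.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    u = field.displacement
    data = img.labels.astype(np.float64) if is_label else img.pixels
    out = _sample(data, rr + u[:, :, 0], cc + u[:, :, 1], order)
    if is_label:
        return LabelMap(np.round(out).astype(np.int32), img.spacing, img.origin)
    return img.with_pixels(out)


def average_fields(f1: DeformationField, f2: DeformationField) -> DeformationField:
    """Componentwise arithmetic mean of two fields on the same fixed grid."""
    if not f1.same_grid(f2):
        raise ValueError("fields are on different grids; resample first")
    return DeformationField(0.5 * (f1.displacement + f2.displacement),
                            f1.spacing, f1.origin)


def _affine_pixel_map(a: AffineTransform, spacing, origin, shape):
    """Return pixel-index coordinates alpha(p) of the affine applied at every
    fixed-grid pixel center (physical-space action, same grid for both)."""
    H, W = shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    sp = np.asarray(spacing)
    org = np.asarray(origin)
    phys = np.stack([rr * sp[0] + org[0], cc * sp[1] + org[1]], axis=-1)
    mapped = a.apply(phys)
    return (mapped[:, :, 0] - org[0]) / sp[0], (mapped[:, :, 1] - org[1]) / sp[1]


def field_from_affine(a: AffineTransform, like) -> DeformationField:
    """Dense backward field equivalent to the affine on the grid of ``like``."""
    ar, ac = _affine_pixel_map(a, like.spacing, like.origin, like.shape)
    H, W = like.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    disp = np.stack([ar - rr, ac - cc], axis=-1)
    return DeformationField(disp, like.spacing, like.origin)


def compose_affine_field(a: AffineTransform, f: DeformationField) -> DeformationField:
    """Single backward field equivalent to applying the affine, then ``f``.

    ``warp(img, composed) == warp(warp(img, field_of_a), f)``:
    ``composed(p) = alpha(p + u(p)) - p`` where alpha is the affine in pixel
    coordinates.
    """
    H, W = f.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    u = f.displacement
    pr, pc = rr + u[:, :, 0], cc + u[:, :, 1]
    sp = np.asarray(f.spacing)
    org = np.asarray(f.origin)
    phys = np.stack([pr * sp[0] + org[0], pc * sp[1] + org[1]], axis=-1)
    mapped = a.apply(phys)
    mr = (mapped[:, :, 0] - org[0]) / sp[0]
    mc = (mapped[:, :, 1] - org[1]) / sp[1]
    return DeformationField(np.stack([mr - rr, mc - cc], axis=-1), f.spacing, f.origin)


# ---------------------------------------------------------------------------
# affine (grid) registration
# ---------------------------------------------------------------------------

def _downsample(img: ImageGrid, factor: int) -> ImageGrid:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img.pixels, sigma=factor / 2.0, mode="nearest")
    sub = sm[::factor, ::factor]
    return ImageGrid(sub, (img.spacing[0] * factor, img.spacing[1] * factor),
                     img.origin, img.modality)


def _warp_affine(fixed_like: ImageGrid, moving: ImageGrid, a: AffineTransform) -> np.ndarray:
    ar, ac = _affine_pixel_map(a, fixed_like.spacing, fixed_like.origin,
                               fixed_like.shape)
    # map physical coordinates into the moving image's own grid
    sp_m = np.asarray(moving.spacing)
    org_m = np.asarray(moving.origin)
    sp_f = np.asarray(fixed_like.spacing)
    org_f = np.asarray(fixed_like.origin)
    pr = (ar * sp_f[0] + org_f[0] - org_m[0]) / sp_m[0]
    pc = (ac * sp_f[1] + org_f[1] - org_m[1]) / sp_m[1]
    return _sample(moving.pixels, pr, pc, order=1)


def _params_to_affine(p: np.ndarray, center) -> AffineTransform:
    tx, ty, rot, lsr, lsc, shear = p
    return AffineTransform.from_params(tx, ty, rot, float(np.exp(lsr)),
                                       float(np.exp(lsc)), shear, center)


def affine_register(fixed: ImageGrid, moving: ImageGrid,
                    config: RegistrationConfig | None = None) -> AffineTransform:
    """FLIRT-style grid registration by Powell's method, coarse-to-fine.

    Optimizes translation (mm), rotation, two log-scales and shear about the
    fixed image's physical center.  The returned transform carries a
    ``converged`` attribute; on hitting the evaluation budget the best-so-far
    transform is returned with ``converged = False`` and a warning.
    """
    config = config or RegistrationConfig()
    center = (np.asarray(fixed.origin)
              + (np.asarray(fixed.shape) - 1) / 2.0 * np.asarray(fixed.spacing))
    p = np.zeros(6)
    scales = np.array([max(fixed.spacing), max(fixed.spacing), 0.02, 0.02, 0.02, 0.02])
    converged = True
    levels = list(range(config.pyramid_levels - 1, -1, -1))
    for lvl in levels:
        factor = 2 ** lvl
        if min(fixed.shape) // factor < 16:
            continue
        f_lvl = _downsample(fixed, factor)
        m_lvl = _downsample(moving, factor)

        def cost(q):
            a = _params_to_affine(q, center)
            warped = _warp_affine(f_lvl, m_lvl, a)
            return similarity(f_lvl.pixels, warped, config.metric)

        res = optimize.minimize(
            cost, p, method="Powell",
            options={"xtol": config.powell_xtol, "ftol": config.powell_ftol,
                     "maxfev": config.powell_maxfev,
                     "direc": np.diag(scales)})
        p = res.x
        if not res.success and "maximum" in (res.message or "").lower():
            converged = False
    if not converged:
        warnings.warn("affine_register hit its evaluation budget; "
                      "returning best transform found", RuntimeWarning)
    out = _params_to_affine(p, center)
    out.converged = converged
    return out


# ---------------------------------------------------------------------------
# Demons (nongrid) registration
# ---------------------------------------------------------------------------

def _demons_level(f: np.ndarray, m: np.ndarray, u: np.ndarray,
                  config: RegistrationConfig):
    """Run Demons iterations at one pyramid level; returns (best_u, trace)."""
    H, W = f.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    gr, gc = np.gradient(f)
    g2 = gr ** 2 + gc ** 2
    best_u = u.copy()
    warped = _sample(m, rr + u[:, :, 0], cc + u[:, :, 1], order=1)
    best_score = float(np.mean((f - warped) ** 2))
    trace = [best_score]
    bad_streak = 0
    for _ in range(config.demons_iterations):
        diff = f - warped
        denom = g2 + diff ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            step_r = np.where(denom > 1e-9, diff * gr / denom, 0.0)
            step_c = np.where(denom > 1e-9, diff * gc / denom, 0.0)
        mag = np.sqrt(step_r ** 2 + step_c ** 2)
        cap = np.where(mag > config.demons_step_cap,
                       config.demons_step_cap / np.maximum(mag, 1e-12), 1.0)
        u = u + np.stack([step_r * cap, step_c * cap], axis=-1)
        u[:, :, 0] = ndimage.gaussian_filter(u[:, :, 0], config.demons_sigma,
                                             mode="nearest")
        u[:, :, 1] = ndimage.gaussian_filter(u[:, :, 1], config.demons_sigma,
                                             mode="nearest")
        warped = _sample(m, rr + u[:, :, 0], cc + u[:, :, 1], order=1)
        score = float(np.mean((f - warped) ** 2))
        if score < best_score:
            best_score = score
            best_u = u.copy()
            bad_streak = 0
        else:
            bad_streak += 1
            if bad_streak >= 10:
                break
        trace.append(best_score)
    return best_u, trace


def demons_register(fixed: ImageGrid, moving: ImageGrid,
                    config: RegistrationConfig | None = None,
                    init: DeformationField | None = None) -> DeformationField:
    """Thirion Demons deformable registration with Gaussian regularization.

    The displacement update at each pixel is the intensity-difference-driven
    step ``(f - m∘u)·∇f / (‖∇f‖² + (f - m∘u)²)``, capped at
    ``demons_step_cap`` pixels, with the field smoothed by a Gaussian of
    ``demons_sigma`` after every iteration; runs coarse-to-fine over
    ``pyramid_levels``.  Iterations that fail to improve the mean-squared
    difference ten times in a row trigger an early stop, and the best field
    seen is returned (never worse than the initialization).
    """
    config = config or RegistrationConfig()
    if fixed.shape != moving.shape:
        raise ValueError("demons_register requires images on the same grid")
    fp = fixed.pixels
    mp = moving.pixels
    if config.image_smooth_sigma > 0:
        fp = ndimage.gaussian_filter(fp, config.image_smooth_sigma, mode="nearest")
        mp = ndimage.gaussian_filter(mp, config.image_smooth_sigma, mode="nearest")
    levels = [2 ** k for k in range(config.pyramid_levels - 1, -1, -1)]
    u = None
    for factor in levels:
        if min(fixed.shape) // factor < 16:
            continue
        f_lvl = ndimage.gaussian_filter(fp, factor / 2.0, mode="nearest")[::factor, ::factor] \
            if factor > 1 else fp
        m_lvl = ndimage.gaussian_filter(mp, factor / 2.0, mode="nearest")[::factor, ::factor] \
            if factor > 1 else mp
        if u is None:
            if init is not None:
                u = init.displacement[::factor, ::factor] / factor
            else:
                u = np.zeros(f_lvl.shape + (2,))
        else:
            zoom = (f_lvl.shape[0] / u.shape[0], f_lvl.shape[1] / u.shape[1])
            u = np.stack([ndimage.zoom(u[:, :, i], zoom, order=1, mode="nearest")
                          for i in range(2)], axis=-1) * zoom[0]
        u, _ = _demons_level(f_lvl, m_lvl, u, config)
    if u is None:  # image too small for any level
        u = np.zeros(fixed.shape + (2,))
    if u.shape[:2] != fixed.shape:
        zoom = (fixed.shape[0] / u.shape[0], fixed.shape[1] / u.shape[1])
        u = np.stack([ndimage.zoom(u[:, :, i], zoom, order=1, mode="nearest")
                      for i in range(2)], axis=-1) * zoom[0]
    # acceptance guarantee on the *input* images: never return a field worse
    # than the initialization (zero field if none was given)
    base = init.displacement if init is not None else np.zeros_like(u)
    out = DeformationField(u, fixed.spacing, fixed.origin)
    base_fld = DeformationField(base, fixed.spacing, fixed.origin)
    if (similarity(fixed.pixels, warp(moving, base_fld).pixels, "SSD")
            < similarity(fixed.pixels, warp(moving, out).pixels, "SSD")):
        return base_fld
    return out


# ---------------------------------------------------------------------------
# Powell-optimized B-spline FFD (nongrid) registration
# ---------------------------------------------------------------------------

def _ffd_dense(coeffs: np.ndarray, shape, grid_spacing: float) -> np.ndarray:
    """Evaluate the cubic B-spline series with control coefficients ``coeffs``
    (n_r, n_c, 2) on a dense pixel grid; control point (i, j) sits at pixel
    ((i - 1)·δ, (j - 1)·δ)."""
    H, W = shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    pr = rr / grid_spacing + 1.0
    pc = cc / grid_spacing + 1.0
    out = np.empty((H, W, 2))
    for i in range(2):
        out[:, :, i] = ndimage.map_coordinates(coeffs[:, :, i], [pr, pc],
                                               order=3, prefilter=False,
                                               mode="nearest")
    return out


def ffd_register(fixed: ImageGrid, moving: ImageGrid,
                 config: RegistrationConfig | None = None) -> DeformationField:
    """Free-form deformation on a cubic B-spline lattice, fit by Powell.

    Control-point displacements (pixels) are the optimization variables; the
    dense field is the direct B-spline series of the fitted coefficients, so
    the output is C²-smooth by construction.
    """
    config = config or RegistrationConfig()
    if fixed.shape != moving.shape:
        raise ValueError("ffd_register requires images on the same grid")
    H, W = fixed.shape
    delta = config.ffd_grid_spacing
    n_r = int(np.ceil((H - 1) / delta)) + 3
    n_c = int(np.ceil((W - 1) / delta)) + 3
    shape_c = (n_r, n_c, 2)

    def cost(flat):
        coeffs = flat.reshape(shape_c)
        u = _ffd_dense(coeffs, (H, W), delta)
        fld = DeformationField(u, fixed.spacing, fixed.origin)
        return similarity(fixed.pixels, warp(moving, fld).pixels, config.metric)

    x0 = np.zeros(np.prod(shape_c))
    res = optimize.minimize(
        cost, x0, method="Powell",
        options={"xtol": config.powell_xtol, "ftol": config.powell_ftol,
                 "maxfev": config.powell_maxfev * x0.size // 6})
    if not res.success and "maximum" in (res.message or "").lower():
        warnings.warn("ffd_register hit its evaluation budget; "
                      "returning best lattice found", RuntimeWarning)
    u = _ffd_dense(res.x.reshape(shape_c), (H, W), delta)
    return DeformationField(u, fixed.spacing, fixed.origin)
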