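"""Subset-based digital image correlation (DIC / PIV).

Each node of a regular grid carries a square subset of the first image that
is located in the second image by normalized cross-correlation, with
three-point Gaussian subpixel refinement of the correlation peak in each
axis. Consecutive phase-contrast frames give cell velocities (default
48 px subsets at 12 px spacing); particle images against the traction-free
reference give substrate displacements (default 32 px subsets at 8 px
spacing), both at 10-minute frame intervals.

An optional second warp-and-recorrelate pass resamples the deformed image
with the current displacement estimate and correlates again, accumulating
the increment; the default is a single pass.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .fields import GriddedVectorField

__all__ = ["correlate_pair", "correlate_stack", "fill_missing",
           "DEFAULT_CELL_PARAMS", "DEFAULT_PARTICLE_PARAMS"]

DEFAULT_CELL_PARAMS = dict(subset_size=48, spacing=12)
DEFAULT_PARTICLE_PARAMS = dict(subset_size=32, spacing=8)


def _subpixel_1d(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian peak interpolation along one axis.

    Falls back to a parabolic fit when any sample is non-positive (the
    Gaussian fit needs logarithms)."""
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm - 2.0 * l0 + lp
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -1.0, 1.0))
    denom = cm - 2.0 * c0 + cp
    if denom < 0:
        return float(np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0))
    return 0.0


def _correlate_nodes(image_a: np.ndarray, image_b: np.ndarray,
                     xs: np.ndarray, ys: np.ndarray, half: int,
                     search: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer+subpixel displacement (px) and peak NCC per node."""
    du = np.full((ys.size, xs.size), np.nan)
    dv = np.full((ys.size, xs.size), np.nan)
    q = np.full((ys.size, xs.size), np.nan)
    # subsets with negligible contrast relative to the image cannot be
    # matched (the normalized correlation divides by their variance)
    min_std = 1e-8 * (image_a.std() + image_b.std())
    for i, yc in enumerate(ys):
        for j, xc in enumerate(xs):
            tpl = image_a[yc - half:yc + half, xc - half:xc + half]
            if tpl.std() <= min_std:
                continue
            win = image_b[yc - half - search:yc + half + search,
                          xc - half - search:xc + half + search]
            if win.std() <= min_std:
                continue
            corr = match_template(win, tpl)
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            peak = corr[py, px]
            if not np.isfinite(peak) or abs(peak) > 1.0 + 1e-6:
                continue
            peak = float(np.clip(peak, -1.0, 1.0))
            sx = sy = 0.0
            # a perfect correlation peak means exact integer alignment; the
            # three-point fit would otherwise be nudged by the (asymmetric)
            # side lobes of the speckle autocorrelation
            if peak < 1.0 - 1e-9:
                if 0 < px < corr.shape[1] - 1:
                    sx = _subpixel_1d(corr[py, px - 1], peak, corr[py, px + 1])
                if 0 < py < corr.shape[0] - 1:
                    sy = _subpixel_1d(corr[py - 1, px], peak, corr[py + 1, px])
            du[i, j] = px - search + sx
            dv[i, j] = py - search + sy
            q[i, j] = peak
    return du, dv, q


def fill_missing(arr: np.ndarray) -> np.ndarray:
    """Inpaint NaN nodes by iterated local (3x3) neighbour means."""
    out = arr.copy()
    missing = np.isnan(out)
    if missing.all():
        raise ValueError("cannot inpaint a field with no valid nodes")
    kernel = np.ones((3, 3))
    while missing.any():
        filled = np.where(missing, 0.0, out)
        weight = (~missing).astype(float)
        num = ndimage.convolve(filled, kernel, mode="constant")
        den = ndimage.convolve(weight, kernel, mode="constant")
        upd = missing & (den > 0)
        out[upd] = num[upd] / den[upd]
        missing[upd] = False
    return out


def _warp(image: np.ndarray, du_px: np.ndarray, dv_px: np.ndarray,
          xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Resample ``image`` backward by a nodal displacement field (px)."""
    ny, nx = image.shape
    Yi, Xi = np.mgrid[0:ny, 0:nx]
    # extend the nodal field over the full frame (nearest at the borders)
    from scipy.interpolate import RegularGridInterpolator
    kw = dict(bounds_error=False, fill_value=None, method="linear")
    fu = RegularGridInterpolator((ys, xs), du_px, **kw)
    fv = RegularGridInterpolator((ys, xs), dv_px, **kw)
    pts = np.column_stack([np.clip(Yi.ravel(), ys[0], ys[-1]),
                           np.clip(Xi.ravel(), xs[0], xs[-1])])
    U = fu(pts).reshape(ny, nx)
    V = fv(pts).reshape(ny, nx)
    coords = np.array([Yi + V, Xi + U])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def correlate_pair(image_a: np.ndarray, image_b: np.ndarray,
                   subset_size: int = 32, spacing: int = 8,
                   pixel_size: float = 1.0,
                   search_range: Optional[int] = None,
                   quality_threshold: float = 0.5,
                   n_passes: int = 1,
                   inpaint: bool = True) -> GriddedVectorField:
    """Displacement field (µm) mapping ``image_a`` onto ``image_b``.

    A pattern translated by +d between the two images yields +d. Nodes whose
    correlation peak falls below ``quality_threshold`` are flagged missing
    (NaN in ``quality``) and, when ``inpaint`` is set, filled by local
    neighbour means so downstream Fourier operators receive complete fields.
    """
    image_a = np.asarray(image_a, dtype=float)
    image_b = np.asarray(image_b, dtype=float)
    if image_a.shape != image_b.shape:
        raise ValueError("images must have the same shape")
    if subset_size < 16:
        raise ValueError("subset_size must be >= 16 px")
    if spacing > subset_size:
        raise ValueError("spacing must not exceed subset_size")
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    half = subset_size // 2
    search = search_range if search_range is not None else subset_size // 2
    ny, nx = image_a.shape
    margin = half + search
    if 2 * margin >= min(ny, nx):
        raise ValueError("subset plus search range is larger than the image")
    xs = np.arange(margin, nx - margin + 1, spacing)
    ys = np.arange(margin, ny - margin + 1, spacing)

    du, dv, q = _correlate_nodes(image_a, image_b, xs, ys, half, search)
    low = ~(q >= quality_threshold)      # NaN quality counts as low
    du[low] = np.nan
    dv[low] = np.nan
    if inpaint and np.isnan(du).any():
        du = fill_missing(du)
        dv = fill_missing(dv)

    for _ in range(n_passes - 1):
        # warp-and-recorrelate refinement: the predictor is smoothed (3x3
        # node box) before warping so that per-node estimator noise is not
        # re-imprinted as intra-subset distortion; the increment measured on
        # the warped image then sees nearly rigid subsets, which removes the
        # shear-induced error of the translation-only first pass
        du_s = ndimage.uniform_filter(du, size=3, mode="nearest")
        dv_s = ndimage.uniform_filter(dv, size=3, mode="nearest")
        warped = _warp(image_b, du_s, dv_s, xs, ys)
        ddu, ddv, q2 = _correlate_nodes(image_a, warped, xs, ys, half,
                                        max(4, search // 4))
        good = q2 >= quality_threshold
        du = du_s + np.where(good & np.isfinite(ddu), ddu, 0.0)
        dv = dv_s + np.where(good & np.isfinite(ddv), ddv, 0.0)
        q = np.where(np.isfinite(q2), np.maximum(q, q2), q)

    qual = q.copy()
    qual[low] = np.nan
    return GriddedVectorField(xs * pixel_size, ys * pixel_size,
                              du * pixel_size, dv * pixel_size,
                              units="um", quality=qual,
                              meta=dict(subset_size=subset_size,
                                        spacing=spacing,
                                        pixel_size=pixel_size,
                                        search_range=search,
                                        quality_threshold=quality_threshold,
                                        n_passes=n_passes))


def correlate_stack(stack: Sequence[np.ndarray],
                    reference_mode: str = "consecutive",
                    subset_size: int = 32, spacing: int = 8,
                    pixel_size: float = 1.0, dt: float = 10.0,
                    reference: Optional[np.ndarray] = None,
                    **kwargs) -> list[GriddedVectorField]:
    """Correlate a time-lapse stack.

    ``reference_mode="consecutive"`` correlates frame t with frame t+1 and
    divides by ``dt`` (minutes), yielding one velocity field (µm/min) per
    frame pair. ``reference_mode="fixed"`` correlates every frame against a
    fixed undeformed reference (default frame 0), yielding one displacement
    field (µm) per frame.
    """
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 2 and reference_mode == "consecutive":
        raise ValueError("need at least 2 frames for consecutive correlation")
    if reference_mode not in ("consecutive", "fixed"):
        raise ValueError("reference_mode must be 'consecutive' or 'fixed'")
    if not frames:
        raise ValueError("empty stack")

    fields = []
    if reference_mode == "consecutive":
        if dt <= 0:
            raise ValueError("dt must be positive")
        for t in range(len(frames) - 1):
            f = correlate_pair(frames[t], frames[t + 1],
                               subset_size=subset_size, spacing=spacing,
                               pixel_size=pixel_size, **kwargs)
            f = GriddedVectorField(f.x, f.y, f.u / dt, f.v / dt,
                                   units="um/min", quality=f.quality,
                                   time_index=t, meta=f.meta)
            fields.append(f)
    else:
        ref = frames[0] if reference is None else np.asarray(reference, float)
        for t, frame in enumerate(frames):
            f = correlate_pair(ref, frame, subset_size=subset_size,
                               spacing=spacing, pixel_size=pixel_size,
                               **kwargs)
            f.time_index = t
            fields.append(f)
    return fields
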