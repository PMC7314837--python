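"""Fourier-transform traction microscopy on an elastic half-space.

The substrate is treated as a linear elastic half-space (Boussinesq). In
Fourier space the surface displacement u(k) due to a tangential surface
traction T(k) is u = G(k)·T with the symmetric 2x2 kernel

    G(k) = 2(1+ν)/(E k³) · [[(1-ν)k² + ν ky²,  -ν kx ky],
                            [-ν kx ky,          (1-ν)k² + ν kx²]]

whose determinant is positive for every nonzero mode and all ν in [0, 0.5],
so the mode-by-mode inversion is well defined up to and including the
incompressible limit ν = 0.5. The zero mode (rigid translation / net force)
carries no information and is set to zero in both directions.

Forward and inverse use the same transform conventions, so with λ = 0 they
are exact mutual inverses on the grid. Optional zero-padding and a cosine
taper window suppress periodic wrap-around for fields that are not
compactly supported inside the frame; both default to off (island tractions
vanish well inside the frame) and are recorded in the field metadata.
"""
from __future__ import annotations

import numpy as np

from .domain import IslandDomain, Substrate
from .fields import GriddedVectorField

__all__ = ["fttc_forward", "fttc_inverse", "enforce_equilibrium",
           "boussinesq_displacement_direct"]


def _kernel(nyq_shape: tuple[int, int], spacing: tuple[float, float],
            substrate: Substrate):
    """Kernel components (Gxx, Gyy, Gxy) on the FFT frequency grid.

    Units: µm / Pa with E in Pa and k in rad/µm. The zero mode is zeroed.
    """
    ny, nx = nyq_shape
    dx, dy = spacing
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=dy)
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX ** 2 + KY ** 2
    k = np.sqrt(k2)
    k_safe = np.where(k > 0, k, 1.0)
    E = substrate.youngs_modulus_E
    nu = substrate.poisson_ratio
    pre = 2.0 * (1.0 + nu) / (E * k_safe ** 3)
    Gxx = pre * ((1.0 - nu) * k2 + nu * KY ** 2)
    Gyy = pre * ((1.0 - nu) * k2 + nu * KX ** 2)
    Gxy = -pre * nu * KX * KY
    Gxx[0, 0] = Gyy[0, 0] = Gxy[0, 0] = 0.0
    # the cross term is odd in kx (and ky); on the self-mapped Nyquist lines
    # of an even grid it would break the Hermitian symmetry a real field
    # requires, so it is zeroed there (both directions use the same kernel,
    # keeping forward/inverse exact mutual inverses)
    if nx % 2 == 0:
        Gxy[:, nx // 2] = 0.0
    if ny % 2 == 0:
        Gxy[ny // 2, :] = 0.0
    return Gxx, Gyy, Gxy


def _window(shape: tuple[int, int], alpha: float = 0.2) -> np.ndarray:
    from scipy.signal.windows import tukey
    wy = tukey(shape[0], alpha)
    wx = tukey(shape[1], alpha)
    return np.outer(wy, wx)


def _pad_factor(pad) -> int:
    if pad is True:
        return 2
    if pad in (False, None):
        return 1
    f = int(pad)
    if f < 1:
        raise ValueError("pad factor must be >= 1")
    return f


def _prepare(field: GriddedVectorField, pad, window):
    if np.any(~np.isfinite(field.u)) or np.any(~np.isfinite(field.v)):
        raise ValueError("field contains missing values; inpaint first")
    u, v = field.u, field.v
    if window:
        w = _window(field.shape)
        u, v = u * w, v * w
    f = _pad_factor(pad)
    ny, nx = field.shape
    if f > 1:
        U = np.zeros((f * ny, f * nx))
        V = np.zeros((f * ny, f * nx))
        U[:ny, :nx], V[:ny, :nx] = u, v
        u, v = U, V
    return u, v, (ny, nx)


def fttc_forward(traction: GriddedVectorField, substrate: Substrate,
                 pad=False, window: bool = False) -> GriddedVectorField:
    """Substrate surface displacement (µm) generated by a traction field (Pa).

    Multiplication by the half-space kernel mode-by-mode; the zero-frequency
    (rigid-translation) component is zero.
    """
    tx, ty, (ny, nx) = _prepare(traction, pad, window)
    G = _kernel(tx.shape, traction.spacing, substrate)
    Tx = np.fft.fft2(tx)
    Ty = np.fft.fft2(ty)
    Ux = G[0] * Tx + G[2] * Ty
    Uy = G[2] * Tx + G[1] * Ty
    u = np.fft.ifft2(Ux).real[:ny, :nx]
    v = np.fft.ifft2(Uy).real[:ny, :nx]
    meta = dict(traction.meta)
    meta.update(fttc_pad=_pad_factor(pad), fttc_window=bool(window),
                youngs_modulus_Pa=substrate.youngs_modulus_E,
                poisson_ratio=substrate.poisson_ratio)
    return GriddedVectorField(traction.x, traction.y, u, v, units="um",
                              meta=meta)


def fttc_inverse(displacement: GriddedVectorField, substrate: Substrate,
                 regularization_lambda: float = 0.0, pad=False,
                 window: bool = False) -> GriddedVectorField:
    """Tractions (Pa) from substrate surface displacements (µm).

    Per-mode inversion of the half-space kernel; Tikhonov-regularized when
    ``regularization_lambda`` (units µm/Pa, the kernel's own units) is
    positive: T = (G² + λ²I)⁻¹ G u.
    """
    lam = regularization_lambda
    if lam < 0:
        raise ValueError("regularization_lambda must be >= 0")
    ux, uy, (ny, nx) = _prepare(displacement, pad, window)
    Gxx, Gyy, Gxy = _kernel(ux.shape, displacement.spacing, substrate)
    Ux = np.fft.fft2(ux)
    Uy = np.fft.fft2(uy)
    if lam == 0.0:
        det = Gxx * Gyy - Gxy ** 2
        det_safe = np.where(det > 0, det, 1.0)
        Tx = (Gyy * Ux - Gxy * Uy) / det_safe
        Ty = (-Gxy * Ux + Gxx * Uy) / det_safe
    else:
        # normal equations of the symmetric kernel, mode by mode
        Mxx = Gxx ** 2 + Gxy ** 2 + lam ** 2
        Myy = Gyy ** 2 + Gxy ** 2 + lam ** 2
        Mxy = Gxy * (Gxx + Gyy)
        Rx = Gxx * Ux + Gxy * Uy
        Ry = Gxy * Ux + Gyy * Uy
        det = Mxx * Myy - Mxy ** 2
        det_safe = np.where(det > 0, det, 1.0)
        Tx = (Myy * Rx - Mxy * Ry) / det_safe
        Ty = (-Mxy * Rx + Mxx * Ry) / det_safe
    Tx[0, 0] = Ty[0, 0] = 0.0
    tx = np.fft.ifft2(Tx).real[:ny, :nx]
    ty = np.fft.ifft2(Ty).real[:ny, :nx]
    meta = dict(displacement.meta)
    meta.update(fttc_pad=_pad_factor(pad), fttc_window=bool(window),
                regularization_lambda=lam,
                youngs_modulus_Pa=substrate.youngs_modulus_E,
                poisson_ratio=substrate.poisson_ratio)
    return GriddedVectorField(displacement.x, displacement.y, tx, ty,
                              units="Pa", meta=meta)


def boussinesq_displacement_direct(traction: GriddedVectorField,
                                   substrate: Substrate,
                                   sample_points: np.ndarray) -> np.ndarray:
    """Real-space convolution with the Boussinesq surface Green's function.

    Independent of the FFT path: sums G(x - x')·T(x')·ΔA over all grid
    sources for each requested surface point, skipping the singular
    self-cell. Intended as a cross-check on small problems.

    Parameters
    ----------
    sample_points : (N, 2) array of (x, y) in µm.

    Returns
    -------
    (N, 2) array of displacements (µm).
    """
    E = substrate.youngs_modulus_E
    nu = substrate.poisson_ratio
    dx, dy = traction.spacing
    a = min(dx, dy)
    dA = dx * dy
    X, Y = np.meshgrid(traction.x, traction.y)
    src = np.column_stack([X.ravel(), Y.ravel()])
    tx = traction.u.ravel()
    ty = traction.v.ravel()
    out = np.zeros((len(sample_points), 2))
    c = (1.0 + nu) / (np.pi * E)

    def kernel_sum(rx, ry, txi, tyi, weight):
        r = np.hypot(rx, ry)
        inv_r = 1.0 / r
        inv_r3 = inv_r ** 3
        gxx = c * ((1.0 - nu) * inv_r + nu * rx * rx * inv_r3)
        gyy = c * ((1.0 - nu) * inv_r + nu * ry * ry * inv_r3)
        gxy = c * nu * rx * ry * inv_r3
        return (np.sum(gxx * txi + gxy * tyi) * weight,
                np.sum(gxy * txi + gyy * tyi) * weight)

    # exact integral of 1/r over a unit square centred on the singularity
    I1_UNIT = 4.0 * np.arcsinh(1.0)
    nsub = 7
    off = (np.arange(nsub) + 0.5) / nsub - 0.5
    OX, OY = np.meshgrid(off * dx, off * dy)

    for i, (sx, sy) in enumerate(np.asarray(sample_points, float)):
        rx = sx - src[:, 0]
        ry = sy - src[:, 1]
        r = np.hypot(rx, ry)
        far = r > 4.0 * a
        ux, uy = kernel_sum(rx[far], ry[far], tx[far], ty[far], dA)
        # near cells: midpoint quadrature of the 1/r kernel is too crude,
        # so subdivide; the self cell gets the closed-form integral
        near = ~far & (r > 0.5 * a)
        for j in np.nonzero(near)[0]:
            sub_x = rx[j] + OX.ravel()
            sub_y = ry[j] + OY.ravel()
            dux, duy = kernel_sum(sub_x, sub_y, tx[j], ty[j], dA / nsub ** 2)
            ux += dux
            uy += duy
        self_cells = np.nonzero(r <= 0.5 * a)[0]
        for j in self_cells:
            # ∫ x²/r³ = ∫ y²/r³ = I1/2 over the centred square, and the
            # cross term vanishes by symmetry
            I1 = I1_UNIT * a
            ux += c * (1.0 - nu / 2.0) * I1 * tx[j]
            uy += c * (1.0 - nu / 2.0) * I1 * ty[j]
        out[i] = (ux, uy)
    return out


def enforce_equilibrium(traction: GriddedVectorField, domain: IslandDomain,
                        ) -> tuple[GriddedVectorField, dict]:
    """Minimal least-squares correction to zero net force and net moment.

    The correction inside the mask is the projection of the traction field
    onto the span of {uniform x, uniform y, in-plane rotation about the
    island centroid}: ΔT = α + β·(-(y-ȳ), x-x̄). With centroid-centred
    coordinates the three equations decouple, so a uniform offset or a
    rigid-rotation-like component is removed exactly. An already balanced
    field is returned unchanged (zero correction magnitude).

    Returns the corrected field and a report with the pre/post net force,
    net moment and the RMS correction magnitude.
    """
    mask = domain.mask_at(traction.x, traction.y)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("island mask is empty on the traction grid")
    X, Y = np.meshgrid(traction.x, traction.y)
    xt = X[mask] - X[mask].mean()
    yt = Y[mask] - Y[mask].mean()
    tx = traction.u[mask]
    ty = traction.v[mask]

    fx, fy = tx.sum(), ty.sum()
    m0 = np.sum(xt * ty - yt * tx)
    r2 = np.sum(xt ** 2 + yt ** 2)

    ax, ay = -fx / n, -fy / n
    beta = -m0 / r2 if r2 > 0 else 0.0

    du = np.zeros_like(traction.u)
    dv = np.zeros_like(traction.v)
    du[mask] = ax - beta * yt
    dv[mask] = ay + beta * xt
    out = GriddedVectorField(traction.x, traction.y, traction.u + du,
                             traction.v + dv, units=traction.units,
                             quality=traction.quality,
                             meta=dict(traction.meta))
    rms_corr = float(np.sqrt(np.mean(du[mask] ** 2 + dv[mask] ** 2)))
    report = dict(
        net_force_before=(float(fx), float(fy)),
        net_moment_before=float(m0),
        net_force_after=(float(out.u[mask].sum()), float(out.v[mask].sum())),
        net_moment_after=float(np.sum(xt * out.v[mask] - yt * out.u[mask])),
        correction_rms=rms_corr,
    )
    out.meta["equilibrium_correction_rms_Pa"] = rms_corr
    return out, report
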