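"""Ground-truthed synthetic island generator.

Builds every quantity the inverse pipeline estimates, in the forward
direction: a smooth in-plane velocity field on a circular island
→ strain rates → monolayer stress (thin-sheet constitutive law)
→ cell-substrate tractions (in-plane force balance)
→ substrate surface displacements (Boussinesq half-space)
→ synthetic fluorescent-particle (speckle) images.

Every stage of the measurement chain (DIC, FTTC, MSM) can then be tested
closed-loop against known ground truth. The default parameters emulate the
study conditions at desk scale: a contractile epithelial island on a 6 kPa
gel, imaged at 0.65 µm/px every 10 min, with cell speeds of a few tenths of
a µm/min and monolayer stresses of a few hundred Pa.

Sign convention (fixed once, package-wide): ``T`` is the traction exerted by
the cells on the substrate, so in-plane force balance of the monolayer reads
``∇·σ − T/h = 0`` and a contractile island has radially inward edge tractions
together with positive (tensile) stress. Because active contraction of the
actomyosin network generates tension while the observed flow is inward, the
island synthesizer applies the constitutive law with the active-contraction
sign: σ = −[(K1 − 2/3·K2)·tr(ε̇)·δ + 2·K2·ε̇]. The pointwise law itself
(:func:`stress_from_strainrate`) is kept in its literal passive form; the
stress recovery downstream is invariant to the overall constitutive scale,
including its sign.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as _dc_field
from typing import Optional

import numpy as np

from .domain import IslandDomain, Monolayer, Substrate, make_island
from .fields import GriddedVectorField, StrainRateField, StressField

__all__ = [
    "sample_velocity_field", "contractile_velocity_field",
    "axisymmetric_contractile_solution",
    "strain_rate_from_velocity", "stress_from_strainrate",
    "traction_from_stress", "compatibility_residual",
    "SpeckleImage", "render_speckle_pair", "render_advected_stack",
    "SyntheticIsland", "synthesize_island",
    "fluctuation_solution", "FluctuationSolution",
]


# ---------------------------------------------------------------------------
# velocity fields

def _taper_profile(r: np.ndarray, R: float, width: float):
    """Quintic smoothstep rolloff t(r) from 1 to 0 over [R-width, R].

    Returns (t, t', t''). The taper is a function of the physical radius
    only, so fields built with it refine consistently under grid refinement.
    The quintic profile is C² — t' and t'' both vanish at the ramp ends — so
    the traction T = h∇·σ of a tapered field (which contains t'') goes to
    zero continuously at the island edge instead of jumping there.
    """
    u = (r - (R - width)) / width
    ramp = (u > 0) & (u < 1)
    t = np.ones_like(r)
    t[u >= 1] = 0.0
    ur = u[ramp]
    t[ramp] = 1.0 - ur ** 3 * (10.0 - 15.0 * ur + 6.0 * ur ** 2)
    tp = np.zeros_like(r)
    tp[ramp] = -30.0 * ur ** 2 * (1.0 - ur) ** 2 / width
    tpp = np.zeros_like(r)
    tpp[ramp] = -60.0 * ur * (1.0 - ur) * (1.0 - 2.0 * ur) / width ** 2
    return t, tp, tpp


def _radial_taper(domain: IslandDomain, width: float,
                  x: Optional[np.ndarray] = None,
                  y: Optional[np.ndarray] = None) -> np.ndarray:
    r, _, _ = domain.radial_coords(x, y)
    return _taper_profile(r, domain.radius, width)[0]


def _fourier_modes(domain: IslandDomain, amplitude: float,
                   correlation_length: float, seed: int):
    """Random Fourier-mode table defining a smooth continuous field.

    Returns (kx, ky, amps, phases) with amps/phases of shape (2, n_modes) —
    one row per velocity component. The same seed defines the same continuous
    field at any grid resolution, and the untapered field has RMS equal to
    ``amplitude`` analytically (sum of independent-phase cosines).
    """
    ny, nx = domain.shape
    Lx = nx * domain.pixel_size
    Ly = ny * domain.pixel_size
    L = max(Lx, Ly)
    # include modes out to k ~ 4 / L_c, where the spectrum has fallen to e^-4
    P = max(2, math.ceil(2.0 * L / (math.pi * correlation_length)))
    pq = [(p, q) for p in range(0, P + 1)
          for q in range(-P, P + 1)
          if (p > 0 or q > 0)]
    kx = 2.0 * np.pi * np.array([p for p, _ in pq]) / Lx
    ky = 2.0 * np.pi * np.array([q for _, q in pq]) / Ly
    weight = np.exp(-(kx ** 2 + ky ** 2) * correlation_length ** 2 / 4.0)

    rng = np.random.default_rng(seed)
    amps = np.empty((2, len(pq)))
    phases = np.empty((2, len(pq)))
    # per-component RMS of amplitude/sqrt(2), so the vector-magnitude RMS of
    # the untapered field equals ``amplitude`` analytically
    per_comp = amplitude / np.sqrt(2.0)
    for c in range(2):
        a = weight * rng.standard_normal(len(pq))
        phases[c] = rng.uniform(0.0, 2.0 * np.pi, len(pq))
        amps[c] = a * (per_comp / np.sqrt(0.5 * np.sum(a ** 2)))
    return kx, ky, amps, phases


def sample_velocity_field(domain: IslandDomain, amplitude: float,
                          correlation_length: float, seed: int,
                          taper_width: Optional[float] = None,
                          ) -> GriddedVectorField:
    """Smooth random velocity field on the island, zero outside the mask.

    The field is synthesized from a fixed set of low-wavenumber Fourier modes
    with a Gaussian spectrum exp(-(k·L_c)²/4), so that the *same seed* defines
    the same continuous field at any grid resolution (required for grid
    refinement studies). The untapered field is normalized analytically to the
    requested RMS amplitude; the edge taper reduces the in-mask RMS slightly.

    Parameters
    ----------
    amplitude : target RMS speed (µm/min). Zero yields an identically zero
        field; negative values are rejected.
    correlation_length : spectral correlation length L_c (µm); must be at
        least two grid spacings.
    seed : RNG seed; the field is deterministic given the seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    if correlation_length < 2 * domain.pixel_size:
        raise ValueError("correlation_length must be >= 2 grid spacings")
    x, y = domain.grid()
    ny, nx = domain.shape
    if amplitude == 0.0:
        z = np.zeros((ny, nx))
        return GriddedVectorField(x, y, z, z.copy(), units="um/min")

    kx, ky, amps, phases = _fourier_modes(domain, amplitude,
                                          correlation_length, seed)
    X, Y = np.meshgrid(x, y)
    comps = []
    for c in range(2):
        field = np.zeros((ny, nx))
        for a, kxi, kyi, ph in zip(amps[c], kx, ky, phases[c]):
            field += a * np.cos(kxi * X + kyi * Y + ph)
        comps.append(field)

    if taper_width is None:
        taper_width = 0.2 * domain.radius
    taper = _radial_taper(domain, taper_width)
    return GriddedVectorField(x, y, comps[0] * taper, comps[1] * taper,
                              units="um/min")


def contractile_velocity_field(domain: IslandDomain, speed: float,
                               nu_m: float = 0.5) -> GriddedVectorField:
    """Axisymmetric radially inward (contractile) flow profile.

    v_r(r) = -(speed/R)·r·(1 − α·r²/R²) with α = (1+ν_m)/(3+ν_m), the unique
    cubic inward profile whose constitutive stress satisfies the free-edge
    condition σrr(R) = 0 exactly (see
    :func:`axisymmetric_contractile_solution`). The flow remains inward at
    the island edge — v_r(R) = -speed·(1-α) — which is what makes the
    island-average tension positive: the mean in-plane dilation rate equals
    the boundary flux of v, which vanishes for any flow tapered to zero at
    the edge. Negative ``speed`` gives an expanding island.
    """
    x, y = domain.grid()
    r, rx, ry = domain.radial_coords()
    R = domain.radius
    alpha = (1.0 + nu_m) / (3.0 + nu_m)
    profile = np.where(r <= R,
                       -(speed / R) * r * (1.0 - alpha * (r / R) ** 2), 0.0)
    return GriddedVectorField(x, y, profile * rx, profile * ry, units="um/min")


def axisymmetric_contractile_solution(domain: IslandDomain,
                                      monolayer: Monolayer, speed: float,
                                      ) -> tuple[GriddedVectorField,
                                                 StressField,
                                                 GriddedVectorField]:
    """Closed-form contractile island: velocity, stress and traction.

    For the cubic inward profile of :func:`contractile_velocity_field` the
    active-sign constitutive stress is, with ν = ν_m, α = (1+ν)/(3+ν),
    β = (1+3ν)/(3+ν) and σ0 = (A + 2K2)·(1+ν)·speed/R:

        σrr(r) = σ0·(1 − r²/R²)          (tensile, zero at the free edge)
        σθθ(r) = σ0·(1 − β·r²/R²)        (tensile everywhere for ν ≤ 1)
        σrθ    = 0

    and force balance T = h·∇·σ gives a purely radial traction

        T_r(r) = −h·σ0·(3 − β)·r/R²      (inward everywhere),

    evaluated analytically so no finite difference crosses the island edge,
    where the velocity (and hence the stress) is cut off. Outside the mask
    all fields are zero.
    """
    x, y = domain.grid()
    r, rx, ry = domain.radial_coords()
    R = domain.radius
    nu = monolayer.nu_m
    A = monolayer.K1 - 2.0 / 3.0 * monolayer.K2
    alpha = (1.0 + nu) / (3.0 + nu)
    beta = (1.0 + 3.0 * nu) / (3.0 + nu)
    sigma0 = (A + 2.0 * monolayer.K2) * (1.0 + nu) * speed / R

    inside = r <= R
    rr2 = (r / R) ** 2
    srr = np.where(inside, sigma0 * (1.0 - rr2), 0.0)
    stt = np.where(inside, sigma0 * (1.0 - beta * rr2), 0.0)
    # at r = 0 the tensor is isotropic; the unit radial vector is undefined
    # there (radial_coords returns 0), so split the identity evenly
    rx2 = np.where(r > 0, rx ** 2, 0.5)
    ry2 = np.where(r > 0, ry ** 2, 0.5)
    sxx = srr * rx2 + stt * ry2
    syy = srr * ry2 + stt * rx2
    sxy = (srr - stt) * rx * ry
    stress = StressField(x, y, sxx, syy, sxy)

    vel = contractile_velocity_field(domain, speed, nu_m=nu)
    tr_r = np.where(inside,
                    -monolayer.height_h * sigma0 * (3.0 - beta) * r / R ** 2,
                    0.0)
    traction = GriddedVectorField(x, y, tr_r * rx, tr_r * ry, units="Pa")
    return vel, stress, traction


def fluctuation_solution(domain: IslandDomain, monolayer: Monolayer,
                         amplitude: float, correlation_length: float,
                         seed: int, taper_width: Optional[float] = None,
                         active_sign: float = -1.0,
                         ) -> tuple[GriddedVectorField, StrainRateField,
                                    StressField, GriddedVectorField]:
    """Exact constitutive/force-balance chain for the random velocity field.

    The field of :func:`sample_velocity_field` is a finite Fourier sum times
    a radial taper, so its strain rates and the divergence of the resulting
    stress can be differentiated in closed form. This returns (velocity,
    strain rate, stress, traction) evaluated exactly at the pixel centres —
    the same chain as :func:`strain_rate_from_velocity` →
    :func:`stress_from_strainrate` → :func:`traction_from_stress` but with no
    finite-difference truncation, which is what a discretization-convergence
    benchmark for the stress recovery needs. ``active_sign=-1`` applies the
    package's active-contraction sign to stress and traction.

    With σ = s·[A·tr(ε̇)·δ + 2·K2·ε̇] and A = K1 − 2/3·K2, force balance
    T = h·∇·σ reduces to T = h·s·[(A + K2)·∇(∇·v) + K2·∆v].
    """
    sol = FluctuationSolution(domain, monolayer, amplitude,
                              correlation_length, seed, taper_width,
                              active_sign)
    return sol.fields()


@dataclass
class FluctuationSolution:
    """Closed-form solution object for the tapered random velocity field.

    Evaluates velocity, strain rate, stress and traction exactly at
    arbitrary points (see :func:`fluctuation_solution` for the math), which
    lets the finite-element solver integrate the load by quadrature instead
    of grid interpolation when benchmarking.
    """

    domain: IslandDomain
    monolayer: Monolayer
    amplitude: float
    correlation_length: float
    seed: int
    taper_width: Optional[float] = None
    active_sign: float = -1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.correlation_length < 2 * self.domain.pixel_size:
            raise ValueError("correlation_length must be >= 2 grid spacings")
        if self.taper_width is None:
            self.taper_width = 0.2 * self.domain.radius
        if not 0 < self.taper_width < self.domain.radius:
            raise ValueError("taper_width must lie in (0, radius)")
        if self.amplitude > 0:
            self._modes = _fourier_modes(self.domain, self.amplitude,
                                         self.correlation_length, self.seed)
        else:
            self._modes = None

    def _eval(self, X: np.ndarray, Y: np.ndarray) -> dict:
        """All fields at arbitrary physical points (µm)."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        cx, cy = self.domain.center
        dx, dy = X - cx, Y - cy
        r = np.hypot(dx, dy)
        r_safe = np.maximum(r, 1e-12)
        rx, ry = dx / r_safe, dy / r_safe
        t, tp, tpp = _taper_profile(r, self.domain.radius, self.taper_width)

        acc = np.zeros((2, 6) + X.shape)  # per comp: g, gx, gy, gxx, gxy, gyy
        if self._modes is not None:
            kx, ky, amps, phases = self._modes
            for c in range(2):
                for a, kxi, kyi, ph in zip(amps[c], kx, ky, phases[c]):
                    phase = kxi * X + kyi * Y + ph
                    cph = np.cos(phase)
                    sph = np.sin(phase)
                    acc[c, 0] += a * cph
                    acc[c, 1] += -a * kxi * sph
                    acc[c, 2] += -a * kyi * sph
                    acc[c, 3] += -a * kxi * kxi * cph
                    acc[c, 4] += -a * kxi * kyi * cph
                    acc[c, 5] += -a * kyi * kyi * cph
        (gx0, gx_x, gx_y, gx_xx, gx_xy, gx_yy) = acc[0]
        (gy0, gy_x, gy_y, gy_xx, gy_xy, gy_yy) = acc[1]

        # velocity and its gradient (product rule with the radial taper)
        u = t * gx0
        v = t * gy0
        du_dx = tp * rx * gx0 + t * gx_x
        du_dy = tp * ry * gx0 + t * gx_y
        dv_dx = tp * rx * gy0 + t * gy_x
        dv_dy = tp * ry * gy0 + t * gy_y
        exx, eyy = du_dx, dv_dy
        exy = 0.5 * (du_dy + dv_dx)

        ml = self.monolayer
        A = ml.K1 - 2.0 / 3.0 * ml.K2
        K2 = ml.K2
        s = self.active_sign
        tr = exx + eyy

        # gradient of the dilation rate: ∇(∇·v)
        rg = rx * gx0 + ry * gy0
        divg = gx_x + gy_y
        dtr_x = (tpp * rx * rg
                 + tp * (((1 - rx * rx) * gx0 - rx * ry * gy0) / r_safe
                         + rx * gx_x + ry * gy_x)
                 + tp * rx * divg + t * (gx_xx + gy_xy))
        dtr_y = (tpp * ry * rg
                 + tp * (((1 - ry * ry) * gy0 - rx * ry * gx0) / r_safe
                         + rx * gx_y + ry * gy_y)
                 + tp * ry * divg + t * (gx_xy + gy_yy))
        # vector Laplacian of the velocity
        lap_t = tpp + tp / r_safe
        lap_u = (lap_t * gx0 + 2 * tp * (rx * gx_x + ry * gx_y)
                 + t * (gx_xx + gx_yy))
        lap_v = (lap_t * gy0 + 2 * tp * (rx * gy_x + ry * gy_y)
                 + t * (gy_xx + gy_yy))

        h = ml.height_h
        return dict(
            u=u, v=v, exx=exx, eyy=eyy, exy=exy,
            sxx=s * (A * tr + 2 * K2 * exx),
            syy=s * (A * tr + 2 * K2 * eyy),
            sxy=s * 2 * K2 * exy,
            tx=h * s * ((A + K2) * dtr_x + K2 * lap_u),
            ty=h * s * ((A + K2) * dtr_y + K2 * lap_v),
        )

    def traction_at(self, X: np.ndarray, Y: np.ndarray):
        """Exact traction (Pa) at arbitrary points, for quadrature loading."""
        f = self._eval(X, Y)
        return f["tx"], f["ty"]

    def fields(self) -> tuple[GriddedVectorField, StrainRateField,
                              StressField, GriddedVectorField]:
        x, y = self.domain.grid()
        X, Y = np.meshgrid(x, y)
        f = self._eval(X, Y)
        velocity = GriddedVectorField(x, y, f["u"], f["v"], units="um/min")
        strain_rate = StrainRateField(x, y, f["exx"], f["eyy"], f["exy"])
        stress = StressField(x, y, f["sxx"], f["syy"], f["sxy"])
        traction = GriddedVectorField(x, y, f["tx"], f["ty"], units="Pa")
        return velocity, strain_rate, stress, traction


# ---------------------------------------------------------------------------
# forward mechanics

def strain_rate_from_velocity(velocity: GriddedVectorField) -> StrainRateField:
    """Strain rates by centred differences (one-sided at the grid edges)."""
    dx, dy = velocity.spacing
    dudy, dudx = np.gradient(velocity.u, dy, dx, edge_order=2)
    dvdy, dvdx = np.gradient(velocity.v, dy, dx, edge_order=2)
    return StrainRateField(velocity.x, velocity.y,
                           exx=dudx, eyy=dvdy, exy=0.5 * (dudy + dvdx))


def stress_from_strainrate(strain_rate: StrainRateField,
                           monolayer: Monolayer) -> StressField:
    """Pointwise thin-sheet constitutive law.

    σij = (K1 − 2/3·K2)·tr(ε̇)·δij + 2·K2·ε̇ij, with the 2-D trace
    tr(ε̇) = ε̇xx + ε̇yy (plane-stress reading). Linear in the strain rate;
    symmetric by construction.
    """
    a = monolayer.K1 - 2.0 / 3.0 * monolayer.K2
    tr = strain_rate.trace
    sxx = a * tr + 2.0 * monolayer.K2 * strain_rate.exx
    syy = a * tr + 2.0 * monolayer.K2 * strain_rate.eyy
    sxy = 2.0 * monolayer.K2 * strain_rate.exy
    return StressField(strain_rate.x, strain_rate.y, sxx, syy, sxy)


def traction_from_stress(stress: StressField, monolayer: Monolayer,
                         domain: IslandDomain) -> GriddedVectorField:
    """Tractions from in-plane force balance: T = h·(∇·σ).

    ``T`` is the traction the cells exert on the substrate, so a tensile
    stress peaking at the island centre produces radially inward edge
    tractions. The stress must vanish (or be smoothly tapered) at the mask
    boundary; the returned field is zeroed outside the mask.
    """
    if stress.shape != domain.shape:
        raise ValueError(
            f"stress grid {stress.shape} does not cover the island mask "
            f"{domain.shape}")
    dx, dy = stress.spacing
    dsxx_dx = np.gradient(stress.sxx, dx, axis=1, edge_order=2)
    dsxy_dy = np.gradient(stress.sxy, dy, axis=0, edge_order=2)
    dsxy_dx = np.gradient(stress.sxy, dx, axis=1, edge_order=2)
    dsyy_dy = np.gradient(stress.syy, dy, axis=0, edge_order=2)
    h = monolayer.height_h
    tx = h * (dsxx_dx + dsxy_dy) * domain.mask
    ty = h * (dsxy_dx + dsyy_dy) * domain.mask
    return GriddedVectorField(stress.x, stress.y, tx, ty, units="Pa")


def compatibility_residual(strain_rate: StrainRateField) -> np.ndarray:
    """Residual of the 2-D compatibility condition.

    ∂²ε̇xx/∂y² + ∂²ε̇yy/∂x² − 2·∂²ε̇xy/∂x∂y, which vanishes (to
    finite-difference accuracy) whenever the strain rates derive from an
    actual velocity field.
    """
    dx = float(strain_rate.x[1] - strain_rate.x[0])
    dy = float(strain_rate.y[1] - strain_rate.y[0])
    d2exx = np.gradient(np.gradient(strain_rate.exx, dy, axis=0), dy, axis=0)
    d2eyy = np.gradient(np.gradient(strain_rate.eyy, dx, axis=1), dx, axis=1)
    dexy = np.gradient(np.gradient(strain_rate.exy, dx, axis=1), dy, axis=0)
    return d2exx + d2eyy - 2.0 * dexy


# ---------------------------------------------------------------------------
# speckle rendering

@dataclass
class SpeckleImage:
    """Synthetic fluorescent-particle image (analytic Gaussian spots)."""

    data: np.ndarray
    pixel_size: float
    density: float       # particles per pixel²
    spot_sigma: float    # px
    seed: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("speckle intensities must be non-negative")


def _render_spots(px: np.ndarray, py: np.ndarray, amp: np.ndarray,
                  shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Sum Gaussian spots analytically onto a pixel grid (no resampling)."""
    ny, nx = shape
    w = int(math.ceil(4.0 * sigma))
    off = np.arange(-w, w + 1)
    ix0 = np.round(px).astype(int)
    iy0 = np.round(py).astype(int)
    # (N, P) index and offset arrays
    jx = ix0[:, None] + off[None, :]
    jy = iy0[:, None] + off[None, :]
    gx = np.exp(-((jx - px[:, None]) ** 2) / (2.0 * sigma ** 2))
    gy = np.exp(-((jy - py[:, None]) ** 2) / (2.0 * sigma ** 2))
    gx *= (jx >= 0) & (jx < nx)
    gy *= (jy >= 0) & (jy < ny)
    patch = amp[:, None, None] * gy[:, :, None] * gx[:, None, :]
    img = np.zeros(shape)
    np.add.at(img, (np.clip(jy, 0, ny - 1)[:, :, None],
                    np.clip(jx, 0, nx - 1)[:, None, :]), patch)
    return img


def render_speckle_pair(displacement: Optional[GriddedVectorField],
                        density: float = 0.03, spot_sigma: float = 1.5,
                        seed: int = 0,
                        shape: Optional[tuple[int, int]] = None,
                        pixel_size: Optional[float] = None,
                        ) -> tuple[SpeckleImage, SpeckleImage]:
    """Render an (undeformed, deformed) particle-image pair.

    The first image is a field of random Gaussian spots (the traction-free
    reference); the second renders the same spots at positions shifted by the
    displacement field interpolated at each particle, so there are no
    image-resampling artefacts. Particles are also seeded in a margin beyond
    the frame so that spots translate in and out of view consistently.

    ``displacement`` is in µm on a physical grid; ``None`` means zero
    displacement (then ``shape`` and ``pixel_size`` are required).
    """
    if displacement is not None:
        if shape is None:
            shape = displacement.shape
        if pixel_size is None:
            pixel_size = float(displacement.x[1] - displacement.x[0])
    if shape is None or pixel_size is None:
        raise ValueError("shape and pixel_size are required when no "
                         "displacement field is given")
    ny, nx = shape
    if density <= 0:
        raise ValueError("density must be positive")
    if density * 32 ** 2 < 3:
        warnings.warn("particle density is so low that 32-px correlation "
                      "subsets may be empty", stacklevel=2)

    max_shift_px = 0.0
    if displacement is not None:
        max_shift_px = float(np.nanmax(displacement.magnitude)) / pixel_size
        if max_shift_px > 0.25 * min(ny, nx):
            raise ValueError("displacement magnitudes must be small compared "
                             "with the image size")
    margin = int(math.ceil(4.0 * spot_sigma + max_shift_px + 2.0))

    rng = np.random.default_rng(seed)
    n_part = int(round(density * (nx + 2 * margin) * (ny + 2 * margin)))
    px = rng.uniform(-margin, nx - 1 + margin, n_part)
    py = rng.uniform(-margin, ny - 1 + margin, n_part)
    amp = rng.uniform(0.5, 1.0, n_part)

    img_a = _render_spots(px, py, amp, (ny, nx), spot_sigma)
    if displacement is None:
        du = dv = np.zeros(n_part)
    else:
        # margin particles take the nearest in-grid displacement, so a
        # uniform shift really shifts every spot
        qx = np.clip(px * pixel_size, displacement.x[0], displacement.x[-1])
        qy = np.clip(py * pixel_size, displacement.y[0], displacement.y[-1])
        du, dv = displacement.sample(qx, qy)
        du = np.asarray(du) / pixel_size
        dv = np.asarray(dv) / pixel_size
    img_b = _render_spots(px + du, py + dv, amp, (ny, nx), spot_sigma)

    mk = lambda d: SpeckleImage(d, pixel_size, density, spot_sigma, seed)
    return mk(img_a), mk(img_b)


def render_advected_stack(velocity: GriddedVectorField, n_frames: int,
                          dt: float, density: float = 0.03,
                          spot_sigma: float = 1.5, seed: int = 0,
                          ) -> list[SpeckleImage]:
    """Texture stack advected by a static velocity field (µm/min).

    Frame k renders the particles displaced by k·dt·v evaluated at their
    initial positions — a stand-in for phase-contrast cell texture when
    testing consecutive-frame image correlation.
    """
    pixel_size = float(velocity.x[1] - velocity.x[0])
    ny, nx = velocity.shape
    vmax = float(np.nanmax(velocity.magnitude))
    margin = int(math.ceil(4.0 * spot_sigma + vmax * dt * n_frames / pixel_size + 2.0))
    rng = np.random.default_rng(seed)
    n_part = int(round(density * (nx + 2 * margin) * (ny + 2 * margin)))
    px = rng.uniform(-margin, nx - 1 + margin, n_part)
    py = rng.uniform(-margin, ny - 1 + margin, n_part)
    amp = rng.uniform(0.5, 1.0, n_part)
    qx = np.clip(px * pixel_size, velocity.x[0], velocity.x[-1])
    qy = np.clip(py * pixel_size, velocity.y[0], velocity.y[-1])
    vu, vv = velocity.sample(qx, qy)
    frames = []
    for k in range(n_frames):
        shift_u = np.asarray(vu) * dt * k / pixel_size
        shift_v = np.asarray(vv) * dt * k / pixel_size
        img = _render_spots(px + shift_u, py + shift_v, amp, (ny, nx),
                            spot_sigma)
        frames.append(SpeckleImage(img, pixel_size, density, spot_sigma, seed))
    return frames


# ---------------------------------------------------------------------------
# end-to-end bundle

@dataclass
class SyntheticIsland:
    """Ground-truthed synthetic island: every forward-model quantity."""

    domain: IslandDomain
    monolayer: Monolayer
    substrate: Substrate
    velocity: GriddedVectorField          # µm/min, cell flow
    strain_rate: StrainRateField          # 1/min
    stress: StressField                   # Pa, ground-truth monolayer stress
    traction: GriddedVectorField          # Pa, cells-on-substrate
    substrate_displacement: GriddedVectorField   # µm, gel surface
    speckle_reference: Optional[SpeckleImage] = None
    speckle_deformed: Optional[SpeckleImage] = None
    params: dict = _dc_field(default_factory=dict)


def synthesize_island(n: int = 256, pixel_size: float = 0.65,
                      radius_um: float = 52.0, speed: float = 0.3,
                      fluctuation: float = 0.1,
                      correlation_length: float = 13.0,
                      monolayer: Optional[Monolayer] = None,
                      substrate: Optional[Substrate] = None,
                      seed: int = 0, mode: str = "contractile",
                      render_speckle: bool = True,
                      speckle_density: float = 0.03,
                      spot_sigma: float = 1.5) -> SyntheticIsland:
    """Generate a fully ground-truthed synthetic island.

    Defaults are the desk-scale study conditions: a 52 µm-radius island on a
    256² grid at 0.65 µm/px (stand-in for the 1 mm lab island), mean inward
    cell speed 0.3 µm/min with 0.1 µm/min smooth fluctuations, monolayer
    height 5 µm with constitutive ratio ν_m = 0.5, and a 6 kPa near-
    incompressible substrate. With these choices tractions are tens of Pa,
    stresses a few hundred Pa and substrate displacements around one pixel —
    the magnitudes typical of epithelial islands on soft gels.

    ``mode`` is ``"contractile"`` (inward flow, tensile stress, inward edge
    tractions) or ``"expanding"`` (everything sign-flipped).
    """
    if mode not in ("contractile", "expanding"):
        raise ValueError("mode must be 'contractile' or 'expanding'")
    monolayer = monolayer or Monolayer()
    substrate = substrate or Substrate()
    domain = make_island(radius_um, pixel_size, n)

    # axisymmetric contractile base in closed form (free edge satisfied
    # exactly, no finite difference across the island edge) ...
    sgn = 1.0 if mode == "contractile" else -1.0
    base_v, base_s, base_t = axisymmetric_contractile_solution(
        domain, monolayer, sgn * speed)
    # ... plus smooth random fluctuations, tapered to zero at the edge and
    # pushed through the constitutive/force-balance chain in closed form
    # (same active-contraction sign, no finite-difference truncation)
    fluct, _, fl_stress, fl_traction = fluctuation_solution(
        domain, monolayer, fluctuation, correlation_length, seed=seed)

    velocity = GriddedVectorField(base_v.x, base_v.y, base_v.u + fluct.u,
                                  base_v.v + fluct.v, units="um/min")
    sr = strain_rate_from_velocity(velocity)
    stress = StressField(base_s.x, base_s.y, base_s.sxx + fl_stress.sxx,
                         base_s.syy + fl_stress.syy,
                         base_s.sxy + fl_stress.sxy)
    traction = GriddedVectorField(base_t.x, base_t.y,
                                  base_t.u + fl_traction.u,
                                  base_t.v + fl_traction.v, units="Pa")

    from .traction import enforce_equilibrium, fttc_forward
    traction, _ = enforce_equilibrium(traction, domain)
    displacement = fttc_forward(traction, substrate)

    ref = deformed = None
    if render_speckle:
        ref, deformed = render_speckle_pair(displacement,
                                            density=speckle_density,
                                            spot_sigma=spot_sigma, seed=seed)
    params = dict(n=n, pixel_size=pixel_size, radius_um=radius_um,
                  speed=speed, fluctuation=fluctuation,
                  correlation_length=correlation_length, seed=seed, mode=mode,
                  speckle_density=speckle_density, spot_sigma=spot_sigma)
    return SyntheticIsland(domain, monolayer, substrate, velocity, sr, stress,
                           traction, displacement, ref, deformed, params)
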