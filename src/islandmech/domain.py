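"""Island geometry and physical-parameter containers.

The experimental system is a circular micropatterned island of epithelial
monolayer (diameter ~1 mm in the lab) adhering to a soft elastic substrate.
At desk scale the island is represented by a binary mask on the image grid
plus its physical centre and radius.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class IslandDomain:
    """Binary island mask with physical geometry.

    mask : bool array, shape (ny, nx); True inside the island.
    center : (cx, cy) in µm, image convention (x along columns, y down rows).
    radius : island radius in µm.
    pixel_size : µm per pixel.
    """

    mask: np.ndarray
    center: tuple[float, float]
    radius: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        cx, cy = self.center
        j = int(round(cx / self.pixel_size))
        i = int(round(cy / self.pixel_size))
        ny, nx = self.mask.shape
        if not (0 <= i < ny and 0 <= j < nx and self.mask[i, j]):
            raise ValueError("center must lie inside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinate vectors (x, y) of pixel centres, µm."""
        ny, nx = self.mask.shape
        return (np.arange(nx) * self.pixel_size,
                np.arange(ny) * self.pixel_size)

    def radial_coords(self, x: np.ndarray | None = None,
                      y: np.ndarray | None = None):
        """Radius r and unit radial vectors (rhat_x, rhat_y) on a grid.

        Defaults to the domain's own pixel grid. At the centre node the unit
        vector is set to zero.
        """
        if x is None or y is None:
            x, y = self.grid()
        cx, cy = self.center
        X, Y = np.meshgrid(np.asarray(x, float) - cx,
                           np.asarray(y, float) - cy)
        r = np.hypot(X, Y)
        with np.errstate(invalid="ignore", divide="ignore"):
            rx = np.where(r > 0, X / np.maximum(r, 1e-300), 0.0)
            ry = np.where(r > 0, Y / np.maximum(r, 1e-300), 0.0)
        return r, rx, ry

    def mask_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Sample the mask at physical node coordinates (nearest pixel)."""
        j = np.clip(np.round(np.asarray(x, float) / self.pixel_size).astype(int),
                    0, self.mask.shape[1] - 1)
        i = np.clip(np.round(np.asarray(y, float) / self.pixel_size).astype(int),
                    0, self.mask.shape[0] - 1)
        J, I = np.meshgrid(j, i)
        return self.mask[I, J]


def make_island(radius_um: float, pixel_size: float,
                image_size: int | tuple[int, int]) -> IslandDomain:
    """Build a centred circular island mask.

    The island must fit inside the image with a margin of at least 10% of the
    image size on every side, so that a ring of zeros (cell-free substrate)
    surrounds it.

    Parameters
    ----------
    radius_um : island radius in µm (lab scale: 500 µm; desk scale: tens of µm).
    pixel_size : µm per pixel (0.65 µm/px matches a 10x objective on a
        6.5 µm-pixel camera).
    image_size : image side in pixels, or (ny, nx).
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if np.isscalar(image_size):
        ny = nx = int(image_size)
    else:
        ny, nx = map(int, image_size)
    n_min = min(ny, nx)
    radius_px = radius_um / pixel_size
    if radius_px > 0.4 * n_min:
        raise ValueError(
            f"island radius {radius_px:.1f} px does not fit in a {ny}x{nx} "
            f"image with a 10% margin (max {0.4 * n_min:.1f} px); "
            "use a larger image or a smaller island"
        )
    # centre at half the physical extent (not the middle pixel), so the same
    # physical island refines consistently when the grid is refined
    cx = nx / 2 * pixel_size
    cy = ny / 2 * pixel_size
    x = np.arange(nx) * pixel_size
    y = np.arange(ny) * pixel_size
    X, Y = np.meshgrid(x - cx, y - cy)
    # hypot, not the squared comparison: radial_coords and the generator's
    # edge taper classify pixels by hypot, and boundary pixels must land on
    # the same side in both (tractions are largest right at the taper edge)
    mask = np.hypot(X, Y) <= radius_um
    return IslandDomain(mask=mask, center=(cx, cy), radius=radius_um,
                        pixel_size=pixel_size)


def domain_from_mask(mask: np.ndarray, pixel_size: float) -> IslandDomain:
    """Wrap a measured binary mask (e.g. a thresholded boundary image).

    Centre and radius are estimated from the mask centroid and area
    (r = sqrt(area/π)), which is exact for a filled circle and a reasonable
    equivalent radius for real, slightly irregular islands.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ii, jj = np.nonzero(mask)
    cy = ii.mean() * pixel_size
    cx = jj.mean() * pixel_size
    radius = np.sqrt(mask.sum() / np.pi) * pixel_size
    return IslandDomain(mask=mask, center=(cx, cy), radius=radius,
                        pixel_size=pixel_size)


@dataclass
class Monolayer:
    """Cell-layer height and constitutive pair.

    The monolayer is modelled as a thin homogeneous sheet with
    σij = (K1 − 2/3·K2)·tr(ε̇)·δij + 2·K2·ε̇ij  (2-D trace). K1 and K2 play
    the role of bulk and shear viscosities if ε̇ is a strain rate, or moduli
    if it is a strain — the stress recovery only depends on the dimensionless
    ratio, expressed here as the Poisson-like ratio ``nu_m``.
    """

    height_h: float = 5.0       # µm
    K1: float = 8.0e4 / 3.0     # arbitrary consistent units (e.g. Pa·min)
    K2: float = 1.0e4

    def __post_init__(self) -> None:
        if self.height_h <= 0:
            raise ValueError("height_h must be positive")
        if self.K2 <= 0:
            raise ValueError("K2 must be positive")
        # 2-D bulk response (K1 - 2/3 K2) + K2 must be positive-definite
        if self.K1 - 2.0 / 3.0 * self.K2 + self.K2 <= 0:
            raise ValueError("constitutive pair is not positive definite: "
                             "need K1 + K2/3 > 0")

    @property
    def nu_m(self) -> float:
        """Effective plane-stress Poisson-like ratio of the (K1, K2) pair."""
        a = self.K1 - 2.0 / 3.0 * self.K2
        return a / (a + 2.0 * self.K2)

    @classmethod
    def from_nu(cls, nu_m: float, K2: float = 1.0e4,
                height_h: float = 5.0) -> "Monolayer":
        """Construct from a Poisson-like ratio (inverse of :attr:`nu_m`)."""
        if not -1.0 < nu_m < 1.0:
            raise ValueError("nu_m must lie in (-1, 1)")
        a = 2.0 * K2 * nu_m / (1.0 - nu_m)
        return cls(height_h=height_h, K1=a + 2.0 / 3.0 * K2, K2=K2)


@dataclass
class Substrate:
    """Elastic half-space substrate for the traction inverse problem.

    The gel thickness (~100–120 µm in the lab) is recorded but the Boussinesq
    half-space kernel is used throughout: the thickness is much larger than
    the displacement decay length at the island's traction wavelengths.
    """

    youngs_modulus_E: float = 6000.0   # Pa
    poisson_ratio: float = 0.45
    thickness_um: float = 110.0

    def __post_init__(self) -> None:
        if self.youngs_modulus_E <= 0:
            raise ValueError("youngs_modulus_E must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
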