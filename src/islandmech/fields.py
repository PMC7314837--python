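"""Gridded field containers shared across the pipeline.

All fields live on regular rectangular grids. Coordinates follow the image
convention: ``x`` runs along columns, ``y`` along rows with y increasing
downward, and arrays are indexed ``[row, col]`` i.e. ``[y, x]``. Physical
coordinates are in micrometres unless a field's ``units`` say otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def _check_regular(coords: np.ndarray, name: str) -> float:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 1 or coords.size < 2:
        raise ValueError(f"{name} must be a 1-D coordinate vector with >= 2 entries")
    d = np.diff(coords)
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10):
        raise ValueError(f"{name} must be regularly spaced")
    if d[0] <= 0:
        raise ValueError(f"{name} must be strictly increasing")
    return float(d[0])


@dataclass
class GriddedVectorField:
    """Two-component vector field (displacement, velocity, or traction).

    Parameters
    ----------
    x, y : 1-D coordinate vectors (µm), regularly spaced.
    u, v : 2-D component arrays of shape ``(y.size, x.size)``; x- and
        y-components respectively. Units are carried in ``units``
        (``"um"``, ``"um/min"``, ``"Pa"``...).
    quality : optional per-node correlation quality in [-1, 1]; NaN marks
        nodes that were flagged missing before inpainting.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    units: str = "um"
    quality: Optional[np.ndarray] = None
    time_index: Optional[int] = None
    meta: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        _check_regular(self.x, "x")
        _check_regular(self.y, "y")
        expected = (self.y.size, self.x.size)
        if self.u.shape != expected or self.v.shape != expected:
            raise ValueError(
                f"component arrays must have shape {expected}, "
                f"got u{self.u.shape} v{self.v.shape}"
            )
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != expected:
                raise ValueError("quality must match the component shape")

    @property
    def spacing(self) -> tuple[float, float]:
        """(dx, dy) grid spacing in the coordinate units."""
        return float(self.x[1] - self.x[0]), float(self.y[1] - self.y[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def rms(self, mask: Optional[np.ndarray] = None) -> float:
        """Root-mean-square vector magnitude, optionally restricted to a mask."""
        m2 = self.u ** 2 + self.v ** 2
        if mask is not None:
            m2 = m2[mask]
        if m2.size == 0:
            raise ValueError("empty region for RMS")
        return float(np.sqrt(np.nanmean(m2)))

    def scaled(self, factor: float) -> "GriddedVectorField":
        return replace(self, u=self.u * factor, v=self.v * factor)

    def interpolator(self, fill_value: float = 0.0):
        """Bilinear interpolators ``(fu, fv)`` taking points ``(y, x)`` in µm."""
        kw = dict(bounds_error=False, fill_value=fill_value, method="linear")
        fu = RegularGridInterpolator((self.y, self.x), self.u, **kw)
        fv = RegularGridInterpolator((self.y, self.x), self.v, **kw)
        return fu, fv

    def sample(self, xs: np.ndarray, ys: np.ndarray, fill_value: float = 0.0):
        """Sample (u, v) at physical points (µm)."""
        fu, fv = self.interpolator(fill_value)
        pts = np.column_stack([np.asarray(ys, float).ravel(),
                               np.asarray(xs, float).ravel()])
        return fu(pts).reshape(np.shape(xs)), fv(pts).reshape(np.shape(xs))


@dataclass
class StrainRateField:
    """In-plane strain-rate tensor on a grid (units 1/time).

    Only one shear component ``exy`` is stored, so the tensor is symmetric by
    construction.
    """

    x: np.ndarray
    y: np.ndarray
    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray
    units: str = "1/min"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        expected = (self.y.size, self.x.size)
        for name in ("exx", "eyy", "exy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != expected:
                raise ValueError(f"{name} must have shape {expected}")

    @property
    def trace(self) -> np.ndarray:
        """2-D trace exx + eyy (the in-plane dilation rate)."""
        return self.exx + self.eyy


@dataclass
class StressField:
    """In-plane symmetric stress tensor (Pa) on a grid.

    ``s1 >= s2`` are principal values and ``theta`` the orientation (radians,
    measured from +x toward +y) of the first principal direction; they are
    filled by :func:`islandmech.msm.principal_stresses`.
    """

    x: np.ndarray
    y: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    s1: Optional[np.ndarray] = None
    s2: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    units: str = "Pa"
    meta: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        expected = (self.y.size, self.x.size)
        for name in ("sxx", "syy", "sxy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != expected:
                raise ValueError(f"{name} must have shape {expected}")

    @property
    def spacing(self) -> tuple[float, float]:
        return float(self.x[1] - self.x[0]), float(self.y[1] - self.y[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.sxx.shape

    @property
    def tension(self) -> np.ndarray:
        """Contractile tension (σ1 + σ2)/2 = (σxx + σyy)/2, positive in tension."""
        return 0.5 * (self.sxx + self.syy)

    def scaled(self, factor: float) -> "StressField":
        out = replace(self, sxx=self.sxx * factor, syy=self.syy * factor,
                      sxy=self.sxy * factor)
        out.s1 = out.s2 = out.theta = None
        return out
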