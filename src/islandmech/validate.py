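"""Data-quality checks for processed islands.

Three reusable validation metrics for traction/stress measurements on
confined islands: (i) tractions should be confined to the cell-covered
region, quantified by the outside/inside RMS traction ratio; (ii) cells at a
free edge pull themselves toward the free space, so the mean radial traction
in the outer annulus should be negative (inward); (iii) the island-average
contractile tension should evolve smoothly and respond in the right
direction to contractility drugs, assessed on a series normalized by its
pre-treatment mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from typing import Optional

import numpy as np
from scipy import ndimage

from .domain import IslandDomain
from .fields import GriddedVectorField

__all__ = ["rms_traction_ratio", "edge_traction_sign", "TensionSeries",
           "normalize_tension", "island_report", "DEFAULT_REPORT_THRESHOLDS"]


def _region_masks(traction: GriddedVectorField, domain: IslandDomain,
                  margin: int) -> tuple[np.ndarray, np.ndarray]:
    mask = domain.mask_at(traction.x, traction.y)
    if margin > 0:
        inside = ndimage.binary_erosion(mask, iterations=margin)
        outside = ~ndimage.binary_dilation(mask, iterations=margin)
    else:
        inside, outside = mask, ~mask
    return inside, outside


def rms_traction_ratio(traction: GriddedVectorField, domain: IslandDomain,
                       margin: int = 2) -> float:
    """RMS traction outside the island divided by RMS traction inside.

    A ring of ``margin`` grid nodes around the mask boundary is excluded from
    both regions to avoid edge bleed (the exclusion width is a package
    default, configurable). Values near zero indicate tractions confined to
    the cells; the ratio is invariant to rescaling the traction field.
    """
    inside, outside = _region_masks(traction, domain, margin)
    if not inside.any() or not outside.any():
        raise ValueError("inside or outside region is empty; reduce the "
                         "margin or use a larger field of view")
    rms_in = traction.rms(inside)
    rms_out = traction.rms(outside)
    if rms_in == 0:
        raise ValueError("zero traction inside the island")
    return rms_out / rms_in


def edge_traction_sign(traction: GriddedVectorField, domain: IslandDomain,
                       annulus_fraction: float = 0.2) -> float:
    """Mean radial traction component in the outer annulus of the island.

    The annulus spans radii [ (1 - annulus_fraction)·R, R ]. Negative means
    the cells pull radially inward (the expected sign for a cohesive island
    tugging itself toward the free edge); positive means outward pushing.
    """
    r, rx, ry = domain.radial_coords(traction.x, traction.y)
    mask = domain.mask_at(traction.x, traction.y)
    R = domain.radius
    annulus = mask & (r >= (1.0 - annulus_fraction) * R) & (r <= R)
    if not annulus.any():
        raise ValueError("outer annulus contains no grid nodes")
    tr = traction.u * rx + traction.v * ry
    return float(tr[annulus].mean())


@dataclass
class TensionSeries:
    """Island-average contractile tension over time.

    ``time`` is in minutes with 0 at the treatment; ``tension`` in Pa;
    ``normalized`` (dimensionless) has pre-treatment mean 1 by construction
    once :func:`normalize_tension` has been applied.
    """

    time: np.ndarray
    tension: np.ndarray
    normalized: Optional[np.ndarray] = None
    meta: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.tension = np.asarray(self.tension, dtype=float)
        if self.time.shape != self.tension.shape:
            raise ValueError("time and tension must have the same length")


def normalize_tension(series: TensionSeries,
                      treatment_time: float = 0.0) -> TensionSeries:
    """Divide the series by its mean over samples before the treatment.

    Requires at least one sample with t < treatment_time. Idempotent: applying
    it to an already-normalized series returns the same values.
    """
    pre = series.time < treatment_time
    if not pre.any():
        raise ValueError("no samples before the treatment time; cannot "
                         "normalize")
    baseline = float(series.tension[pre].mean())
    if baseline == 0:
        raise ValueError("pre-treatment mean tension is zero")
    return TensionSeries(series.time, series.tension / baseline,
                         normalized=series.tension / baseline,
                         meta=dict(series.meta, baseline_Pa=baseline,
                                   treatment_time=treatment_time))


DEFAULT_REPORT_THRESHOLDS = dict(
    # leakage bound for the full image-correlation pipeline: subset DIC
    # jitter (~0.02 px) is amplified by the kernel inverse at the grid
    # Nyquist, giving an expected outside/inside ratio of a few percent
    max_rms_traction_ratio=0.1,
    # cohesive islands pull inward and are under tension
    max_edge_radial_traction=0.0,
    min_contractile_tension=0.0,
)


def island_report(traction: GriddedVectorField, domain: IslandDomain,
                  tension_average: float, margin: int = 2,
                  thresholds: Optional[dict] = None) -> dict:
    """Bundle the validation metrics for a processed island into a report.

    Returns a JSON-serializable dict with each metric, its threshold and a
    pass flag, plus an overall ``passed``.
    """
    th = dict(DEFAULT_REPORT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    ratio = rms_traction_ratio(traction, domain, margin=margin)
    edge = edge_traction_sign(traction, domain)
    checks = {
        "rms_traction_ratio": dict(
            value=ratio, threshold=th["max_rms_traction_ratio"],
            passed=bool(ratio < th["max_rms_traction_ratio"])),
        "edge_radial_traction_Pa": dict(
            value=edge, threshold=th["max_edge_radial_traction"],
            passed=bool(edge < th["max_edge_radial_traction"])),
        "contractile_tension_Pa": dict(
            value=float(tension_average),
            threshold=th["min_contractile_tension"],
            passed=bool(tension_average > th["min_contractile_tension"])),
    }
    return dict(checks=checks,
                passed=bool(all(c["passed"] for c in checks.values())))
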