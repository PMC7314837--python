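"""Velocity-field post-processing: radial decomposition and trajectories."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain import IslandDomain
from .fields import GriddedVectorField

__all__ = ["radial_component", "TrajectorySet", "compute_trajectories",
           "default_seeds"]


def radial_component(field: GriddedVectorField,
                     center: tuple[float, float],
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Radial and tangential components about a centre point (µm).

    v_r = v·r̂ with r̂ the unit vector from the centre; positive outward.
    v_t = v·t̂ with t̂ = (−r̂_y, r̂_x) (90° counterclockwise in image
    coordinates). At the centre node both are zero by convention, and
    v_r² + v_t² = |v|² elsewhere.
    """
    cx, cy = center
    if not (field.x[0] <= cx <= field.x[-1] and field.y[0] <= cy <= field.y[-1]):
        raise ValueError("center must lie inside the grid")
    X, Y = np.meshgrid(field.x - cx, field.y - cy)
    r = np.hypot(X, Y)
    rx = np.where(r > 0, X / np.maximum(r, 1e-300), 0.0)
    ry = np.where(r > 0, Y / np.maximum(r, 1e-300), 0.0)
    vr = field.u * rx + field.v * ry
    vt = -field.u * ry + field.v * rx
    return vr, vt


@dataclass
class TrajectorySet:
    """Integrated seed-point trajectories.

    ``times[i]`` and ``points[i]`` hold the (strictly increasing) time stamps
    (min) and (x, y) positions (µm) of trajectory i; ``exited[i]`` flags
    trajectories truncated for leaving the island mask.
    """

    times: list[np.ndarray]
    points: list[np.ndarray]
    exited: list[bool]
    seed_meta: dict = _dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table with columns (trajectory_id, t, x, y, exited)."""
        rows = []
        for tid, (t, p, ex) in enumerate(zip(self.times, self.points,
                                             self.exited)):
            for ti, (xi, yi) in zip(t, p):
                rows.append((tid, ti, xi, yi, ex))
        return pd.DataFrame(rows, columns=["trajectory_id", "t", "x", "y",
                                           "exited"])


def default_seeds(field: GriddedVectorField, domain: IslandDomain,
                  stride: int = 4) -> np.ndarray:
    """Every ``stride``-th grid node inside the mask, as (N, 2) µm points."""
    xs = field.x[::stride]
    ys = field.y[::stride]
    X, Y = np.meshgrid(xs, ys)
    inside = domain.mask_at(xs, ys)
    return np.column_stack([X[inside], Y[inside]])


def compute_trajectories(velocity_sequence: Sequence[GriddedVectorField],
                         seeds: np.ndarray, dt: float,
                         domain: Optional[IslandDomain] = None,
                         ) -> TrajectorySet:
    """Integrate seed points through a sequence of velocity fields.

    Forward Euler with one step per frame — x(t+dt) = x(t) + dt·v(x(t), t) —
    using bilinear interpolation of the frame's field at off-grid positions
    and piecewise-constant velocity in time. Higher-order schemes would
    pretend to information between the 10-minute frames. Seeds outside the
    grid are skipped with a warning; trajectories that leave the island mask
    (when a domain is given) or the grid are truncated and flagged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.shape[1] != 2:
        raise ValueError("seeds must be (N, 2) points")
    f0 = velocity_sequence[0]
    xmin, xmax = f0.x[0], f0.x[-1]
    ymin, ymax = f0.y[0], f0.y[-1]

    interps = [f.interpolator(fill_value=np.nan) for f in velocity_sequence]

    times, points, exited = [], [], []
    for sx, sy in seeds:
        if not (xmin <= sx <= xmax and ymin <= sy <= ymax):
            warnings.warn(f"seed ({sx:.1f}, {sy:.1f}) outside the grid; "
                          "skipped", stacklevel=2)
            continue
        t = [0.0]
        pos = [(sx, sy)]
        flag = False
        x, y = sx, sy
        for k, (fu, fv) in enumerate(interps):
            vx = float(fu([[y, x]])[0])
            vy = float(fv([[y, x]])[0])
            if not (np.isfinite(vx) and np.isfinite(vy)):
                flag = True
                break
            x = x + dt * vx
            y = y + dt * vy
            if not (xmin <= x <= xmax and ymin <= y <= ymax):
                flag = True
                break
            if domain is not None and not domain.mask_at(
                    np.array([x]), np.array([y]))[0, 0]:
                flag = True
                break
            t.append((k + 1) * dt)
            pos.append((x, y))
        times.append(np.asarray(t))
        points.append(np.asarray(pos))
        exited.append(flag)
    return TrajectorySet(times, points, exited,
                         seed_meta=dict(n_seeds=len(seeds), dt=dt))
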