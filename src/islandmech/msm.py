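"""Monolayer stress microscopy: plane-stress finite-element stress recovery.

The in-plane stress tensor of the cell sheet is recovered from the measured
cell-substrate tractions by enforcing force balance, ∇·σ = T/h, closed by
compatibility and a linear constitutive law. The domain is meshed with
bilinear quadrilateral (Q4) plane-stress elements, one per traction-grid
cell inside the island mask, and the linear system K u = f is solved with a
sparse direct factorization. Because stresses are obtained by applying K
after applying K⁻¹, the overall magnitude (and units, and sign) of the
constitutive constants cancels: only the dimensionless Poisson-like ratio
ν_m enters, and its influence is modest. The tractions must be in force and
moment equilibrium before solving — three Dirichlet constraints (vertical
motion pinned at the leftmost node, both components at the rightmost node)
then merely remove the rigid modes and do not load the island, which is why
relocating them leaves the stresses unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dc_field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu

from .domain import IslandDomain, Monolayer
from .fields import GriddedVectorField, StressField

__all__ = ["FEMesh", "build_mesh", "mesh_from_node_mask", "solve_stress",
           "principal_stresses", "contractile_tension", "element_to_node_stress"]

_BALANCE_TOL = 1e-6


@dataclass
class FEMesh:
    """Q4 mesh covering the island.

    Element centres coincide with the traction-grid sample sites (``x_sites``
    × ``y_sites``, subset ``site_mask``); element corners are the FEM nodes.
    """

    nodes: np.ndarray          # (Nn, 2) µm
    elements: np.ndarray       # (Ne, 4) node ids, corners (-,-),(+,-),(+,+),(-,+)
    elem_sites: np.ndarray     # (Ne, 2) (row, col) site index of each element
    site_mask: np.ndarray      # (nys, nxs) bool, retained elements
    x_sites: np.ndarray        # (nxs,) µm
    y_sites: np.ndarray        # (nys,) µm
    spacing: float             # element side, µm
    meta: dict = _dc_field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def mesh_from_node_mask(site_mask: np.ndarray, x: np.ndarray,
                        y: np.ndarray, spacing: Optional[float] = None,
                        ) -> FEMesh:
    """Mesh an arbitrary boolean site mask on a regular grid.

    Each True site becomes one square element centred on it. If the retained
    sites are disconnected, the largest 4-connected component is kept with a
    warning. ``spacing`` (element side, µm) is inferred from the coordinate
    vectors when they have more than one entry; a single-site mesh needs it
    passed explicitly (default 1).
    """
    site_mask = np.asarray(site_mask, dtype=bool)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not site_mask.any():
        raise ValueError("mask is empty: nothing to mesh")
    if site_mask.shape != (y.size, x.size):
        raise ValueError("site_mask shape must match the coordinate vectors")
    if x.size > 1:
        a = float(x[1] - x[0])
    elif y.size > 1:
        a = float(y[1] - y[0])
    else:
        a = float(spacing) if spacing else 1.0

    labels, n_comp = ndimage.label(site_mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(site_mask, labels, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(f"mask has {n_comp} connected components; keeping the "
                      "largest", stacklevel=2)
        site_mask = labels == keep

    nys, nxs = site_mask.shape
    # corner lattice (nys+1, nxs+1); mark corners adjacent to retained elements
    corner_used = np.zeros((nys + 1, nxs + 1), dtype=bool)
    ei, ej = np.nonzero(site_mask)
    for di in (0, 1):
        for dj in (0, 1):
            corner_used[ei + di, ej + dj] = True
    node_id = -np.ones((nys + 1, nxs + 1), dtype=int)
    node_id[corner_used] = np.arange(corner_used.sum())

    cx = np.concatenate([x - a / 2, [x[-1] + a / 2]]) if x.size > 1 else \
        np.array([x[0] - a / 2, x[0] + a / 2])
    cy = np.concatenate([y - a / 2, [y[-1] + a / 2]]) if y.size > 1 else \
        np.array([y[0] - a / 2, y[0] + a / 2])
    CI, CJ = np.nonzero(corner_used)
    nodes = np.column_stack([cx[CJ], cy[CI]])

    elements = np.column_stack([
        node_id[ei, ej], node_id[ei, ej + 1],
        node_id[ei + 1, ej + 1], node_id[ei + 1, ej]])
    return FEMesh(nodes=nodes, elements=elements,
                  elem_sites=np.column_stack([ei, ej]),
                  site_mask=site_mask, x_sites=x, y_sites=y, spacing=a)


def build_mesh(domain: IslandDomain, spacing: int = 1) -> FEMesh:
    """Mesh the island mask with one Q4 element per retained grid cell.

    ``spacing`` subsamples the pixel grid (element size = spacing × pixel
    size), matching the traction-grid resolution.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1 pixel")
    x, y = domain.grid()
    return mesh_from_node_mask(domain.mask[::spacing, ::spacing],
                               x[::spacing], y[::spacing])


# ---------------------------------------------------------------------------
# element matrices

def _constitutive(nu_m: float, scale: float = 1.0) -> np.ndarray:
    """Plane-stress constitutive matrix for Voigt (εxx, εyy, γxy).

    Parameterized by the Poisson-like ratio ν_m and an arbitrary stiffness
    scale (which cancels from the recovered stresses). Equivalent to the
    (K1, K2) pair through A = K1 − 2/3·K2 = 2·K2·ν_m/(1 − ν_m).
    """
    if not -1.0 < nu_m < 1.0:
        raise ValueError("ratio_nu_m must lie in (-1, 1)")
    K2 = scale
    A = 2.0 * K2 * nu_m / (1.0 - nu_m)
    return np.array([[A + 2 * K2, A, 0.0],
                     [A, A + 2 * K2, 0.0],
                     [0.0, 0.0, K2]])


def _shape_gradients(xi: float, eta: float, a: float):
    dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    return dN_dxi * (2.0 / a), dN_deta * (2.0 / a)


def _b_matrix(dndx: np.ndarray, dndy: np.ndarray) -> np.ndarray:
    B = np.zeros((3, 8))
    B[0, 0::2] = dndx
    B[1, 1::2] = dndy
    B[2, 0::2] = dndy
    B[2, 1::2] = dndx
    return B


def _q4_stiffness(D: np.ndarray, a: float) -> np.ndarray:
    """8x8 plane-stress stiffness of a square Q4 element (2x2 Gauss)."""
    g = 1.0 / np.sqrt(3.0)
    Ke = np.zeros((8, 8))
    for xi in (-g, g):
        for eta in (-g, g):
            B = _b_matrix(*_shape_gradients(xi, eta, a))
            Ke += B.T @ D @ B * (a / 2.0) ** 2
    return Ke


_M_CONSISTENT = np.array([[4, 2, 1, 2],
                          [2, 4, 2, 1],
                          [1, 2, 4, 2],
                          [2, 1, 2, 4]]) / 36.0


# ---------------------------------------------------------------------------
# solve

def _check_balance(tx: np.ndarray, ty: np.ndarray, xs: np.ndarray,
                   ys: np.ndarray) -> None:
    n = tx.size
    rms = np.sqrt(np.mean(tx ** 2 + ty ** 2))
    if rms == 0:
        return
    xt = xs - xs.mean()
    yt = ys - ys.mean()
    f_rel = np.hypot(tx.sum(), ty.sum()) / (n * rms)
    rg = np.sqrt(np.mean(xt ** 2 + yt ** 2))
    m_rel = abs(np.sum(xt * ty - yt * tx)) / (n * rms * max(rg, 1e-12))
    if f_rel > _BALANCE_TOL or m_rel > _BALANCE_TOL:
        raise ValueError(
            f"traction field is not in equilibrium (net force {f_rel:.2e}, "
            f"net moment {m_rel:.2e} of the RMS traction scale, tolerance "
            f"{_BALANCE_TOL:.0e}); run enforce_equilibrium first")


def _default_bc(mesh: FEMesh) -> list[tuple[int, int]]:
    """(node, dof) constraints: uy at the leftmost node, ux and uy at the
    rightmost node (dof 0 = x, 1 = y)."""
    nodes = mesh.nodes
    order_left = np.lexsort((nodes[:, 1], nodes[:, 0]))
    left = int(order_left[0])
    right = int(order_left[-1])
    return [(left, 1), (right, 0), (right, 1)]


def _project_rigid(f: np.ndarray, nodes: np.ndarray) -> float:
    """Remove net force and net moment from a nodal force vector.

    Returns the relative magnitude of the removed part. The removed residual
    comes from interpolating tractions onto the nodes and is O(grid²); after
    projection the Dirichlet pins carry exactly zero reaction.
    """
    fx, fy = f[0::2], f[1::2]
    n = len(nodes)
    xt = nodes[:, 0] - nodes[:, 0].mean()
    yt = nodes[:, 1] - nodes[:, 1].mean()
    norm = np.linalg.norm(f)
    fx -= fx.sum() / n
    fy -= fy.sum() / n
    r2 = np.sum(xt ** 2 + yt ** 2)
    beta = np.sum(xt * fy - yt * fx) / r2
    fx += beta * yt
    fy -= beta * xt
    removed = np.sqrt(max(norm ** 2 - np.linalg.norm(f) ** 2, 0.0))
    return removed / norm if norm > 0 else 0.0


def solve_stress(traction: GriddedVectorField, mesh: FEMesh,
                 monolayer: Monolayer,
                 ratio_nu_m: Optional[float] = None,
                 load_scheme: str = "lumped",
                 bc_nodes: Optional[list[tuple[int, int]]] = None,
                 traction_fn=None,
                 ) -> StressField:
    """Recover the monolayer stress tensor from balanced tractions.

    Assembles the plane-stress stiffness from the monolayer's constitutive
    pair (or the override ``ratio_nu_m``), loads the nodes from −T/h (``T``
    is the cells-on-substrate traction, so −T/h is the in-plane body force
    the substrate exerts on the sheet), pins three degrees of freedom, solves
    K u = f, and evaluates element stresses at the element centres — which
    coincide with the traction-grid sites.

    ``load_scheme``: the default "lumped" assigns each element's total force
    T·a² in tributary quarters to its corners — which is exactly the
    consistent load vector for the piecewise-constant (cell-centred)
    representation the traction samples natively have, and on convergence
    benchmarks it is the more accurate choice. "consistent" first
    interpolates tractions to the nodes and integrates the bilinear
    interpolant against the shape functions; the extra interpolation acts as
    a smoothing half-step. When the traction is known in closed form,
    ``traction_fn(X, Y) -> (Tx, Ty)`` switches to 2x2 Gauss quadrature of
    the load (used by synthetic benchmarks; measured tractions have no
    closed form).
    """
    if load_scheme not in ("consistent", "lumped"):
        raise ValueError("load_scheme must be 'consistent' or 'lumped'")
    if not (np.allclose(traction.x, mesh.x_sites)
            and np.allclose(traction.y, mesh.y_sites)):
        raise ValueError("traction grid does not match the mesh sites")

    ei, ej = mesh.elem_sites[:, 0], mesh.elem_sites[:, 1]
    tx = traction.u[ei, ej]
    ty = traction.v[ei, ej]
    X, Y = np.meshgrid(mesh.x_sites, mesh.y_sites)
    _check_balance(tx, ty, X[ei, ej], Y[ei, ej])

    nu = monolayer.nu_m if ratio_nu_m is None else float(ratio_nu_m)
    D = _constitutive(nu, scale=monolayer.K2)
    a = mesh.spacing
    h = monolayer.height_h
    Ne, Nn = mesh.n_elements, mesh.n_nodes

    f = np.zeros(2 * Nn)
    if traction_fn is not None:
        # exact consistent load: 2x2 Gauss quadrature of the closed-form
        # traction over each element
        g = 1.0 / np.sqrt(3.0)
        xc = X[ei, ej]
        yc = Y[ei, ej]
        corners = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], dtype=float)
        for xi, eta in ((-g, -g), (g, -g), (g, g), (-g, g)):
            gx = xc + xi * a / 2.0
            gy = yc + eta * a / 2.0
            tgx, tgy = traction_fn(gx, gy)
            N = 0.25 * (1 + corners[:, 0] * xi) * (1 + corners[:, 1] * eta)
            for c in range(4):
                np.add.at(f, 2 * mesh.elements[:, c],
                          N[c] * (-tgx / h) * (a / 2.0) ** 2)
                np.add.at(f, 2 * mesh.elements[:, c] + 1,
                          N[c] * (-tgy / h) * (a / 2.0) ** 2)
    else:
        # nodal body force: average -T/h of the elements touching a node
        bx_sum = np.zeros(Nn)
        by_sum = np.zeros(Nn)
        cnt = np.zeros(Nn)
        for c in range(4):
            nid = mesh.elements[:, c]
            np.add.at(bx_sum, nid, -tx / h)
            np.add.at(by_sum, nid, -ty / h)
            np.add.at(cnt, nid, 1.0)
        bxn = bx_sum / cnt
        byn = by_sum / cnt
        bx_e = bxn[mesh.elements]            # (Ne, 4)
        by_e = byn[mesh.elements]
        if load_scheme == "consistent":
            fe_x = bx_e @ _M_CONSISTENT.T * a ** 2
            fe_y = by_e @ _M_CONSISTENT.T * a ** 2
        else:
            fe_x = bx_e * (a ** 2 / 4.0)
            fe_y = by_e * (a ** 2 / 4.0)
        np.add.at(f, 2 * mesh.elements, fe_x)
        np.add.at(f, 2 * mesh.elements + 1, fe_y)
    load_residual = _project_rigid(f, mesh.nodes)

    Ke = _q4_stiffness(D, a)
    dofs = np.empty((Ne, 8), dtype=int)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    data = np.tile(Ke.ravel(), Ne)
    K = sparse.coo_matrix((data, (rows, cols)),
                          shape=(2 * Nn, 2 * Nn)).tocsc()

    bc = bc_nodes if bc_nodes is not None else _default_bc(mesh)
    if len(bc) < 3:
        raise ValueError("at least three Dirichlet constraints are required")
    fixed = np.array(sorted({2 * n + d for n, d in bc}), dtype=int)
    free = np.setdiff1d(np.arange(2 * Nn), fixed)
    lu = splu(K[np.ix_(free, free)])
    u = np.zeros(2 * Nn)
    u[free] = lu.solve(f[free])

    # element-centre stresses
    B0 = _b_matrix(*_shape_gradients(0.0, 0.0, a))
    ue = u[dofs]                          # (Ne, 8)
    sig = ue @ (D @ B0).T                 # (Ne, 3)

    nys, nxs = mesh.site_mask.shape
    out = {k: np.full((nys, nxs), np.nan) for k in ("sxx", "syy", "sxy")}
    out["sxx"][ei, ej] = sig[:, 0]
    out["syy"][ei, ej] = sig[:, 1]
    out["sxy"][ei, ej] = sig[:, 2]
    meta = dict(ratio_nu_m=nu, height_um=h, load_scheme=load_scheme,
                bc=[(int(n), int(d)) for n, d in bc],
                load_projection_residual=load_residual,
                n_elements=Ne, n_nodes=Nn)
    field = StressField(mesh.x_sites, mesh.y_sites, out["sxx"], out["syy"],
                        out["sxy"], meta=meta)
    field.meta["solution"] = u
    return field


def element_to_node_stress(mesh: FEMesh, stress: StressField) -> np.ndarray:
    """Arithmetic average of adjacent element stresses at each node.

    Returns an (Nn, 3) array of (σxx, σyy, σxy)."""
    ei, ej = mesh.elem_sites[:, 0], mesh.elem_sites[:, 1]
    sig = np.column_stack([stress.sxx[ei, ej], stress.syy[ei, ej],
                           stress.sxy[ei, ej]])
    acc = np.zeros((mesh.n_nodes, 3))
    cnt = np.zeros(mesh.n_nodes)
    for c in range(4):
        nid = mesh.elements[:, c]
        np.add.at(acc, nid, sig)
        np.add.at(cnt, nid, 1.0)
    return acc / cnt[:, None]


def principal_stresses(stress: StressField) -> StressField:
    """Principal values σ1 ≥ σ2 and orientation of the 2x2 stress tensor.

    θ is the angle of the first principal direction (radians from +x); the
    degenerate isotropic case returns θ = 0. The (σ1, σ2, θ) triple is the
    stress-ellipse descriptor: major axis ∝ |σ1|, minor ∝ |σ2|, tilt θ.
    """
    mean = 0.5 * (stress.sxx + stress.syy)
    half_diff = 0.5 * (stress.sxx - stress.syy)
    radius = np.hypot(half_diff, stress.sxy)
    s1 = mean + radius
    s2 = mean - radius
    theta = 0.5 * np.arctan2(2.0 * stress.sxy, stress.sxx - stress.syy)
    return replace(stress, s1=s1, s2=s2, theta=theta)


def contractile_tension(stress: StressField,
                        mask: Optional[np.ndarray] = None,
                        ) -> tuple[np.ndarray, float]:
    """Contractile tension (σ1 + σ2)/2 per node and its island average.

    Equal to (σxx + σyy)/2 by trace invariance, so it does not require the
    principal decomposition. Elements all have the same area, so the island
    average is the plain mean over valid (or masked) sites.
    """
    tension = stress.tension
    if mask is None:
        mask = np.isfinite(tension)
    vals = tension[mask & np.isfinite(tension)]
    if vals.size == 0:
        raise ValueError("no valid sites for the island average")
    return tension, float(vals.mean())
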