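"""Shared fixtures: a half-resolution synthetic island reused across tests.

The session-scoped fixtures keep the expensive pieces (FEM solve, speckle
rendering) to one computation each; tests must not mutate them.
"""
import numpy as np
import pytest

import islandmech as im
from islandmech.synthetic import FluctuationSolution

# half-resolution desk island: same physical geometry as the 256² default
N = 128
PIXEL = 166.4 / N          # µm/px
RADIUS = 52.0              # µm
CORR_LEN = 13.0            # µm
SEED = 2


@pytest.fixture(scope="session")
def domain():
    return im.make_island(RADIUS, PIXEL, N)


@pytest.fixture(scope="session")
def monolayer():
    return im.Monolayer()


@pytest.fixture(scope="session")
def substrate():
    return im.Substrate()


@pytest.fixture(scope="session")
def fluct(domain, monolayer):
    """Exact-chain random benchmark: (solution, velocity, strain rate,
    stress, balanced traction)."""
    sol = FluctuationSolution(domain, monolayer, amplitude=0.2,
                              correlation_length=CORR_LEN, seed=SEED)
    velocity, strain_rate, stress, traction = sol.fields()
    traction, _ = im.enforce_equilibrium(traction, domain)
    return sol, velocity, strain_rate, stress, traction


@pytest.fixture(scope="session")
def mesh(domain):
    return im.build_mesh(domain)


@pytest.fixture(scope="session")
def recovered(fluct, mesh, monolayer):
    """FEM-recovered stress for the random benchmark."""
    _, _, _, _, traction = fluct
    return im.solve_stress(traction, mesh, monolayer)


@pytest.fixture(scope="session")
def island(monolayer, substrate):
    """Full contractile synthetic island (no speckle, for speed)."""
    return im.synthesize_island(n=N, pixel_size=PIXEL, radius_um=RADIUS,
                                monolayer=monolayer, substrate=substrate,
                                seed=1, render_speckle=False)


def rel_rms(a, b, mask=None):
    """Relative RMS difference of two arrays (NaN-aware)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if mask is not None:
        a, b = a[mask], b[mask]
    return float(np.sqrt(np.nanmean((a - b) ** 2))
                 / np.sqrt(np.nanmean(b ** 2)))


def stress_rel_rms(st, gt):
    """Relative RMS error of a recovered stress tensor against ground truth."""
    m = np.isfinite(st.sxx)
    num = np.sqrt(np.nanmean((st.sxx - gt.sxx)[m] ** 2
                             + (st.syy - gt.syy)[m] ** 2
                             + (st.sxy - gt.sxy)[m] ** 2))
    den = np.sqrt(np.nanmean(gt.sxx[m] ** 2 + gt.syy[m] ** 2
                             + gt.sxy[m] ** 2))
    return float(num / den)
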