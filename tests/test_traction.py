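"""Half-space traction microscopy: kernel, inversion, equilibrium."""
import numpy as np
import pytest

import islandmech as im
from islandmech.fields import GriddedVectorField
from islandmech.traction import (boussinesq_displacement_direct,
                                 enforce_equilibrium, fttc_forward,
                                 fttc_inverse)
from conftest import rel_rms


def _gaussian_dipole(n=96, sep=8.0, sigma=2.5, amp=50.0):
    """Force-balanced traction: two opposite Gaussian spots (zero net force,
    zero net moment), so the far field decays fast enough for periodic FFTs
    and real-space sums to agree."""
    x = np.arange(n, dtype=float)
    X, Y = np.meshgrid(x, x)
    c = n / 2
    g1 = np.exp(-((X - c + sep / 2) ** 2 + (Y - c) ** 2) / (2 * sigma ** 2))
    g2 = np.exp(-((X - c - sep / 2) ** 2 + (Y - c) ** 2) / (2 * sigma ** 2))
    tx = amp * (g1 - g2)
    ty = np.zeros_like(tx)
    return GriddedVectorField(x, x, tx, ty, units="Pa")


class TestForward:
    def test_zero_traction_zero_displacement(self, substrate):
        x = np.arange(64.0)
        z = np.zeros((64, 64))
        u = fttc_forward(GriddedVectorField(x, x, z, z, units="Pa"),
                         substrate)
        assert not u.u.any() and not u.v.any()

    def test_linear_in_traction(self, substrate):
        T = _gaussian_dipole()
        u1 = fttc_forward(T, substrate)
        u2 = fttc_forward(T.scaled(2.0), substrate)
        assert np.allclose(u2.u, 2 * u1.u)

    def test_stiffer_substrate_smaller_displacement(self):
        T = _gaussian_dipole()
        soft = im.Substrate(youngs_modulus_E=6000.0)
        stiff = im.Substrate(youngs_modulus_E=12000.0)
        u_soft = fttc_forward(T, soft)
        u_stiff = fttc_forward(T, stiff)
        assert np.allclose(u_soft.u, 2 * u_stiff.u)

    def test_matches_real_space_greens_function(self, substrate):
        # independent oracle: direct convolution with the Boussinesq surface
        # Green's function, sampled beyond three spot widths
        T = _gaussian_dipole()
        u = fttc_forward(T, substrate, pad=4)
        c = 48.0
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, 120)
        rad = rng.uniform(8.0, 30.0, 120)
        pts = np.column_stack([c + rad * np.cos(ang), c + rad * np.sin(ang)])
        direct = boussinesq_displacement_direct(T, substrate, pts)
        ju = np.clip(np.round(pts[:, 0]).astype(int), 0, 95)
        iv = np.clip(np.round(pts[:, 1]).astype(int), 0, 95)
        pts_i = np.column_stack([ju.astype(float), iv.astype(float)])
        direct_i = boussinesq_displacement_direct(T, substrate, pts_i)
        fft_vals = np.column_stack([u.u[iv, ju], u.v[iv, ju]])
        scale = np.sqrt(np.mean(direct_i ** 2))
        err = np.sqrt(np.mean((fft_vals - direct_i) ** 2))
        assert err < 0.02 * scale

    def test_missing_values_rejected(self, substrate):
        T = _gaussian_dipole()
        T.u[3, 3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fttc_forward(T, substrate)


class TestInverse:
    def test_roundtrip_identity(self, substrate, fluct, domain):
        _, _, _, _, traction = fluct
        disp = fttc_forward(traction, substrate)
        back = fttc_inverse(disp, substrate)
        err = np.sqrt(np.mean((back.u - traction.u) ** 2
                              + (back.v - traction.v) ** 2))
        assert err < 1e-8 * traction.rms()

    def test_zero_displacement_zero_traction(self, substrate):
        x = np.arange(64.0)
        z = np.zeros((64, 64))
        T = fttc_inverse(GriddedVectorField(x, x, z, z), substrate)
        assert not T.u.any()

    def test_incompressible_limit_invertible(self):
        sub = im.Substrate(poisson_ratio=0.5)
        T = _gaussian_dipole()
        back = fttc_inverse(fttc_forward(T, sub), sub)
        assert rel_rms(back.u, T.u) < 1e-8

    def test_regularization_beats_none_under_noise(self, substrate):
        T = _gaussian_dipole(amp=50.0)
        disp = fttc_forward(T, substrate)
        scale = np.abs(disp.u).max()
        lams = [3e-5, 1e-4, 3e-4]
        gains = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            noisy = GriddedVectorField(
                disp.x, disp.y,
                disp.u + 0.05 * scale * rng.standard_normal(disp.shape),
                disp.v + 0.05 * scale * rng.standard_normal(disp.shape))
            def err(lam):
                back = fttc_inverse(noisy, substrate,
                                    regularization_lambda=lam)
                return np.sqrt(np.mean((back.u - T.u) ** 2
                                       + (back.v - T.v) ** 2))
            gains.append(min(err(l) for l in lams) <= err(0.0))
        assert all(gains)

    def test_negative_lambda_rejected(self, substrate):
        T = _gaussian_dipole()
        with pytest.raises(ValueError):
            fttc_inverse(T, substrate, regularization_lambda=-1.0)

    def test_localization_noise_free(self, fluct, domain, substrate):
        # tractions recovered from the exact forward displacement stay
        # confined to the island
        _, _, _, _, traction = fluct
        disp = fttc_forward(traction, substrate)
        back = fttc_inverse(disp, substrate)
        assert im.rms_traction_ratio(back, domain) < 0.01


class TestEquilibrium:
    def test_balanced_field_unchanged(self, fluct, domain):
        _, _, _, _, traction = fluct
        out, report = enforce_equilibrium(traction, domain)
        assert report["correction_rms"] < 1e-12 * traction.rms()
        assert np.allclose(out.u, traction.u, atol=1e-12)

    def test_uniform_offset_removed_exactly(self, fluct, domain):
        _, _, _, _, traction = fluct
        mask = domain.mask_at(traction.x, traction.y)
        biased = GriddedVectorField(traction.x, traction.y,
                                    traction.u + 7.5 * mask,
                                    traction.v - 3.25 * mask, units="Pa")
        out, report = enforce_equilibrium(biased, domain)
        assert np.allclose(out.u[mask], traction.u[mask], atol=1e-9)
        assert np.allclose(out.v[mask], traction.v[mask], atol=1e-9)

    def test_rotational_moment_removed(self, domain):
        # a solid-rotation-like tangential field carries pure moment
        x, y = domain.grid()
        r, rx, ry = domain.radial_coords()
        tx = -ry * r * domain.mask
        ty = rx * r * domain.mask
        T = GriddedVectorField(x, y, tx, ty, units="Pa")
        out, report = enforce_equilibrium(T, domain)
        assert abs(report["net_moment_after"]) \
            < 1e-10 * abs(report["net_moment_before"])

    def test_empty_mask_rejected(self, fluct):
        _, _, _, _, traction = fluct
        tiny = im.IslandDomain.__new__(im.IslandDomain)
        tiny.mask = np.zeros((128, 128), bool)
        tiny.center = (0.0, 0.0)
        tiny.radius = 1.0
        tiny.pixel_size = 1.3
        with pytest.raises(ValueError, match="empty"):
            enforce_equilibrium(traction, tiny)


class TestUnits:
    def test_resolution_independence(self, substrate):
        # the same physical traction sampled at two resolutions produces the
        # same physical displacement field within discretization error
        def make(n):
            x = np.arange(n) * (96.0 / n)
            X, Y = np.meshgrid(x, x)
            sigma, c = 6.0, 48.0
            g1 = np.exp(-((X - c + 6) ** 2 + (Y - c) ** 2) / (2 * sigma ** 2))
            g2 = np.exp(-((X - c - 6) ** 2 + (Y - c) ** 2) / (2 * sigma ** 2))
            return GriddedVectorField(x, x, 50 * (g1 - g2),
                                      np.zeros((n, n)), units="Pa")
        u64 = fttc_forward(make(64), substrate)
        u128 = fttc_forward(make(128), substrate)
        assert rel_rms(u128.u[::2, ::2], u64.u) < 0.05
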