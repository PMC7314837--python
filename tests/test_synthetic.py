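"""Generator module: geometry, random fields, constitutive chain, speckle."""
import numpy as np
import pytest

import islandmech as im
from islandmech.synthetic import (FluctuationSolution,
                                  axisymmetric_contractile_solution,
                                  compatibility_residual, render_speckle_pair,
                                  sample_velocity_field,
                                  strain_rate_from_velocity,
                                  stress_from_strainrate,
                                  traction_from_stress)
from conftest import rel_rms


class TestMakeIsland:
    def test_mask_area_matches_circle(self):
        dom = im.make_island(50.0, 1.0, 200)
        assert abs(dom.mask.sum() - np.pi * 50 ** 2) < 0.05 * np.pi * 50 ** 2

    def test_center_inside_mask(self):
        dom = im.make_island(30.0, 0.65, 128)
        cx, cy = dom.center
        j, i = round(cx / 0.65), round(cy / 0.65)
        assert dom.mask[i, j]

    def test_island_touching_frame_rejected(self):
        # radius = half the image extent leaves no margin
        with pytest.raises(ValueError, match="margin"):
            im.make_island(64.0, 1.0, 128)

    def test_margin_requirement(self):
        # 10% margin: radius up to 0.4 * image size is fine, beyond is not
        im.make_island(51.0, 1.0, 128)
        with pytest.raises(ValueError):
            im.make_island(52.0, 1.0, 128)

    def test_zeros_surround_island(self):
        dom = im.make_island(40.0, 1.0, 128)
        assert not dom.mask[:10].any() and not dom.mask[:, :10].any()


class TestMonolayer:
    def test_nu_roundtrip(self):
        ml = im.Monolayer.from_nu(0.37)
        assert ml.nu_m == pytest.approx(0.37, abs=1e-12)

    def test_default_ratio_is_half(self):
        assert im.Monolayer().nu_m == pytest.approx(0.5)

    @pytest.mark.parametrize("kwargs", [dict(height_h=0.0),
                                        dict(K2=-1.0),
                                        dict(K1=-5000.0, K2=1000.0)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            im.Monolayer(**kwargs)


class TestSampleVelocityField:
    def test_zero_amplitude_gives_zero_field(self, domain):
        v = sample_velocity_field(domain, 0.0, 13.0, seed=0)
        assert not v.u.any() and not v.v.any()

    def test_negative_amplitude_rejected(self, domain):
        with pytest.raises(ValueError):
            sample_velocity_field(domain, -0.1, 13.0, seed=0)

    def test_short_correlation_length_rejected(self, domain):
        with pytest.raises(ValueError, match="grid spacings"):
            sample_velocity_field(domain, 0.1, 0.5 * domain.pixel_size,
                                  seed=0)

    def test_deterministic_given_seed(self, domain):
        a = sample_velocity_field(domain, 0.2, 13.0, seed=7)
        b = sample_velocity_field(domain, 0.2, 13.0, seed=7)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)

    def test_zero_outside_mask(self, domain):
        v = sample_velocity_field(domain, 0.2, 13.0, seed=3)
        outside = ~domain.mask
        scale = np.abs(v.u).max()
        assert np.abs(v.u[outside]).max() < 1e-15 * scale

    def test_rms_within_20pct_of_amplitude(self, domain):
        # Monte-Carlo over seeds; the edge taper eats a little of the RMS
        rms = [sample_velocity_field(domain, 0.3, 13.0, seed=s).rms(domain.mask)
               for s in range(5)]
        assert abs(np.mean(rms) - 0.3) < 0.2 * 0.3

    def test_resolution_consistency(self):
        # the same seed defines the same continuous field at any resolution
        d64 = im.make_island(52.0, 166.4 / 64, 64)
        d128 = im.make_island(52.0, 166.4 / 128, 128)
        v64 = sample_velocity_field(d64, 0.2, 13.0, seed=5)
        v128 = sample_velocity_field(d128, 0.2, 13.0, seed=5)
        assert np.allclose(v128.u[::2, ::2], v64.u, atol=1e-12)


class TestConstitutiveLaw:
    def _sr(self, exx, eyy, exy):
        x = np.arange(4.0)
        z = np.zeros((4, 4))
        return im.StrainRateField(x, x, z + exx, z + eyy, z + exy)

    def test_equibiaxial(self, monolayer):
        e = 0.01
        s = stress_from_strainrate(self._sr(e, e, 0.0), monolayer)
        expect = (monolayer.K1 - 2 / 3 * monolayer.K2) * 2 * e \
            + 2 * monolayer.K2 * e
        assert np.allclose(s.sxx, expect) and np.allclose(s.syy, expect)
        assert not s.sxy.any()

    def test_pure_shear(self, monolayer):
        g = 0.02
        s = stress_from_strainrate(self._sr(0.0, 0.0, g), monolayer)
        assert np.allclose(s.sxy, 2 * monolayer.K2 * g)
        assert not s.sxx.any() and not s.syy.any()

    def test_linear_in_strain_rate(self, monolayer, domain):
        v = sample_velocity_field(domain, 0.2, 13.0, seed=9)
        sr = strain_rate_from_velocity(v)
        s1 = stress_from_strainrate(sr, monolayer)
        sr2 = im.StrainRateField(sr.x, sr.y, 2 * sr.exx, 2 * sr.eyy,
                                 2 * sr.exy)
        s2 = stress_from_strainrate(sr2, monolayer)
        assert np.allclose(s2.sxx, 2 * s1.sxx)
        assert np.allclose(s2.sxy, 2 * s1.sxy)


class TestTractionFromStress:
    def test_uniform_stress_zero_divergence(self, domain, monolayer):
        x, y = domain.grid()
        ones = np.ones(domain.shape)
        s = im.StressField(x, y, 100 * ones, 50 * ones, 10 * ones)
        T = traction_from_stress(s, monolayer, domain)
        interior = np.zeros(domain.shape, bool)
        interior[10:-10, 10:-10] = domain.mask[10:-10, 10:-10]
        assert np.abs(T.u[interior]).max() < 1e-9

    def test_axisymmetric_tension_analytic(self, monolayer):
        # p(r) = s0 (1 - r²/R²) isotropic: |T| = 2 h s0 r / R², inward
        dom = im.make_island(40.0, 1.0, 128)
        x, y = dom.grid()
        r, rx, ry = dom.radial_coords()
        s0, R = 100.0, dom.radius
        p = np.where(r <= R, s0 * (1 - (r / R) ** 2), 0.0)
        s = im.StressField(x, y, p, p, np.zeros_like(p))
        T = traction_from_stress(s, monolayer, dom)
        tr = T.u * rx + T.v * ry
        inner = dom.mask & (r < 0.7 * R) & (r > 5)
        expect = -2 * monolayer.height_h * s0 * r / R ** 2
        assert rel_rms(tr[inner], expect[inner]) < 0.02
        # edge tractions point inward
        edge = dom.mask & (r > 0.8 * R)
        assert tr[edge].mean() < 0

    def test_linear_in_height(self, domain, monolayer, fluct):
        _, _, _, stress, _ = fluct
        T1 = traction_from_stress(stress, monolayer, domain)
        tall = im.Monolayer(height_h=2 * monolayer.height_h,
                            K1=monolayer.K1, K2=monolayer.K2)
        T2 = traction_from_stress(stress, tall, domain)
        assert np.allclose(T2.u, 2 * T1.u)

    def test_grid_mismatch_rejected(self, domain, monolayer):
        x = np.arange(16.0)
        z = np.zeros((16, 16))
        with pytest.raises(ValueError, match="cover"):
            traction_from_stress(im.StressField(x, x, z, z, z), monolayer,
                                 domain)


class TestAnalyticChain:
    def test_velocity_matches_sampled_field(self, domain, monolayer, fluct):
        sol, velocity, _, _, _ = fluct
        v = sample_velocity_field(domain, 0.2, 13.0, seed=2)
        assert np.allclose(velocity.u, v.u, atol=1e-12)

    def test_fd_chain_converges_to_analytic(self, monolayer):
        # the FD operators approach the closed-form chain under refinement
        errs = {}
        for n in (64, 128):
            dom = im.make_island(52.0, 166.4 / n, n)
            sol = FluctuationSolution(dom, monolayer, 0.2, 13.0, seed=2)
            _, sr_an, s_an, T_an = sol.fields()
            v = sample_velocity_field(dom, 0.2, 13.0, seed=2)
            sr = strain_rate_from_velocity(v)
            s_fd = stress_from_strainrate(sr, monolayer).scaled(-1.0)
            T_fd = traction_from_stress(s_fd, monolayer, dom)
            errs[n] = (rel_rms(sr.exx, sr_an.exx),
                       np.sqrt(np.mean((T_fd.u - T_an.u) ** 2
                                       + (T_fd.v - T_an.v) ** 2))
                       / T_an.rms())
        assert errs[128][0] < errs[64][0]
        assert errs[128][1] < errs[64][1]

    def test_discrete_compatibility_is_exact(self, domain):
        # strain rates built by the discrete gradient of an actual velocity
        # field satisfy the compatibility condition to roundoff, because the
        # discrete partial-derivative operators commute
        v = sample_velocity_field(domain, 0.2, 13.0, seed=4)
        res = compatibility_residual(strain_rate_from_velocity(v))
        scale = np.abs(strain_rate_from_velocity(v).exx).max()
        assert np.abs(res).max() < 1e-10 * scale / domain.pixel_size ** 2

    def test_compatibility_residual_vanishes_under_refinement(self, monolayer):
        # on the closed-form strain rates the same FD residual is pure
        # truncation error, O(dx²): it must fall ~4x per grid halving
        norms = {}
        for n in (64, 128):
            dom = im.make_island(52.0, 166.4 / n, n)
            sol = FluctuationSolution(dom, monolayer, 0.2, 13.0, seed=4)
            _, sr_an, _, _ = sol.fields()
            res = compatibility_residual(sr_an)
            r, _, _ = dom.radial_coords()
            interior = dom.mask & (r < 0.75 * dom.radius)  # clear of the
            # taper ramp, where the third velocity derivative jumps
            norms[n] = np.sqrt(np.mean(res[interior] ** 2))
        assert norms[128] < norms[64] / 2.5


class TestSpeckle:
    def test_zero_displacement_identical_images(self):
        a, b = render_speckle_pair(None, shape=(96, 96), pixel_size=1.0,
                                   seed=3)
        assert np.array_equal(a.data, b.data)

    def test_uniform_integer_shift_is_a_roll(self):
        x = np.arange(96.0)
        u = np.full((96, 96), 5.0)
        v = np.full((96, 96), 3.0)
        disp = im.GriddedVectorField(x, x, u, v, units="um")
        a, b = render_speckle_pair(disp, seed=3)
        assert np.allclose(b.data[3:, 5:], a.data[:-3, :-5], atol=1e-10)

    def test_deterministic(self):
        a1, _ = render_speckle_pair(None, shape=(64, 64), pixel_size=1.0,
                                    seed=9)
        a2, _ = render_speckle_pair(None, shape=(64, 64), pixel_size=1.0,
                                    seed=9)
        assert np.array_equal(a1.data, a2.data)

    def test_nonnegative_intensities(self):
        a, _ = render_speckle_pair(None, shape=(64, 64), pixel_size=1.0,
                                   seed=1)
        assert a.data.min() >= 0

    def test_low_density_warns(self):
        with pytest.warns(UserWarning, match="density"):
            render_speckle_pair(None, shape=(64, 64), pixel_size=1.0,
                                density=0.001, seed=0)


class TestContractileIsland:
    def test_contractile_signs(self, island):
        # inward flow -> tensile stress, inward edge tractions
        d = island.domain
        tension = island.stress.tension[d.mask].mean()
        assert tension > 0
        assert im.edge_traction_sign(island.traction, d) < 0
        r, rx, ry = d.radial_coords()
        vr = island.velocity.u * rx + island.velocity.v * ry
        edge = d.mask & (r > 0.8 * d.radius)
        assert vr[edge].mean() < 0          # flow is inward at the edge

    def test_expanding_island_flips_signs(self, monolayer, substrate):
        isl = im.synthesize_island(n=128, pixel_size=1.3, radius_um=52.0,
                                   monolayer=monolayer, substrate=substrate,
                                   seed=1, mode="expanding",
                                   render_speckle=False)
        assert im.edge_traction_sign(isl.traction, isl.domain) > 0
        assert isl.stress.tension[isl.domain.mask].mean() < 0

    def test_axisymmetric_solution_in_equilibrium(self, monolayer):
        # independent FD oracle: h * div(sigma) reproduces the closed-form T
        dom = im.make_island(40.0, 1.0, 128)
        vel, stress, traction = axisymmetric_contractile_solution(
            dom, monolayer, 0.3)
        T_fd = traction_from_stress(stress, monolayer, dom)
        r, _, _ = dom.radial_coords()
        inner = dom.mask & (r < 0.85 * dom.radius)
        err = np.sqrt(np.mean((T_fd.u - traction.u)[inner] ** 2
                              + (T_fd.v - traction.v)[inner] ** 2))
        scale = np.sqrt(np.mean(traction.u[inner] ** 2
                                + traction.v[inner] ** 2))
        assert err < 0.02 * scale

    def test_base_profile_free_edge(self, monolayer):
        # the axisymmetric base satisfies σrr(R) = 0: σrr = σ0(1 - r²/R²)
        dom = im.make_island(40.0, 1.0, 128)
        _, stress, _ = axisymmetric_contractile_solution(dom, monolayer, 0.3)
        r, rx, ry = dom.radial_coords()
        srr = (stress.sxx * rx ** 2 + stress.syy * ry ** 2
               + 2 * stress.sxy * rx * ry)
        ring = dom.mask & (r > 0.97 * dom.radius)
        sigma0 = np.nanmax(srr)
        assert np.abs(srr[ring]).max() < 0.07 * sigma0

    def test_full_island_stress_recovery(self, island):
        # end-to-end: the FEM inverse reproduces the bundle's ground truth
        from conftest import stress_rel_rms
        mesh = im.build_mesh(island.domain)
        st = im.solve_stress(island.traction, mesh, island.monolayer)
        # half-resolution grid; the error drops ~4x at the full 256² grid
        assert stress_rel_rms(st, island.stress) < 0.04

    def test_deterministic_bundle(self, monolayer, substrate):
        a = im.synthesize_island(n=96, pixel_size=1.733, radius_um=35.0,
                                 seed=5, render_speckle=False)
        b = im.synthesize_island(n=96, pixel_size=1.733, radius_um=35.0,
                                 seed=5, render_speckle=False)
        assert np.array_equal(a.traction.u, b.traction.u)
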