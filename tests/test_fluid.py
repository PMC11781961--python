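"""Staggered-grid Navier-Stokes: stencils, projection, diffusion,
Poiseuille recovery."""

import numpy as np
import pytest

from venavalve import fluid_mac as fm


def random_state(grid, seed=0, rho=1.08, mu=0.36):
    rng = np.random.default_rng(seed)
    st = fm.FluidState.zeros(grid, rho=rho, mu=mu)
    st.u = rng.standard_normal(grid.face_shape(0))
    st.v = rng.standard_normal(grid.face_shape(1))
    st.w = rng.standard_normal(grid.face_shape(2))
    return st


class TestGrid:
    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValueError):
            fm.FluidGrid((16, 16, 16), (1.0, 1.0, 2.0))

    def test_minimum_cells(self):
        with pytest.raises(ValueError):
            fm.FluidGrid((4, 16, 16), (0.25, 1.0, 1.0))

    def test_default_is_study_grid(self):
        g = fm.FluidGrid()
        assert g.shape == (50, 50, 150)
        assert g.h == pytest.approx(0.02)


class TestDivergence:
    def test_uniform_field_divergence_free(self):
        g = fm.FluidGrid((8, 8, 8), (1, 1, 1))
        st = fm.FluidState.zeros(g)
        st.u += 2.0
        st.w -= 1.0
        assert np.abs(fm.divergence(g, st.u, st.v, st.w)).max() == 0.0

    def test_linear_solenoidal_field_exact(self):
        # u = (x, -y, 0) is discretely divergence-free on the MAC grid
        g = fm.FluidGrid((8, 8, 8), (1, 1, 1))
        st = fm.FluidState.zeros(g)
        st.u = np.broadcast_to((np.arange(9) * g.h)[:, None, None],
                               g.face_shape(0)).copy()
        st.v = -np.broadcast_to((np.arange(9) * g.h)[None, :, None],
                                g.face_shape(1)).copy()
        div = fm.divergence(g, st.u, st.v, st.w)
        assert np.abs(div).max() < 1e-13

    def test_uniaxial_linear_field_unit_divergence(self):
        g = fm.FluidGrid((8, 8, 8), (1, 1, 1))
        st = fm.FluidState.zeros(g)
        st.u = np.broadcast_to((np.arange(9) * g.h)[:, None, None],
                               g.face_shape(0)).copy()
        div = fm.divergence(g, st.u, st.v, st.w)
        np.testing.assert_allclose(div, 1.0, rtol=1e-12)


class TestProjection:
    def test_projection_removes_divergence(self):
        g = fm.FluidGrid((16, 16, 48), (1, 1, 3))
        st = random_state(g)
        fm.apply_pressure_bcs(st, 0.0, 0.0)
        u, v, w, _ = fm.project(st, 1e-3)
        div = np.abs(fm.divergence(g, u, v, w)).max()
        assert div <= 1e-8 * st.max_speed() / g.h

    def test_projection_idempotent(self):
        g = fm.FluidGrid((16, 16, 48), (1, 1, 3))
        st = random_state(g, seed=1)
        fm.apply_pressure_bcs(st, 0.0, 0.0)
        st.u, st.v, st.w, _ = fm.project(st, 1e-3)
        u2, v2, w2, _ = fm.project(st, 1e-3)
        assert np.abs(u2 - st.u).max() < 1e-12 * max(1, st.max_speed())

    def test_gradient_fields_annihilated_periodic(self):
        g = fm.FluidGrid((16, 16, 16), (1, 1, 1), periodic=True)
        rng = np.random.default_rng(5)
        spec = np.fft.fftn(rng.standard_normal(g.shape))
        mask = np.abs(np.fft.fftfreq(16))[:, None, None] < 0.2
        phi = np.real(np.fft.ifftn(spec * mask))
        st = fm.FluidState.zeros(g)
        st.u = fm._expand((phi - np.roll(phi, 1, 0)) / g.h, 0)
        st.v = fm._expand((phi - np.roll(phi, 1, 1)) / g.h, 1)
        st.w = fm._expand((phi - np.roll(phi, 1, 2)) / g.h, 2)
        scale = st.max_speed()
        u, v, w, _ = fm.project(st, 1e-3)
        assert max(np.abs(u).max(), np.abs(v).max(),
                   np.abs(w).max()) < 1e-12 * scale

    def test_balanced_end_pressures_no_flow(self):
        """Equal pressure on every boundary is a hydrostatic fixed point."""
        g = fm.FluidGrid((16, 16, 48), (1, 1, 3))
        st = fm.FluidState.zeros(g)
        p0 = 4.0 * 1333.22
        fm.apply_pressure_bcs(st, p0, p0, p0)
        for _ in range(5):
            star = fm.advect_diffuse(st, 1e-5)
            st.u, st.v, st.w, st.p = fm.project(st, 1e-5, velocity=star)
        assert st.max_speed() < 1e-10
        np.testing.assert_allclose(st.p, p0, rtol=1e-10)

    def test_pressure_difference_drives_positive_axial_flow(self):
        g = fm.FluidGrid((16, 16, 48), (1, 1, 3))
        st = fm.FluidState.zeros(g)
        fm.apply_pressure_bcs(st, 1333.22, 0.0, 0.0)
        for _ in range(20):
            star = fm.advect_diffuse(st, 1e-5)
            st.u, st.v, st.w, st.p = fm.project(st, 1e-5, velocity=star)
        assert st.w.sum() > 0.0


class TestDiffusion:
    @pytest.mark.parametrize("scheme", ["centered", "upwind"])
    def test_uniform_field_is_steady_periodic(self, scheme):
        g = fm.FluidGrid((8, 8, 8), (1, 1, 1), periodic=True)
        st = fm.FluidState.zeros(g)
        st.u += 1.5
        st.v -= 0.5
        out = fm.advect_diffuse(st, 1e-4, scheme=scheme)
        np.testing.assert_allclose(out[0], st.u, atol=1e-13)
        np.testing.assert_allclose(out[1], st.v, atol=1e-13)

    def test_single_mode_decay_matches_heat_kernel(self):
        """Transverse shear mode decays at exp(-nu*k^2 t) within the
        O(dt^2) + O(h^2) discretisation error."""
        g = fm.FluidGrid((16, 16, 16), (1, 1, 1), periodic=True)
        nu = 0.01
        st = fm.FluidState.zeros(g, rho=1.0, mu=nu)
        k = 2 * np.pi
        yc = (np.arange(16) + 0.5) * g.h
        st.u = np.broadcast_to(np.sin(k * yc)[None, :, None],
                               g.face_shape(0)).copy()
        dt, nsteps = 2e-4, 100
        a0 = np.abs(st.u).max()
        for _ in range(nsteps):
            star = fm.advect_diffuse(st, dt, scheme="centered")
            st.u, st.v, st.w, st.p = fm.project(st, dt, velocity=star)
        decay = np.abs(st.u).max() / a0
        expect = np.exp(-nu * k * k * dt * nsteps)
        # discrete wavenumber error ~ (kh)^2/12 ~ 1.3%; time error O(dt)
        assert decay == pytest.approx(expect, rel=0.02)
        k_disc = (2 - 2 * np.cos(k * g.h)) / g.h ** 2
        assert decay == pytest.approx(np.exp(-nu * k_disc * dt * nsteps),
                                      rel=1e-4)

    def test_momentum_balance_uniform_force_periodic(self):
        g = fm.FluidGrid((8, 8, 8), (1, 1, 1), periodic=True)
        st = fm.FluidState.zeros(g, rho=2.0)
        f = 10.0
        forces = (np.full(g.face_shape(0), f),
                  np.zeros(g.face_shape(1)), np.zeros(g.face_shape(2)))
        dt, n = 1e-4, 50
        for _ in range(n):
            star = fm.advect_diffuse(st, dt, forces=forces)
            st.u, st.v, st.w, st.p = fm.project(st, dt, velocity=star)
        np.testing.assert_allclose(st.u, f / st.rho * dt * n, rtol=1e-10)

    def test_cfl_violation_raises_with_suggestion(self):
        g = fm.FluidGrid((8, 8, 8), (1, 1, 1))
        st = fm.FluidState.zeros(g)
        st.u += 100.0
        with pytest.raises(fm.TimeStepError, match="suggest"):
            fm.advect_diffuse(st, 5e-3)


class TestPoiseuille:
    def test_centreline_velocity_and_parabolic_profile(self,
                                                       poiseuille_result):
        """Steady flow in the rigid tethered tube matches Hagen-Poiseuille
        within 10%, with a quadratic radial profile (R^2 >= 0.98)."""
        from venavalve.materials import MMHG_TO_DYN_CM2
        from venavalve.postprocess import axial_velocity_profiles

        sim = poiseuille_result["sim"]
        dp = poiseuille_result["dp_mmhg"] * MMHG_TO_DYN_CM2
        R = 0.5 * sim.geometry.d
        L = sim.grid.lengths[2]
        u_analytic = dp * R * R / (4.0 * sim.fluid.mu * L)
        profs = axial_velocity_profiles(
            sim.fluid, sim.geometry,
            {"mid": 0.5 * L, "q3": 0.62 * L})
        u_peak = max(p["max_speed"] for p in profs.values())
        assert u_peak == pytest.approx(u_analytic, rel=0.10)
        assert all(p["r_squared"] >= 0.98 for p in profs.values())
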