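"""Hemodynamic observables: GOA, flow rate, stagnation, dilation, phases."""

import numpy as np
import pytest

from venavalve import postprocess as post
from venavalve.fluid_mac import FluidGrid, FluidState
from venavalve.geometry import GeometryParams, build_structural_mesh
from venavalve.materials import WALL


def half_ellipse_edges(d_major, d_minor, n=33):
    """Two opposed half-ellipse free edges spanning the major axis."""
    t = np.linspace(0, np.pi, n)
    y = 0.5 * d_major * np.cos(t)
    x = 0.5 * d_minor * np.sin(t)
    e1 = np.stack([x, y, np.full(n, 1.75)], axis=1)
    e2 = np.stack([-x, y, np.full(n, 1.75)], axis=1)
    return [e1, e2]


class TestGOA:
    def test_circular_orifice(self):
        goa = post.geometric_orifice_area(half_ellipse_edges(0.4, 0.4))
        assert goa == pytest.approx(np.pi / 4 * 0.16, rel=1e-3)

    def test_elliptic_orifice(self):
        goa = post.geometric_orifice_area(half_ellipse_edges(0.6, 0.2))
        assert goa == pytest.approx(np.pi / 4 * 0.6 * 0.2, rel=1e-3)

    def test_contact_gives_zero(self):
        goa = post.geometric_orifice_area(half_ellipse_edges(0.6, 1e-4),
                                          closed_tol=2.5e-3)
        assert goa == 0.0

    def test_too_few_points_rejected(self):
        e1, e2 = half_ellipse_edges(0.4, 0.2, n=5)
        with pytest.raises(ValueError):
            post.geometric_orifice_area([e1, e2])

    def test_reference_mesh_goa_is_gap_limited(self):
        p = GeometryParams(g=0.01)
        mesh = build_structural_mesh(p, 0.11)
        goa = post.geometric_orifice_area(
            [mesh.X[fe] for fe in mesh.free_edges], closed_tol=p.g / 4)
        d_major = 2.0 * float(
            np.hypot(*(mesh.X[mesh.free_edges[0][0], :2])))
        assert goa <= np.pi / 4 * d_major * p.g * 1.05


class TestFlowRate:
    GRID = FluidGrid((16, 16, 48), (1, 1, 3))

    def test_uniform_axial_flow_through_lumen(self):
        st = FluidState.zeros(self.GRID)
        st.w += 1.0
        geom = GeometryParams()
        mask = post.lumen_face_mask(self.GRID, geom, z=0.2)
        q = post.transvalvular_flow_rate(st, 1.5, mask)
        # pi r^2 * u within one-cell rasterisation error of the disc
        assert q == pytest.approx(np.pi * 0.3455 ** 2, rel=0.10)

    def test_zero_velocity(self):
        st = FluidState.zeros(self.GRID)
        assert post.transvalvular_flow_rate(st, 1.5) == 0.0

    def test_reversed_flow_negative(self):
        st = FluidState.zeros(self.GRID)
        st.w -= 2.0
        assert post.transvalvular_flow_rate(st, 1.5) < 0.0

    def test_plane_outside_box_rejected(self):
        st = FluidState.zeros(self.GRID)
        with pytest.raises(ValueError):
            post.transvalvular_flow_rate(st, 5.0)


class TestStagnantFraction:
    GRID = FluidGrid((16, 16, 48), (1, 1, 3))

    def test_all_zero_velocity(self):
        st = FluidState.zeros(self.GRID)
        mask = post.sinus_pocket_mask(self.GRID, GeometryParams())
        assert post.stagnant_fraction(st, mask) == 1.0

    def test_uniform_fast_flow(self):
        st = FluidState.zeros(self.GRID)
        st.w += 2.0
        mask = post.sinus_pocket_mask(self.GRID, GeometryParams())
        assert post.stagnant_fraction(st, mask) == 0.0

    def test_half_and_half(self):
        st = FluidState.zeros(self.GRID)
        mask = np.zeros(self.GRID.shape, dtype=bool)
        mask[:, :, 10] = True
        mask[:, :, 20] = True
        st.w[:, :, 20:22] = 1.5     # both faces of cell layer 20
        assert post.stagnant_fraction(st, mask) == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        st = FluidState.zeros(self.GRID)
        with pytest.raises(ValueError):
            post.stagnant_fraction(st, np.zeros(self.GRID.shape, bool))


class TestDilation:
    def test_undeformed_is_unity(self, coarse_mesh):
        assert post.dilation_ratio(coarse_mesh, coarse_mesh.X.copy()) == \
            pytest.approx(1.0)

    def test_uniform_radial_expansion(self, coarse_mesh):
        x = coarse_mesh.X.copy()
        x[:, :2] *= 1.10
        assert post.dilation_ratio(coarse_mesh, x) == pytest.approx(1.10)

    def test_warns_inside_sinus(self, coarse_mesh):
        zmid = 0.5 * sum(coarse_mesh.params.sinus_window)
        with pytest.warns(RuntimeWarning):
            post.dilation_ratio(coarse_mesh, coarse_mesh.X.copy(),
                                measurement_z=zmid)


class TestPressureDilation:
    def test_monotone_and_strain_stiffening(self):
        d = post.pressure_dilation_curve(WALL, [4.0, 15.0, 31.0],
                                         0.691, 0.020)
        assert np.all(np.diff(d) > 0)            # inflates with pressure
        assert d[0] > 1.0
        # exponential stiffening: increments shrink with pressure
        assert d[2] - d[1] < d[1] - d[0]

    def test_vessel_expansion_above_30mmhg_is_about_15_percent(self):
        d = post.pressure_dilation_curve(WALL, [31.0], 0.691, 0.020)[0]
        assert d == pytest.approx(1.15, abs=0.05)


class TestPhases:
    def trapezoid(self):
        t = np.linspace(0.0, 1.0, 2001)
        g = np.interp(t, [0.0, 0.15, 0.45, 0.65, 1.0],
                      [0.0, 1.0, 1.0, 0.0, 0.0])
        return t, g

    def test_trapezoid_fractions_exact(self):
        t, g = self.trapezoid()
        seg = post.segment_phases(t, g)
        assert seg.fractions["opening"] == pytest.approx(0.15, abs=1e-6)
        assert seg.fractions["equilibrium"] == pytest.approx(0.30, abs=1e-6)
        assert seg.fractions["closing"] == pytest.approx(0.20, abs=1e-6)
        assert seg.fractions["closed"] == pytest.approx(0.35, abs=1e-6)

    def test_constant_zero_is_fully_closed(self):
        t = np.linspace(0, 1, 100)
        with pytest.warns(RuntimeWarning):
            seg = post.segment_phases(t, np.zeros_like(t))
        assert seg.fractions["closed"] == 1.0

    def test_constant_open_is_fully_equilibrium(self):
        t = np.linspace(0, 1, 100)
        with pytest.warns(RuntimeWarning):
            seg = post.segment_phases(t, np.full_like(t, 0.1))
        assert seg.fractions["equilibrium"] == 1.0

    def test_fractions_partition_the_cycle(self):
        t, g = self.trapezoid()
        seg = post.segment_phases(t, g, closed_level=0.05, open_frac=0.9)
        assert sum(seg.fractions.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in seg.fractions.values())


class TestVelocityProfiles:
    def test_poiseuille_field_fit(self):
        grid = FluidGrid((32, 32, 96), (1, 1, 3))
        geom = GeometryParams()
        st = FluidState.zeros(grid)
        R, umax = 0.3455, 10.0
        xc = grid.cell_centers(0) - 0.5
        yc = grid.cell_centers(1) - 0.5
        r2 = xc[:, None] ** 2 + yc[None, :] ** 2
        prof = np.where(r2 < R * R, umax * (1 - r2 / R ** 2), 0.0)
        st.w = np.broadcast_to(prof[:, :, None], grid.face_shape(2)).copy()
        # probe in the plain-tube section (away from the sinus bulge)
        out = post.axial_velocity_profiles(st, geom, {"mid": 0.5})
        assert out["mid"]["r_squared"] >= 0.98
        assert out["mid"]["max_speed"] == pytest.approx(umax, rel=0.02)
        # fitted curvature matches the imposed parabola
        c = out["mid"]["quadratic_coeffs"][0]
        assert c == pytest.approx(-umax / R ** 2, rel=0.02)

    def test_zero_field_zero_profiles(self):
        grid = FluidGrid((16, 16, 48), (1, 1, 3))
        st = FluidState.zeros(grid)
        out = post.axial_velocity_profiles(st, GeometryParams(),
                                           {"A": 0.2})
        assert np.all(out["A"]["speed_x"] == 0.0)

    def test_probe_outside_box_rejected(self):
        grid = FluidGrid((16, 16, 48), (1, 1, 3))
        st = FluidState.zeros(grid)
        with pytest.raises(ValueError):
            post.axial_velocity_profiles(st, GeometryParams(), {"X": 9.0})
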