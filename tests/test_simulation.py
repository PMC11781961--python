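"""Pressure protocol, scenarios and the coupled FSI time loop."""

import warnings

import numpy as np
import pytest

from venavalve import ib_coupling as ib
from venavalve import simulation as sim
from venavalve.fluid_mac import FluidGrid
from venavalve.materials import default_materials


class TestPressureProtocol:
    def test_peak_forward_difference(self):
        spec = sim.PressureProfileSpec()
        p_in, p_out = sim.inlet_outlet_pressures(0.25, spec)
        assert p_in == pytest.approx(4.5)
        assert p_out == pytest.approx(4.0)

    def test_zero_at_cycle_start(self):
        spec = sim.PressureProfileSpec()
        assert sim.pressure_difference(0.0, spec) == pytest.approx(0.0)

    def test_closing_dip(self):
        spec = sim.PressureProfileSpec()
        assert sim.pressure_difference(0.95, spec) == pytest.approx(-0.05)

    def test_periodic_in_t(self):
        spec = sim.PressureProfileSpec()
        assert sim.pressure_difference(2.33, spec) == pytest.approx(
            sim.pressure_difference(0.33, spec))

    def test_dip_ramps_are_continuous(self):
        spec = sim.PressureProfileSpec()
        t = np.linspace(0.88, 1.0, 4001)
        dp = np.array([sim.pressure_difference(x, spec) for x in t])
        assert np.abs(np.diff(dp)).max() < 0.01   # no jumps

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sim.PressureProfileSpec(amplitude=-1.0)
        with pytest.raises(ValueError):
            sim.PressureProfileSpec(mode="sawtooth")


class TestScenarios:
    def test_normal_unchanged(self):
        base = default_materials()
        assert sim.scenario_params(base, "normal") == base

    def test_fibrotic_multiplies_by_ten(self):
        out = sim.scenario_params(default_materials(), "fibrotic")
        assert out["leaflet"].c0 == pytest.approx(40.0)
        assert out["leaflet"].c1 == pytest.approx(1700.6)
        assert out["wall"] == default_materials()["wall"]

    def test_atrophic_divides_by_ten(self):
        out = sim.scenario_params(default_materials(), "atrophic")
        assert out["leaflet"].c0 == pytest.approx(0.4)
        assert out["leaflet"].c1 == pytest.approx(17.006)

    def test_hypertension_keeps_materials(self):
        out = sim.scenario_params(default_materials(), "hypertension")
        assert out == default_materials()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            sim.scenario_params(default_materials(), "calcified")


class TestConfig:
    def test_viscous_bound_enforced(self):
        cfg = sim.preset("desk16")
        cfg.dt = 1e-2
        with pytest.raises(ValueError, match="viscous"):
            cfg.validate()

    def test_preset_names(self):
        for name in ("paper", "desk32", "desk16"):
            sim.preset(name).validate()
        with pytest.raises(ValueError):
            sim.preset("desk8")


class TestStep:
    def test_equilibrium_fixed_point(self):
        """No driving pressure + undeformed structure stays stationary."""
        cfg = sim.preset("desk16")
        cfg.pressure = sim.PressureProfileSpec(
            amplitude=1e-12, offset=0.0, dip=0.0, period=0.25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sim.Simulation(cfg)
            for _ in range(1000):
                s.step()
        assert s.fluid.max_speed() < 1e-6
        assert np.abs(s.x - s.mesh.X).max() < 1e-6

    def test_forward_pressure_creates_upstream_flow(self):
        cfg = sim.preset("desk16")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sim.Simulation(cfg)
            for _ in range(200):       # dp has risen to ~0.1 mmHg
                s.step()
        upstream = s.fluid.w[:, :, : s.grid.shape[2] // 3]
        assert np.abs(upstream).max() > 0.1

    def test_checkpoint_restart_is_bit_compatible(self, tmp_path):
        cfg = sim.preset("desk16")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sim.Simulation(cfg)
            for _ in range(60):
                s.step()
            ck = str(tmp_path / "state.h5")
            s.save_checkpoint(ck)
            for _ in range(40):
                s.step()
            s2 = sim.Simulation.from_checkpoint(ck)
            for _ in range(40):
                s2.step()
        assert np.array_equal(s.x, s2.x)
        assert np.array_equal(s.fluid.w, s2.fluid.w)
        assert s.t == s2.t

    def test_determinism(self):
        cfg = sim.preset("desk16")
        states = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = sim.Simulation(sim.preset("desk16"))
                for _ in range(100):
                    s.step()
            states.append((s.x.copy(), s.fluid.w.copy()))
        assert np.array_equal(states[0][0], states[1][0])
        assert np.array_equal(states[0][1], states[1][1])
        del cfg


class TestAdvectedVolume:
    def test_enclosed_surface_volume_conserved(self):
        """A closed surface advected through a divergence-free field by
        the kernel-interpolated velocity keeps its volume."""
        import trimesh

        grid = FluidGrid((32, 32, 32), (1.0, 1.0, 1.0), periodic=True)
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.15)
        pos = np.asarray(sphere.vertices) + 0.5
        faces = np.asarray(sphere.faces)

        def faces_field():
            out = []
            for comp in range(3):
                shape = grid.face_shape(comp)
                coords = []
                for ax in range(3):
                    off = 0.0 if ax == comp else 0.5
                    coords.append((np.arange(shape[ax]) + off) * grid.h)
                X = coords[0][:, None, None]
                Y = coords[1][None, :, None]
                Z = coords[2][None, None, :]
                k = 2 * np.pi
                if comp == 0:
                    f = np.sin(k * X) * np.cos(k * Y)
                elif comp == 1:
                    f = -np.cos(k * X) * np.sin(k * Y)
                else:
                    f = np.zeros((1, 1, 1))
                out.append(np.broadcast_to(f, shape).copy())
            return tuple(out)

        vel = faces_field()

        def volume(p):
            return abs(trimesh.Trimesh(vertices=p, faces=faces,
                                       process=False).volume)

        v0 = volume(pos)
        dt = 2e-4          # keeps the surface well inside the box
        for _ in range(1000):
            u1 = ib.interpolate(grid, pos, vel)
            um = ib.interpolate(grid, pos + 0.5 * dt * u1, vel)
            pos = pos + dt * um
        assert abs(volume(pos) - v0) / v0 < 0.005


class TestSmokeRun:
    def test_valve_cycles_and_reseats(self, smoke_result):
        m = smoke_result.metrics
        goa0 = m.goa[0]
        assert m.goa.max() > 2.5 * goa0          # opens well beyond the gap
        last = m.goa[m.time >= smoke_result.config.pressure.period]
        assert last.min() < 2.0 * goa0           # reseats near the gap area

    def test_structure_volume_conserved(self, smoke_result):
        for loss in smoke_result.volume_loss_per_cycle:
            assert abs(loss) < 0.02

    def test_leaflet_stress_strain_tracked(self, smoke_result):
        m = smoke_result.metrics
        assert m.max_shear_kpa.max() > 0.0
        assert m.max_strain.max() > 0.01
        # stress peaks while the valve is loaded, not at rest
        assert m.max_shear_kpa[0] < m.max_shear_kpa.max()
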