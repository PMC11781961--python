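"""Shared fixtures.

Heavy coupled runs (smoke run, scenario comparison, Poiseuille spin-up)
are session-scoped so the qualitative-behaviour tests and the acceptance
suite share a single computation.
"""

import warnings

import numpy as np
import pytest

from venavalve.geometry import GeometryParams, build_structural_mesh
from venavalve.simulation import Simulation, SimulationConfig, preset


@pytest.fixture(scope="session")
def table_params():
    """The study's geometric dimensions (cm)."""
    return GeometryParams()


@pytest.fixture(scope="session")
def coarse_mesh(table_params):
    return build_structural_mesh(table_params, resolution=0.11)


@pytest.fixture(scope="session")
def smoke_result():
    """Coupled 2-cycle run of the coarse desk preset (shared)."""
    cfg = preset("desk16")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = Simulation(cfg)
        return sim.run()


@pytest.fixture(scope="session")
def scenario_peaks(smoke_result):
    """Peak transvalvular flow rate per scenario over the opening window
    [0, 0.6 T] (normal from the shared smoke run; fibrotic and atrophic
    from dedicated short runs over the same window)."""
    m = smoke_result.metrics
    T = smoke_result.config.pressure.period
    window = (m.time >= 0.0) & (m.time <= 0.6 * T)
    peaks = {"normal": float(m.flow_rate[window].max())}
    for scenario in ("fibrotic", "atrophic"):
        cfg = preset("desk16")
        cfg.scenario = scenario
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = Simulation(cfg)
            n = int(round(0.6 * T / cfg.dt))
            peak = 0.0
            for i in range(n):
                sim.step()
                if (i + 1) % cfg.output_every == 0:
                    peak = max(peak,
                               sim.current_metrics()["flow_rate"])
        peaks[scenario] = peak
    return peaks


@pytest.fixture(scope="session")
def poiseuille_result():
    """Steady pressure-driven flow through a rigid tethered tube at
    32x32x96, for comparison with the Hagen-Poiseuille solution."""
    from venavalve.ib_coupling import KernelSpec
    from venavalve.simulation import PressureProfileSpec

    dp_mmhg = 0.2
    cfg = SimulationConfig(
        geometry=GeometryParams(sinus_bulge_ratio=1.0 + 1e-9),
        grid_shape=(32, 32, 96), box=(1.0, 1.0, 3.0),
        pressure=PressureProfileSpec(amplitude=dp_mmhg, offset=0.0,
                                     period=1.0, mode="constant"),
        dt=2e-4, cycles=1, output_every=1000,
        structure_resolution=0.05, include_leaflets=False, rigid=True,
        kernel=KernelSpec("ib3"),   # narrowest kernel: sharpest wall
        startup_ramp=0.02, settle_time=0.0, label="poiseuille")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = Simulation(cfg)
        n = int(0.45 / cfg.dt)
        for _ in range(n):
            sim.step()
    return {"sim": sim, "dp_mmhg": dp_mmhg}
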