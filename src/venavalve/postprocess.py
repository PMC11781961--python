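"""Hemodynamic and mechanical observables of a valve simulation.

Everything here is a pure function of simulation states: geometric orifice
area (GOA) from the leaflet free edges, transvalvular flow rate, sinus
stagnant-zone fraction, venous dilation ratio, phase segmentation of the
valve cycle and radial velocity profiles.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .fluid_mac import FluidGrid, FluidState
from .geometry import GeometryParams, StructuralMesh, inner_radius
from .materials import MMHG_TO_DYN_CM2

PHASES = ("opening", "equilibrium", "closing", "closed")


# ----------------------------------------------------------------- GOA
def geometric_orifice_area(free_edges: Sequence[np.ndarray],
                           closed_tol: float = 2.5e-3,
                           n_samples: int = 65) -> float:
    """Geometric orifice area (cm^2) from the two free-edge curves.

    The edges are projected onto the cross-sectional (x, y) plane.  The
    major axis is the commissure-to-commissure extent; the minor axis is
    the maximum transverse separation of the two edges perpendicular to
    it.  The orifice is treated as an ellipse on full axes,
    ``GOA = pi/4 * D_major * D_minor``; edges in contact (separation within
    ``closed_tol``) give 0.
    """
    if len(free_edges) != 2:
        raise ValueError("expected exactly two free-edge point sets")
    e1, e2 = (np.asarray(e, dtype=float) for e in free_edges)
    if e1.shape[0] < 8 or e2.shape[0] < 8:
        raise ValueError("need at least 8 points per free edge")
    p1, p2 = e1[:, :2], e2[:, :2]
    # align orderings so matched indices run commissure-to-commissure
    if np.linalg.norm(p2[0] - p1[0]) > np.linalg.norm(p2[-1] - p1[0]):
        p2 = p2[::-1]
    c_a = 0.5 * (p1[0] + p2[0])
    c_b = 0.5 * (p1[-1] + p2[-1])
    axis = c_b - c_a
    d_major = float(np.linalg.norm(axis))
    if d_major < 1e-12:
        warnings.warn("degenerate orifice projection; GOA set to 0",
                      RuntimeWarning)
        return 0.0
    axis /= d_major
    normal = np.array([-axis[1], axis[0]])

    def resample(p):
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] < 1e-14:
            return np.repeat(p[:1], n_samples, axis=0)
        ss = np.linspace(0.0, s[-1], n_samples)
        return np.stack([np.interp(ss, s, p[:, k]) for k in range(2)],
                        axis=1)

    q1, q2 = resample(p1), resample(p2)
    sep = (q1 - q2) @ normal
    if np.abs(sep.max()) < np.abs(sep.min()):
        sep = -sep
    d_minor = float(sep.max())
    if d_minor <= closed_tol:
        return 0.0
    return 0.25 * np.pi * d_major * d_minor


# ------------------------------------------------------------- flow rate
def transvalvular_flow_rate(state: FluidState, plane_z: float,
                            lumen: Optional[np.ndarray] = None) -> float:
    """Volumetric flow rate (cm^3/s) through the plane at ``plane_z``.

    Positive in +z (distal -> proximal).  ``lumen`` is an optional
    (nx, ny) boolean mask restricting the integration to the vein lumen.
    """
    grid = state.grid
    if not (0.0 <= plane_z <= grid.lengths[2]):
        raise ValueError(f"plane z={plane_z} outside the box")
    k = int(round(plane_z / grid.h))
    k = min(max(k, 0), grid.shape[2])
    wz = state.w[:, :, k]
    if lumen is not None:
        wz = np.where(lumen, wz, 0.0)
    return float(wz.sum() * grid.h ** 2)


def lumen_face_mask(grid: FluidGrid, params: GeometryParams,
                    z: float, margin: float = 0.0) -> np.ndarray:
    """(nx, ny) mask of cells inside the luminal radius at height z."""
    xc = grid.cell_centers(0) - 0.5 * grid.lengths[0]
    yc = grid.cell_centers(1) - 0.5 * grid.lengths[1]
    r = np.hypot(xc[:, None], yc[None, :])
    return r <= float(inner_radius(params, z)) - margin


def sinus_pocket_mask(grid: FluidGrid, params: GeometryParams) -> np.ndarray:
    """3D mask of the sinus pocket: the bulge volume outside the plain
    lumen cylinder, where the recirculating/stagnant flow lives."""
    xc = grid.cell_centers(0) - 0.5 * grid.lengths[0]
    yc = grid.cell_centers(1) - 0.5 * grid.lengths[1]
    zc = grid.cell_centers(2)
    r = np.hypot(xc[:, None, None], yc[None, :, None])
    rin = np.asarray(inner_radius(params, zc))[None, None, :]
    z0, z1 = params.sinus_window
    inwin = (zc > z0) & (zc < z1)
    return (r < rin) & (r > 0.5 * params.d) & inwin[None, None, :]


def stagnant_fraction(state: FluidState, mask: np.ndarray,
                      threshold: float = 1.0) -> float:
    """Volume fraction of masked cells with speed below ``threshold``
    (cm/s; default 1 cm/s, the clinical near-stasis cutoff)."""
    if not np.any(mask):
        raise ValueError("empty region mask")
    speed = np.linalg.norm(state.cell_center_velocity(), axis=-1)
    return float((speed[mask] < threshold).mean())


# --------------------------------------------------------------- dilation
def dilation_ratio(mesh: StructuralMesh, x_current: np.ndarray,
                   measurement_z: Optional[float] = None) -> float:
    """Ratio d/d0 of current to reference mean wall-ring diameter.

    The ring nearest ``measurement_z`` is used (default: middle of the
    proximal plain-tube section, away from the sinus).
    """
    z0, z1 = mesh.params.sinus_window
    if measurement_z is None:
        measurement_z = 0.5 * (z1 + mesh.params.l)
    if z0 < measurement_z < z1:
        warnings.warn("dilation measurement plane intersects the sinus",
                      RuntimeWarning)
    ring = mesh.wall_ring(measurement_z)
    axis_xy = mesh.X[:, :2].mean(axis=0)
    r_ref = np.linalg.norm(mesh.X[ring, :2] - axis_xy, axis=1).mean()
    r_cur = np.linalg.norm(x_current[ring, :2] - axis_xy, axis=1).mean()
    return float(r_cur / r_ref)


def pressure_dilation_curve(material, pressures_mmhg,
                            diameter: float, thickness: float,
                            axial_stretch: float = 1.0) -> np.ndarray:
    """Equilibrium diameter ratio d/d0 of a thin-walled vessel vs
    transmural pressure.

    Solves the Laplace balance ``sigma_theta - sigma_r = dp * r / t`` for
    the hoop stretch, with the through-thickness stretch fixed by
    incompressibility and the axial stretch prescribed (1 = fixed ends).
    The circumferential stress comes from the package's constitutive law,
    so this isolates the pressure--dilation response of the vessel tissue
    from the flow solution.

    Parameters: ``material`` -- wall :class:`~venavalve.materials.
    MaterialParams`; ``pressures_mmhg`` -- transmural pressures;
    ``diameter``/``thickness`` -- reference luminal diameter and wall
    thickness (cm).  Returns d/d0 per pressure.
    """
    from scipy.optimize import brentq

    from .materials import cauchy_stress, pk1_stress
    r0 = 0.5 * diameter + 0.5 * thickness        # mid-wall radius
    lz = axial_stretch

    def dp_of(lam):
        F = np.diag([1.0 / (lam * lz), lam, lz])   # radial, hoop, axial
        sig = cauchy_stress(F, pk1_stress(material, F)) * 1.0e4  # dyn/cm^2
        t = thickness / (lam * lz)
        return (sig[1, 1] - sig[0, 0]) * t / (lam * r0)

    out = []
    for p in np.atleast_1d(pressures_mmhg):
        target = p * MMHG_TO_DYN_CM2
        f = lambda lam: dp_of(lam) - target       # noqa: E731
        hi = 1.0 + 1e-6
        while dp_of(hi) < target and hi < 3.0:
            hi += 0.05
        out.append(brentq(f, 1.0 + 1e-9, hi, xtol=1e-10))
    return np.asarray(out)


# ------------------------------------------------------------------ phases
@dataclass
class PhaseSegmentation:
    """Boundaries (s) and cycle fractions of the four valve phases."""

    boundaries: Dict[str, tuple]
    fractions: Dict[str, float]

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"phase fractions must sum to 1, got {total}")


def _cross_time(times, values, level, rising: bool, start_idx: int = 0):
    """First linear-interpolated crossing of ``level`` from index on."""
    v = values[start_idx:]
    t = times[start_idx:]
    if rising:
        hit = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    else:
        hit = np.flatnonzero((v[:-1] > level) & (v[1:] <= level))
    if hit.size == 0:
        return None
    i = hit[0]
    dv = v[i + 1] - v[i]
    frac = 0.0 if dv == 0 else (level - v[i]) / dv
    return float(t[i] + frac * (t[i + 1] - t[i]))


def segment_phases(times: np.ndarray, goa: np.ndarray,
                   closed_level: Optional[float] = None,
                   open_frac: float = 1.0,
                   rel_tol: float = 1e-9) -> PhaseSegmentation:
    """Split one cycle of a GOA trace into opening / equilibrium /
    closing / closed phases.

    Opening runs from the first crossing above ``closed_level`` to the
    first time the trace reaches ``open_frac`` of the cycle maximum;
    equilibrium lasts while it stays there; closing runs back down to
    ``closed_level``; closed is the remainder.  Defaults segment an ideal
    trace exactly (``closed_level`` just above zero, ``open_frac = 1``);
    simulated traces are segmented with a finite ``closed_level`` (e.g.
    twice the reference gap area) and ``open_frac ~ 0.9``.
    """
    times = np.asarray(times, dtype=float)
    goa = np.asarray(goa, dtype=float)
    if times.ndim != 1 or times.shape != goa.shape or times.size < 4:
        raise ValueError("need matching 1D time/GOA arrays (>= 4 samples)")
    T = times[-1] - times[0]
    gmax = goa.max()
    tol = rel_tol * max(gmax, 1e-300)
    closed_lv = tol if closed_level is None else closed_level
    open_lv = open_frac * gmax - tol

    if gmax <= closed_lv:
        warnings.warn("GOA never opens; single closed phase", RuntimeWarning)
        return PhaseSegmentation(
            boundaries={"closed": (times[0], times[-1])},
            fractions={"opening": 0.0, "equilibrium": 0.0,
                       "closing": 0.0, "closed": 1.0})
    if goa.min() >= open_lv:
        warnings.warn("GOA always at maximum; single equilibrium phase",
                      RuntimeWarning)
        return PhaseSegmentation(
            boundaries={"equilibrium": (times[0], times[-1])},
            fractions={"opening": 0.0, "equilibrium": 1.0,
                       "closing": 0.0, "closed": 0.0})

    if goa[0] > closed_lv:
        t_open = times[0]
    else:
        t_open = _cross_time(times, goa, closed_lv, rising=True)
    above = np.flatnonzero(goa >= open_lv)
    t_eq_start = float(times[above[0]])
    t_eq_end = float(times[above[-1]])
    t_closed = _cross_time(times, goa, closed_lv, rising=False,
                           start_idx=above[-1])
    if t_closed is None:
        t_closed = times[-1]
    t_open = min(t_open, t_eq_start)
    frac = {
        "opening": (t_eq_start - t_open) / T,
        "equilibrium": (t_eq_end - t_eq_start) / T,
        "closing": (t_closed - t_eq_end) / T,
    }
    frac["closed"] = 1.0 - sum(frac.values())
    bounds = {"opening": (t_open, t_eq_start),
              "equilibrium": (t_eq_start, t_eq_end),
              "closing": (t_eq_end, t_closed),
              "closed": (t_closed, times[-1])}
    return PhaseSegmentation(boundaries=bounds, fractions=frac)


# ----------------------------------------------------------- velocity probes
def default_probe_stations(grid: FluidGrid, valve_z: float) -> Dict[str, float]:
    """Axial stations A-E: near the distal end, approaching the valve,
    between the cusps, past the valve and near the proximal end."""
    L = grid.lengths[2]
    return {"A": 0.08 * L, "B": 0.30 * L, "C": valve_z,
            "D": 0.70 * L, "E": 0.92 * L}


def axial_velocity_profiles(state: FluidState, params: GeometryParams,
                            stations: Dict[str, float]) -> Dict[str, dict]:
    """Radial speed profiles at the given axial stations.

    Samples |u| along the two transverse axes through the vein axis and
    fits a quadratic; reports the fit R^2 and the peak sampled speed.
    """
    grid = state.grid
    L = grid.lengths
    for name, z in stations.items():
        if not (0.0 <= z <= L[2]):
            raise ValueError(f"probe {name} at z={z} outside the box")
    speed = np.linalg.norm(state.cell_center_velocity(), axis=-1)
    xc = grid.cell_centers(0) - 0.5 * L[0]
    yc = grid.cell_centers(1) - 0.5 * L[1]
    ix = int(np.argmin(np.abs(xc)))
    iy = int(np.argmin(np.abs(yc)))
    out = {}
    for name, z in stations.items():
        k = int(np.clip(round(z / grid.h - 0.5), 0, grid.shape[2] - 1))
        rin = float(inner_radius(params, z))
        prof_x = speed[:, iy, k]
        prof_y = speed[ix, :, k]
        rs = np.concatenate([xc, yc])
        vs = np.concatenate([prof_x, prof_y])
        sel = np.abs(rs) <= 0.85 * rin
        r2 = 1.0
        coeffs = np.zeros(3)
        if sel.sum() >= 4 and vs[sel].max() > 0:
            coeffs = np.polyfit(rs[sel], vs[sel], 2)
            fit = np.polyval(coeffs, rs[sel])
            ss_res = ((vs[sel] - fit) ** 2).sum()
            ss_tot = ((vs[sel] - vs[sel].mean()) ** 2).sum()
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[name] = {"z": z, "r_x": xc, "speed_x": prof_x,
                     "r_y": yc, "speed_y": prof_y,
                     "quadratic_coeffs": coeffs, "r_squared": float(r2),
                     "max_speed": float(vs[sel].max() if sel.any() else 0.0)}
    return out


# --------------------------------------------------------------- time series
@dataclass
class MetricsTimeSeries:
    """Per-output-step metrics of a run (pressures in mmHg)."""

    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    goa: np.ndarray = field(default_factory=lambda: np.empty(0))
    flow_rate: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_in: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_out: np.ndarray = field(default_factory=lambda: np.empty(0))
    dilation: np.ndarray = field(default_factory=lambda: np.empty(0))
    stagnant: np.ndarray = field(default_factory=lambda: np.empty(0))
    max_shear_kpa: np.ndarray = field(default_factory=lambda: np.empty(0))
    max_strain: np.ndarray = field(default_factory=lambda: np.empty(0))
    structure_volume: np.ndarray = field(default_factory=lambda: np.empty(0))
    phase: Optional[np.ndarray] = None

    FIELDS = ("time", "goa", "flow_rate", "p_in", "p_out", "dilation",
              "stagnant", "max_shear_kpa", "max_strain", "structure_volume")

    def append(self, **kw):
        for name in self.FIELDS:
            arr = getattr(self, name)
            setattr(self, name, np.append(arr, kw[name]))

    def label_phases(self, seg: PhaseSegmentation,
                     period: float, t0: float = 0.0):
        """Assign a phase label to every sample from a segmentation of one
        cycle (boundaries taken modulo the period)."""
        labels = np.full(self.time.shape, "closed", dtype=object)
        tau = (self.time - t0) % period
        for name in ("opening", "equilibrium", "closing"):
            if name in seg.boundaries:
                a, b = seg.boundaries[name]
                labels[(tau >= (a - t0) % period)
                       & (tau < (b - t0) % period)] = name
        self.phase = labels

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            header = list(self.FIELDS) + ["phase"]
            wr.writerow(header)
            phases = (self.phase if self.phase is not None
                      else ["" for _ in self.time])
            for i in range(self.time.size):
                row = [repr(float(getattr(self, f)[i])) for f in self.FIELDS]
                row.append(phases[i])
                wr.writerow(row)

    @classmethod
    def from_csv(cls, path) -> "MetricsTimeSeries":
        with open(path, newline="") as fh:
            rd = csv.reader(fh)
            header = next(rd)
            cols = {h: [] for h in header}
            for row in rd:
                for h, val in zip(header, row):
                    cols[h].append(val)
        ts = cls()
        for f in cls.FIELDS:
            setattr(ts, f, np.array([float(x) for x in cols[f]]))
        if any(cols["phase"]):
            ts.phase = np.array(cols["phase"], dtype=object)
        return ts
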