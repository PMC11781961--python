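"""Staggered-grid incompressible Navier-Stokes solver.

Spatial discretisation is a uniform marker-and-cell (MAC) grid: velocity
components on cell faces, pressure at cell centres.  The momentum equation

    rho (du/dt + (u.grad) u) = -grad p + mu lap u + f

is advanced explicitly (the Runge-Kutta staging lives in
:mod:`venavalve.simulation`); incompressibility is enforced by a Chorin
projection whose pressure Poisson equation is solved *exactly* by a fast
discrete-sine-transform eigen-decomposition (the uniform-grid Laplacian
with cell-centred Dirichlet pressure boundaries is separable, so the
direct transform solve replaces an iterative Krylov/multigrid solve and
leaves the discrete divergence at transform round-off).

Boundary conditions model an open box: every face carries a prescribed
boundary pressure (normal traction) -- the z faces carry the inlet/outlet
pressures of the vein, the lateral faces a reference pressure (default 0)
-- with zero-gradient (free outflow) velocity ghosts.  A fully periodic
test mode (FFT Poisson solve) backs the analytic verification tests.

Units are CGS: cm, s, g/cm^3, poise = g/(cm s), dyn/cm^2.  Blood defaults:
rho = 1.08 g/cm^3, mu = 0.36 poise (0.036 Pa s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.fft

BLOOD_DENSITY = 1.08        # g/cm^3
BLOOD_VISCOSITY = 0.36      # poise


class TimeStepError(RuntimeError):
    """dt violates the advective CFL or explicit viscous bound."""


class PoissonError(RuntimeError):
    """Pressure solve failed (non-finite right-hand side/solution)."""


@dataclass(frozen=True)
class FluidGrid:
    """Uniform Cartesian MAC grid over a box (default 1 x 1 x 3 cm)."""

    shape: Tuple[int, int, int] = (50, 50, 150)
    lengths: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    periodic: bool = False

    def __post_init__(self):
        if any(n < 8 for n in self.shape):
            raise ValueError("need at least 8 cells per axis")
        hs = [L / n for L, n in zip(self.lengths, self.shape)]
        if max(hs) - min(hs) > 1e-12:
            raise ValueError(f"grid spacing must be uniform, got {hs}")

    @property
    def h(self) -> float:
        return self.lengths[0] / self.shape[0]

    def cell_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.h

    def face_shape(self, comp: int) -> Tuple[int, int, int]:
        s = list(self.shape)
        s[comp] += 1
        return tuple(s)


@dataclass(frozen=True)
class BoundaryPressures:
    """Prescribed boundary pressures (dyn/cm^2) on the six box faces.

    ``p_in`` acts on the z-min (distal/inlet) face, ``p_out`` on the z-max
    (proximal/outlet) face and ``lateral`` on the four side faces.  The
    inlet/outlet pressures act on the ends *of the vein*: ``in_profile``
    is an optional (nx, ny) weight field s in [0, 1] such that the z-face
    pressure is ``lateral + (p_end - lateral) * s`` -- in the valve model
    s is ~1 over the lumen disc and 0 outside the vein, so the remainder
    of the boundary carries the reference (zero) pressure.  ``None``
    applies the end pressures uniformly.
    """

    p_in: float = 0.0
    p_out: float = 0.0
    lateral: float = 0.0
    in_profile: Optional[np.ndarray] = None

    def z_face_values(self):
        """Effective pressure fields on the z-min and z-max faces."""
        if self.in_profile is None:
            return self.p_in, self.p_out
        s = self.in_profile
        return (self.lateral + (self.p_in - self.lateral) * s,
                self.lateral + (self.p_out - self.lateral) * s)


@dataclass
class FluidState:
    """MAC-grid velocity, pressure and body force."""

    grid: FluidGrid
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: float = 0.0
    rho: float = BLOOD_DENSITY
    mu: float = BLOOD_VISCOSITY
    bc: BoundaryPressures = field(default_factory=BoundaryPressures)

    @classmethod
    def zeros(cls, grid: FluidGrid, rho: float = BLOOD_DENSITY,
              mu: float = BLOOD_VISCOSITY) -> "FluidState":
        return cls(grid=grid,
                   u=np.zeros(grid.face_shape(0)),
                   v=np.zeros(grid.face_shape(1)),
                   w=np.zeros(grid.face_shape(2)),
                   p=np.zeros(grid.shape), rho=rho, mu=mu)

    def copy(self) -> "FluidState":
        return FluidState(grid=self.grid, u=self.u.copy(), v=self.v.copy(),
                          w=self.w.copy(), p=self.p.copy(), t=self.t,
                          rho=self.rho, mu=self.mu, bc=self.bc)

    def velocity(self):
        return (self.u, self.v, self.w)

    def max_speed(self) -> float:
        return max(np.abs(self.u).max(), np.abs(self.v).max(),
                   np.abs(self.w).max())

    def cell_center_velocity(self) -> np.ndarray:
        """(nx, ny, nz, 3) velocity averaged to cell centres."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return np.stack([uc, vc, wc], axis=-1)


def apply_pressure_bcs(state: FluidState, p_in: float, p_out: float,
                       lateral: float = 0.0,
                       in_profile: Optional[np.ndarray] = None) -> FluidState:
    """Attach the open-boundary pressure values (dyn/cm^2) to the state.

    The values enter the projection as Dirichlet pressure conditions half a
    cell outside the boundary cells and drive the boundary-face normal
    velocities; tangential velocities see zero-gradient ghosts.  See
    :class:`BoundaryPressures` for ``in_profile``.
    """
    state.bc = BoundaryPressures(p_in=p_in, p_out=p_out, lateral=lateral,
                                 in_profile=in_profile)
    return state


def divergence(grid: FluidGrid, u, v, w) -> np.ndarray:
    """Cell-centred MAC divergence (1/s)."""
    h = grid.h
    return ((u[1:] - u[:-1]) + (v[:, 1:] - v[:, :-1])
            + (w[:, :, 1:] - w[:, :, :-1])) / h


# ------------------------------------------------------------------ stencils
def _reduce(arr, comp):
    """Drop the duplicated wrap face of a periodic component array."""
    sl = [slice(None)] * 3
    sl[comp] = slice(0, -1)
    return arr[tuple(sl)]


def _expand(arr, comp):
    """Re-append the wrap face (periodic)."""
    sl = [slice(None)] * 3
    sl[comp] = slice(0, 1)
    return np.concatenate([arr, arr[tuple(sl)]], axis=comp)


def _lap(arr, h, periodic):
    mode = "wrap" if periodic else "edge"
    p = np.pad(arr, 1, mode=mode)
    return (p[2:, 1:-1, 1:-1] + p[:-2, 1:-1, 1:-1]
            + p[1:-1, 2:, 1:-1] + p[1:-1, :-2, 1:-1]
            + p[1:-1, 1:-1, 2:] + p[1:-1, 1:-1, :-2]
            - 6.0 * arr) / h ** 2


def _advection_physical(grid, u, v, w):
    """Conservative-form convective tendencies on the face arrays."""
    h = grid.h

    def pad(a, axis):
        widths = [(0, 0)] * 3
        widths[axis] = (1, 1)
        return np.pad(a, widths, mode="edge")

    def d(a, axis):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        return (a[tuple(sl_hi)] - a[tuple(sl_lo)]) / h

    def avg(a, axis):
        return 0.5 * (a[tuple([slice(1, None) if i == axis else slice(None)
                               for i in range(3)])]
                      + a[tuple([slice(None, -1) if i == axis
                                 else slice(None) for i in range(3)])])

    out = []
    vel = (u, v, w)
    for comp in range(3):
        a = vel[comp]
        conv = np.zeros_like(a)
        for axis in range(3):
            if axis == comp:
                c = avg(a, comp)               # own component at centres
                conv += d(pad(c * c, axis), axis)
            else:
                b = vel[axis]
                a_edge = avg(pad(a, axis), axis)       # a at edge nodes
                b_edge = avg(pad(b, comp), comp)       # b at edge nodes
                conv += d(a_edge * b_edge, axis)
        out.append(-conv)
    return tuple(out)


def _advection_periodic(grid, u, v, w):
    h = grid.h
    vel = [_reduce(a, c) for c, a in enumerate((u, v, w))]
    out = []
    for comp in range(3):
        a = vel[comp]
        conv = np.zeros_like(a)
        for axis in range(3):
            if axis == comp:
                c = 0.5 * (a + np.roll(a, -1, axis))
                F = c * c
                conv += (F - np.roll(F, 1, axis)) / h
            else:
                b = vel[axis]
                a_edge = 0.5 * (a + np.roll(a, 1, axis))
                b_edge = 0.5 * (b + np.roll(b, 1, comp))
                G = a_edge * b_edge
                conv += (np.roll(G, -1, axis) - G) / h
        out.append(-conv)
    return tuple(_expand(o, c) for c, o in enumerate(out))


def _advection_upwind(grid, u, v, w):
    """First-order upwind advective-form tendencies -(U.grad)a.

    Robust at the open-boundary corner jets where the cell Reynolds
    number is O(30); the default scheme (the centred form is available for
    smooth low-Re verification problems).
    """
    h = grid.h
    periodic = grid.periodic
    vel = ([_reduce(a, c) for c, a in enumerate((u, v, w))]
           if periodic else [u, v, w])
    mode = "wrap" if periodic else "edge"

    def pad1(a, axis):
        widths = [(0, 0)] * 3
        widths[axis] = (1, 1)
        return np.pad(a, widths, mode=mode)

    def one_sided(a, axis):
        p = pad1(a, axis)
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        mid = [slice(None)] * 3
        hi[axis] = slice(2, None)
        lo[axis] = slice(None, -2)
        mid[axis] = slice(1, -1)
        fwd = (p[tuple(hi)] - p[tuple(mid)]) / h
        bwd = (p[tuple(mid)] - p[tuple(lo)]) / h
        return fwd, bwd

    def avg(a, axis):
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[axis] = slice(1, None)
        lo[axis] = slice(None, -1)
        return 0.5 * (a[tuple(hi)] + a[tuple(lo)])

    out = []
    for comp in range(3):
        a = vel[comp]
        conv = np.zeros_like(a)
        for axis in range(3):
            if axis == comp:
                adv = a
            elif periodic:
                b = vel[axis]
                # average b onto a's lattice: to centres along axis, then
                # to a's faces along comp
                b1 = 0.5 * (b + np.roll(b, -1, axis))
                adv = 0.5 * (b1 + np.roll(b1, 1, comp))
            else:
                b = vel[axis]
                adv = avg(pad1(avg(b, axis), comp), comp)
            if periodic:
                fwd = (np.roll(a, -1, axis) - a) / h
                bwd = (a - np.roll(a, 1, axis)) / h
            else:
                fwd, bwd = one_sided(a, axis)
            conv += np.where(adv > 0.0, adv * bwd, adv * fwd)
        out.append(-conv)
    if periodic:
        return tuple(_expand(o, c) for c, o in enumerate(out))
    return tuple(out)


def check_dt(state: FluidState, dt: float) -> None:
    """Raise :class:`TimeStepError` if dt violates stability bounds."""
    h = state.grid.h
    nu = state.mu / state.rho
    dt_visc = h * h / (6.0 * nu)
    umax = state.max_speed()
    dt_adv = h / umax if umax > 0 else np.inf
    bound = min(dt_visc, dt_adv)
    if dt > bound:
        raise TimeStepError(
            f"dt={dt:.3e} s exceeds stability bound {bound:.3e} s "
            f"(viscous {dt_visc:.3e}, advective {dt_adv:.3e}); "
            f"suggest dt <= {0.5 * bound:.3e}")


def advect_diffuse(state: FluidState, dt: float, forces=None,
                   advecting: Optional[tuple] = None,
                   check: bool = True, scheme: str = "upwind"):
    """One explicit evaluation of the momentum update (no projection):

        u* = u + dt * ( -(u.grad)u + (mu/rho) lap u + f/rho ).

    ``advecting`` optionally supplies the velocity used for the advective
    and diffusive terms (midpoint Runge-Kutta staging); ``forces`` is the
    face-centred body force triple (dyn/cm^3).  ``scheme`` selects the
    convective discretisation: first-order ``upwind`` (default, robust at
    the open-boundary jets) or second-order ``centered`` (conservative
    form, for smooth low-Reynolds verification flows).
    """
    if check:
        check_dt(state, dt)
    grid = state.grid
    base = advecting if advecting is not None else state.velocity()
    nu = state.mu / state.rho
    if scheme == "upwind":
        adv = _advection_upwind(grid, *base)
    elif grid.periodic:
        adv = _advection_periodic(grid, *base)
    else:
        adv = _advection_physical(grid, *base)
    out = []
    for comp, (a0, a, tend) in enumerate(zip(state.velocity(), base, adv)):
        if grid.periodic:
            lap = _expand(_lap(_reduce(a, comp), grid.h, True), comp)
        else:
            lap = _lap(a, grid.h, False)
        da = tend + nu * lap
        if forces is not None:
            da = da + forces[comp] / state.rho
        out.append(a0 + dt * da)
    return tuple(out)


# ------------------------------------------------------------------ Poisson
_EIG_CACHE: dict = {}


def _poisson_eigenvalues(grid: FluidGrid):
    key = (grid.shape, grid.periodic)
    if key not in _EIG_CACHE:
        lams = []
        for n in grid.shape:
            q = np.arange(n)
            if grid.periodic:
                lam = 2.0 * np.cos(2.0 * np.pi * q / n) - 2.0
            else:
                lam = 2.0 * np.cos(np.pi * (q + 1) / n) - 2.0
            lams.append(lam)
        lx, ly, lz = lams
        tot = (lx[:, None, None] + ly[None, :, None]
               + lz[None, None, :]) / grid.h ** 2
        _EIG_CACHE[key] = tot
    return _EIG_CACHE[key]


def solve_pressure_poisson(grid: FluidGrid, rhs: np.ndarray) -> np.ndarray:
    """Solve lap p = rhs with the grid's pressure boundary closure.

    Non-periodic: cell-centred Dirichlet closure (the inhomogeneous
    boundary values must already be folded into ``rhs``); periodic: FFT
    with the zero-mean gauge.
    """
    if not np.all(np.isfinite(rhs)):
        raise PoissonError("non-finite Poisson right-hand side")
    lam = _poisson_eigenvalues(grid)
    if grid.periodic:
        rhs = rhs - rhs.mean()
        rhat = scipy.fft.fftn(rhs)
        with np.errstate(divide="ignore", invalid="ignore"):
            phat = np.where(np.abs(lam) > 1e-14, rhat / lam, 0.0)
        p = np.real(scipy.fft.ifftn(phat))
    else:
        rhat = scipy.fft.dstn(rhs, type=2)
        p = scipy.fft.idstn(rhat / lam, type=2)
    if not np.all(np.isfinite(p)):
        raise PoissonError("non-finite pressure solution")
    return p


def project(state: FluidState, dt: float, velocity=None):
    """Chorin projection onto the divergence-free space.

    Returns ``(u, v, w, p)`` with the corrected face velocities (including
    the open boundary faces, which the boundary pressures drive) and the
    pressure field.  After projection the discrete divergence is at
    transform round-off (<= 1e-8 relative by a wide margin).
    """
    grid = state.grid
    h = grid.h
    u, v, w = velocity if velocity is not None else state.velocity()
    scale = state.rho / dt
    if grid.periodic:
        rhs = scale * divergence(grid, u, v, w)
        p = solve_pressure_poisson(grid, rhs)
        coef = dt / state.rho / h
        pr = [p - np.roll(p, 1, ax) for ax in range(3)]
        u2 = _expand(_reduce(u, 0) - coef * pr[0], 0)
        v2 = _expand(_reduce(v, 1) - coef * pr[1], 1)
        w2 = _expand(_reduce(w, 2) - coef * pr[2], 2)
        return u2, v2, w2, p
    bc = state.bc
    pz0, pz1 = bc.z_face_values()
    rhs = scale * divergence(grid, u, v, w)
    rhs[0, :, :] -= 2.0 * bc.lateral / h ** 2
    rhs[-1, :, :] -= 2.0 * bc.lateral / h ** 2
    rhs[:, 0, :] -= 2.0 * bc.lateral / h ** 2
    rhs[:, -1, :] -= 2.0 * bc.lateral / h ** 2
    rhs[:, :, 0] -= 2.0 * pz0 / h ** 2
    rhs[:, :, -1] -= 2.0 * pz1 / h ** 2
    p = solve_pressure_poisson(grid, rhs)
    coef = dt / state.rho
    u2, v2, w2 = u.copy(), v.copy(), w.copy()
    u2[1:-1] -= coef * (p[1:] - p[:-1]) / h
    u2[0] -= coef * (p[0] - bc.lateral) * 2.0 / h
    u2[-1] -= coef * (bc.lateral - p[-1]) * 2.0 / h
    v2[:, 1:-1] -= coef * (p[:, 1:] - p[:, :-1]) / h
    v2[:, 0] -= coef * (p[:, 0] - bc.lateral) * 2.0 / h
    v2[:, -1] -= coef * (bc.lateral - p[:, -1]) * 2.0 / h
    w2[:, :, 1:-1] -= coef * (p[:, :, 1:] - p[:, :, :-1]) / h
    w2[:, :, 0] -= coef * (p[:, :, 0] - pz0) * 2.0 / h
    w2[:, :, -1] -= coef * (pz1 - p[:, :, -1]) * 2.0 / h
    return u2, v2, w2, p
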