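"""Regularised-delta-function coupling between structure and fluid.

Force spreading and velocity interpolation,

    f(x) = sum_n F_L(X_n) w_n  delta_h(x - chi_n),
    U_n  = sum_x u(x) h^3      delta_h(x - chi_n),

use a tensor product of one-dimensional immersed-boundary kernels
``delta_h(x) = phi(x1/h) phi(x2/h) phi(x3/h) / h^3``.  Supported families:

* ``ib4`` (default): Peskin's classical 4-point kernel,
* ``ib3``: the 3-point kernel of Roma & Peskin,
* ``ib6``: the quintic B-spline (6-point support).

All satisfy the partition of unity ``sum_j phi(r - j) = 1`` and the zero
first moment ``sum_j (r - j) phi(r - j) = 0`` for every offset ``r``, which
makes interpolation exact for constant and linear fields and conserves the
total spread force.  Spreading and interpolation use the same weights, so
they are exact adjoints under the discrete inner products (the power
identity that keeps the coupling energy-consistent).

Velocity components live on the staggered faces of the MAC grid, so each
component is spread/interpolated on its own offset lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def phi_ib4(r: np.ndarray) -> np.ndarray:
    """Peskin 4-point kernel (support |r| <= 2, nonnegative)."""
    r = np.abs(np.asarray(r, dtype=float))
    inner = (3.0 - 2.0 * r
             + np.sqrt(np.maximum(1.0 + 4.0 * r - 4.0 * r * r, 0.0))) / 8.0
    outer = (5.0 - 2.0 * r
             - np.sqrt(np.maximum(-7.0 + 12.0 * r - 4.0 * r * r, 0.0))) / 8.0
    return np.where(r <= 1.0, inner, np.where(r <= 2.0, outer, 0.0))


def phi_ib3(r: np.ndarray) -> np.ndarray:
    """Roma-Peskin 3-point kernel (support |r| <= 1.5)."""
    r = np.abs(np.asarray(r, dtype=float))
    inner = (1.0 + np.sqrt(np.maximum(1.0 - 3.0 * r * r, 0.0))) / 3.0
    outer = (5.0 - 3.0 * r
             - np.sqrt(np.maximum(1.0 - 3.0 * (1.0 - r) ** 2, 0.0))) / 6.0
    return np.where(r <= 0.5, inner, np.where(r <= 1.5, outer, 0.0))


def phi_ib6(r: np.ndarray) -> np.ndarray:
    """Quintic B-spline kernel (support |r| <= 3), via truncated powers."""
    r = np.asarray(r, dtype=float)
    x = r + 3.0
    out = np.zeros_like(x)
    from math import comb
    for k in range(7):
        t = x - k
        out += (-1.0) ** k * comb(6, k) * np.where(t > 0, t, 0.0) ** 5
    return out / 120.0


_FAMILIES = {
    "ib3": (phi_ib3, 3),
    "ib4": (phi_ib4, 4),
    "ib6": (phi_ib6, 6),
}


@dataclass(frozen=True)
class KernelSpec:
    """Choice of regularised delta kernel."""

    family: str = "ib4"

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; "
                             f"choose from {sorted(_FAMILIES)}")

    @property
    def phi(self):
        return _FAMILIES[self.family][0]

    @property
    def support(self) -> int:
        return _FAMILIES[self.family][1]


def kernel_weights(r, kernel: KernelSpec = KernelSpec()):
    """1D weights of the kernel for a point at offset ``r`` (in cells).

    Returns ``(offsets, weights)`` where ``offsets`` are the integer grid
    positions in the kernel's support around ``r`` and ``weights`` their
    kernel values; the weights sum to 1 and reproduce ``r`` as their first
    moment.
    """
    r = float(r)
    if not np.isfinite(r):
        raise ValueError("offset must be finite")
    K = kernel.support
    if K % 2 == 0:
        base = int(np.floor(r)) - (K // 2 - 1)
    else:
        base = int(np.round(r)) - (K // 2)
    offsets = base + np.arange(K)
    return offsets, kernel.phi(r - offsets)


def _axis_indices_weights(pos_over_h: np.ndarray, n: int,
                          kernel: KernelSpec):
    """Support indices and weights along one axis for many points.

    ``pos_over_h``: point coordinate divided by h, already shifted so that
    grid points sit at integers.  Indices are clamped to [0, n-1]; points
    whose support is clamped are reported by the caller.
    """
    K = kernel.support
    if K % 2 == 0:
        base = np.floor(pos_over_h).astype(np.int64) - (K // 2 - 1)
    else:
        base = np.round(pos_over_h).astype(np.int64) - (K // 2)
    idx = base[:, None] + np.arange(K)[None, :]          # (N, K)
    w = kernel.phi(pos_over_h[:, None] - idx)
    clipped = (idx < 0) | (idx > n - 1)
    idx = np.clip(idx, 0, n - 1)
    return idx, w, bool(np.any(clipped))


# staggered offsets (in cells) of each velocity component along (x, y, z)
_STAG = {0: (0.0, 0.5, 0.5), 1: (0.5, 0.0, 0.5), 2: (0.5, 0.5, 0.0)}


def _component_geometry(grid, comp: int):
    shape = list(grid.shape)
    shape[comp] += 1
    return tuple(shape), _STAG[comp]


def _warn_clamped(where: str):
    warnings.warn(
        f"structure node kernel support extends beyond the fluid box "
        f"({where}); weights clamped to the boundary", RuntimeWarning,
        stacklevel=3)


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:                                        # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(fn):
            return fn
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _phi1(family, r):
    """Scalar kernel evaluation (0: ib3, 1: ib4, 2: ib6)."""
    a = abs(r)
    if family == 1:
        if a <= 1.0:
            s = 1.0 + 4.0 * a - 4.0 * a * a
            return (3.0 - 2.0 * a + np.sqrt(s if s > 0 else 0.0)) / 8.0
        if a <= 2.0:
            s = -7.0 + 12.0 * a - 4.0 * a * a
            return (5.0 - 2.0 * a - np.sqrt(s if s > 0 else 0.0)) / 8.0
        return 0.0
    if family == 0:
        if a <= 0.5:
            s = 1.0 - 3.0 * a * a
            return (1.0 + np.sqrt(s if s > 0 else 0.0)) / 3.0
        if a <= 1.5:
            s = 1.0 - 3.0 * (1.0 - a) ** 2
            return (5.0 - 3.0 * a - np.sqrt(s if s > 0 else 0.0)) / 6.0
        return 0.0
    # quintic B-spline via truncated powers
    x = r + 3.0
    out = 0.0
    sign = 1.0
    binom = (1.0, 6.0, 15.0, 20.0, 15.0, 6.0, 1.0)
    for k in range(7):
        t = x - k
        if t > 0.0:
            out += sign * binom[k] * t ** 5
        sign = -sign
    return out / 120.0


@_njit(cache=True)
def _build_weights(pos, h, shapes, family, K):
    """Per-component linear indices and tensor-product weights."""
    N = pos.shape[0]
    KK = K * K * K
    lin = np.empty((3, N, KK), dtype=np.int64)
    W = np.empty((3, N, KK))
    clamped = False
    ax_idx = np.empty((3, K), dtype=np.int64)
    ax_w = np.empty((3, K))
    for comp in range(3):
        n0, n1, n2 = shapes[comp, 0], shapes[comp, 1], shapes[comp, 2]
        for p in range(N):
            for ax in range(3):
                off = 0.0 if ax == comp else 0.5
                r = pos[p, ax] / h - off
                if K % 2 == 0:
                    base = np.int64(np.floor(r)) - (K // 2 - 1)
                else:
                    base = np.int64(np.round(r)) - (K // 2)
                nax = shapes[comp, ax]
                for m in range(K):
                    idx = base + m
                    ax_w[ax, m] = _phi1(family, r - idx)
                    if idx < 0:
                        idx = 0
                        clamped = True
                    elif idx > nax - 1:
                        idx = nax - 1
                        clamped = True
                    ax_idx[ax, m] = idx
            q = 0
            for a in range(K):
                ia = ax_idx[0, a] * n1
                wa = ax_w[0, a]
                for b in range(K):
                    ib_ = (ia + ax_idx[1, b]) * n2
                    wb = wa * ax_w[1, b]
                    for c in range(K):
                        lin[comp, p, q] = ib_ + ax_idx[2, c]
                        W[comp, p, q] = wb * ax_w[2, c]
                        q += 1
    return lin, W, clamped


@_njit(cache=True)
def _scatter(lin, W, val, sizes):
    """Scatter val[p, comp] * W into flat per-component arrays."""
    N, KK = lin.shape[1], lin.shape[2]
    out0 = np.zeros(sizes[0])
    out1 = np.zeros(sizes[1])
    out2 = np.zeros(sizes[2])
    for p in range(N):
        v = val[p, 0]
        for q in range(KK):
            out0[lin[0, p, q]] += W[0, p, q] * v
        v = val[p, 1]
        for q in range(KK):
            out1[lin[1, p, q]] += W[1, p, q] * v
        v = val[p, 2]
        for q in range(KK):
            out2[lin[2, p, q]] += W[2, p, q] * v
    return out0, out1, out2


@_njit(cache=True)
def _gather(lin, W, f0, f1, f2):
    N, KK = lin.shape[1], lin.shape[2]
    U = np.empty((N, 3))
    for p in range(N):
        s0 = 0.0
        s1 = 0.0
        s2 = 0.0
        for q in range(KK):
            s0 += W[0, p, q] * f0[lin[0, p, q]]
            s1 += W[1, p, q] * f1[lin[1, p, q]]
            s2 += W[2, p, q] * f2[lin[2, p, q]]
        U[p, 0] = s0
        U[p, 1] = s1
        U[p, 2] = s2
    return U


_FAMILY_CODE = {"ib3": 0, "ib4": 1, "ib6": 2}


class FaceWeights:
    """Precomputed tensor-product kernel weights of a set of points on the
    three staggered component lattices.

    Spreading and interpolation at the same structure positions share one
    :class:`FaceWeights` (they must, to be exact adjoints); the simulation
    computes it once per Runge-Kutta stage.
    """

    __slots__ = ("grid", "n", "lin", "W", "shapes", "sizes", "clamped")

    def __init__(self, grid, positions: np.ndarray,
                 kernel: KernelSpec = KernelSpec()):
        pos = np.ascontiguousarray(positions, dtype=float)
        self.grid = grid
        self.n = pos.shape[0]
        self.shapes = [grid.face_shape(c) for c in range(3)]
        self.sizes = np.array([int(np.prod(s)) for s in self.shapes])
        shapes = np.array(self.shapes, dtype=np.int64)
        self.lin, self.W, self.clamped = _build_weights(
            pos, grid.h, shapes, _FAMILY_CODE[kernel.family],
            kernel.support)

    def spread(self, force_density: np.ndarray,
               node_volumes: np.ndarray):
        """Eulerian body-force triple from nodal force densities."""
        h3 = self.grid.h ** 3
        val = np.ascontiguousarray(
            np.asarray(force_density, dtype=float)
            * np.asarray(node_volumes, dtype=float)[:, None] / h3)
        flat = _scatter(self.lin, self.W, val, self.sizes)
        return tuple(f.reshape(s) for f, s in zip(flat, self.shapes))

    def interpolate(self, velocity) -> np.ndarray:
        """Lagrangian velocities from the staggered face arrays."""
        return _gather(self.lin, self.W,
                       np.ascontiguousarray(velocity[0]).ravel(),
                       np.ascontiguousarray(velocity[1]).ravel(),
                       np.ascontiguousarray(velocity[2]).ravel())


def spread(grid, positions: np.ndarray, force_density: np.ndarray,
           node_volumes: np.ndarray,
           kernel: KernelSpec = KernelSpec()):
    """Spread Lagrangian force densities to the staggered Eulerian grid.

    ``force_density``: (N, 3) dyn/cm^3 of reference volume;
    ``node_volumes``: (N,) lumped reference volumes (cm^3).  Returns the
    three face-centred body-force arrays (dyn/cm^3).  The total force is
    conserved: ``h^3 * sum(f)`` equals ``sum(F_L * w)`` per component
    (exactly, unless supports are clamped at the domain boundary).
    """
    fw = FaceWeights(grid, positions, kernel)
    if fw.clamped:
        _warn_clamped("spread")
    return fw.spread(force_density, node_volumes)


def interpolate(grid, positions: np.ndarray, velocity,
                kernel: KernelSpec = KernelSpec()) -> np.ndarray:
    """Interpolate staggered velocities to the Lagrangian points.

    ``velocity``: tuple of the three face arrays.  Returns (N, 3) cm/s.
    Exact for uniform and linear fields (partition of unity and first
    moment of the kernels).
    """
    fw = FaceWeights(grid, positions, kernel)
    if fw.clamped:
        _warn_clamped("interpolate")
    return fw.interpolate(velocity)
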