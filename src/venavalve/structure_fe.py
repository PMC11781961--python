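"""Finite-element elasticity of the immersed structure.

The structure's elasticity enters the immersed-boundary scheme through the
weak form: for every FE test function ``V``,

    integral_U F_L . V dX  =  - integral_U P : grad_X V dX,

so the Lagrangian force density ``F_L`` is the (negative) divergence of the
first Piola-Kirchhoff stress in a distributional sense.  With linear
tetrahedra and one-point quadrature, the deformation gradient is constant
per element and the weak-form load vector has the closed form
``f_a = -V_e * P * gradN_a`` per element node ``a``.  Nodal force densities
are obtained with a lumped reference-volume mass matrix (one quarter of
each element's reference volume per node), which keeps the subsequent
immersed-boundary force spreading local.

Tube ends are fixed by stiff penalty tether springs pulling displaced end
nodes back to their reference positions (standard immersed-boundary
practice; the spring stiffness is configurable and by default auto-scaled
to the time step).

Units: coordinates cm, stresses inside :mod:`venavalve.materials` are kPa
and are converted here to CGS (1 kPa = 1e4 dyn/cm^2); force densities are
dyn/cm^3 of reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import materials as mat
from .geometry import REGION_ID, REGIONS, StructuralMesh

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
def _assemble_forces(elems, gradN, vol, x, form, ca, cb, beta, f_out,
                     jfloor=0.0):
    """Fused per-element stress evaluation and weak-form scatter.

    Same constitutive math as :mod:`venavalve.materials` (modified PK1
    with the identity correction), specialised to constant-gradient
    linear tetrahedra.  Returns the index of the first inverted element,
    or -1.
    """
    E = elems.shape[0]
    kpa = 1.0e4
    for e in range(E):
        n0, n1, n2, n3 = elems[e, 0], elems[e, 1], elems[e, 2], elems[e, 3]
        F = np.zeros((3, 3))
        for a in range(4):
            n = elems[e, a]
            for i in range(3):
                xi = x[n, i]
                F[i, 0] += xi * gradN[e, a, 0]
                F[i, 1] += xi * gradN[e, a, 1]
                F[i, 2] += xi * gradN[e, a, 2]
        c00 = F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]
        c01 = F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]
        c02 = F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]
        c10 = F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]
        c11 = F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]
        c12 = F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]
        c20 = F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]
        c21 = F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]
        c22 = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]
        J = F[0, 0] * c00 + F[0, 1] * c01 + F[0, 2] * c02
        if J <= 0.0 and jfloor <= 0.0:
            return e
        Jc = J if J > jfloor else jfloor
        I1 = 0.0
        for i in range(3):
            for j in range(3):
                I1 += F[i, j] * F[i, j]
        xm = I1 - 3.0
        if form[e] == 0:            # polynomial
            coef = 2.0 * ca[e] + 4.0 * cb[e] * xm
        else:                       # exponential
            arg = cb[e] * xm * xm
            if arg > 200.0:         # far beyond physical strains
                arg = 200.0
            coef = 4.0 * ca[e] * cb[e] * xm * np.exp(arg)
        if jfloor > 0.0:
            # inversion-tolerant continuation: cap stress magnitudes so
            # crushed sub-grid elements stay finite and corrective
            if coef > 1.0e5:
                coef = 1.0e5
            elif coef < -1.0e5:
                coef = -1.0e5
        vterm = (2.0 * beta[e] * np.log(Jc) - coef) / Jc
        if jfloor > 0.0:
            if vterm > 1.0e6:
                vterm = 1.0e6
            elif vterm < -1.0e6:
                vterm = -1.0e6
        P = np.empty((3, 3))
        P[0, 0] = (coef * F[0, 0] + vterm * c00) * kpa
        P[0, 1] = (coef * F[0, 1] + vterm * c01) * kpa
        P[0, 2] = (coef * F[0, 2] + vterm * c02) * kpa
        P[1, 0] = (coef * F[1, 0] + vterm * c10) * kpa
        P[1, 1] = (coef * F[1, 1] + vterm * c11) * kpa
        P[1, 2] = (coef * F[1, 2] + vterm * c12) * kpa
        P[2, 0] = (coef * F[2, 0] + vterm * c20) * kpa
        P[2, 1] = (coef * F[2, 1] + vterm * c21) * kpa
        P[2, 2] = (coef * F[2, 2] + vterm * c22) * kpa
        ve = vol[e]
        for a in range(4):
            n = elems[e, a]
            g0, g1, g2 = gradN[e, a, 0], gradN[e, a, 1], gradN[e, a, 2]
            f_out[n, 0] -= ve * (P[0, 0] * g0 + P[0, 1] * g1 + P[0, 2] * g2)
            f_out[n, 1] -= ve * (P[1, 0] * g0 + P[1, 1] * g1 + P[1, 2] * g2)
            f_out[n, 2] -= ve * (P[2, 0] * g0 + P[2, 1] * g1 + P[2, 2] * g2)
    return -1


class SingularElementError(ValueError):
    """Reference element is degenerate (zero volume)."""


class ElementInversionError(RuntimeError):
    """Deformation inverted one or more elements."""

    def __init__(self, element_ids, context: str = ""):
        self.element_ids = np.asarray(element_ids)
        msg = (f"{len(self.element_ids)} element(s) inverted"
               f"{' during ' + context if context else ''}: "
               f"{self.element_ids[:20].tolist()}")
        super().__init__(msg)


@dataclass
class StructuralState:
    """Current configuration of the structure."""

    x: np.ndarray                         # (N, 3) current positions, cm
    force_density: Optional[np.ndarray] = None    # (N, 3) dyn/cm^3 (ref)
    F: Optional[np.ndarray] = None        # (E, 3, 3) per-element def. grad.

    def copy(self) -> "StructuralState":
        return StructuralState(
            x=self.x.copy(),
            force_density=None if self.force_density is None
            else self.force_density.copy(),
            F=None if self.F is None else self.F.copy())


def element_deformation_gradient(ref_nodes: np.ndarray,
                                 cur_nodes: np.ndarray) -> np.ndarray:
    """Deformation gradient of a single linear tetrahedron.

    ``F`` maps reference edge vectors to current edge vectors:
    ``F @ (X_a - X_0) = x_a - x_0``.
    """
    ref = np.asarray(ref_nodes, dtype=float)
    cur = np.asarray(cur_nodes, dtype=float)
    D0 = (ref[1:] - ref[0]).T
    if abs(np.linalg.det(D0)) < 1e-300:
        raise SingularElementError("degenerate reference tetrahedron")
    Dc = (cur[1:] - cur[0]).T
    return Dc @ np.linalg.inv(D0)


class StructureFE:
    """Precomputed assembler for a fixed reference mesh.

    Caches per-element reference shape-function gradients, volumes and the
    lumped nodal reference volumes, and groups elements by material region
    so the stress evaluation vectorises per region.
    """

    def __init__(self, mesh: StructuralMesh,
                 materials: Optional[Dict[str, mat.MaterialParams]] = None):
        self.mesh = mesh
        self.materials = dict(materials or mat.default_materials())
        X = mesh.X
        conn = mesh.elements
        v = X[conn]                                   # (E, 4, 3)
        D0 = np.swapaxes(v[:, 1:] - v[:, :1], 1, 2)   # (E, 3, 3) edge cols
        det = np.linalg.det(D0)
        if np.any(np.abs(det) < 1e-300):
            raise SingularElementError("degenerate reference element(s)")
        self.volume = det / 6.0                       # (E,) signed, > 0
        if np.any(self.volume <= 0):
            raise SingularElementError("negatively oriented reference "
                                       "element(s)")
        D0inv = np.linalg.inv(D0)
        # gradN[a] for a=1..3 are rows of D0inv; gradN[0] = -sum
        gN = np.empty((conn.shape[0], 4, 3))
        gN[:, 1:, :] = D0inv
        gN[:, 0, :] = -D0inv.sum(axis=1)
        self.gradN = gN
        # lumped nodal reference volumes
        w = np.zeros(mesh.n_nodes)
        np.add.at(w, conn.ravel(),
                  np.repeat(self.volume / 4.0, 4))
        self.nodal_volume = w
        self._by_region = {
            name: np.flatnonzero(mesh.region == rid)
            for name, rid in REGION_ID.items()
            if np.any(mesh.region == rid)}
        # per-element constitutive coefficient arrays for the fused
        # assembly kernel (0: polynomial c0/c1, 1: exponential c2/c3)
        E = conn.shape[0]
        self._form = np.zeros(E, dtype=np.int8)
        self._ca = np.zeros(E)
        self._cb = np.zeros(E)
        self._beta = np.zeros(E)
        for name, idx in self._by_region.items():
            m = self.materials[name]
            if m.model_form == mat.POLYNOMIAL:
                self._form[idx] = 0
                self._ca[idx] = m.c0
                self._cb[idx] = m.c1
            else:
                self._form[idx] = 1
                self._ca[idx] = m.c2
                self._cb[idx] = m.c3
            self._beta[idx] = m.beta

    # -----------------------------------------------------------------
    def deformation_gradients(self, x: np.ndarray) -> np.ndarray:
        """Per-element deformation gradients at current positions ``x``."""
        v = x[self.mesh.elements]
        # F = sum_a x_a (x) gradN_a  (constant per linear tetrahedron)
        return np.einsum("eai,eaj->eij", v, self.gradN)

    def internal_forces(self, x: np.ndarray, context: str = "",
                        engine: str = "auto",
                        j_floor: float = 0.0) -> np.ndarray:
        """Nodal elastic force densities F_L (dyn/cm^3 reference).

        Raises :class:`ElementInversionError` if any element has J <= 0,
        unless ``j_floor`` > 0, in which case the volumetric response is
        evaluated with J floored at that value -- a finite, corrective
        continuation through transient inversion used by the static
        relaxation solver.  ``engine='numpy'`` forces the reference
        vectorised path (used to cross-check the fused compiled kernel).
        """
        if engine == "auto" and _HAVE_NUMBA:
            f = np.zeros_like(x)
            bad = _assemble_forces(self.mesh.elements, self.gradN,
                                   self.volume,
                                   np.ascontiguousarray(x, dtype=float),
                                   self._form, self._ca, self._cb,
                                   self._beta, f, j_floor)
            if bad >= 0:
                F = self.deformation_gradients(x)
                ids = np.flatnonzero(mat.det33(F) <= 0.0)
                raise ElementInversionError(ids, context)
        else:
            F = self.deformation_gradients(x)
            J = mat.det33(F)
            if j_floor <= 0.0:
                bad = np.flatnonzero(J <= 0.0)
                if bad.size:
                    raise ElementInversionError(bad, context)
                P = np.zeros_like(F)
                for name, idx in self._by_region.items():
                    P[idx] = mat.pk1_stress(self.materials[name], F[idx])
            else:
                Jc = np.maximum(J, j_floor)[:, None, None]
                I1 = np.einsum("eij,eij->e", F, F)
                xm = (I1 - 3.0)[:, None, None]
                coef = np.where(
                    (self._form == 0)[:, None, None],
                    2.0 * self._ca[:, None, None]
                    + 4.0 * self._cb[:, None, None] * xm,
                    4.0 * (self._ca * self._cb)[:, None, None] * xm
                    * np.exp(np.minimum(self._cb[:, None, None]
                                        * xm ** 2, 200.0)))
                coef = np.clip(coef, -1.0e5, 1.0e5)
                cof = mat.cof33(F)
                vterm = np.clip((2.0 * self._beta[:, None, None]
                                 * np.log(Jc) - coef) / Jc, -1.0e6, 1.0e6)
                P = coef * F + vterm * cof
            P *= mat.KPA_TO_DYN_CM2
            # weak form: f_a = -V_e * P . gradN_a   (dyn)
            fa = -np.einsum("e,eij,eaj->eai", self.volume, P, self.gradN)
            f = np.zeros_like(x)
            np.add.at(f, self.mesh.elements.ravel(), fa.reshape(-1, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = f / self.nodal_volume[:, None]
        dens[self.nodal_volume == 0] = 0.0
        return dens

    def element_fields(self, x: np.ndarray):
        """Per-element Cauchy stress (kPa), Tresca max shear (kPa) and max
        principal Green-Lagrange strain -- for post-processing."""
        F = self.deformation_gradients(x)
        P = np.zeros_like(F)
        for name, idx in self._by_region.items():
            P[idx] = mat.pk1_stress(self.materials[name], F[idx])
        sigma = mat.cauchy_stress(F, P)
        return sigma, mat.tresca_max_shear(sigma), \
            mat.max_principal_strain(F)

    def leaflet_stress_strain(self, x: np.ndarray):
        """Max Tresca shear (kPa) and max principal strain over the
        leaflet elements (0, 0 if there are none).  Elements inverted
        under the tolerant continuation are excluded."""
        idx = self._by_region.get("leaflet")
        if idx is None or idx.size == 0:
            return 0.0, 0.0
        v = x[self.mesh.elements[idx]]
        F = np.einsum("eai,eaj->eij", v, self.gradN[idx])
        F = F[mat.det33(F) > 1e-6]
        if F.shape[0] == 0:
            return 0.0, 0.0
        P = mat.pk1_stress(self.materials["leaflet"], F)
        sigma = mat.cauchy_stress(F, P)
        tau = mat.tresca_max_shear(sigma)
        eps = mat.max_principal_strain(F)
        return float(tau.max()), float(eps.max())

    def strain_energy_total(self, x: np.ndarray) -> float:
        """Total elastic energy (erg) at configuration ``x``."""
        F = self.deformation_gradients(x)
        psi = np.zeros(F.shape[0])
        for name, idx in self._by_region.items():
            psi[idx] = mat.strain_energy(self.materials[name], F[idx])
        return float((psi * mat.KPA_TO_DYN_CM2 * self.volume).sum())


def assemble_internal_forces(mesh: StructuralMesh, state: StructuralState,
                             materials: Optional[Dict] = None) -> np.ndarray:
    """One-shot weak-form assembly (see :class:`StructureFE`)."""
    return StructureFE(mesh, materials).internal_forces(state.x)


def tether_forces(mesh: StructuralMesh, state: StructuralState,
                  kappa: float,
                  tethered_nodes: Optional[np.ndarray] = None) -> np.ndarray:
    """Penalty tether force densities on fixed nodes.

    ``force = kappa * (X - x)`` on the tethered node set (default: the
    mesh's fixed end rings), zero elsewhere.  ``kappa`` has units of
    dyn/cm^3 per cm of displacement.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    idx = mesh.fixed_nodes if tethered_nodes is None else tethered_nodes
    f = np.zeros_like(state.x)
    f[idx] = kappa * (mesh.X[idx] - state.x[idx])
    return f
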