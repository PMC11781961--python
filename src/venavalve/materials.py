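"""Hyperelastic constitutive models for venous tissue.

Two isotropic, nearly incompressible strain-energy forms are used for the
three tissue regions of the valve model:

* a polynomial form  ``Psi = c0*(I1-3) + c1*(I1-3)**2 + (beta/4)*log(I3)**2``
  (venous valve leaflets), and
* an exponential form ``Psi = c2*(exp(c3*(I1-3)**2) - 1) + (beta/4)*log(I3)**2``
  (vein wall and sinus, same functional form with different stiffness).

Here ``I1 = tr(F^T F)``, ``I3 = det(F^T F)`` and ``F`` is the deformation
gradient.  The volumetric term ``(beta/4)*log(I3)**2`` penalises volume
change; ``beta`` defaults to 500 kPa.

The first Piola-Kirchhoff stress is the energy gradient plus a correction
term proportional to ``F^{-T}`` that makes the stress vanish identically at
``F = I``.  This correction is known to reduce spurious volume loss at the
fluid-structure interface of immersed-boundary schemes.  For the polynomial
form::

    P = 2*c0*F + 4*c1*(I1-3)*F - [2*c0 + 4*c1*(I1-3)]*F^{-T} + beta*log(I3)*F^{-T}

and for the exponential form::

    P = 4*c2*c3*(I1-3)*exp(c3*(I1-3)**2) * (F - F^{-T}) + beta*log(I3)*F^{-T}

All coefficients and stresses in this module are expressed in kPa; the
finite-element assembly converts to CGS (1 kPa = 1e4 dyn/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

KPA_TO_DYN_CM2 = 1.0e4
MMHG_TO_DYN_CM2 = 1333.22

POLYNOMIAL = "polynomial"
EXPONENTIAL = "exponential"


def det33(F: np.ndarray) -> np.ndarray:
    """Determinant of batched 3x3 tensors (closed form)."""
    return (F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2]
                            - F[..., 1, 2] * F[..., 2, 1])
            - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2]
                              - F[..., 1, 2] * F[..., 2, 0])
            + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1]
                              - F[..., 1, 1] * F[..., 2, 0]))


def cof33(F: np.ndarray) -> np.ndarray:
    """Cofactor matrix of batched 3x3 tensors; ``F^{-T} = cof(F)/det(F)``."""
    c = np.empty_like(F)
    c[..., 0, 0] = F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1]
    c[..., 0, 1] = F[..., 1, 2] * F[..., 2, 0] - F[..., 1, 0] * F[..., 2, 2]
    c[..., 0, 2] = F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]
    c[..., 1, 0] = F[..., 0, 2] * F[..., 2, 1] - F[..., 0, 1] * F[..., 2, 2]
    c[..., 1, 1] = F[..., 0, 0] * F[..., 2, 2] - F[..., 0, 2] * F[..., 2, 0]
    c[..., 1, 2] = F[..., 0, 1] * F[..., 2, 0] - F[..., 0, 0] * F[..., 2, 1]
    c[..., 2, 0] = F[..., 0, 1] * F[..., 1, 2] - F[..., 0, 2] * F[..., 1, 1]
    c[..., 2, 1] = F[..., 0, 2] * F[..., 1, 0] - F[..., 0, 0] * F[..., 1, 2]
    c[..., 2, 2] = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return c


class InvertedDeformationError(ValueError):
    """Raised when det F <= 0 (locally inverted material)."""


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive coefficients for one tissue region.

    Exactly the coefficients belonging to ``model_form`` must be set:
    ``c0`` (kPa) and ``c1`` for the polynomial form, ``c2`` (kPa) and ``c3``
    for the exponential form.  ``beta`` (kPa) is the volumetric penalty.
    """

    model_form: str
    c0: Optional[float] = None
    c1: Optional[float] = None
    c2: Optional[float] = None
    c3: Optional[float] = None
    beta: float = 500.0

    def __post_init__(self) -> None:
        if self.model_form not in (POLYNOMIAL, EXPONENTIAL):
            raise ValueError(f"unknown model_form {self.model_form!r}")
        if self.model_form == POLYNOMIAL:
            need, forbid = ("c0", "c1"), ("c2", "c3")
        else:
            need, forbid = ("c2", "c3"), ("c0", "c1")
        for name in need:
            val = getattr(self, name)
            if val is None:
                raise ValueError(f"{self.model_form} form requires {name}")
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        for name in forbid:
            if getattr(self, name) is not None:
                raise ValueError(
                    f"{name} must not be set for the {self.model_form} form")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")

    def scaled(self, factor: float) -> "MaterialParams":
        """Return a copy with the stress-like coefficients multiplied.

        For the polynomial form both ``c0`` and ``c1`` scale; for the
        exponential form only ``c2`` scales (``c3`` sits inside the exponent
        and is dimensionless).  Used by the fibrotic (x10) and atrophic
        (/10) disease scenarios.
        """
        if self.model_form == POLYNOMIAL:
            return replace(self, c0=self.c0 * factor, c1=self.c1 * factor)
        return replace(self, c2=self.c2 * factor)


#: Default per-region parameter assignment.  The table of coefficients binds
#: the exponential form to the wall (c2=2.00 kPa, c3=187.5) and sinus
#: (c2=0.50 kPa, c3=46.875) and the polynomial form to the leaflets
#: (c0=4 kPa, c1=170.06); the sinus shares the wall's functional form at a
#: lower stiffness.
WALL = MaterialParams(EXPONENTIAL, c2=2.00, c3=187.5)
SINUS = MaterialParams(EXPONENTIAL, c2=0.50, c3=46.875)
LEAFLET = MaterialParams(POLYNOMIAL, c0=4.0, c1=170.06)


def default_materials() -> dict:
    """Per-region default material table (fresh dict)."""
    return {"wall": WALL, "sinus": SINUS, "leaflet": LEAFLET}


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient with cached invariants.

    ``F`` may be a single 3x3 tensor or a batch of shape (..., 3, 3).
    """

    F: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape[-2:] != (3, 3):
            raise ValueError("F must have shape (..., 3, 3)")
        object.__setattr__(self, "F", F)

    @property
    def J(self) -> np.ndarray:
        return np.linalg.det(self.F)

    @property
    def I1(self) -> np.ndarray:
        return np.einsum("...ij,...ij->...", self.F, self.F)

    @property
    def I3(self) -> np.ndarray:
        return self.J ** 2


def _as_F(deformation) -> np.ndarray:
    if isinstance(deformation, DeformationState):
        return deformation.F
    F = np.asarray(deformation, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError("deformation gradient must have shape (..., 3, 3)")
    return F


def _check_J(J: np.ndarray) -> None:
    if np.any(J <= 0):
        raise InvertedDeformationError(
            f"det F must be > 0 everywhere (min {np.min(J):.3e})")


def strain_energy(mat: MaterialParams, deformation) -> np.ndarray:
    """Strain-energy density (kPa) for ``mat`` at the given deformation."""
    F = _as_F(deformation)
    J = np.linalg.det(F)
    _check_J(J)
    I1 = np.einsum("...ij,...ij->...", F, F)
    I3 = J ** 2
    x = I1 - 3.0
    vol = 0.25 * mat.beta * np.log(I3) ** 2
    if mat.model_form == POLYNOMIAL:
        iso = mat.c0 * x + mat.c1 * x ** 2
    else:
        iso = mat.c2 * (np.exp(mat.c3 * x ** 2) - 1.0)
    return iso + vol


def _pk1_parts(mat: MaterialParams, F: np.ndarray):
    """Return (dPsi/dF, correction) in kPa, both shaped like F.

    ``dPsi/dF`` is the exact energy gradient (isochoric + volumetric); the
    correction is the extra ``-(...)*F^{-T}`` term that zeroes the stress at
    the identity.  The full modified stress is their sum.
    """
    J = det33(F)
    _check_J(J)
    I1 = np.einsum("...ij,...ij->...", F, F)
    I3 = J ** 2
    x = (I1 - 3.0)[..., None, None]
    FinvT = cof33(F) / J[..., None, None]
    if mat.model_form == POLYNOMIAL:
        coef = 2.0 * mat.c0 + 4.0 * mat.c1 * x
    else:
        coef = 4.0 * mat.c2 * mat.c3 * x * np.exp(mat.c3 * x ** 2)
    grad = coef * F + mat.beta * np.log(I3)[..., None, None] * FinvT
    correction = -coef * FinvT
    return grad, correction


def pk1_stress(mat: MaterialParams, deformation) -> np.ndarray:
    """Modified first Piola-Kirchhoff stress (kPa).

    Includes the ``F^{-T}`` correction terms, so ``P(I) = 0`` exactly and
    ``P(R) = 0`` for any rotation ``R``.
    """
    grad, correction = _pk1_parts(mat, _as_F(deformation))
    return grad + correction


def pk1_energy_gradient(mat: MaterialParams, deformation) -> np.ndarray:
    """``dPsi/dF`` alone (kPa), i.e. the stress without the correction.

    Exposed so the consistency of the analytic gradient can be verified
    against finite differences of :func:`strain_energy`.
    """
    grad, _ = _pk1_parts(mat, _as_F(deformation))
    return grad


def cauchy_stress(deformation, P: np.ndarray) -> np.ndarray:
    """Cauchy stress ``sigma = J^{-1} P F^T`` (kPa)."""
    F = _as_F(deformation)
    J = np.linalg.det(F)
    _check_J(J)
    P = np.asarray(P, dtype=float)
    return np.einsum("...ik,...jk->...ij", P, F) / J[..., None, None]


def tresca_max_shear(sigma: np.ndarray) -> np.ndarray:
    """Tresca maximum shear stress ``(sigma1 - sigma3)/2`` (kPa).

    The input is symmetrised first; works on batches (..., 3, 3).
    """
    s = np.asarray(sigma, dtype=float)
    s = 0.5 * (s + np.swapaxes(s, -1, -2))
    ev = np.linalg.eigvalsh(s)
    return 0.5 * (ev[..., -1] - ev[..., 0])


def max_principal_strain(deformation) -> np.ndarray:
    """Largest eigenvalue of the Green-Lagrange strain ``E = (F^T F - I)/2``."""
    F = _as_F(deformation)
    _check_J(np.linalg.det(F))
    C = np.einsum("...ki,...kj->...ij", F, F)
    E = 0.5 * (C - np.eye(3))
    return np.linalg.eigvalsh(E)[..., -1]
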