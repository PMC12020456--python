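"""Conductor-like PCM linear response: A matrix, surface charges, energy.

With the cavity discretized into spherical-Gaussian surface charges, the
electrostatic problem is the symmetric linear system

    A q = -f_eps v,      f_eps = (eps - 1) / (eps + x),  x = 0

where v is the solute potential at the surface points and A collects the
Gaussian-Gaussian Coulomb interactions

    A_ij = erf(xi_ij r_ij) / r_ij,   xi_ij = xi_i xi_j / sqrt(xi_i^2 + xi_j^2)
    A_ii = xi_i sqrt(2/pi) / F_i

(the diagonal carries the switching attenuation: a vanishing F_i pushes
A_ii to infinity and the point's charge smoothly to zero).  The
polarization energy is E_pol = 1/2 q.v <= 0 for eps > 1.

``calibrate_xi_born`` fixes the dimensionless Gaussian width prefactor per
grid size by requiring that a single sphere with a central unit charge in a
perfect conductor reproduce the exact Born energy -1/(2R); the root is
radius independent and cached per grid size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, lu_factor, lu_solve
from scipy.optimize import brentq
from scipy.special import erf

from .cavity import Cavity
from .chemio import GRID_ORDERS, Molecule, ParameterSet, ValidationError

__all__ = ["CPCMSolution", "solute_potential", "assemble_A", "solve", "calibrate_xi_born"]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class CPCMSolution:
    """Solved surface-charge state over the active cavity points."""

    v: np.ndarray  # solute potential at active points (hartree/e)
    q: np.ndarray  # induced surface charges (e)
    epol: float  # polarization energy (hartree)
    f_eps: float
    A: np.ndarray  # response matrix over active points (1/bohr)
    factor: tuple  # factorization handle for reuse
    spd: bool  # whether the Cholesky route succeeded


def solute_potential(mol: Molecule, cav: Cavity) -> np.ndarray:
    """Coulomb potential of the fixed solute point charges at active points."""
    pts = cav.points[cav.active]
    d = np.linalg.norm(pts[:, None, :] - mol.positions[None, :, :], axis=-1)
    if np.any(d < 1e-10):
        raise ValidationError("cavity point coincides with a nucleus")
    return (mol.solute_charges[None, :] / d).sum(axis=1)


def assemble_A(cav: Cavity) -> np.ndarray:
    """Symmetric response matrix over the active points (1/bohr)."""
    idx = cav.active_index()
    pts = cav.points[idx]
    xi = cav.xi[idx]
    F = cav.F[idx]
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and r[off].min() < 1e-10:
        raise ValidationError("duplicate cavity points in A assembly")
    xi2 = xi**2
    xij = np.outer(xi, xi) / np.sqrt(xi2[:, None] + xi2[None, :])
    A = np.empty((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        A[off] = erf(xij[off] * r[off]) / r[off]
    A[np.diag_indices(n)] = xi * _SQRT_2_OVER_PI / F
    return A


def solve(mol: Molecule, cav: Cavity, params: ParameterSet) -> CPCMSolution:
    """Induced charges and polarization energy for the current cavity."""
    v = solute_potential(mol, cav)
    A = assemble_A(cav)
    f_eps = params.f_eps
    spd = True
    try:
        factor = cho_factor(A)
        q = cho_solve(factor, -f_eps * v)
    except np.linalg.LinAlgError:
        spd = False
        factor = lu_factor(A)
        q = lu_solve(factor, -f_eps * v)
        import warnings

        warnings.warn(
            f"response matrix not positive definite (cond {np.linalg.cond(A):.2e}); "
            "using LU factorization",
            RuntimeWarning,
            stacklevel=2,
        )
    epol = 0.5 * float(q @ v)
    return CPCMSolution(v=v, q=q, epol=epol, f_eps=f_eps, A=A, factor=factor, spd=spd)


# --------------------------------------------------------------------------
# Born calibration

_XI_BORN_CACHE: dict = {}


def _born_epol(xi_born: float, order: int) -> float:
    """Conductor polarization energy of a unit charge centered in a unit
    sphere, as a function of the width prefactor.

    For this geometry A = (1/R) Ahat with Ahat independent of R, so the
    calibration root is radius independent.
    """
    from .grids import lebedev_grid

    u, w = lebedev_grid(order)
    xi = xi_born / np.sqrt(w)  # R = 1
    diff = u[:, None, :] - u[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    n = order
    off = ~np.eye(n, dtype=bool)
    xi2 = xi**2
    xij = np.outer(xi, xi) / np.sqrt(xi2[:, None] + xi2[None, :])
    A = np.empty((n, n))
    A[off] = erf(xij[off] * r[off]) / r[off]
    A[np.diag_indices(n)] = xi * _SQRT_2_OVER_PI  # single sphere: F = 1
    v = np.ones(n)
    q = cho_solve(cho_factor(A), -v)  # conductor: f_eps = 1
    return 0.5 * float(q @ v)


def calibrate_xi_born(order: int, params: ParameterSet | None = None) -> float:
    """Width prefactor making the single-sphere conductor Born energy exact.

    Cached per grid size; the root is bracketed in (1, 10) and solved to
    machine precision.
    """
    order = int(order)
    if order in _XI_BORN_CACHE:
        return _XI_BORN_CACHE[order]
    if order not in GRID_ORDERS:
        raise ValidationError(f"grid size {order} not in packaged set {GRID_ORDERS}")

    def g(x):
        return _born_epol(x, order) + 0.5

    lo, hi = 1.0, 10.0
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise RuntimeError(
            f"Born calibration bracket [1, 10] has no sign change for size {order}: "
            f"g(1)={glo:.3e}, g(10)={ghi:.3e}"
        )
    xi = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    _XI_BORN_CACHE[order] = xi
    return xi
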