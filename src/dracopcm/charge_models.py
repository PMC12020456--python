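"""Geometry-dependent atomic partial charges and their analytic Jacobians.

Two providers are shipped:

``fixed_charges``
    A degenerate provider: user-supplied charges with an identically zero
    Jacobian.  Useful for tests and for isolating the coordination-number
    chain of the radius-scaling gradient.

``eeq_charges`` / ``eeq_jacobian``
    A classical electronegativity-equilibration (EEQ) model.  The charges
    minimize a quadratic energy with an erf-damped Coulomb kernel under a
    total-charge constraint, i.e. they solve the bordered symmetric system

        [ M   1 ] [ q ]   [ -chi_I + kappa_I sqrt(CN_I) ]
        [ 1^T 0 ] [ l ] = [  Q_total                    ]

    with M_IJ = erf(r_IJ / gamma_IJ) / r_IJ, gamma_IJ = sqrt(a_I^2 + a_J^2),
    and M_II = eta_I + sqrt(2/pi) / alpha_I.  sqrt(CN) is smoothed as
    sqrt(CN + 1e-14) so isolated atoms keep a finite derivative.

Any provider returning a :class:`ChargeResult` whose charges sum to the
molecular charge and whose Jacobian is translationally invariant plugs into
the radius-scaling module unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import erf

from .chemio import Molecule, ParameterSet, ValidationError
from .connectivity import CNResult

__all__ = ["ChargeResult", "fixed_charges", "eeq_charges", "eeq_jacobian", "eeq_full"]

_CN_SMOOTH = 1e-14
_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class ChargeResult:
    """Charges (N,) in e and Jacobian (N, N, 3) in e/bohr.

    ``jacobian[I, A, :]`` is d q_I / d R_A.
    """

    q: np.ndarray
    jacobian: np.ndarray


def fixed_charges(mol: Molecule, values) -> ChargeResult:
    """Constant charges with zero Jacobian."""
    q = np.asarray(values, dtype=float).ravel()
    if q.shape != (mol.n_atoms,):
        raise ValidationError("fixed charge list has wrong length")
    if abs(q.sum() - mol.total_charge) > 1e-8:
        raise ValidationError(
            f"fixed charges sum to {q.sum():.10f}, expected {mol.total_charge}"
        )
    return ChargeResult(q=q, jacobian=np.zeros((mol.n_atoms, mol.n_atoms, 3)))


def _eeq_system(mol: Molecule, params: ParameterSet):
    """Bordered EEQ matrix, its LU factorization, and kernel geometry."""
    n = mol.n_atoms
    arr = params.arrays(mol)
    alpha, eta = arr["alpha"], arr["eta"]
    pos = mol.positions
    dvec = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(dvec, axis=-1)
    gamma = np.sqrt(alpha[:, None] ** 2 + alpha[None, :] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = erf(r / gamma) / r
    kernel[np.diag_indices(n)] = eta + _SQRT_2_OVER_PI / alpha
    m = np.zeros((n + 1, n + 1))
    m[:n, :n] = kernel
    m[:n, n] = 1.0
    m[n, :n] = 1.0
    try:
        factor = lu_factor(m)
    except Exception as exc:  # pragma: no cover - singular parametrization
        cond = np.linalg.cond(m)
        raise np.linalg.LinAlgError(
            f"EEQ system not solvable (condition number {cond:.3e})"
        ) from exc
    return m, factor, dvec, r, gamma


def _eeq_rhs(mol: Molecule, params: ParameterSet, cn: np.ndarray) -> np.ndarray:
    arr = params.arrays(mol)
    rhs = np.empty(mol.n_atoms + 1)
    rhs[:-1] = -arr["chi"] + arr["kappa_cn"] * np.sqrt(cn + _CN_SMOOTH)
    rhs[-1] = mol.total_charge
    return rhs


def eeq_charges(mol: Molecule, params: ParameterSet, cn: CNResult) -> np.ndarray:
    """EEQ charges (N,), summing to the molecular charge."""
    _, factor, *_ = _eeq_system(mol, params)
    rhs = _eeq_rhs(mol, params, cn.cn)
    return lu_solve(factor, rhs)[:-1]


def eeq_jacobian(mol: Molecule, params: ParameterSet, cn: CNResult) -> np.ndarray:
    """Analytic d q_I / d R_A as (N, N, 3), by differentiating the linear system.

    With M qt = b (qt the bordered unknown vector), d qt = M^{-1} (db - dM qt):
    the kernel derivative contributes through dM, the coordination-number
    chain through db.
    """
    n = mol.n_atoms
    _, factor, dvec, r, gamma = _eeq_system(mol, params)
    rhs = _eeq_rhs(mol, params, cn.cn)
    qt = lu_solve(factor, rhs)
    q = qt[:-1]

    arr = params.arrays(mol)
    kappa = arr["kappa_cn"]
    # d kernel / d r for off-diagonal pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        dker = (
            2.0 / (np.sqrt(np.pi) * gamma) * np.exp(-((r / gamma) ** 2)) / r
            - erf(r / gamma) / r**2
        )
    dker[np.diag_indices(n)] = 0.0
    rhat = np.zeros_like(dvec)
    mask = r > 0
    rhat[mask] = dvec[mask] / r[mask][:, None]

    # (dM qt)_I for every displaced atom A and component:
    # only rows/cols I != J carry geometry; d r_IJ / d R_A = rhat_IJ (d_IA - d_JA)
    g = dker * q[None, :]  # g[I, J] = dK_IJ * q_J
    rhs_d = np.zeros((n, 3, n + 1))  # (A, comp, row); rhs = db - dM qt
    idx = np.arange(n)
    # (dM qt)_I for A == I: sum_J dK_IJ q_J rhat_IJ  (enters with minus sign)
    row_own = np.einsum("ij,ijc->ic", g, rhat)  # (I, comp)
    rhs_d[idx, :, idx] -= row_own
    # (dM qt)_I for A == J != I: -dK_IJ q_J rhat_IJ  (enters with plus sign)
    rhs_d[:, :, :n] += np.transpose(g[:, :, None] * rhat, (1, 2, 0))
    # db: CN chain term, rows I for every A
    dsqrt = kappa / (2.0 * np.sqrt(cn.cn + _CN_SMOOTH))  # (I,)
    db = dsqrt[:, None, None] * cn.jacobian  # (I, A, comp)
    rhs_d[:, :, :n] += np.transpose(db, (1, 2, 0))
    # solve M d qt = (db - dM qt) for all 3N right-hand sides at once
    flat = rhs_d.reshape(3 * n, n + 1).T  # column j = (A, comp) C-flattened
    sol = lu_solve(factor, flat)  # (n+1, 3N)
    return sol[:-1].reshape(n, n, 3)  # (row I, A, comp)


def eeq_full(mol: Molecule, params: ParameterSet, cn: CNResult) -> ChargeResult:
    """Charges and Jacobian in one call."""
    return ChargeResult(
        q=eeq_charges(mol, params, cn),
        jacobian=eeq_jacobian(mol, params, cn),
    )
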