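"""Smooth coordination numbers and their position derivatives.

The coordination number of atom I is a smooth neighbor count

    CN_I = sum_{J != I} 1 / (f1_IJ * f2_IJ)

built from two logistic-type counting factors of the interatomic distance
r_IJ measured against the covalent-radius sum R_IJ,cov = Rcov_I + Rcov_J:

    f1 = 1 + exp(-10 [ (4/3) R_IJ,cov / r_IJ - 1 ])
    f2 = 1 + exp(-20 [ ((4/3) R_IJ,cov + s) / r_IJ - 1 ])

The second factor damps the count at long range; its additive shift ``s``
(default 2 bohr) is a length and is configurable through
``ParameterSet.cn_shift``.  Both CN and its full N x N x 3 position Jacobian
are returned; the Jacobian is what the radius-scaling chain terms of the
nuclear gradient consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import Molecule, ParameterSet, ValidationError

__all__ = ["CNResult", "coordination_number", "cn_jacobian", "cn_full"]


@dataclass(frozen=True)
class CNResult:
    """Coordination numbers (N,) and Jacobian (N, N, 3).

    ``jacobian[I, A, :]`` is d CN_I / d R_A in 1/bohr.
    """

    cn: np.ndarray
    jacobian: np.ndarray


def _pair_terms(mol: Molecule, params: ParameterSet):
    """Distances, counting factors and their radial derivatives per pair."""
    n = mol.n_atoms
    pos = mol.positions
    rcov = np.array([params.element(s).rcov for s in mol.symbols])
    dvec = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(dvec, axis=-1)
    np.fill_diagonal(r, np.inf)
    if np.min(r) <= 1e-6:
        raise ValidationError("coincident atoms in coordination number")
    rc = (4.0 / 3.0) * (rcov[:, None] + rcov[None, :])
    s = params.cn_shift
    e1 = np.exp(-10.0 * (rc / r - 1.0))
    e2 = np.exp(-20.0 * ((rc + s) / r - 1.0))
    f1 = 1.0 + e1
    f2 = 1.0 + e2
    # d f / d r_IJ (scalars)
    df1 = e1 * 10.0 * rc / r**2
    df2 = e2 * 20.0 * (rc + s) / r**2
    return dvec, r, f1, f2, df1, df2


def coordination_number(mol: Molecule, params: ParameterSet) -> np.ndarray:
    """CN per atom (dimensionless, >= 0)."""
    if mol.n_atoms == 1:
        return np.zeros(1)
    _, _, f1, f2, _, _ = _pair_terms(mol, params)
    inv = 1.0 / (f1 * f2)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1)


def cn_jacobian(mol: Molecule, params: ParameterSet) -> np.ndarray:
    """d CN_I / d R_A as an (N, N, 3) tensor (1/bohr)."""
    n = mol.n_atoms
    jac = np.zeros((n, n, 3))
    if n == 1:
        return jac
    dvec, r, f1, f2, df1, df2 = _pair_terms(mol, params)
    # dCN_I/dr_IJ for each pair (I, J)
    dcn_dr = -(df1 / (f1**2 * f2) + df2 / (f1 * f2**2))
    np.fill_diagonal(dcn_dr, 0.0)
    rhat = dvec / r[:, :, None]  # unit vector from J to I
    # dr_IJ/dR_I = +rhat, dr_IJ/dR_J = -rhat
    contrib = dcn_dr[:, :, None] * rhat  # (I, J, 3) = dCN_I/dR_I pair pieces
    jac = -contrib  # displacing A = J flips the sign of the pair term
    idx = np.arange(n)
    jac[idx, idx, :] = contrib.sum(axis=1)
    return jac


def cn_full(mol: Molecule, params: ParameterSet) -> CNResult:
    """Coordination numbers together with their Jacobian."""
    return CNResult(coordination_number(mol, params), cn_jacobian(mol, params))
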