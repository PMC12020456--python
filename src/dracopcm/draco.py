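"""Dynamic cavity radii: charge- and coordination-dependent radius scaling.

Each sphere radius is the element base radius scaled by a smooth function of
an effective atomic charge,

    q_eff,I = q_I * (1 + k_Z * CN_I)
    f_I     = erf( a_Z * (q_eff,I - b_Z) ) + 1          in (0, 2)
    R_I     = f_I * R_I,0

so more positively charged atoms grow and more negatively charged atoms
shrink (or vice versa, per the sign of a_Z).  The Jacobian

    dR_I/dR_A = (2 R_I,0 a_Z / sqrt(pi)) exp(-[a_Z (q_eff,I - b_Z)]^2)
                * [ dq_I/dR_A (1 + k_Z CN_I) + q_I k_Z dCN_I/dR_A ]

is the quantity that makes every cavity-derived object geometry dependent;
it feeds the chain terms of the nuclear gradient.  With a_Z = 0 for every
element the scaling is exactly 1, the Jacobian exactly zero, and the static
fixed-radii model is recovered bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .charge_models import ChargeResult
from .chemio import Molecule, ParameterSet
from .connectivity import CNResult

__all__ = ["DracoRadii", "scale_radii", "radii_jacobian", "dynamic_radii", "static_radii"]


@dataclass(frozen=True)
class DracoRadii:
    """Per-sphere radii (bohr), their Jacobian and a static-shortcut flag.

    ``jacobian[I, A, :]`` is d R_I / d R_A (dimensionless).  ``static_flag``
    is True when the Jacobian is identically zero, letting downstream code
    skip every chain term.
    """

    radii: np.ndarray
    jacobian: np.ndarray
    static_flag: bool


def _scaling_inputs(mol: Molecule, params: ParameterSet, charges: ChargeResult, cn: CNResult):
    arr = params.arrays(mol)
    q_eff = charges.q * (1.0 + arr["k"] * cn.cn)
    u = arr["a"] * (q_eff - arr["b"])
    return arr, q_eff, u


def scale_radii(
    mol: Molecule, params: ParameterSet, charges: ChargeResult, cn: CNResult
) -> np.ndarray:
    """Scaled radii R_I = (erf(a (q_eff - b)) + 1) R_I,0 (bohr)."""
    arr, _, u = _scaling_inputs(mol, params, charges, cn)
    return (erf(u) + 1.0) * arr["r0"]


def radii_jacobian(
    mol: Molecule, params: ParameterSet, charges: ChargeResult, cn: CNResult
) -> np.ndarray:
    """Analytic d R_I / d R_A as (N, N, 3)."""
    arr, _, u = _scaling_inputs(mol, params, charges, cn)
    pref = (2.0 / np.sqrt(np.pi)) * arr["r0"] * arr["a"] * np.exp(-(u**2))  # (I,)
    chain = (
        charges.jacobian * (1.0 + arr["k"] * cn.cn)[:, None, None]
        + (charges.q * arr["k"])[:, None, None] * cn.jacobian
    )
    return pref[:, None, None] * chain


def dynamic_radii(
    mol: Molecule, params: ParameterSet, charges: ChargeResult, cn: CNResult
) -> DracoRadii:
    """Scaled radii plus Jacobian."""
    arr = params.arrays(mol)
    jac = radii_jacobian(mol, params, charges, cn)
    static = bool(np.all(arr["a"] == 0.0)) or not np.any(jac)
    return DracoRadii(
        radii=scale_radii(mol, params, charges, cn),
        jacobian=jac,
        static_flag=static,
    )


def static_radii(mol: Molecule, params: ParameterSet) -> DracoRadii:
    """Unscaled base radii with zero Jacobian (plain fixed-radii model)."""
    n = mol.n_atoms
    return DracoRadii(
        radii=params.arrays(mol)["r0"].copy(),
        jacobian=np.zeros((n, n, 3)),
        static_flag=True,
    )
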