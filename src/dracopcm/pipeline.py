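"""End-to-end driver: geometry -> charges -> radii -> cavity -> energy/gradient.

This is the composition every caller (CLI, scans, finite-difference oracles)
goes through, so that a displaced geometry rebuilds *everything*: the
coordination numbers, the equilibrated charges, the scaled radii, the cavity
and the linear system.  Only the per-grid-size Born calibration constant is
cached across calls (it is geometry independent by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from .cavity import Cavity, FrozenOrderCache, build_cavity
from .charge_models import ChargeResult, eeq_full, fixed_charges
from .chemio import Molecule, ParameterSet, ValidationError
from .connectivity import cn_full
from .draco import DracoRadii, dynamic_radii, static_radii
from .gradient import GradientResult, assemble_gradient
from .solver import CPCMSolution, solve

__all__ = ["SolvationState", "compute", "energy", "gradient"]


@dataclass(frozen=True)
class SolvationState:
    """Every intermediate of one solvation calculation."""

    mol: Molecule
    params: ParameterSet
    radii: DracoRadii
    cavity: Cavity
    solution: CPCMSolution
    charges: ChargeResult | None = None

    @property
    def epol(self) -> float:
        return self.solution.epol

    def gradient(self) -> GradientResult:
        return assemble_gradient(
            self.solution, self.mol, self.cavity, self.radii, self.params
        )

    def to_record(self) -> dict:
        """JSON-ready summary of the solved state."""
        return {
            "epol": self.solution.epol,
            "f_eps": self.solution.f_eps,
            "n_active": self.cavity.n_active,
            "radii_bohr": self.radii.radii.tolist(),
            "orders": self.cavity.orders.tolist(),
            "static_radii": self.radii.static_flag,
        }


def compute(
    mol: Molecule,
    params: ParameterSet,
    draco: bool = True,
    charge_model: str = "eeq",
    fixed_q=None,
    cache: FrozenOrderCache | None = None,
) -> SolvationState:
    """Run the full pipeline on one geometry.

    ``draco=False`` uses the static base radii (zero radii Jacobian);
    ``charge_model`` is ``"eeq"`` or ``"fixed"`` (with ``fixed_q`` values)
    and only matters when the dynamic radii are on.
    """
    params.for_molecule(mol)
    charges = None
    if draco:
        cn = cn_full(mol, params)
        if charge_model == "eeq":
            charges = eeq_full(mol, params, cn)
        elif charge_model == "fixed":
            if fixed_q is None:
                raise ValidationError("charge_model='fixed' needs fixed_q values")
            charges = fixed_charges(mol, fixed_q)
        else:
            raise ValidationError(f"unknown charge model {charge_model!r}")
        radii = dynamic_radii(mol, params, charges, cn)
    else:
        radii = static_radii(mol, params)
    cav = build_cavity(mol, radii, params, cache=cache)
    sol = solve(mol, cav, params)
    return SolvationState(
        mol=mol, params=params, radii=radii, cavity=cav, solution=sol, charges=charges
    )


def energy(mol: Molecule, params: ParameterSet, **kw) -> float:
    """Polarization energy (hartree) of one geometry."""
    return compute(mol, params, **kw).epol


def gradient(mol: Molecule, params: ParameterSet, **kw) -> GradientResult:
    """Analytic dE_pol/dR for one geometry."""
    return compute(mol, params, **kw).gradient()
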