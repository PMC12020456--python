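"""Numerical-gradient oracle, potential-energy-surface scans, fixtures.

The four-point central difference

    dE/dx = [ -E(x+2d) + 8 E(x+d) - 8 E(x-d) + E(x-2d) ] / (12 d)

with d = 5e-3 bohr is the independent oracle for the analytic gradient; the
whole pipeline (charges, coordination numbers, radii, cavity) is rebuilt at
every displaced geometry and no translational-invariance shortcut is taken.

``bond_scan`` stretches one bond of a triatomic through a range of scale
factors and records energy, gradient projection and cavity size at every
step, together with the energy-gradient consistency metric

    max_k | E_{k+1} - E_k - 1/2 (g_k + g_{k+1}) . dr |

which stays at trapezoid-rule accuracy on a continuous surface and spikes
where the surface jumps (e.g. when the isodensity scheme switches grid
sizes mid-scan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cavity import FrozenOrderCache
from .chemio import Molecule, ParameterSet, ValidationError
from .pipeline import compute
from .units import angstrom_to_bohr

__all__ = [
    "DELTA_FD",
    "numerical_gradient",
    "ScanRecord",
    "bond_scan",
    "FixtureSpec",
    "random_molecule",
    "water_like",
]

#: default finite-difference step (bohr)
DELTA_FD = 5.0e-3


def numerical_gradient(energy_fn, mol: Molecule, delta: float = DELTA_FD) -> np.ndarray:
    """Four-point central-difference gradient of ``energy_fn`` (N, 3)."""
    n = mol.n_atoms
    out = np.zeros((n, 3))
    for a in range(n):
        for c in range(3):
            e = np.zeros(3)
            e[c] = delta
            vals = [
                energy_fn(mol.displaced(a, f * e)) for f in (2.0, 1.0, -1.0, -2.0)
            ]
            if not all(np.isfinite(vals)):
                raise ValidationError(
                    f"non-finite energy at displacement atom {a} component {c}"
                )
            out[a, c] = (-vals[0] + 8.0 * vals[1] - 8.0 * vals[2] + vals[3]) / (
                12.0 * delta
            )
    return out


# --------------------------------------------------------------------------
# scans


@dataclass(frozen=True)
class ScanRecord:
    """One step of a bond scan."""

    factor: float  # bond scale relative to the reference geometry
    epol: float  # hartree
    grad_proj: float  # gradient projection on the scan coordinate, hartree/bohr
    n_active: int
    radii: np.ndarray  # per-atom sphere radii, bohr


def water_like(oh: float = 0.9572, angle_deg: float = 104.52) -> Molecule:
    """Synthetic water-like triatomic with fixed classical charges.

    O at the origin, both H at distance ``oh`` (angstrom); charges
    (-0.8, +0.4, +0.4) e mimic a polar solute without any electronic
    structure.
    """
    t = np.deg2rad(angle_deg)
    r = angstrom_to_bohr(oh)
    pos = np.array(
        [
            [0.0, 0.0, 0.0],
            [r, 0.0, 0.0],
            [r * np.cos(t), r * np.sin(t), 0.0],
        ]
    )
    return Molecule(["O", "H", "H"], pos, [-0.8, 0.4, 0.4], total_charge=0.0)


def bond_scan(
    mol: Molecule,
    params: ParameterSet,
    lo: float = 0.8,
    hi: float = 2.0,
    step_ang: float = 1.0e-3,
    atom: int = 1,
    anchor: int = 0,
    draco: bool = True,
    charge_model: str = "eeq",
    fixed_q=None,
) -> list[ScanRecord]:
    """Stretch the ``anchor``-``atom`` bond from lo x to hi x its length.

    ``step_ang`` is the step of the scan coordinate in angstrom.  The scheme
    comes from ``params``; the isodensity-frozen scheme keeps the grid sizes
    chosen at the first step.
    """
    bond = mol.positions[atom] - mol.positions[anchor]
    r0 = np.linalg.norm(bond)
    direction = bond / r0
    step = angstrom_to_bohr(step_ang) / r0  # step in scale factor
    factors = np.arange(lo, hi + 0.5 * step, step)
    cache = FrozenOrderCache() if params.scheme == "isodensity-frozen" else None
    records = []
    for fac in factors:
        pos = mol.positions.copy()
        pos[atom] = pos[anchor] + fac * r0 * direction
        m = Molecule(mol.symbols, pos, mol.solute_charges, mol.total_charge)
        state = compute(
            m, params, draco=draco, charge_model=charge_model, fixed_q=fixed_q, cache=cache
        )
        g = state.gradient().total
        records.append(
            ScanRecord(
                factor=float(fac),
                epol=state.epol,
                grad_proj=float(g[atom] @ direction),
                n_active=state.cavity.n_active,
                radii=state.radii.radii.copy(),
            )
        )
    return records


def consistency_metric(records: list[ScanRecord], r0_bohr: float) -> np.ndarray:
    """Per-interval |dE - mean gradient * dr| of a scan (hartree)."""
    f = np.array([r.factor for r in records])
    e = np.array([r.epol for r in records])
    g = np.array([r.grad_proj for r in records])
    dr = np.diff(f) * r0_bohr
    return np.abs(np.diff(e) - 0.5 * (g[1:] + g[:-1]) * dr)


# --------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible random-cluster specification."""

    seed: int
    n_atoms: int = 5
    elements: tuple = ("H", "C", "N", "O")
    box: float = 10.0  # bohr
    min_dist: float = 2.0  # bohr
    #: "zero", "uniform:<Q>" (total Q spread evenly), or "random:<s>"
    #: (zero-sum per-atom charges drawn uniformly from +-s)
    charge: str = "random:0.4"
    max_attempts: int = 2000


def random_molecule(spec: FixtureSpec) -> Molecule:
    """Rejection-sampled random cluster, deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_attempts):
        pos = rng.uniform(-spec.box / 2, spec.box / 2, (spec.n_atoms, 3))
        if spec.n_atoms > 1:
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            d[np.diag_indices(spec.n_atoms)] = np.inf
            if d.min() < spec.min_dist:
                continue
        symbols = [spec.elements[i] for i in rng.integers(0, len(spec.elements), spec.n_atoms)]
        if spec.charge.startswith("uniform:"):
            total = float(spec.charge.split(":", 1)[1])
            q = np.full(spec.n_atoms, total / spec.n_atoms)
        elif spec.charge.startswith("random:"):
            scale = float(spec.charge.split(":", 1)[1])
            total = 0.0
            q = rng.uniform(-scale, scale, spec.n_atoms)
            q -= q.mean()  # neutral solute with a nonzero potential
        else:
            total = 0.0
            q = np.zeros(spec.n_atoms)
        return Molecule(symbols, pos, q, total_charge=total)
    raise ValidationError(
        f"could not place {spec.n_atoms} atoms at min distance {spec.min_dist} "
        f"in a box of {spec.box} bohr after {spec.max_attempts} attempts"
    )
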