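"""Domain types and file I/O.

A :class:`Molecule` is a classical solute: element symbols, positions and
fixed per-atom point charges that generate the electrostatic potential on the
cavity.  A :class:`ParameterSet` collects every tunable of the solvation
model: per-element radii and charge-model parameters, the solvent dielectric,
and the cavity discretization controls.

Internal units are atomic units throughout (bohr / hartree / e); XYZ files
and config radii are read in angstrom and converted on input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .elements import default_element_table
from .units import angstrom_to_bohr, bohr_to_angstrom

try:  # tomllib is stdlib from 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None

#: Lebedev-style octahedral grid sizes packaged with dracopcm.
GRID_ORDERS = (6, 14, 26, 38, 50, 74, 86, 110, 146, 170, 194, 302, 350, 434, 590, 770)

SCHEMES = ("isogrid", "isodensity", "isodensity-frozen")


class ParseError(ValueError):
    """Malformed input file."""


class ElementError(KeyError):
    """Element symbol without a parameter entry."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


# --------------------------------------------------------------------------
# Molecule


@dataclass(frozen=True)
class Molecule:
    """Classical solute.

    Parameters
    ----------
    symbols : list of str
        Element symbols.
    positions : (N, 3) ndarray
        Nuclear Cartesian coordinates in bohr.
    solute_charges : (N,) ndarray
        Fixed point charges Z_K (e) generating the solute potential.  These
        are inputs, independent of geometry; the geometry-dependent charges
        of the radius-scaling model are a separate quantity.
    total_charge : float
        Net charge of the solute (e).
    """

    symbols: tuple
    positions: np.ndarray
    solute_charges: np.ndarray
    total_charge: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        q = np.asarray(self.solute_charges, dtype=float).ravel()
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "solute_charges", q)
        n = len(self.symbols)
        if n < 1:
            raise ValidationError("molecule needs at least one atom")
        if pos.shape != (n, 3) or q.shape != (n,):
            raise ValidationError("inconsistent symbols/positions/charges shapes")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("non-finite coordinates")
        if n > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            d[np.diag_indices(n)] = np.inf
            if d.min() <= 1e-6:
                raise ValidationError(
                    f"coincident atoms: minimum pair distance {d.min():.2e} bohr"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def displaced(self, atom: int, delta: np.ndarray) -> "Molecule":
        """A copy with one atom displaced by ``delta`` (bohr)."""
        pos = self.positions.copy()
        pos[atom] = pos[atom] + delta
        return replace(self, positions=pos)


def read_xyz(path, charge_spec="zero") -> Molecule:
    """Read a standard XYZ file (coordinates in angstrom).

    ``charge_spec`` assigns the fixed solute charges:

    - ``"zero"``: all zero;
    - a sequence of N floats: explicit per-atom charges;
    - a mapping {atom index: charge}: formal charges on selected atoms,
      zero elsewhere.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: expected atom count") from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}: header claims {n} atoms, found {len(lines) - 2}")
    symbols, coords = [], []
    for ln in range(2, 2 + n):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln + 1}: expected 'symbol x y z'")
        sym = parts[0].capitalize()
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}:{ln + 1}: non-numeric coordinate") from None
        symbols.append(sym)
        coords.append(xyz)
    pos = angstrom_to_bohr(np.array(coords))
    charges = _resolve_charges(charge_spec, n)
    return Molecule(symbols, pos, charges, total_charge=float(charges.sum()))


def _resolve_charges(charge_spec, n: int) -> np.ndarray:
    if charge_spec is None or (isinstance(charge_spec, str) and charge_spec == "zero"):
        return np.zeros(n)
    if isinstance(charge_spec, dict):
        q = np.zeros(n)
        for idx, val in charge_spec.items():
            q[int(idx)] = float(val)
        return q
    q = np.asarray(charge_spec, dtype=float).ravel()
    if q.shape != (n,):
        raise ValidationError(f"charge list length {q.size} != atom count {n}")
    return q


def write_xyz(path, mol: Molecule, comment: str = "") -> None:
    """Write a standard XYZ file (angstrom)."""
    with open(path, "w") as fh:
        fh.write(f"{mol.n_atoms}\n{comment}\n")
        for sym, r in zip(mol.symbols, bohr_to_angstrom(mol.positions)):
            fh.write(f"{sym} {r[0]:.12f} {r[1]:.12f} {r[2]:.12f}\n")


# --------------------------------------------------------------------------
# ParameterSet


@dataclass(frozen=True)
class ElementParams:
    """Per-element parameters, internal units (radii in bohr)."""

    r0: float
    rcov: float
    chi: float
    eta: float
    alpha: float
    kappa_cn: float
    a: float
    b: float
    k: float


@dataclass(frozen=True)
class ParameterSet:
    """Model parameters.

    ``epsilon`` may be ``math.inf`` (perfect conductor).  ``cn_shift`` is the
    additive constant (bohr) in the long-range factor of the coordination
    number counting function.  ``rho_leb`` is the target surface point
    density of the isodensity scheme in points per square angstrom.
    """

    elements: dict = field(default_factory=dict)
    epsilon: float = 78.4
    scheme: str = "isogrid"
    n_leb: int = 194
    rho_leb: float = 7.5
    f_min: float = 1e-8
    cn_shift: float = 2.0
    x_dielectric: float = 0.0

    def __post_init__(self):
        if not (self.epsilon >= 1.0):  # also rejects nan
            raise ValidationError(f"epsilon must be >= 1, got {self.epsilon}")
        if self.scheme not in SCHEMES:
            raise ValidationError(f"scheme must be one of {SCHEMES}")
        if self.n_leb not in GRID_ORDERS:
            raise ValidationError(
                f"n_leb={self.n_leb} not in packaged grid set {GRID_ORDERS}"
            )
        if self.rho_leb <= 0:
            raise ValidationError("rho_leb must be positive")
        if not (0 <= self.f_min < 1):
            raise ValidationError("f_min must lie in [0, 1)")
        for sym, ep in self.elements.items():
            if ep.r0 <= 0:
                raise ValidationError(f"{sym}: base radius must be positive")
            if ep.rcov <= 0:
                raise ValidationError(f"{sym}: covalent radius must be positive")
            if ep.alpha <= 0:
                raise ValidationError(f"{sym}: EEQ width alpha must be positive")

    @property
    def f_eps(self) -> float:
        """Dielectric screening factor (eps-1)/(eps+x); 1 for a conductor."""
        if math.isinf(self.epsilon):
            return 1.0
        return (self.epsilon - 1.0) / (self.epsilon + self.x_dielectric)

    def element(self, sym: str) -> ElementParams:
        try:
            return self.elements[sym]
        except KeyError:
            raise ElementError(
                f"no parameters for element {sym!r}; add it to the config"
            ) from None

    def for_molecule(self, mol: Molecule) -> None:
        """Validate that every element of ``mol`` has parameters."""
        for sym in mol.symbols:
            self.element(sym)

    # convenience per-molecule arrays -------------------------------------
    def arrays(self, mol: Molecule) -> dict:
        """Per-atom parameter arrays for ``mol`` (bohr / a.u.)."""
        eps = [self.element(s) for s in mol.symbols]
        return {
            name: np.array([getattr(e, name) for e in eps])
            for name in ("r0", "rcov", "chi", "eta", "alpha", "kappa_cn", "a", "b", "k")
        }


def _element_from_config(sym: str, entry: dict, base: dict) -> ElementParams:
    """Merge a config entry (radii in angstrom) over the default table."""
    merged = dict(base.get(sym, {}))
    merged.update(entry)
    required = ("r0", "rcov", "chi", "eta", "alpha", "kappa_cn", "a", "b", "k")
    missing = [kk for kk in required if kk not in merged]
    if missing:
        raise ValidationError(f"element {sym}: missing parameters {missing}")
    return ElementParams(
        r0=angstrom_to_bohr(float(merged["r0"])),
        rcov=angstrom_to_bohr(float(merged["rcov"])),
        chi=float(merged["chi"]),
        eta=float(merged["eta"]),
        alpha=float(merged["alpha"]),
        kappa_cn=float(merged["kappa_cn"]),
        a=float(merged["a"]),
        b=float(merged["b"]),
        k=float(merged["k"]),
    )


def load_parameters(path=None, overrides: dict | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a TOML/JSON config file.

    An empty or missing config gives the shipped defaults (water-like
    dielectric 78.4, isogrid scheme with 194 points per sphere).  Element
    entries in the config are merged over the default table; radii are given
    in angstrom.  ``overrides`` (same structure as the file content) wins
    over both.
    """
    cfg: dict = {}
    if path is not None:
        text = open(path, "rb").read()
        if str(path).endswith(".json"):
            cfg = json.loads(text.decode())
        else:
            if tomllib is None:  # pragma: no cover
                raise RuntimeError("TOML config requires Python >= 3.11")
            cfg = tomllib.load(open(path, "rb"))
    if overrides:
        elems = {**cfg.get("elements", {})}
        for sym, entry in overrides.get("elements", {}).items():
            elems[sym] = {**elems.get(sym, {}), **entry}
        cfg = {**cfg, **{k: v for k, v in overrides.items() if k != "elements"}}
        if elems:
            cfg["elements"] = elems

    base = default_element_table()
    elem_cfg = cfg.get("elements", {})
    symbols = set(base) | set(elem_cfg)
    elements = {
        sym: _element_from_config(sym, elem_cfg.get(sym, {}), base) for sym in symbols
    }

    eps = cfg.get("epsilon", 78.4)
    if isinstance(eps, str):
        if eps.lower() in ("inf", "conductor"):
            eps = math.inf
        else:
            eps = float(eps)
    return ParameterSet(
        elements=elements,
        epsilon=float(eps),
        scheme=cfg.get("scheme", "isogrid"),
        n_leb=int(cfg.get("n_leb", 194)),
        rho_leb=float(cfg.get("rho_leb", 7.5)),
        f_min=float(cfg.get("f_min", 1e-8)),
        cn_shift=float(cfg.get("cn_shift", 2.0)),
        x_dielectric=float(cfg.get("x_dielectric", 0.0)),
    )
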