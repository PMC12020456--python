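"""Default per-element parameter tables.

Every entry is overridable from the user config; these defaults exist so the
package runs out of the box on ordinary organic/inorganic solutes.

Columns (units):
  r0       base cavity radius, angstrom (Bondi-style van der Waals radius
           scaled by the conventional 1.2 electrostatic-cavity factor)
  rcov     single-bond covalent radius, angstrom (used by the coordination
           number counting function)
  chi      electronegativity parameter of the charge-equilibration model
           (hartree / e)
  eta      chemical hardness (hartree / e^2)
  alpha    Gaussian charge width of the equilibration kernel (bohr)
  kappa_cn coordination-number coupling of the electronegativity (hartree / e)
  a, b, k  cavity-radius scaling parameters: steepness (1/e), charge offset
           (e) and coordination-number coupling (dimensionless) of the
           erf-based radius scaling function
"""

# fmt: off
_BONDI = {
    "H": 1.20, "He": 1.40, "Li": 1.82, "Be": 1.53, "B": 1.92, "C": 1.70,
    "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54, "Na": 2.27, "Mg": 1.73,
    "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Fe": 2.00, "Ni": 1.63, "Cu": 1.40, "Zn": 1.39,
    "Br": 1.85, "I": 1.98,
}

_RCOV = {
    "H": 0.32, "He": 0.46, "Li": 1.33, "Be": 1.02, "B": 0.85, "C": 0.75,
    "N": 0.71, "O": 0.63, "F": 0.64, "Ne": 0.67, "Na": 1.55, "Mg": 1.39,
    "Al": 1.26, "Si": 1.16, "P": 1.11, "S": 1.03, "Cl": 0.99, "Ar": 0.96,
    "K": 1.96, "Ca": 1.71, "Fe": 1.16, "Ni": 1.10, "Cu": 1.12, "Zn": 1.18,
    "Br": 1.14, "I": 1.33,
}

# charge-equilibration parameters: (chi, eta, alpha, kappa_cn)
_EEQ = {
    "H":  (1.20, 0.80, 0.80, 0.05),
    "He": (1.50, 1.50, 0.90, 0.00),
    "Li": (0.90, 0.45, 1.60, 0.05),
    "Be": (1.00, 0.50, 1.40, 0.05),
    "B":  (1.25, 0.55, 1.40, 0.06),
    "C":  (1.40, 0.60, 1.40, 0.08),
    "N":  (1.60, 0.65, 1.30, 0.10),
    "O":  (1.80, 0.70, 1.20, 0.12),
    "F":  (2.00, 0.80, 1.10, 0.10),
    "Ne": (2.00, 1.60, 1.00, 0.00),
    "Na": (0.90, 0.40, 1.80, 0.04),
    "Mg": (1.00, 0.45, 1.60, 0.05),
    "Al": (1.10, 0.50, 1.60, 0.05),
    "Si": (1.25, 0.52, 1.55, 0.06),
    "P":  (1.35, 0.55, 1.50, 0.07),
    "S":  (1.50, 0.58, 1.45, 0.08),
    "Cl": (1.75, 0.70, 1.30, 0.08),
    "Ar": (1.90, 1.50, 1.20, 0.00),
    "K":  (0.85, 0.35, 2.00, 0.04),
    "Ca": (0.95, 0.40, 1.80, 0.05),
    "Fe": (1.20, 0.45, 1.55, 0.06),
    "Ni": (1.25, 0.48, 1.50, 0.06),
    "Cu": (1.30, 0.48, 1.50, 0.06),
    "Zn": (1.25, 0.50, 1.50, 0.06),
    "Br": (1.65, 0.62, 1.45, 0.08),
    "I":  (1.55, 0.58, 1.60, 0.08),
}

# radius-scaling parameters: (a, b, k)
_DRACO = {
    "H":  (0.80,  0.20, -0.30),
    "C":  (0.50,  0.00, -0.10),
    "N":  (0.60, -0.05, -0.10),
    "O":  (0.70, -0.10, -0.10),
    "F":  (0.70, -0.10, -0.10),
    "P":  (0.50,  0.00, -0.10),
    "S":  (0.55, -0.05, -0.10),
    "Cl": (0.60, -0.10, -0.10),
    "Br": (0.55, -0.10, -0.10),
    "I":  (0.50, -0.10, -0.10),
}
_DRACO_GENERIC = (0.50, 0.00, -0.10)
# fmt: on


def default_element_table() -> dict:
    """Merged default table: symbol -> dict of per-element parameters (angstrom
    for radii; see module docstring for the rest)."""
    table = {}
    for sym in _BONDI:
        chi, eta, alpha, kappa = _EEQ[sym]
        a, b, k = _DRACO.get(sym, _DRACO_GENERIC)
        table[sym] = {
            "r0": _BONDI[sym],
            "rcov": _RCOV[sym],
            "chi": chi,
            "eta": eta,
            "alpha": alpha,
            "kappa_cn": kappa,
            "a": a,
            "b": b,
            "k": k,
        }
    return table
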