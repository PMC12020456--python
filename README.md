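# dracopcm

Conductor-like polarizable continuum model (CPCM) solvation for classical
solutes, with a smooth Gaussian-switching cavity discretization,
**dynamically scaled per-atom cavity radii**, and the **complete analytic
nuclear gradient** of the polarization energy.

## The problem

Implicit solvation models place the solute in a cavity of atom-centered
spheres inside a dielectric continuum. The cavity radii largely determine
the quality of the electrostatics, and the best radii are not constants:
they depend on each atom's charge state and coordination. Scaling radii
on the fly — R_I = f_I·R_I,0 with f_I = erf(a_Z(q_eff,I − b_Z)) + 1 and
q_eff,I = q_I(1 + k_Z·CN_I) built from equilibrated atomic charges q_I
and smooth coordination numbers CN_I — fixes that, but it makes **every
sphere radius depend on every nuclear position**. Geometry optimization
then needs a gradient in which the cavity itself is differentiated: grid
points ride on moving, resizing spheres; Gaussian widths and switching
functions change with the radii; and the charge model behind the scaling
carries its own Jacobian.

This package implements that model and its full first derivative for
solutes described by classical point charges, and validates the
derivative against an independent four-point finite-difference oracle.

## The core quantities

Surface charges solve `A q = −f_ε v` with `f_ε = (ε−1)/ε`,
`A_ij = erf(ξ_ij r_ij)/r_ij`, `A_ii = ξ_i √(2/π)/F_i`, and the
polarization energy is `E_pol = ½ qᵀv`. Because E_pol is stationary in q,

```
dE_pol/dR_A = qᵀ (∂v/∂R_A) + 1/(2 f_ε) qᵀ (∂A/∂R_A) q
```

with every term carrying both a direct part and a radii-chain part
(∂R_I/∂R_A ≠ 0 for all atom pairs). See `docs/methods.md` for the full
derivation conventions, the quadrature grids, and the Born calibration of
the Gaussian widths.

## Worked example

A water-like triatomic with classical charges (−0.8, +0.4, +0.4) e in a
water-like dielectric (ε = 78.4), isogrid cavity with 194 points per
sphere:

```sh
dracopcm energy --xyz water.xyz --charges=-0.8,0.4,0.4
```

```json
{
  "epol": -0.019362313917217662,
  "f_eps": 0.9872448979591837,
  "n_active": 428,
  "radii_bohr": [2.4767264631658685, 2.105350055730242, 2.1053500564328815],
  "orders": [194, 194, 194],
  "static_radii": false
}
```

The polarization energy is −0.0194 hartree (≈ −12 kcal/mol, the
electrostatic stabilization of this charge distribution by the
continuum). Of 3·194 = 582 surface points, 428 survive the switching
screen — the rest are buried inside neighbouring spheres. The oxygen
sphere has shrunk from its base 4.13 bohr to 2.48 bohr and the hydrogens
to 2.11 bohr: the dynamic scaling reacting to the equilibrated charges.

Check the analytic gradient against the four-point numerical one
(step 5·10⁻³ bohr, full pipeline rebuilt at every displacement):

```sh
dracopcm check-grad --xyz water.xyz --charges=-0.8,0.4,0.4
```

reports `max_abs_dev ≈ 1.5e-10` and `rms_dev ≈ 7.4e-11` hartree/bohr —
the analytic and numerical gradients agree to well below optimization
tolerances.

Other subcommands: `grad` (per-term gradient breakdown), `scan` (bond
scan with energy/gradient/cavity-size records, CSV output), `calibrate`
(per-grid-size Born width constants). `--no-draco` switches to fixed
radii; `--scheme isodensity` selects per-sphere grid sizes by target
surface density (and demonstrably breaks the continuity of a scan — see
the tests).

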