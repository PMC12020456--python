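# Methods

`dracopcm` implements a conductor-like polarizable continuum model (CPCM)
for classical solutes with a smooth Gaussian-switching cavity
discretization, dynamically scaled per-atom cavity radii, and the complete
analytic nuclear gradient of the polarization energy. This note documents
the model, its numerical choices, and what the shipped tests do and do not
establish.

## Model

### Electrostatics

The solute is a set of fixed point charges Z_K at the nuclear positions
R_K. The solvent is a dielectric continuum outside a van der Waals cavity
(one sphere per atom). Discretizing the cavity surface into N_q spherical
Gaussian charges gives the linear response problem

    A q = −f_ε v,    f_ε = (ε − 1)/(ε + x),  x = 0,

with v_i = Σ_K Z_K/|r_i − R_K| the solute potential at the surface points
and E_pol = ½ qᵀv ≤ 0 the polarization energy. ε = ∞ (perfect conductor,
f_ε = 1) is supported as a sentinel; it is required by the Born
calibration and the image-charge oracle.

The matrix elements follow the switching-Gaussian scheme: off-diagonal
A_ij = erf(ξ_ij r_ij)/r_ij with the pair width
ξ_ij = ξ_i ξ_j/√(ξ_i² + ξ_j²), and diagonal A_ii = ξ_i √(2/π)/F_i. Each
point's width is ξ_i = ξ_Born/(R_I √w_i), where w_i is its unit-sphere
quadrature weight and ξ_Born a dimensionless per-grid-size constant. The
switching function

    F_i = Π_{J≠I} f(r_iJ; R_J),
    f = 1 − ½[erf(ξ_i(R_J − r_iJ)) + erf(ξ_i(R_J + r_iJ))]

attenuates points that sink into neighbouring spheres; dividing the
diagonal by F_i drives the charge of a buried point smoothly to zero, which
is what keeps the potential-energy surface continuous as points enter and
leave the exposed surface.

### Dynamic radii

Sphere radii are scaled by a smooth function of an effective atomic charge:

    q_eff,I = q_I (1 + k_Z CN_I),
    f_I = erf(a_Z (q_eff,I − b_Z)) + 1 ∈ (0, 2),
    R_I = f_I R_I,0.

q_I comes from a classical electronegativity-equilibration (EEQ) model:
the minimizer of a quadratic charge energy with an erf-damped Coulomb
kernel erf(r_IJ/√(α_I²+α_J²))/r_IJ, hardness diagonal η_I + √(2/π)/α_I,
electronegativity right-hand side −χ_I + κ_I √(CN_I), and a Lagrange row
enforcing Σ q = Q_total. CN_I is the smooth coordination number built from
two logistic counting factors of r_IJ against covalent-radius sums. Because
q_I and CN_I depend on all positions, every radius depends on every atom:
∂R_I/∂R_A is a dense N×N×3 object, and this is what distinguishes the
gradient below from the fixed-radii case.

The *solute* charges Z_K generating v are deliberately a separate, fixed
input: the scaling charges q_I are a cheap classical surrogate for the
charge state of each atom and carry their own analytic Jacobian, while Z_K
is whatever charge model the user assigns (zero, formal, or explicit) and
has zero derivative. Conflating the two would change the physics being
differentiated.

### Gradient

E_pol = −(f_ε/2) vᵀA⁻¹v is stationary in q, so

    dE_pol/dR_A = qᵀ(∂v/∂R_A) + 1/(2 f_ε) qᵀ(∂A/∂R_A) q

with no ∂q/∂R_A term. All cavity quantities are differentiated with the
radii chain included:

* grid points: ∂r_i/∂R_A = [I(i)=A]·Id + u_i ⊗ ∂R_I/∂R_A, with u_i the
  *fixed laboratory-frame* unit vector of the quadrature grid. Grid
  orientations do not rotate with the molecule; consequently rotational
  invariance of the energy holds only to discretization accuracy, while
  translational invariance is exact (verified to 1e-10 in the tests).
* widths: ∂ξ_i/∂R_A = −(ξ_i/R_I) ∂R_I/∂R_A (quadrature weights are
  constants), and the pair width by the quotient rule,
  ∂ξ_ij = (ξ_j³ ∂ξ_i + ξ_i³ ∂ξ_j)/(ξ_i²+ξ_j²)^{3/2}.
* switching: ∂F_i = F_i Σ_J ∂f_iJ/f_iJ with the two Gaussian terms of the
  elementary factor.

∂A/∂R_A is never materialized. All pair sums are reduced once (O(N_q²)) to
per-point and per-sphere scalar coefficients which are then contracted with
the radii Jacobian (O(N² ) for all atoms at once), so the gradient costs
about as much as one extra matrix assembly. Every term is stored split into
its **direct** part (present with static radii) and its **chain** part
(proportional to ∂R_I/∂R_A). With a_Z = 0 the chain parts are exactly zero
— not small, zero — and the code path is identical to the fixed-radii
model, which the tests check bit for bit.

The A-contraction prefactor is 1/(2 f_ε), obtained by re-deriving the
gradient from the closed form above; the four-point finite-difference
suite, run at two very different screening factors (ε = 2 and the
conductor), is the arbiter and rules out the multiplicative reading.

## Discretization

### Quadrature grids

Angular grids are octahedrally symmetric quadratures at the canonical
point counts {6, 14, 26, 38, 50, 74, 86, 110, 146, 170, 194, 302, 350,
434, 590, 770}. They are generated by the package's own moment-fitting
solver (`dracopcm.gridgen`, driven by `scripts/generate_grids.py`): full
octahedral symmetry makes all non-invariant spherical harmonics integrate
to zero identically, so exactness to degree p reduces to a small set of
moment conditions on the orbit-class parameters and weights. Every
packaged grid has strictly positive weights — a hard requirement here,
since ξ_i ∝ 1/√w_i — and moment residuals ≲ 1e-14.

Three solver regimes are used, by size. Up to 194 points the systems are
solved at (or near) their maximal degree by bounded trust-region
multistart with a Levenberg–Marquardt polish. At 302–434 points the joint
solve is run deliberately underdetermined (target degree a few steps below
maximal) so that a spread-out start converges to a nearby well-separated
solution. At 590 and 770 points every joint nonlinear solve tried
collapses orbit classes onto each other; those two grids instead fix the
orbit geometry at a deterministic low-discrepancy spread (refined only by
a cheap jitter search for weight positivity and point separation) and
obtain the class weights — which enter the moment conditions linearly —
from a dense least-squares solve, exact to machine precision at a lower
degree.

Attained algebraic degrees: 3, 5, 7, 9, 11 for sizes 6–50; 11 for 74 (the
classical 74-point rule carries a negative weight, so the positive-weight
grid drops from 13); 15, 17, 19, 21, 23 for 86–194; 23, 23, 25 for
302–434; 21 and 23 for 590 and 770. The solvation energy does not rely on
high algebraic degree: ξ_Born calibration makes the Born energy exact by
construction, and the off-center conductor test (below) converges like the
source's multipole content, which decays as (d/R)^l — at d/R = 0.3 even
degree ~20 resolves it far beyond the test tolerance. Grid quality enters
mainly through surface coverage, which the general (48-point) orbits
provide; the measured image-charge error at the 590-point grid is ~5e-5,
twenty times below the acceptance bound.

### Per-sphere grid size

Three schemes: `isogrid` (fixed size per sphere, default 194),
`isodensity` (nearest packaged size to ρ·4πR_I² with ρ = 7.5 Å⁻² by
default), and `isodensity-frozen` (isodensity once, then frozen per sphere
for the lifetime of a scan/optimization). With radii that change along a
path, isodensity re-selection makes N_q jump; the scan tests demonstrate
the resulting energy discontinuities and that freezing (or isogrid)
removes them. Only schemes with a constant per-sphere size give a
continuous surface.

### Born calibration

ξ_Born is defined operationally: for a single sphere with a central unit
charge in the conductor limit, E_pol must equal −1/(2R) exactly. For that
geometry A = (1/R)·Â with Â radius independent, so the root (bracketed in
(1, 10), solved by Brent to ~1e-14) is a pure per-grid-size constant; it
is computed on first use and cached. Born exactness at R = 1, 2, 3 bohr
with a single constant is a test, not an input.

### Screening threshold

Points with F_i < F_min = 1e-8 are excluded from the linear system. A
point at the threshold carries a charge suppressed by ~F_min, so the
energy jump across activation is far below every gradient tolerance used
here; the scan tests bound the practical effect (the isogrid consistency
metric stays at trapezoid accuracy, ≤ 1e-8 hartree at 1e-3 Å steps).
F_min is configurable; it exists as a numerical economy, not a model
feature.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| ε | 78.4 | — | solvent dielectric (water-like); `inf` = conductor |
| n_leb | 194 | points | isogrid points per sphere |
| ρ_leb | 7.5 | Å⁻² | isodensity target point density |
| F_min | 1e-8 | — | switching screening threshold |
| R_I,0 | per element | Å | base radii (Bondi-style vdW × 1.2) |
| R_cov | per element | Å | covalent radii for the coordination number |
| χ, η, α, κ_CN | per element | a.u. | EEQ electronegativity, hardness, kernel width, CN coupling |
| a_Z, b_Z, k_Z | per element | see below | radius-scaling steepness (1/e), charge offset (e), CN coupling (—) |
| cn_shift | 2.0 | bohr | additive constant in the long-range CN factor |

The coordination-number shift of 2 is a length; it is interpreted in bohr,
consistent with the all-atomic-units internals, and is configurable
(`cn_shift`) since the convention is not universal. All element tables are
defaults of this package, chosen to be physically plausible for ordinary
organic solutes (moderate radius scalings of ±10–30 % at equilibrium
geometries, EEQ charges of a few tenths of e for polar bonds), and every
value can be overridden from the config file. The signs of k_Z are set so
that an atom losing coordination (e.g. a hydrogen being abstracted) moves
its effective charge and hence its radius the way the scaling model
intends; none of the shipped numbers are fitted to any dataset.

Internally everything is in Hartree atomic units; XYZ files and config
radii are in Å (1 Å = 1.8897259886 bohr).

## Verification strategy and its limits

The analytic gradient is checked against the four-point central difference
(step 5e-3 bohr) with the *entire* pipeline — coordination numbers, EEQ
charges, radii, cavity, calibration cache — rebuilt at every displaced
geometry. Sub-Jacobians (CN, EEQ, radii, grid points, switching values)
get their own four-point suites on 20 seeded random clusters; the
finite-difference steps per quantity (5e-3 bohr for energies and smooth
scalars, 2e-3/1e-3 bohr for the width- and switching-type quantities whose
higher derivatives are large) were chosen so the oracle's own truncation
error sits well below the 1e-8 tolerances being asserted.

The synthetic solutes are random clusters and a water-like triatomic with
fixed classical charges. They exercise every term of the model, including
heavily overlapping spheres and strongly varying radii, but they are not
quantum-mechanical solutes: there is no electron density, so the
electronic part of the surface potential and all self-consistent-field
coupling are out of scope, and absolute solvation energies produced here
are not comparable to any experimental or DFT reference. What the passing
tests establish is the *internal consistency* of the model and the
*exactness of its derivatives* — the properties that make geometry
optimization on this surface meaningful — not solvation accuracy, which
lives entirely in the parameter tables.

Problem sizes used by the shipped checks: clusters of 3–8 atoms
(≤ ~1500 surface points), bond scans of ~1200 steps at 1e-3 Å, grids up to
770 points per sphere. The dense symmetric solve (Cholesky with an LU
fallback) is the right tool at this scale; no iterative solver is
provided.

## Degenerate inputs and edge cases

* erf saturates in double precision: |a_Z(q_eff − b_Z)| ≳ 5.5 makes
  f_I hit exactly 0 or 2. A radius of exactly zero is rejected at cavity
  construction; no floor is applied because clamping would destroy
  gradient continuity. With the shipped parameter ranges this requires
  |q_eff| ≳ 6 e, far outside classical charge states.
* A point fully buried in several spheres can underflow F_i to exactly 0;
  such points are screened out by F_min long before, and the reference
  switching-derivative routine treats the 0/0 as 0.
* √CN is smoothed as √(CN + 1e-14) in the EEQ right-hand side so isolated
  atoms (CN = 0) keep a finite derivative.
* Coincident atoms (pair distance ≤ 1e-6 bohr) are rejected at molecule
  construction.

## Design choices that were genuinely open

* **Grid provenance.** Classical Lebedev tables are data external to this
  package; regenerating octahedral grids from their defining moment
  conditions keeps the artifact self-contained and text-only, at the cost
  of one size (74) carrying a slightly lower degree to keep all weights
  positive. The generator and its compositions ship with the package.
* **Effective-charge form.** q_eff = q(1 + k·CN) — the product form — is
  used; its product-rule derivative is what the radii Jacobian implements,
  and the finite-difference suites pin the two to each other.
* **Diagonal switching placement.** A_ii divides by F_i. The alternative
  (multiplying) fails the finite-difference gradient check immediately and
  does not drive buried charges to zero.
* **Fixed lab-frame grid orientations.** Simplifies ∂r_i/∂R_A and matches
  the derivative implemented; the cost (rotational invariance only to
  quadrature accuracy) is inherent to all fixed-grid cavity codes.
* **No CN cutoff.** The coordination number sums over all pairs, O(N²);
  at the target scale a neighbour list would be noise.
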