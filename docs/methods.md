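# Methods

## The model

`sidebead` treats a protein as its backbone trace — the N, CA and C atoms
of each residue — plus, per residue, a single *oriented bead* that stands
in for the whole side chain.  Every other geometric feature is derived
deterministically from the trace:

* **Carbonyl O and amide H.**  O sits in the CA/C/N(next) plane along the
  external bisector of the CA←C and N(next)←C directions at the C=O bond
  length; H sits in the C(prev)/N/CA plane along the analogous bisector at
  the N–H length.  The bond lengths (C=O 1.229 Å, N–H 1.010 Å) are
  conventional values carried in the parameter file, not hard-coded.  The
  first residue and prolines carry no H.  The last residue's O is built
  from a virtual next-N placed at ideal geometry through the residue
  frame, so every residue has a carbonyl (this resolves an ambiguity in
  the placement contract in favor of a complete H-bond network).
* **Residue frames.**  A reference N/CA/C triple at the ideal bond
  lengths/angles (N–CA 1.453 Å, CA–C 1.526 Å, C–N 1.300 Å; 109.5° at CA,
  120° elsewhere) is superposed onto the actual triple by least-RMSD
  (Kabsch) fit; bead reference positions and directions stored per
  (residue type, coarse state) are mapped through that rigid frame.

### Coarse rotamer states

A fine rotamer library tabulates discrete side-chain states f per residue
type with probabilities p^f(φ,ψ) and representative atom positions.  Fine
states are aggregated into at most six coarse states by minimizing the
Ramachandran-weighted positional variance

    σ² = ∫ p^Rama(φ,ψ) σ²(φ,ψ) dφ dψ,
    σ²(φ,ψ) = Σ_f p^f/N_atom · Σ_atoms |x^f − y^{c(f)}|²,

by complete enumeration over all partitions that (1) depend only on the
(χ1, χ2) bins, (2) keep a single χ1 bin per coarse state — making the
coarse→χ1 map unambiguous — and (3) group only circularly contiguous χ2
bins.  Contiguity is judged on the cyclic order of the χ2 bins *present*
for the given χ1 bin.  The quadrature is the midpoint rule on the library
grid; ties are broken toward the lexicographically smallest mapping.  The
probability weight in the coarse-position average is the atom-independent
p^f.  Where a coarse state has zero probability at a grid point, its
position falls back to the unweighted member mean and the point is
flagged.

### Pair potential

Each interacting pair contributes

    V = κ ( V_radial(r₁₂) + ang1(−n₁·n̂₁₂) · ang2(n₂·n̂₁₂) · V_angular(r₁₂) )

with r₁₂ the bead separation and n̂₁₂ the displacement unit vector.  All
four curves are cubic splines with zero-derivative (clamped) ends: radial
knots every 0.5 Å on [0, R_cutoff] with the cutoff knot pinned to zero
(so the energy vanishes continuously at the cutoff), angular knots every
1/6 in cosθ on [−1, 1].  Cutoffs are 7 Å for side chain–side chain terms
and 5 Å for side chain–backbone terms.  The angular factors are kept
positive by storing their knot values through an exponential transform.
Energies are in natural units, k_BT = 1.

Backbone partners are: the carbonyl O and amide H (directional, with
site directions along C→O and N→H), and three interaction beads placed
through the residue frame at reference positions initialized from the
ideal N/CA/C coordinates.  The N/CA/C beads are radial-only by default
(a config switch enables directional terms for them; the printed model
description does not settle this).  Own-backbone sites are excluded by
default, sequence-adjacent side chains interact (min_seq_sep = 1), and
the neighbor test uses a strict inequality at the cutoff — energetically
irrelevant since the potential vanishes there.

**Hydrogen-bond coupling.**  Every backbone N–H···O=C pair gets a
confidence f = S_d(|H−O|) · S_a(∠NHO) · S_a(∠HOC): the distance switch is
a cubic smoothstep from 1 at 1.4 Å to 0 at 2.5 Å, and each angular switch
is a cubic smoothstep in the cosine of the deviation from collinear with
its half-height exactly at 47°.  The exact interpolant shapes are a
recorded convention; only the endpoints and half-heights are
constrained by the model description.  A site participating in several
possible H-bonds combines them as f_site = 1 − Π(1 − f_pair); donors and
acceptors closer than two residues apart in sequence are not paired.
Side chain–O and side chain–H terms are scaled by κ = 1 − f_site, so the
directional interaction switches off for sites already hydrogen bonded;
κ = 1 everywhere else.

### One-body term

v_i(χ̃) adds the rotamer prior −log q^c(φ_i, ψ_i) — bilinearly
interpolated on the library grid with periodic wrap — to the side
chain–backbone terms.  A flag replaces the prior with its (φ,ψ)-average
(the "backbone-independent prior" ablation).  Terminal residues lacking
φ or ψ use the table averaged over the missing axis.

### Free energy and marginals

For a fixed backbone the side chains form a pairwise Markov random field
(v_i vectors, v_ij matrices on the neighbor graph).  The free energy is
the Bethe approximation

    G^SC = ⟨v⟩ − S_approx,  S_approx = Σ_i H(p_i) − Σ_edges MI(p_ij),

minimized by damped synchronous belief propagation (λ = 0.4), iterated
until node beliefs move less than 0.001 (tighter in the validation
studies).  Pair beliefs divide node beliefs by the reverse message;
messages are floored at 1e-300 and renormalized each round (the fixed
point is scale-invariant per message), and 0·log 0 = 0.  On trees the
procedure is exact, which the suite verifies against complete
enumeration.  Non-convergence within max_iter (default 1000) returns the
best state flagged, never an exception — a simulation needs a force every
step.  Warm-starting from the previous frame's beliefs is enabled in
dynamics; a cold-start equivalence test guards it, and messages for edges
that appear between frames initialize as uniform.

Pairwise-consistent marginals need not correspond to any joint
distribution (three variables with two perfectly correlated pairs and one
independent pair pass all pairwise checks); the consistency report is
therefore a necessary condition only, and the suite documents this with
that exact counterexample.

### Forces

Because the BP marginals are stationary for the Bethe functional, the
backbone derivative of G^SC reduces to the expectation of the energy
derivatives (the entropy's partial derivative vanishes).  All placement
Jacobians are analytic: the Kabsch frame is differentiated through
first-order perturbation of the quaternion (Davenport) eigenproblem, the
O/H bisector constructions and their unit directions by direct chain
rule, φ/ψ by the standard dihedral gradients, and the H-bond κ factors
through the smoothstep switches.  Finite-difference tests (with BP
re-solved at every displaced configuration) guard every piece and the
assembled gradient.  The bilinear (φ,ψ) tables make the gradient
piecewise-constant within a grid cell; this is invisible to central
differences at h = 1e-4 but is the reason the Ramachandran term is
excluded from the energy-conservation diagnostic below.

### Maximum-likelihood training

The loss per example is the energy gap E_gap = V(χ̃_native) − G^SC =
−log p(native states), evaluated with the same BP solver used at
inference.  Since every spline energy is linear in its knot values, each
example is compiled once into cardinal-basis arrays; the parametric
gradient is the native-indicator-minus-marginal weighted basis sum
(envelope identity again).  Optimization is Adam (α = 0.03, β₁ = 0.90,
β₂ = 0.96, ε = 1e-6, minibatch 256) on the per-residue-averaged E_gap
plus three regularizers summed at the knot locations: squared second
differences of the radial knots (smoothness), squared V_angular knots
(directional size), and (c₀ − 5 k_BT)² (steric core).  The "directional
coefficient" penalty is applied to the V_angular amplitudes; the ang1/ang2
factors are already constrained positive by the exponential transform.
The three regularizer weights are not specified by the model description;
the package default is 0.01 each — strong enough to help validation
error, weak enough not to bias the planted-recovery study below.
Reporting E_gap per residue (rather than per protein) is the package's
choice; both are exposed.

Dataset filtering: non-globular chains are dropped as RANSAC outliers of
the log R_g vs log N_res line (residual threshold 0.1 in log10 R_g,
minimum sample 2, 1000 trials, seeded — none of these are printed in the
model description).  χ1 accuracy is the fraction of residues whose argmax
marginal maps to the native χ1 bin, excluding Ala/Gly/Pro from numerator
and denominator (NaN when nothing is eligible).

### Dynamics

The backbone potential adds harmonic bond springs at the ideal lengths,
harmonic angle restraints (109.5°/120°), a soft-sphere repulsion
½k(d − 3 Å)² between backbone atoms more than three bonds apart, a
Ramachandran statistical energy (−log density, bilinear), and a backbone
H-bond energy = strength × Σ f_pair (default −1.8, the model
description's near-optimal value).  Force constants (k_bond = 100,
k_angle = 20, k_steric = 4, in k_BT units) are package choices sized so
that the bond frequency satisfies ω·dt ≈ 0.09 at the 0.009 time step.
The integrator is BAOAB Langevin–Verlet with friction
γ = 1/0.135 (the thermalization timescale); with γ = 0 it reduces to
velocity Verlet.  Masses are unit; time units are arbitrary.  Replica
exchange uses the 14-temperature ladder 0.500…1.000 and Metropolis swaps
min(1, exp(Δβ·ΔE)) on alternating even/odd adjacent pairs, rescaling
velocities on acceptance (the exchange mechanics are standard practice;
only the ladder is prescribed).

## Synthetic data

The generators exist so every claim is testable with no external data:

* **Libraries** draw per-state base weights from a Dirichlet and modulate
  them smoothly over the Ramachandran torus (cosine logits), so
  probabilities are normalized at every grid point; atom positions sit
  1.5–4 Å from the frame origin, clustered by χ1 bin so χ1/χ2
  coarse-graining is geometrically meaningful.
* **Backbones** are built by internal-coordinate chaining at ideal bond
  lengths/angles with helix (−57°, −47°), extended (−135°, 135°) or
  basin-sampled random dihedrals, ω = 180°.
* **Ramachandran density** is a smooth two-basin (helix/sheet) von-Mises
  mixture.
* **Training sets** sample native coarse states *exactly* from the
  Boltzmann distribution of a planted parameter set by complete
  enumeration of the joint state space — so a recovery failure implicates
  the trainer, never the sampler.

What the generators do **not** emulate: real amino-acid composition and
covariance, (φ,ψ)-dependent atom positions in the default library
(supported by the types, unused by the generator), crystallographic
noise, multi-chain packing, and the NDRD-scale state counts per residue.
Passing tests therefore demonstrate the correctness of the machinery —
aggregation, inference, derivatives, training, integration — not
biological accuracy of any particular parameterization.

## Validation studies and problem sizes

`sidebead.validation` (driven by `scripts/acceptance.py` and the
acceptance tests) runs, per seed:

* BP vs enumeration on 100 random trees (≤12 residues, ≤6 states).
* The pairwise-consistency counterexample.
* Central-difference checks of side-chain forces (10-residue fixture,
  h = 1e-4) and backbone forces (h = 1e-6), and of dE_gap/dθ over every
  trainable coefficient (5-residue fixture, h = 1e-5).
* Partition optimizer vs an unconstrained set-partition enumerator on a
  9-state toy library, and σ² monotonicity in the state budget.
* BP iteration counts on 30 random 50-residue systems at the 0.001
  tolerance (median lands in the 10–20 range).
* Integrator diagnostics: secular NVE drift over 10,000 frictionless
  steps on the smooth spring/angle system (drift is measured as the
  change between the first and last 10% windows; the bounded symplectic
  energy oscillation is not drift, and the switched/truncated terms —
  sterics, H-bond smoothsteps, bilinear Ramachandran — are excluded
  because they are only C¹ and turn energy conservation into a slow
  random walk, a property of the potential rather than the integrator),
  harmonic equipartition over a 256-oscillator ensemble, and
  two-temperature replica-exchange distribution preservation
  (Kolmogorov–Smirnov, with temperatures close enough that swaps are
  frequent).
* **Planted recovery**: 2 residue types × 3 coarse states, 500 training
  and 100 held-out 8-residue random-topology chains, start perturbed by
  σ = 0.5 on all 622 trainable coefficients, Adam at default settings
  for 35 epochs.  The design puts ~4000 training residues behind ~600
  parameters so the maximum-likelihood estimate is identifiable; at
  larger parameter-to-data ratios the trained model visibly overfits
  (held-out E_gap rises after an early minimum), which is expected
  behavior, not a defect.  Reported: held-out per-residue E_gap excess
  over the planted model, and χ1 accuracy against the prior-only
  baseline.

(φ,ψ) grids in the validation studies are 18 × 18 (20° spacing); the
library default is 36 × 36 (10°).

## Numerical conventions and edge cases

* Degenerate (collinear) backbone triples raise a geometry error; the
  frame Jacobian additionally requires a non-degenerate quaternion
  eigenvalue gap.
* Coincident beads raise; graph construction uses strict inequality.
* Messages/beliefs floored at 1e-300; beliefs renormalized every round.
* PDB coordinates round-trip at the format's 3-decimal precision; the
  JSON containers round-trip bit-exactly (repr-precision floats, SHA-256
  payload checksums, versioned schema).
* Ablation presets (isotropic-only, repulsive-only, no H/O, no N/CA/C
  beads, (φ,ψ)-independent prior, SC–SC only, SC–backbone only, wider
  cutoffs via config) are config flags tested for their structural effect
  on synthetic systems; their quantitative impact on real benchmarks is
  out of scope here.

## Known limitations

* Loopy BP converges to a local stationary point of the non-convex Bethe
  functional; bi-stable rotamer landscapes would be represented by a
  single basin, underestimating side-chain entropy.  No special handling
  is implemented.
* The Bethe entropy ignores 3-body and higher correlations, and
  pairwise-consistent marginals may be non-representable.
* Training updates spline coefficients only; bead reference positions,
  directions and the rotamer prior are held fixed (the types support
  optimizing them, the trainer does not).
* The repulsive-only ablation has a non-smooth energy (positive part of
  the radial spline); it is intended for packing comparisons, not
  dynamics.
* Single chains only; no periodic boundaries, no solvent model, no
  mmCIF.
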