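# Methods

`enmremd` implements a multiscale enhanced-sampling scheme for the global
domain motions of multi-domain proteins at Cα resolution: a coarse-grained
elastic-network analysis identifies the soft collective directions of the
system, a biasing potential built on the inter-domain centroid distances
destabilizes the current domain arrangement along exactly those directions,
and a Hamiltonian replica-exchange (H-REMD) simulation uses a ladder of
increasingly biased replicas to feed barrier-crossing configurations down to
an unbiased reference replica.  The reference replica samples the
*unmodified* physical ensemble (the bias enters only through the exchange
criterion), so its trajectory can be analyzed exactly like a plain
simulation — just with far better coverage of slow domain motions.

## The model chain

### 1. Cα structure and domains

A protein is reduced to one bead per residue (the Cα atom), with author
residue numbering preserved.  Four domains are defined by per-chain residue
intervals supplied in the configuration; their unweighted Cα centroids
c1…c4 are the collective coordinates of the whole method.  By convention
c2 and c3 are the two central, dimer-forming domains and c1, c4 the
terminal domains.  Residues outside every interval are allowed and simply
do not contribute to centroids.  An N-terminal truncation helper removes
all residues up to a boundary (in author numbering) from every chain, for
constructs that drop a terminal domain.

### 2. Elastic network and mode excitation

The elastic network connects beads by harmonic pair springs.  The default
spring rule uses Hinsen-style distance-dependent force constants,
converted to kcal mol⁻¹ Å⁻²:

    k(r) = 205.5·r − 571.2        r < 4 Å   (sequence-neighbour contacts)
    k(r) = 3.0592e5 · r⁻⁶         r ≥ 4 Å

applied to all pairs (springs weaker than 1e-6 kcal mol⁻¹ Å⁻² are pruned;
they are numerically irrelevant at ~1e-11 of the softest meaningful
eigenvalue but dominate the pair count).  A uniform-k cutoff network
(default 10 Å, 1 kcal mol⁻¹ Å⁻²) is available as `enm_rule: cutoff`.

The mass-weighted Hessian is assembled from the standard pairwise
super-elements −(k/r²)(r⊗r) and diagonalized densely.  Modes with
eigenvalue below 1e-10 × λ_max are classified as rigid-body modes.  This
threshold is deliberately far below the common 1e-6: in a weakly coupled
multi-domain system the genuine soft inter-domain modes sit at ~1e-8 of
the stiffest eigenvalue while true rigid modes are at machine zero
(~1e-16), and a 1e-6 threshold would silently discard exactly the modes
the method exists to exploit.  A connected, non-collinear network has
exactly 6 rigid modes; disconnected or collinear networks are tolerated
but flagged, since distance-based pair springs leave transverse motions
of collinear geometries unconstrained (e.g. 7 zero modes for a collinear
3-atom chain — not the physical 5 of a linear molecule).

The first `n_modes` (default 50) non-rigid modes are each excited with a
thermal energy of RT (R·T = 0.5962 kcal/mol at 300 K), giving per-mode
amplitudes a_k = √(2RT/λ_k) in mass-weighted coordinates.  "Energy RT per
mode" is one of two defensible readings of an RT-scale excitation (the
other spreads RT over all modes); it is the equipartition-like choice and
is applied uniformly.

### 3. Bias widths by linear propagation

The per-pair bias half-widths Δd_ij are obtained by first-order
propagation of the excited modes onto the six centroid distances:

    Δd_ij = sqrt( Σ_k (g_ij · a_k v_k)² )

with g_ij the gradient of d_ij with respect to mass-weighted coordinates.
Linear propagation is deterministic, fast and differentiable; the test
suite validates it against a Monte-Carlo sampling oracle.  Note that at
full RT excitation of very soft modes the *second-order* terms are not
negligible for pairs whose first-order gradient nearly vanishes
(intra-domain-pair distances); the oracle comparison is therefore exact in
the small-amplitude regime and holds at full excitation for the pairs
with non-degenerate gradients.  Rigid-body modes contribute nothing, as
internal distances are rotation/translation invariant.

### 4. The biasing potential

Each of the C(4,2) = 6 centroid distances carries a quartic bump

    V(d) = k·((d − d0)² − Δd²)²   for |d − d0| ≤ Δd,   0 otherwise

maximal (k·Δd⁴) at the current reference arrangement d0 and C¹-continuous
at the window edges.  The potential *destabilizes* the present arrangement
without preferring a direction of escape and without imposing any angular
or torsional reaction coordinate.  Because k alone has awkward units
(kcal mol⁻¹ Å⁻⁴) and printed protocol levels are energies, the package
parameterizes the bias by its peak height ("biasing level", kcal/mol):
k = level/Δd⁴ per pair.  Forces distribute over each domain's member
atoms through the centroid definition (∂centroid/∂x = 1/N_domain); the
net force and net torque of the total bias vanish identically.

### 5. Coarse-grained engine

The explicit-solvent atomistic layer of a production implementation is
out of scope here; the physical model is the elastic network itself as a
harmonic pair potential (energy zero, forces zero at the reference
structure), with an optional soft-core repulsion, plus a 1D double well
u(x) = h((x/w)² − 1)² as the closed-form reference system for thermostat
and exchange statistics.  Dynamics use the BAOAB splitting of Langevin
dynamics; at zero friction and temperature it reduces exactly to velocity
Verlet.  Units are Å, ps, kcal/mol, amu, K; accelerations carry the
conversion 1 kcal/mol = 418.4 amu Å² ps⁻², and k_B·300 K = 0.5962
kcal/mol.  Defaults: dt = 0.01 ps, friction 1 ps⁻¹ — a 10 fs step keeps
the stiffest network modes (ω ≈ 31 ps⁻¹) at ω·dt ≈ 0.3.  Each replica
owns a named RNG stream spawned from the master seed; exchanges swap
coordinates (and velocities), never streams, so every run is
bit-reproducible from (config, seed).

### 6. H-REMD with adaptive control

Replica m adds the bias at peak level L_m = scales[m]·unit_level with
scales[0] = 0 (the reference) and, by default, linearly increasing scales
so consecutive replicas start 2.25 kcal/mol (≈4 RT) apart.  Exchanges are
attempted between alternating even/odd neighbour pairs every 2 ps of
simulated time; since all replicas share the physical Hamiltonian, the
Metropolis criterion uses only the four bias energies,

    p = min(1, exp(−β[(V_m(x_n) + V_n(x_m)) − (V_m(x_m) + V_n(x_n))])).

Two adaptive elements operate on a 0.2 ns control period:

**Amplitude controller.**  Whenever a neighbour pair's windowed acceptance
leaves the [20 %, 60 %] band, the biasing level is adjusted by exactly
10 %.  Two granularities are implemented.  The default (`controller_mode:
per_pair`) rescales the *individual* neighbour gap of the triggering pair
(scales are rebuilt as the cumulative sum of gaps, so the ladder stays
monotone with an unbiased reference).  The alternative (`global`) rescales
all biased replicas together, lowering taking priority when both
conditions occur.  The per-pair default is a deliberate design choice:
the acceptance-vs-ladder-position curve of a heterogeneous system is
sloped, and a single global factor can pin only one end of it inside the
window, whereas independent gap control provably converges every pair
(measured final-half acceptance 0.36–0.48 on the toy system).  This is
also how replica ladders are conventionally tuned in the REMD literature.

**Reference-distance tracking.**  d0_ij follows the running average of the
sampled centroid distances over a trailing window of twice the control
period (0.4 ns), so the bias keeps destabilizing the *current*
arrangement as the system drifts.  By default (`d0_mode: shared`) one
bias shape is maintained for the whole ladder, with d0 pooled over every
replica's samples — the ladder is then literally one potential "with
increasing amplitudes".  The alternative (`per_replica`) lets each
replica's d0 chase its own trajectory; it is available in the
configuration but destabilizes the ladder on this CG system: the top
replicas' bias shapes diverge from their neighbours', their exchange
acceptance collapses, and the positive feedback (less mixing → more
divergence) defeats the amplitude controller.

Both adaptive elements violate strict detailed balance while they act, as
in any on-the-fly adapted REMD; the exactness property (reference replica
≡ unbiased Boltzmann ensemble) is therefore verified with the controller
frozen, and the adaptive machinery is tested separately for its own
contracts (window maintenance, exact ±10 % steps).

### 7. Analyses

Optimal rigid superposition uses the Kabsch algorithm (proper rotations
enforced); RMSD series align every frame to each reference.  RMSF is
taken about the iteratively aligned mean structure (2 passes).  The
global coordinates of the four-centroid arrangement are the six
distances, the opening angle measured at the midpoint of the two central
centroids (vertex v = (c2+c3)/2, rays v→c1 and v→c4), and the signed
IUPAC dihedral of the c1-c2-c3-c4 chain.  The midpoint-vertex reading of
the angle is a documented interpretation choice: the construction "angle
formed by c1, (c2, c3), c4" is implemented with the two central
C-domain centroids merged into one vertex.

## The synthetic system

The toy dimer stands in for a truncated two-monomer chaperone: two
helical-arc arms of 2×20 beads (Cα-like 3.8 Å spacing, helix radius 2 Å —
helical rather than straight so the network is non-collinear and
torsionally stiff), joined at a central interface 5 Å wide, with a hinge
angle of 100° between the arm axes and 0.1 Å of seeded jitter.  Its
elastic network has exactly 6 rigid modes, and its softest internal mode
is a hinge/opening motion carrying >80 % of its distance-fluctuation
weight on the terminal-terminal (c1–c4) pair — the design property the
whole pipeline exploits.  What the toy does *not* emulate: real residue
masses and sequence, excluded volume, solvent, anharmonic tertiary
contacts, or realistic domain sizes.  Passing tests on the toy therefore
demonstrate the correctness of the machinery (mode analysis, bias
construction, exchange statistics, controller dynamics, analyses), not
the biology of any particular chaperone.

The double well (h = 1 kcal/mol ≈ 1.7 k_BT at 300 K, minima at ±1 Å) is
the closed-form reference for thermostat and exchange statistics; its
H-REMD ladder uses a barrier-lowering Gaussian bias, since the Boltzmann
property of the reference replica is independent of the bias form.

## Problem sizes and numerical choices

* Toy ("desk") schedule: all protocol times uniformly compressed 100×
  (exchange 0.02 ps, control 2 ps, d0 window 4 ps at dt = 0.01 ps),
  preserving the 100-attempts-per-control-period ratio of the full
  protocol.  The end-to-end controller runs use 12 replicas × 40,000–83,000
  steps (≈0.5–1.0 × 10⁶ total integrator steps).
* Boltzmann goodness-of-fit: ~10⁵ reference-replica samples pooled over
  19 independent 4-replica ladders, sampled every 1 ps ≈ 2.4 integrated
  autocorrelation times (τ measured at 0.42 ps with friction 6 ps⁻¹),
  χ² against the quadrature-normalized Boltzmann density at α = 0.01.
* Finite-difference force checks use central differences along random
  unit directions (directional derivatives), which keeps the comparison
  at 1e-6 relative accuracy; per-component comparisons on ~1e-6-magnitude
  force entries are dominated by roundoff of the energy difference and
  are not meaningful at that tolerance.
* Tie-breaks and degenerate inputs: coincident centroids raise geometry
  errors (bias direction undefined); torsions with collinear interior
  points return NaN; empty domains, overlapping intervals, unknown
  configuration keys and sub-2-replica ladders are rejected with named
  configuration errors; dynamics blow-ups abort naming the replica and
  step.

## Known limitations

* The harmonic network cannot unfold or break contacts, so "domain
  rearrangement" here means elastic excursion along soft modes, not
  conformational switching between distinct basins.
* Δd widths derived from near-zero eigenvalues are large (tens of Å);
  they are consistent with the toy's genuinely large thermal fluctuations
  but would be unphysically wide for a well-packed protein — with real
  systems the widths inherit the ENM's quality.
* The adaptive controller is a bang-bang rule with a fixed 10 % step; it
  maintains the acceptance window but does not optimize round-trip times.
* One CPU, dense eigensolver: systems beyond a few thousand residues
  would need a sparse/iterative mode solver.
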