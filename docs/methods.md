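# Methods

## Model

A cage is a set of building blocks — bead clusters — placed on the typed
vertices of a topology graph and bonded along its edges. Five bead classes
are used: `a` (ditopic binder), `c` (ditopic centre), `b` (polytopic
binder), `n` (tritopic centre), `m` (tetratopic centre). Each class
carries an equilibrium bond radius r (default 2 Å), an excluded-volume
size σ (1 Å) and strength ε (10 kJ mol⁻¹); bond equilibria between unlike
classes mix arithmetically, r₀(i,j) = (rᵢ + rⱼ)/2.

Building blocks are constructed exactly at their internal equilibrium:

* **ditopic** (a–c–a, 3 beads): collinear, with an a–c–a angle term at
  180°. The straight backbone is what makes the bite-angle picture
  well-defined: the two b–a–c angles (targets θ₀, applied at assembly
  time, because the b partner beads do not exist until bonds form) bend
  symmetrically against it, giving θ_bite = 2(θ₀ − 90).
* **tritopic** (n + 3 b): binders on a cone at polar angle
  α = arccos √((2 cos θ + 1)/3), which makes all three b–n–b angles equal
  θ; θ = 120° is planar.
* **tetratopic** (m + 4 b): binders on a cone at α = arccos √(cos θ) with
  azimuths 90° apart, making the four adjacent b–m–b angles θ and the two
  opposite angles 2α; θ = 90° is square planar. The opposite-angle target
  is the geometric closure of the square pyramid — without it the four
  binders could pair up and break the four-fold symmetry.

The topology registry provides eleven graphs (Tri2Di3, Tri4Di6, Tri4_2Di6,
Tri6Di9, Tri8Di12, Tet2Di4, Tet4_2Di8, Tet6Di12, Tet8Di16, Tet12Di24,
Tet6Tri8) with ideal unit-circumradius vertex positions: polyhedron
vertices for the polytopic blocks and edge midpoints for the ditopic
blocks, or explicit bridge constructions for the double-bridged variants.
`Tri4_2Di6` is built as four tritopic vertices with doubled bridges A–B
and C–D plus single bridges A–C and B–D; `Tet4_2Di8` (the double-walled
tetrahedron) as K₄ bridges plus a doubled perfect matching. Both are
data-driven and replaceable through the open registry, as is any custom
graph (validated for arity/degree consistency, handshake, connectivity
and the rule that a ditopic vertex may not bind one partner twice).

## Assembly

Each block is scaled into place (smallest scale such that every
constructed bond can reach its equilibrium length and no inter-block pair
sits closer than 1.2 σ̄) and rotated by the best orthogonal superposition
of its binder directions onto its incident edge directions, minimised
over all binder-to-edge assignments (≤ 4! per vertex; ties break to the
lexicographically first assignment, so assembly is deterministic).

Per edge, one binder–binder bond is formed. At a ditopic end the b–a–c
angle term at θ₀ is added; at a polytopic end a centre–binder–partner
straightness term at 180°, so that the b–a–c angle controls the geometry
the way the bite-angle picture assumes (these straightness terms are
configurable off). With the torsion restriction on, each ditopic block
contributes one *alchemical* torsion on the quadruple (b, a, a, b) — the
two a beads are joined through c, not directly, but the dihedral is
computed from the four positions in that order — with
E = k(1 + cos(φ − 180°)), so the minimum is at φ = 0 (both binding sites
facing the same way) and the trans conformation costs 2k = 100 kJ mol⁻¹.

Excluded volume acts only on bead pairs separated by more than two bonds;
the pairwise form √(εᵢεⱼ)(σᵢⱼ/r)¹² (σᵢⱼ arithmetic mean) is purely
repulsive — a good-solvent assumption: collapse must come from geometric
frustration, not attraction — truncated and shifted to zero at 3σᵢⱼ.

## Conformer search

Seven steps: (1) minimisation with all intra-block bonds restrained at
their current lengths (relaxes the freshly formed inter-block bonds
first), (2) full minimisation, (3) overdamped Langevin dynamics with bond
and angle constants softened ×0.1 (kBT = 2.5 kJ mol⁻¹, 5000 steps of
dt = 0.005 with per-bead displacements capped at 0.25 Å — search
parameters only, the model neglects temperature), (4) minimisation of 10
evenly spaced frames, (5) outward shifts of the best candidate about its
centroid by ×1.25/1.5/2 (anti-collapse restarts), (6) minimisation of
each, (7) tight re-minimisation of the best. The lowest-energy candidate
is returned with E_b = E_total/n_blocks.

Numerical choices: L-BFGS-B with analytic gradients (validated against
central finite differences); bond/angle/torsion gradients are the
standard singularity-guarded forms (Blondel–Karplus for dihedrals). The
construction geometry contains exactly collinear angles whose harmonic-
in-θ potential has a derivative cusp at θ = 180°; when the line search
stalls there at iteration zero the start is jittered by a deterministic
10⁻⁴ Å perturbation and retried. Restrained minimisation stiffens the
hold progressively (10³ → 10⁶ kJ mol⁻¹ Å⁻²) because a cold start at full
stiffness defeats the line search. Convergence is reported as RMS
gradient component < 10⁻⁶ kJ mol⁻¹ Å⁻¹; coincident nonbonded pairs are
distance-floored at 0.05 σ so the repulsion stays finite.

All stochasticity flows from one integer seed. Phase-space scans derive
each point's seed from a CRC of (topology, angles, torsion state, base
seed), making results independent of evaluation order and resumable.

## Phase space and analysis

The default angle grid is ditopic θ₀ ∈ {90…180, step 5}, tritopic
θ ∈ {50…120, step 10}, tetratopic θ ∈ {50…90, step 10}. A point is
accessible when E_b ≤ 0.3 kJ mol⁻¹ — a model-dependent choice (the
energy scale is alchemical) exposed as a parameter; the
`percent_selected` curve shows how the degree of self-sorting varies
with it. Outcome classification, accessible-topology maps (CSV),
`proportion_accessible` and seed-spread reporting (optional repeat count)
follow directly from the scan results.

Continuous shape measures are computed as
100 × min over relabelling/rotation/scale/translation of the normalised
residual; rotation and scale are closed-form per permutation (Kabsch,
proper rotations), and the permutation minimum is exact for n ≤ 8 — a
radius-pairing Cauchy–Schwarz bound prunes candidates, with an unpruned
enumeration kept as an independent cross-check. Reference polyhedra are
the regular solids/polygons, the equilateral trigonal prism and the
equal-edge square antiprism; the registry is data-driven so alternative
conventions can be swapped in. The pore radius is the simplest
centroid-to-nearest-bead-surface distance (floored at zero) — a
deliberate approximation; it ignores windows and non-spherical cavities.

## What the defaults emulate — and what they do not

The default bead set (identical radii 2 Å, σ = 1 Å, ε = 10 kJ mol⁻¹ for
all classes) and the angle grids span the discretised design space of
symmetric building blocks: one ligand length, equal angles on both
ditopic ends, no stereochemistry, no metal-centre twist. Passing tests
therefore demonstrate geometric accessibility trends — which topologies
are unstrained for which angle combinations, and how preorganisation
changes that — not thermodynamic self-sorting: there is no solvent, no
entropy, no kinetics, and the accessibility threshold has no
experimental calibration. Bond-length variation across bead classes and
richer combo spaces are reachable through configuration but are not part
of the defaults.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
bite-angle scans use the 18-point ditopic grid on Tet6Di12 (66 beads)
and Tet12Di24 (132 beads); the double-walled-tetrahedron instability
check uses a 5×5 angle grid; the flexibility comparison a 3×3 sub-grid
on three small topologies. A full production map over all topologies and
both torsion states is a few thousand optimisations and runs unattended
via `cgcage scan`.

## Known limitations

* The conformer search is stochastic and local; occasional phase-space
  instabilities (seed-dependent E_b on strained points) are surfaced via
  the recorded per-point seed and optional repeat spread rather than
  hidden.
* Shape measures on >8-vertex centroid sets are skipped (factorial
  permutation cost); Tet12Di24 therefore has no configured shape report.
* The torsion list contains only the ditopic backbone torsion by design;
  Tet6Tri8 has none.
* Building-block arrangement isomers (vertex permutations) are not
  enumerated; one deterministic arrangement is built per topology.
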