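# cgcage

Coarse-grained bead models of self-assembled cage molecules.

Supramolecular cages — metal–organic cages (MOCs), porous organic cages
(POCs) — form by self-assembly of multi-topic building blocks, and which
topology actually assembles (a Pd₂L₄ capsule? a Pd₆L₁₂ octahedron? a
mixture?) is largely decided by building-block geometry: the bite angle of
the ditopic ligand and the pyramid angle of the tritopic/tetratopic unit.
`cgcage` is a toolkit for chemists and modellers who want to map that
relationship *before* committing to atomistic models or synthesis. It
builds minimalistic bead models of cages on named topology graphs, finds
low-energy conformers under a simple harmonic force field, and turns grids
of building-block angles into *accessible topology maps* that approximate
self-sorting outcomes.

## The model

Building blocks are small bead clusters built exactly at their target
internal geometry: a linear ditopic unit *a–c–a* (bite angle
θ_bite = 2(θ₀ − 90), with θ₀ the *b–a–c* target angle on both ends), a
pyramidal tritopic unit *n* + 3 *b* and a tetratopic unit *m* + 4 *b*.
Placed on a topology graph (e.g. `Tri4Di6` = 4 tritopic + 6 ditopic
blocks on a tetrahedron and its edge midpoints) and bonded along the graph
edges, a cage has potential energy

```
E = E_bond + E_angle + E_torsion + E_excl.vol.
E_bond    = Σ ½ k_bond (r − r₀)²              k_bond    = 1×10⁵ kJ mol⁻¹ nm⁻²
E_angle   = Σ ½ k_angle (θ − θ₀)²             k_angle   = 1×10² kJ mol⁻¹ rad⁻²
E_torsion = Σ k_torsion (1 + cos(pφ − φ₀))    k_torsion = 50 kJ mol⁻¹, p = 1
E_excl.   = Σ √(εᵢεⱼ) (σᵢⱼ/r)¹²  (truncated-shifted; εᵢ = 10 kJ mol⁻¹, σᵢ = 1 Å)
```

The *b–a–a–b* backbone torsion restricted to 0° models ligand
preorganisation; switching it off models flexibility. A multi-step
conformer search (constrained minimisation, softened-potential dynamics,
centroid-shift restarts) returns the lowest-energy conformer and the
stability score **E_b = E_total / n building blocks**; a structure with
E_b ≤ 0.3 kJ mol⁻¹ (configurable) is deemed accessible. Per angle combo
the self-sorting outcome is *unstable* (nothing accessible), *selective*
(exactly one topology) or *mixed*. Shape analysis uses continuous shape
measures (CShM, exact over vertex relabelling for 3–8 vertices) of
building-block centroids against ideal polyhedra (TP-3, SP-4, T-4, TPR-6,
OC-6, CU-8, SAPR-8), plus a centroid-to-surface pore radius.

## Worked example

```python
>>> from cgcage import get_topology, make_block, build_cage, optimise_cage, bite_angle
>>> cage = build_cage(get_topology("Tri4Di6"),
...                   {2: make_block("ditopic", 125.0),
...                    3: make_block("tritopic", 120.0)},
...                   torsion_state="on")
>>> res = optimise_cage(cage, seed=7)
>>> print(f"E_b = {res.e_b:.6f} kJ/mol")
E_b = 0.000000 kJ/mol
```

E_b ≈ 10⁻⁷ kJ mol⁻¹ is far below the 0.3 kJ mol⁻¹ accessibility
threshold: a planar tritopic unit (120°) with a ditopic angle of 125°
(bite angle 70°) forms an essentially unstrained Tri4Di6 tetrahedron —
the geometry of classic imine POCs and M₄L₆ cages. The same scan over
ditopic angles for `Tet6Di12` with square-planar tetratopic blocks puts
the energy minimum at θ₀ = 135°, i.e. a bite angle of 90°, matching the
design rule for Pd₆L₁₂:

```bash
cgcage scan --topology Tet6Di12 --torsion on --out scan.csv
cgcage map  --topology Tri4Di6 --topology Tri8Di12 --out map.csv
cgcage shape Tri4Di6_opt.xyz
```

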