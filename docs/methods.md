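# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `kicloop`, in the order a user meets them.

## Backbone representation

A pose stores, per residue, the heavy backbone atoms N, CA, C, O and the
internal coordinates: φ (C′-N-Cα-C), ψ (N-Cα-C-N′), ω, the N-Cα-C bond
angle θ, and the three backbone bond lengths.  **ω convention:** `omega[i]`
is the torsion of the peptide bond *entering* residue `i`
(Cα(i-1)-C(i-1)-N(i)-Cα(i)), so a cis-proline at position `p` has
`|omega[p]| < 90°` and its torsion-bin letter is lowercased at `p`.
Angles are degrees in (−180°, 180°] at the API surface.  Ideal geometry
constants (Engh/Huber-style) are module constants in `geometry`; the
carbonyl O is placed deterministically in the peptide plane, anti to the
next N across the Cα-C bond (from ψ for the final residue).  Coordinates
are built by sequential NeRF placement and measured back by standard
dihedral/angle formulas; the round trip is exact to well below 1e-9°.

Segment RMSD follows the benchmark convention: least-squares (Kabsch,
via `scipy.spatial.transform.Rotation.align_vectors`) superposition on the
N/CA/C/O atoms of all residues *outside* the remodeled segment, RMSD over
the N/CA/C/O atoms *inside* it.  Whether O belongs in the atom set is a
convention choice; it is included by default and the atom set is an
argument.

## The triaxial closure solver

With every non-pivot internal coordinate frozen, the chain pieces between
consecutive pivot Cα atoms are rigid bodies, so the three pivot Cα atoms
form a triangle with fixed side lengths (r₁, r₂ between pivots; r₃ between
the anchor-determined first and last pivot Cα).  Three degrees of freedom
remain: the rotation τ of the middle Cα about the anchor-anchor axis and
one spin (α₁, α₂) of each rigid body about its chord.  The three N-Cα-C
bond-angle constraints at the pivots couple these cyclically; each of the
two spin constraints is a cone-angle equation `A cos α + B sin α = C`
solved in closed form (two branches), leaving a single smooth residual in
τ per branch combination.  The classical elimination route reduces the
same system to a degree-16 polynomial; we instead bracket the residual on
a 512-point τ grid per branch combination and refine by bisection (52
iterations, i.e. to machine precision).  Two details matter in practice:

* **Branch endpoints.** Where a cone equation becomes tangent
  (|C| = √(A²+B²)) a branch is born or dies between grid points, and a
  root can sit exactly at the boundary (this occurs, e.g., for identity
  closures of short sub-segments).  The solver bisects on branch
  definedness to locate the boundary, then checks the defined-side
  residual for a sign change or near-zero value.
* **Verification, not trust.** Every root is converted to six pivot
  torsions, the sub-segment is rebuilt from internal coordinates, and the
  chain is extended one residue past the sub-segment; the solution is
  returned only if the rebuilt anchor atoms match the fixed ones to
  within 1e-4 Å.  Non-pivot internal coordinates are preserved exactly
  because the rebuild consumes them verbatim.

The solver, rebuild and bump check run as numba kernels (the pure-Python
geometry functions remain the reference implementation in the tests); one
solve costs ~0.4 ms, which keeps a full 1200-trial trajectory near 2.5 s.

Solution multiplicity is bounded by 16 (the polynomial degree); among
bump-surviving solutions one is chosen uniformly at random — whether the
original protocol selects uniformly or with an energy bias is not
documented, so the simplest unbiased rule was taken.

## Ramachandran priors and torsion bins

The bundled tables are **synthetic**: per residue class (general, glycine,
proline, pre-proline) a mixture of 2–4 wrapped bivariate Gaussians centred
on the canonical α, β, α_L and ε basins, rasterised on a 5° grid.  They
caricature residue-specific preferences; they are *not* statistics of any
curated structure set, and nothing in the tests depends on their exact
shape.  Real tables can be substituted from the documented plain-text
format (`class phi_index psi_index probability`).  The 5° raster (rather
than a coarser one) was chosen because the score is constant within a
cell: with 10° cells the energy could not distinguish conformations that
differ by sub-Ångström amounts, which would blunt both minimisation and
the recovery diagnostics.

Torsion bins partition (φ, ψ) space exactly as four inequalities
(A: φ ≤ 0 and −130 ≤ ψ ≤ 50; B: φ ≤ 0 otherwise; G: φ > 0 and
−90 ≤ ψ ≤ 90; E: φ > 0 otherwise); bin boundaries lie on cell edges, so
every cell belongs to one bin and bin-restricted draws re-classify to
their bin by construction (a redraw guards the measure-zero edge hits).

Neighbour-dependent (rama2b) grids exist per (class, neighbour class,
side ∈ {left, right}); sampling picks a side with probability ½ (a chain
terminus forces the other side), and bin/cell probabilities integrate the
two neighbours by taking the **minimum** of the side masses.  The bundled
rama2b grids are deterministic, side-asymmetric reweightings of the base
table — again synthetic, present so the machinery is exercised.

ω sampling: planar mode returns exactly 180°; sampled mode draws from
N(179.1°, 6.3°), and for pre-prolines a cis value from N(0°, 6.3°) at a
rate of 1/10,000 (the spread of the cis distribution is not documented
anywhere we know of; reusing the trans spread is our choice).

## Surrogate energy

Three terms, deterministic and additive:

* `fa_rep_like` — soft-sphere repulsion `k(1 − d/(r₁+r₂))²` for
  `d < r₁+r₂`, `k = 1`, over pairs of (segment backbone atom, backbone
  atom of a non-adjacent residue or environment sphere).  The radii are
  the bump-check element radii (N 1.55, C 1.70, O 1.52 Å) shrunk by a
  factor 0.9 for this term only, so that ordinary packed contacts
  (helical O(i)…N(i+4) hydrogen-bond distances ≈ 2.9 Å) score zero while
  genuine overlap is penalised.  This is explicitly *not* a
  Lennard-Jones repulsive term; it gives the annealing strategies
  something honest to ramp.
* `rama`/`rama2b` — −log(cell probability + 1e-8) summed over segment
  residues (rama2b uses the min-of-neighbours cell probability).
* `omega_restraint` — harmonic deviation from the nearer of 180° and 0°,
  scaled as (Δ/6.3°)²/2.

Default full weights: 0.44 (repulsive, the conventional value used purely
as a familiar default), 0.2 (rama or rama2b — mutually exclusive: with
rama2b active the standard rama weight is 0), 0.1 (ω, small enough that
omega sampling is exercised but not dominated).  Annealing multiplies a
ramped component by `k/n` in outer cycle `k` of `n` (exactly the full
weight at `k = n`) and applies to the high-resolution stage only.

## Protocol

Defaults: 5 outer cycles, 20·L inner cycles per outer cycle, up to 2000
closure attempts per trial, kT = 1.0 (the reference protocol does not
print its acceptance temperature; 1.0 in surrogate score units gives
acceptance rates around 20–30% on the fixtures).  The low-resolution
stage builds the initial closed conformation of the whole segment from
scratch with the repulsive weight reduced to ¼ and no annealing; the
first high-resolution trial also remodels the full segment, subsequent
trials draw sub-segments uniformly over all (start, end) pairs of length
≥ 3 (the production distribution over sub-segment lengths is unprinted;
uniform is the documented choice).  After each applied move the segment
is greedily minimised: a small Gaussian kick (sd 2° on non-pivot φ/ψ,
1.5° on ω) on a random sub-segment, re-closure, keep if the score
improves — the score never increases and every intermediate is an exact
closure.  Trials are accepted by Metropolis; the lowest full-weight score
seen defines the reported model.  Ensembles derive per-trajectory seeds
as base seed + index.  A `legacy` preset reproduces the older protocol
shape (3 outer cycles, no ramping); `ngk` activates rama2b + omega
sampling + both ramps.

Taboo mode consumes one torsion-bin vector per closure attempt from a
1000-entry list, refilled on exhaustion.  The refill draws vectors without
replacement with probability ∝ Π over positions of (prior bin probability
/ (1 + times that bin was already sampled at that position)) — the
division is this package's concrete realisation of the qualitative
"adjusted frequency" rule: monotone-decreasing in the sampling history and
never zero.  Position priors use the rama2b min-rule when rama2b is
active.  The TabooMap stores vectors uppercase-normalised (coverage is
defined over the 4^L φ/ψ bin space), clears at 95% coverage, and retains
its per-position counts across clears so diversification pressure
persists.  For L ≤ 8 the refill enumerates the untested set exactly;
beyond that it samples position-wise (the product weight factorises) with
rejection of duplicates and tested vectors.

## Synthetic fixtures and what passing tests mean

A fixture is a 36-residue chain: helical flanks, a 12-residue central
segment whose native torsions are drawn from the bundled tables
(rejection-sampled until the segment packs clash-free), then **relaxed**
— a greedy, clash-constrained descent of the rama + ω objective using the
same closure moves — so that, like a refined crystal structure, the
native sits in a local minimum of the scoring model.  Thirty environment
spheres (radius 1.6 Å) are then seeded just beyond contact distance
(margin 1.0 Å) off random segment atoms, sculpting a funnel: the native
is exactly clash-free while conformations that stray into the shell
collide.  The start structure discards the segment's torsion information
(redrawn from the tables, rebuilt from the N-side flank, chain break at
the segment end).  Generation is deterministic per seed; an unclosable
geometry bumps the seed (up to 10 times) before failing.

These fixtures make the recovery property meaningful: on all five bundled
cases, 20-trajectory torsion-restricted ensembles reach sub-Ångström
endpoints while paired standard-sampling ensembles do not beat them.
What this shows is that the *machinery* — closure, bin restriction,
minimisation, bookkeeping — concentrates sampling where the prior says to
look.  What it does **not** show is performance on real proteins: the
surrogate energy has no attraction, solvation or side chains, the
environment is isotropic spheres, and the tables are caricatures.  Any
quantitative claim about real loop benchmarks requires a production
energy function and real structures.

## Problem sizes used in the shipped checks

Closure exactness and locality are checked over 1000 random moves;
distribution checks use 10⁶ draws (ω mean/sd, Ramachandran χ² at
α = 0.01) and 10⁷ branch draws for the cis rate; Metropolis at 10⁵
trials; recovery uses the five bundled fixtures × 20 trajectories ×
(restricted, standard) at the full 1200-trial default — about 200
trajectories, the bulk of the suite's runtime.

## Known limitations

* The grid-plus-bisection solver can, in principle, miss root pairs that
  fall entirely inside one grid cell of τ; the 512-point grid makes this
  rare, and every returned solution is still exact (the failure mode is a
  missed alternative conformation, never a wrong one).
* Scores are cell-constant in φ/ψ, so minimisation stalls at the 5°
  resolution floor; sub-Ångström discrimination below that comes from the
  repulsive and ω terms.
* No side chains: "repacking" steps of the reference protocol are absent,
  and environment spheres do not reorganise.
* Cross-trajectory sharing of TabooMaps is out of scope.
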