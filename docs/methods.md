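# Methods

## Model

The package analyses a two-gene decision-making circuit in which each
gene's protein product activates its own conditional promoter and
represses the other gene's constitutive promoter, with first-order
degradation.  Writing `x1`, `x2` for the protein levels,

```
dx_i/dt = λ(A*) · a_i · x_i^n / (θ_a_i^n + x_i^n)
        + λ(A*) · b_i · θ_b_i^n / (θ_b_i^n + x_j^n)
        - k_i · x_i ,            j ≠ i
```

All regulatory interactions are Hill functions with a shared
cooperativity exponent `n`; `θ_a`, `θ_b` are the dissociation constants
of the activator and inhibitor to the promoter regions.  The model
deliberately coarse-grains gene expression to the protein level — there
is no explicit mRNA stage — and treats only the constructive processes
(transcription/translation) as energy dependent; degradation is not
scaled.

Energy enters through the dimensionless factor `λ(A*)` multiplying both
production terms.  `A*` is the cell's free-energy availability as a
fraction of its maximum, so `A* ∈ [0, 1]`.  Three scalings are
implemented:

* **sigmoid** (default): `λ = 1 / (1 + exp(−(s1·A* + s2)))` with
  `s1 = 16`, `s2 = −8`.  These defaults put the midpoint at
  `λ(0.5) = 0.5` exactly and keep `λ` strictly inside `(0, 1)`; they
  reflect the experimentally observed sigmoidal dependence of total
  transcription rate on ATP concentration.
* **linear**: `λ = A*` clamped to `[0, 1]`.  No published formula pins
  this variant down beyond linearity; the identity-with-clamping form is
  the simplest choice and is used to confirm that conclusions do not
  hinge on the sigmoid shape.
* **shifted**: `λ = floor + (ceiling − floor) · σ(s1·A* + s2)` — an
  affine rescale of the same sigmoid modelling uptake of external ATP:
  `λ` is nonzero at `A* = 0` and may exceed 1.  The exact published form
  of this variant is not available; floor and ceiling are exposed
  parameters with demonstration defaults 0.1 and 1.2 in the
  `external_atp` scenario.

For concrete biology, `map_atp_to_astar` maps an absolute ATP
concentration linearly onto `A*` between the bounds observed in
*E. coli* populations, 320 μM (`A* = 0`, taken as the critical energy to
continue as a living cell — lower concentrations are flagged
sub-critical) and 2760 μM (`A* = 1`).  The true concentration-to-energy
curve is not known; the linear map is a documented stand-in.

The canonical parameter set is `a = b = k = 1`, `θ_a = θ_b = 0.5`,
`n = 4`, symmetric across the two genes.  At full energy it is
tristable: two extreme fates (one gene high, the other low) and one
intermediate fate with both genes equally expressed.  Basal rates `b_i`
may be set to 0 (the decoupled limit, where each gene is an independent
bistable switch); all other rates and thresholds must be positive.

## Steady states and stability

Steady states are found by multistart root finding.  Every root of the
system lies in the box `[0, x_max]^2` with
`x_max = max_i λ(a_i + b_i)/k_i` (production is bounded by
`λ(a_i + b_i)` and degradation is linear), so Newton iterations are
started from a 25×25 lattice covering `[0, 1.2·x_max]^2`.  The iteration
is damped (steps capped at half the search span), projected onto the
non-negative quadrant, and uses the analytic Jacobian with the 2×2 system
solved in closed form; all starts are advanced simultaneously as numpy
arrays, which makes a full multistart solve take a few milliseconds.

Numerical choices that matter:

* The Newton target residual is `1e-13`, well below the verification
  tolerance `1e-9` at which a candidate is accepted as a root.  The gap
  is deliberate: near a degenerate (quadratically flat) equilibrium,
  points that merely satisfy `‖f‖ < 1e-9` form a smear of false roots;
  iterating further collapses them into the true root cluster.
* Roots are deduplicated by greedy Euclidean clustering at `1e-5`, the
  cluster representative being the member with the smallest residual.
* The activation Hill term at `x = 0` is defined as 0 for every `n ≥ 1`
  (its limit value); its derivative at 0 is 0 for `n > 1` and `a/θ_a`
  for `n = 1`.  Both conventions fall out of the vectorized power
  expressions without special-casing.
* Stability is classified from the real parts of the Jacobian
  eigenvalues: stable iff the leading real part is below `−1e-8`.
  Marginal roots (within `1e-8` of zero) are labelled *unstable* —
  "functionally unstable": expression noise would not hold the system at
  a metastable point, so such states are not counted as fates.
* If no root survives verification, or a positive-production system
  reports zero stable roots, `find_steady_states` raises a diagnostic
  rather than returning a defective set.

**Known limitation — exact degeneracies.**  With `n = 1`, `b = 0` and
the remaining defaults, the circuit is exactly non-hyperbolic at
`A* = 0.5` (`λ·a/θ_a = k`): the origin is the unique steady state, it
attracts polynomially, but its leading eigenvalue is exactly zero, so the
functional-instability rule labels it unstable and the diagnostic above
fires.  This is a measure-zero knife edge created by the round default
constants; the built-in cooperativity scenarios use an A* lattice that
does not contain the point.  Users scanning custom grids through such a
degeneracy will see the diagnostic, which is preferable to a silently
arbitrary count.

Trajectories (for basin membership and the root-finding oracle) are
integrated with classical RK4 at a fixed step chosen from a crude
Lipschitz bound on the vector field, with early exit once
`‖dx/dt‖ < 1e-8`; terminal points are matched to attractors within
`1e-3`.  Initial conditions are integrated in batch.  Lattice cells that
converge onto a *saddle* — exactly symmetric starts in a symmetric
circuit lie on the diagonal saddle's stable manifold — are separatrix
cells: they are labelled `BOUNDARY` in basin maps, distinct from
`UNDETERMINED` (non-convergence), and only the latter triggers the
bad-integrator diagnostic (more than 1% undetermined).

## Bifurcation sweeps and landscapes

Energy sweeps solve each `A*` independently (no continuation), by
default in steps of `5e-3` over `[0, 1]`.  The stable-count sequence is
run-length encoded; re-entrance is flagged when a count value recurs in
non-adjacent runs (e.g. 1, 3, 2, 3 at high conditional-promoter
activity `a ≳ 2`).  On the default circuit the sweep runs 1 → 2 → 3: the
symmetric low branch loses stability through a pitchfork before the
intermediate branch restabilizes, so a genuine bistable window separates
the monostable and tristable regimes.  Attractor separation is measured
between the two extreme attractors (maximizers of `x1 − x2` and
`x2 − x1`) and grows monotonically with energy once both exist.

Count landscapes evaluate `find_steady_states` on a parameter plane,
canonically `b ∈ [0, 3] × A* ∈ [0, 1]` at fixed `a` (default resolution
61×51; the structural results — which count categories occur, where the
monostability threshold lies — are already stable on 31×26 grids, which
is what the end-to-end checks use to stay fast).  Because attractor
counts are deterministic properties of the circuit, recomputing a grid
with a denser multistart lattice must reproduce it exactly; this is
tested.  The low-energy monostability threshold reported per column is
the first lattice `A*` at which the count leaves 1, i.e. the separatrix
of the phase portrait sampled on the lattice.

## Transition distances

Switching difficulty between the two extreme fates is geometric: the
minimum Euclidean perturbation in `(x1, x2)` that moves the system from
the high-`x1` attractor into the basin of the high-`x2` attractor,
either directly or via an intermediate hop (perturb into a
stepping-stone basin, relax to that attractor, perturb again).  Both the
intermediate and the near-zero attractor (when present in 4-attractor
landscapes) are admitted as stepping stones; routes through more than
one stepping stone are available behind `allow_multihop` (Dijkstra over
the attractor graph) but single-hop minimization is the default, and in
practice multihop never improves on it in the landscapes scanned here.

Point-to-basin distances are evaluated on a basin lattice (default
101×101; 41×41 inside difficulty grids) and then refined: bisection
along the segment from the source point to the nearest labelled cell
localizes the basin boundary to `1e-4` absolute, with membership decided
by integrating the flow rather than by the lattice.  The pure-lattice
distance overestimates by at most one cell diagonal; the refinement
removes this, and agreement with a dense 201×201 brute-force lattice is
tested.  Roles are assigned by rule: high-`x1` maximizes `x1 − x2`,
high-`x2` the reverse (ties toward larger `x1`), near-zero is the
attractor minimizing `x1 + x2` when that sum is below `0.05·x_max`, the
rest are intermediate.  Transition distances are undefined (NaN in
grids, an error for a direct call) on monostable landscapes.

## Scenarios as the synthetic-input generator

There are no external data; the inputs are parameter regimes.  The
`scenarios` module encodes every regime the analyses exercise as a named,
self-describing object: the default-constant sweep, the `(b, A*)` phase
portrait at `a = 1`, the six-panel activity series, the cooperativity
members `n = 1..4`, the binding-strength scans, the external-ATP variant
and the transition-difficulty grids.  Where the published setting pins a
value (default constants, axis ranges, the `5e-3` sweep step) the
scenario uses it exactly; where it does not (the panel `a` values
{0.25, 0.5, 1, 1.5, 2, 3}, the high-`a` scan {1.5, 2, 2.5, 3}, the θ
ranges, the shifted-λ floor/ceiling), the choice is made once here and
the provenance note says "guessed", so no downstream test silently
depends on an invented constant.  `random_params` draws log-uniform
symmetric (optionally asymmetric) parameter sets across these scan
ranges (`a, b ∈ [0.1, 3]`, `k ∈ [0.2, 2]`, `θ ∈ [0.1, 1.5]`,
`n ∈ {1..4}`) for property tests; draws are deterministic per seed.

These regimes emulate the study conditions, not wet-lab data: passing
tests show that the deterministic ODE landscape behaves as described
under these parameterisations.  They say nothing about stochastic gene
expression (noise-driven switching, mean first-passage times), about
mRNA-stage dynamics, or about parameter values fitted to any real
circuit — all outside the model's scope.

## Problem sizes and determinism

The end-to-end checks use 31×26 landscape grids, `5e-3` sweeps and
41–101 point basin lattices; these sizes reproduce every structural
result (category sets, maxima, re-entrance, thresholds) and keep a full
run in minutes on one core.  Everything in the pipeline is
deterministic: the only randomness anywhere is the seeded sampler used
by property tests.
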