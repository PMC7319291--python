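# Methods

## The model

Degree heterogeneity quantifies the inequality of a network's degree
distribution: regular graphs sit at one extreme, star-like graphs at the
other. The raw degree variance v(G) — here always the n−1 (sample)
variance of the degree sequence, which is the convention forced by the
identity v(G) = ‖k‖₂²/(n−1) − (2m)²/(n(n−1)) and by every closed form
below — grows with both network size and density, so it cannot be compared
across networks.

The normalised degree variance

    v̄(G) = (n−1)/(n·m·(1−d)) · v(G),  d ∈ (0,1);   v̄ = 0 at d ∈ {0,1}

follows from the classical upper bound ‖k‖₂² ≤ m(2m/(n−1) + n − 2) on the
sum of squared degrees. Its guarantees:

* **Range.** 0 ≤ v̄ ≤ 1 on every simple graph; 0 exactly iff regular.
  The d ∈ {0,1} branch is a definition, not a limit: empty and complete
  graphs are regular, so assigning 0 keeps the "regular ⇒ 0" axiom while
  avoiding the 0/0 in the general formula.
* **Complement invariance.** v̄(G) = v̄(Ĝ), via k̂ᵢ = n−1−kᵢ and
  m̂ = n(n−1)/2 − m; the unreduced rational forms of the two sides are
  identical, so with the exact evaluation described below the equality is
  bit-exact, not approximate.
* **Extremal values.** Among perfect quasi-stars with r dominant nodes,
  v̄ = 2(n−1)(n−r−1)/((2n−r−1)n), strictly decreasing in r; the star
  (r = 1) gives (n³−5n²+8n−4)/(n³−3n²+2n) → 1. At fixed (n, m) the
  maximum degree variance is attained by a quasi-star or quasi-complete
  graph; the test suite confirms this against exhaustive enumeration of
  all 2^(n(n−1)/2) labelled graphs for n ≤ 6.

## ER ensemble expectation — the corrected constant

For G(n, m), E[v̄] is exactly independent of m. The constant shipped here
is

    E[v̄(G(n,m))] = 2(n−1)/(n² + n),

which differs by a factor n/(n−1) from the constant sometimes quoted for
this quantity. The discrepancy is a denominator-convention mismatch: the
classical expected degree variance of G(n, m),
E[v_pop] = 2m(n² − n − 2m)/(n³ + n²), is stated for the population
(n-denominator) variance, while v̄ is built on the sample (n−1) variance;
since v_sample = (n/(n−1))·v_pop pointwise, the expectation must be
rescaled before normalising. The package's constant is verified two ways:
exhaustive enumeration of **all** graphs at n = 4 (E[v̄] = 0.300 = 2·3/20
at every interior m) and Monte-Carlo at n ∈ {16, 64} (e.g. 20,000 draws of
G(16, 60) give 0.11019 ± 0.00026 against 0.11029 predicted; the unscaled
constant 0.10340 is ~26 standard errors away). Conditional on its edge
count, G(n, p) is uniform over graphs with that edge count, so the same
constant is the G(n, p) expectation up to the negligible probability mass
on the empty and complete graphs; `expected_vbar_er_gnp` therefore returns
the same value.

## Competitor indices

* **J** (quasi-star normalisation): v(G)/v(G_qs) with G_qs the quasi-star
  of the same n and m. Exceeds 1 on quasi-complete graphs (the package's
  own example: J(quasi_complete(6,10)) = 1.4286), and costs a graph
  construction per evaluation. Undefined (flagged) when G_qs is regular,
  i.e. at m = 0 or complete.
* **σ²** (average-degree normalisation): v(G)/(2m/n); grows with n, kept
  only for comparison. Undefined at m = 0.
* **ρ** (heterogeneity index): Σ_edges (kᵢ^(−1/2) − kⱼ^(−1/2))² divided by
  n − 2√(n−1). The sum is over **edges**, not all node pairs — that is the
  reading under which ρ(star) = 1 exactly (the edge sum equals the
  denominator identically), and it matches the index's original
  definition. Undefined on any graph with an isolated node.
* **irr** (Albertson irregularity): Σ_edges |kᵢ − kⱼ|, i.e. ½ of the sum
  over ordered adjacent pairs.

Undefined values are first-class: functions return an `Undefined(reason)`
object, reports serialise it as `NA` plus a reason column, and sweeps
average only over defined repetitions while counting the failures. This is
what makes ρ's failure rate on subsampled graphs measurable rather than an
exception path.

## Lower bounds

If a graph is guaranteed x < n nodes of degree a, then

    v̄ ≥ (1/(1−d)) · x(an − 2m)² / (n²(n−x)m),

with equality-relevant structure at the extremes: the bound vanishes at
a = 2m/n (the average degree) and is tight on stars. `max_lower_bound`
evaluates the bound at every distinct degree with x = its multiplicity
(degrees held by all n nodes are skipped) and returns the maximum, with
ties resolved deterministically toward the smallest degree; the achieving
degree is also reported as a relative degree (k − min k)/(max k − min k).
For a = 1 and a = n−1 the bound approaches (x/n)·2d/(1−d) and
(x/n)·2(1−d)/d respectively for large n — the two limits exchange d ↔ 1−d,
mirroring complement invariance.

## Graph families (the synthetic data)

All stochastic generators are driven by a NumPy `Generator` or integer
seed and are bit-reproducible.

* **quasi_complete(n, m)**: the largest clique with s(s−1)/2 ≤ m, one
  node attached to r = m − s(s−1)/2 clique members, isolated remainder.
* **quasi_star(n, m)**: defined as the complement of
  `quasi_complete(n, n(n−1)/2 − m)`. Verbal descriptions of quasi-stars
  via edge counts are ambiguous about the remainder structure; the
  complement construction is unambiguous, yields exactly m edges for every
  m, and reproduces the perfect-graph duality (perfect quasi-complete of
  order r = complement of perfect quasi-star of order n−r).
* **er_gnm / er_gnp**: uniform fixed-edge-count draws (sampling m distinct
  pair indices) and independent Bernoulli(p) edges.
* **weighted_er(n)**: i.i.d. uniform(0,1) symmetric weights; thresholding
  at density d is distributionally a G(n, round(d·N)) draw, because the
  order statistics of i.i.d. weights are exchangeable over pairs.
* **random_geometric_weighted(n)**: n points uniform in the unit square,
  weight 1 − dist/√2. Any strictly decreasing function of distance gives
  identical thresholded graphs; this one keeps weights in [0,1].
* **scale_free_core(n, core_frac, attach_frac)**: complete core on
  round(core_frac·n) nodes, then each remaining node attaches
  round(attach_frac·n) edges to distinct existing nodes with probability
  proportional to current degree. Defaults core_frac = 0.125,
  attach_frac = 0.0625 give realised density ≈ 12.5%; the edge count
  C(c,2) + (n−c)·a is deterministic. The core-plus-preferential-attachment
  reading is one of several "scale-free at fixed density" constructions;
  only the density bookkeeping is pinned down, and the package treats the
  rest as its own design choice.
* A **plug-in registry** (`register_family`) lets the sweep harness drive
  user-supplied generators (e.g. hierarchical-structure models, which are
  deliberately not built in).

What the synthetic families do *not* emulate: real connectivity matrices
(e.g. electrophysiological phase-coupling networks) have spatially
correlated weights, measurement noise and non-exchangeable structure, so
passing tests here demonstrates the mathematical properties of the indices
and the correctness of the procedures, not field-specific effect sizes.

## Thresholding and subsampling conventions

* Counts derived from fractions — edges kept by `threshold_to_density`,
  nodes/edges removed by subsampling — use round-half-away-from-zero, so
  realised quantities are closest to the target; equal weights are broken
  by lexicographic pair order, making thresholding deterministic and its
  outputs nested across increasing densities.
* Inverse-degree edge removal computes h_ij = ((n−1)−kᵢ)((n−1)−kⱼ) **once**
  from the original degrees, then removes edges sequentially without
  replacement by inverse-transform sampling on the cumulative h over the
  surviving edges. Freezing h (rather than recomputing degrees after each
  removal) keeps the scheme a pure weighted-sampling-without-replacement
  with analytically checkable single-draw probabilities; it is a
  documented interpretation. If every h_ij is zero (any graph whose every
  edge touches a dominant node, e.g. stars and complete graphs), the
  scheme degenerates and uniform removal is used with a logged warning.
* Robustness profiles average each metric over the repetitions where it is
  defined, report the fraction of undefined repetitions separately, and
  for node removal also report the induced fraction of edges lost.

## Sweeps and coefficients of variation

Sweeps evaluate indices on a (family, size, density) grid; the default
density grid is integer percentages 1–99%. Extremal families are
deterministic (one graph per cell, m = round(d·N)); stochastic families
average over seeded repetitions. The coefficient of variation uses the
sample (n−1) standard deviation over the mean, flagged undefined at zero
mean. `cov_wrt_size` takes the CoV across sizes per density and averages
over densities; `cov_wrt_density` the transpose. Quasi-star sweeps of J
give exactly zero under both summaries (J ≡ 1 there), which is the
package's deterministic calibration cell; cells for other families are
reproduced qualitatively, since aligning the discrete achievable densities
of extremal graphs across different sizes admits more than one convention.

## Numerical choices

* v and v̄ are evaluated in exact integer arithmetic —
  v̄ = (n‖k‖₂² − 4m²)(n−1) / (n·m·(n(n−1)−2m)) as one correctly-rounded
  big-integer division. The naive two-term float evaluation cancels
  catastrophically on large dense graphs (about ten digits lost at
  n = 2000 near d = 1) and would break both the 1e−12 closed-form
  agreement and exact complement invariance.
* Exactness tolerances in tests are 1e−12 for algebraic identities; ρ = 1
  on stars is asserted to 1e−12 because the identity is exact but its
  float evaluation rounds in the last ulp.
* Monte-Carlo checks use 3-standard-error bands with 2,000 draws per
  condition; the randomized property suite uses 10,000 graphs over
  n ∈ [4, 256]; exhaustive extremality enumeration stops at n = 6
  (32,768 graphs per size).

## Known limitations

* Simple undirected graphs only: no weights inside the indices, no
  directed or multi-edges, no self-loops.
* `quasistar_normalization` constructs the reference quasi-star per call;
  it is O(m) and fine at desk scale but is exactly the cost v̄'s closed
  form avoids.
* The scale-free generator's Python attachment loop is adequate to
  n ≈ 10⁴, not for million-node graphs.
* CoV tables for stochastic families carry sampling noise of order
  1/√reps; only the structural zeros (J on quasi-stars) are exact.
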