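# Methods

This note records the models, conventions, numerical choices and known
limitations behind `netcompare`. Everything quantitative here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that
the code does not itself check.

## The problem being modelled

Empirical connectivity studies produce, per subject and condition, a
symmetric matrix of connection strengths between N recording sites or
parcels (typically 16–150 for M/EEG sensor arrays, ~70–100 for standard
MRI parcellations). Graphs are derived from these matrices and summarized
by scalar measures. Each measure depends on N and on the average degree k
in a way that differs between topologies (closed forms in
`netcompare.analytic`: for a ring lattice L ∝ N/k with C free of both;
for an Erdős–Rényi graph L ≈ ln N / ln k and C ≈ k/N). Since the
topology of real data is exactly what one is trying to infer, no
universal correction exists; the package implements the candidate
procedures and the simulations that expose their biases.

## Graph measures: conventions

* **Path length L** is the mean shortest-path hop count over *reachable
  ordered pairs*. Published definitions rarely state a policy for
  disconnected graphs; averaging over reachable pairs keeps L finite and
  we always report the reachable-pair fraction so silent disconnection
  cannot hide. A strict `policy="error"` raises, naming the component
  count. Weighted L uses shortest paths over inverse weights (strong
  connections are short).
* **Clustering C** is the mean over nodes of the fraction of closed
  neighbor pairs. Nodes of degree < 2 contribute 0 by default (the
  alternative, excluding them, is available); this keeps C defined for
  every graph and bounded in [0, 1]. Weighted C uses the geometric-mean
  (Onnela) triangle convention via networkx.
* **Hubs**: a node is a hub when its degree strictly exceeds
  mean + 2 SD of the degree distribution. The strict inequality makes
  regular graphs (SD = 0) hub-free, which any relative rule should
  satisfy. The rule is configurable and recorded in provenance.
* **Synchronizability** is the Laplacian eigenratio λ_max/λ₂ (≥ 1,
  equality only for the complete graph); **central point dominance** is
  Freeman's mean gap between the maximum normalized betweenness and each
  node's betweenness. Both are documented conventions — the literature
  contains variants — and are flagged as such rather than asserted as
  canonical.

## Graph construction

Three binarization regimes: fixed threshold (strict `> τ`), fixed average
degree (top `round(Nk/2)` pairs), fixed density (top `round(ρ·N(N−1)/2)`
pairs). Fixed degree and fixed density coincide for equal N (tested as a
property). Ties at the cut value are broken by descending strength then
lexicographic node-pair order, deterministically, and the number of
dropped tied pairs is reported — silent tie-breaking is a real source of
irreproducibility in thresholded network studies. Significance of
connectivity values is *not* computed here: a null distribution for
coherence-like quantities is estimator-specific and upstream of this
package, so thresholds are user-supplied.

## Generators and surrogates

All generators take an integer seed and are bit-reproducible. The
Watts–Strogatz implementation rewires the far endpoint of each lattice
edge independently with probability p (the classic convention; the
package records which edges were rewired, so local/long-range accounting
like "N=100, k=10, p=0.1 has 900 expected local stubs" is exact rather
than heuristic). One consequence, verified in the tests: at p = 1 each
node retains its k/2 outgoing stubs, so the degree distribution is
k/2 + Poisson(k/2) — slightly narrower than Erdős–Rényi — and clustering
sits a few percent below the ER value. Fully rewired WS is
random-graph-like but not exactly G(N,p).

Maslov–Sneppen surrogates perform accepted double-edge swaps (no
self-loops, no duplicates) until the requested budget (default 10·E) is
met; graphs admitting no swap are returned unchanged with a warning flag.
The same routine handles digraphs, preserving in- and out-degree
sequences separately.

Ring lattices require even k. Non-integer-k lattices (needed for
fixed-density sweeps and as range-normalization references) are built by
`nearest_integer_lattice`: full neighbor rings for offsets 1..E//N plus
the remaining E mod N edges at the next offset, round-robin —
deterministic, exactly E edges.

## Normalization

Surrogate normalization divides a measure by its mean over surrogates
matched in N and E (ER ensemble: uniform G(N,E); degree-preserving:
Maslov–Sneppen). Means, not medians, are used, with the surrogate SD
reported for z-scoring; 200 surrogates by default. Surrogate L uses the
reachable-pairs policy with a resampling cap for edgeless draws.

The package's central cautionary result, reproduced in
`tests/test_acceptance.py`: for ring lattices at fixed k, raw C is
independent of N (closed form 3(k−2)/(4(k−1))), yet C/C_rand grows with N
because C_rand ≈ k/N shrinks — the normalization *introduces* a size
dependence that the raw measure did not have, and the small-world index
inherits it (SW of a fixed-topology WS(p=0.1) roughly doubles when N
doubles). Only at fixed edge density, or for p → 1, is the normalized
value approximately size-free.

Range normalization expresses a measure as a position in its obtainable
range, (x − x_rand)/(x_lat − x_rand), with the random reference a matched
G(N,E) ensemble mean and the lattice reference the deterministic
nearest-integer lattice. A lattice scores exactly 1, a random graph 0 in
expectation. Its cross-N coefficient of variation for WS(p=0.1)
clustering is several-fold smaller than that of surrogate normalization
(computed by the acceptance script). It presumes the data lie between
lattice and random — appropriate for small-world-like networks only.

## Baseline-model comparison and k-dependence estimation

`delta_distribution_test` simulates a generative baseline matched to each
network's (N, k), builds the distribution of measure differences over
n_reps = 2000 paired draws (percentile 95% interval; the percentile form
is chosen over a normal approximation because measure differences for
small graphs are visibly skewed), and reports whether the observed
difference is inside. Coverage under the true model is itself tested
(~95%).

`estimate_p_rewire` matches the observed small-world index against mean
simulated SW over a p-grid by least squares. Two design choices matter.
First, the surrogate reference for SW depends only on (N, E), so it is
computed once and shared across all grid points and repetitions — this is
what makes the grid search affordable. Second, SW(p) is *non-monotone*:
it rises from the lattice value (L collapses faster than C as shortcuts
appear), peaks, and then decays toward 1. A given SW value below the peak
is therefore attained on both branches. The default grid starts at
p = 0 (so a pure lattice matches itself exactly) and near-ties — squared
errors within the Monte-Carlo error of the simulated curve — resolve to
the smallest p. Weighted inputs are simulated by placing the empirical
weight multiset in a ring lattice and rewiring; their SW is computed on
the binary pattern.

`estimate_k_dependence` removes edges uniformly at random, cumulatively,
down a decreasing k-grid, recomputing L and C at each step (200
repetitions). The procedure is deliberately biased: removing edges from a
small-world graph destroys local clustering faster than rewiring would,
so the estimated C curve lies below the C of directly generated
small-world networks at the same k, while L (already near its random
value) moves much less, and the curves depend on the source network's k.
The package measures this bias rather than hiding it — it is the reason
sampled-down networks cannot straightforwardly calibrate a k-correction.

## Graph comparison

Hamming distance counts disagreeing ordered off-diagonal entries
(undirected edge differences count twice; an unordered mode halves).
Structural distance minimizes Hamming over relabelings of the second
graph: exhaustive for N ≤ 8, otherwise simulated annealing over
transpositions (geometric cooling, 10⁴ proposals, seeded, flagged
approximate; never below the exact value or above plain Hamming —
property-tested). All N! permutations are treated as accessible; no
exchangeability constraints are imposed.

Graph correlation is the Pearson correlation of off-diagonal entries.
For binary graphs the attainable bounds follow from the overlap count o:
correlation is increasing in o, so the bounds sit at
o = min(E₁,E₂) and o = max(0, E₁+E₂−M); the correlation normalized by its
attainable maximum is reported. Costa's coincidence similarity is
sqrt(r_ones · r_zeros) with both ratios taken relative to the *first*
graph's entries; the measure is asymmetric in its arguments by
construction, which is documented rather than symmetrized away.

## Motifs and ERGMs

The triad classifier is built at import by brute force: each of the 64
labelled 3-node digraphs is canonicalized by minimizing its 6-bit arc
code over the 6 node permutations (16 classes, 13 weakly connected —
itself a unit test), and classes are named by fixed Davis–Leinhardt
anchor representatives. The census enumerates all C(N,3) triples with
vectorized code lookup — O(N³), perfectly adequate for N ≤ 200.
networkx's independent census implementation serves as a test oracle, not
as the implementation. Motif significance uses arc-density-matched
directed ER surrogates by default (so surrogate average degree matches
the data), with degree-preserving rewiring optional; empirical two-sided
p-values use the add-one rank convention.

The ERGM places P(y) ∝ exp(θ·g(y)) on digraphs. No implicit edges term
is added — the sign of every coefficient is read relative to the uniform
(arc probability ½) digraph, and a model contains exactly its listed
statistics. Sampling is single-arc-toggle Metropolis–Hastings with exact
change statistics (dyad terms from the reciprocal arc, star terms from
endpoint degrees, triad terms by reclassifying the N−2 affected triples;
exactness is property-tested against full recounts). Fitting: maximum
pseudo-likelihood (logistic regression of arc indicators on change
statistics, which is the exact MLE for dyad-independent models)
initializes a stochastic-approximation iteration
θ ← θ + a_t Σ̂⁻¹(g_obs − ḡ) with gain a_t = 0.5/(1+t)^0.6 and a
trust-region cap of 0.5 on the step norm — the damping matters: with
short per-iteration samples an undamped step random-walks away from an
already-correct MPLE. Standard errors are sqrt(diag(Σ̂⁻¹)) with Σ̂ the
covariance of sampled statistics (the exponential-family Fisher
information). The default schedule (10 iterations × 10⁴ proposals) is a
desk-scale reduction of a 10 × 10⁵ schedule; both are available.

The log-likelihood is estimated by bridge sampling along the path
θ_t = (t/J)·θ̂ from θ = 0, whose normalizer is analytic
(log n(0) = N(N−1) ln 2), with J = 10 bridges; the delta-method MC error
is reported (it understates the true error somewhat because chain samples
are autocorrelated — tests allow for this). Null deviance is
2 N(N−1) ln 2 (1206.08 at N = 30, df = 870), residual deviance
−2·loglik, AIC = 2p − 2·loglik, Akaike weights
exp(−ΔAIC/2)/Σexp(−ΔAIC/2).

Degeneracy — the fitted distribution collapsing so that sampled
statistics no longer cover the observed values — is detected from the
final sample (observed outside the sampled range, or a collapsed
statistic off the observed value) and flagged; residual deviance and AIC
are then reported as unavailable rather than as numbers. The classic
explosive case, a positive two-in-star coefficient on a hub-concentrated
digraph, reliably triggers the flag and is the tested example. Near
dyad-census boundaries (e.g. no null dyads) the MLE diverges; fitting
refuses boundary statistics, and the exact-enumeration cross-checks
screen such draws.

Goodness of fit simulates 100 networks at θ̂ and overlays the observed
triad census, in/out-degree distributions and modeled statistics on 95%
simulation envelopes, with inside/outside flags per bin.

## Synthetic connectivity data

`synth_connectivity` emulates sensor-level functional connectivity: a
planted topology (default Watts–Strogatz) scaled by `base_strength`
(default 0.6), a `global_offset` emulating between-condition differences
in overall connectivity level, and symmetric additive Gaussian noise
(default SD 0.05), clipped to [0, 1]. With base_strength ≥ 5·noise_sd
the planted graph is recoverable by density-matched thresholding (≥ 95%
of planted edges; tested). What it does *not* emulate: spatially
correlated noise, volume-conduction-like common-input structure,
distance-dependent connectivity, or subject heterogeneity. Tests passing
on these fixtures demonstrate algorithmic correctness, not robustness to
those real-data complications.

## Problem sizes and numerical notes

Simulation-backed checks default to 200 repetitions and 200 surrogates.
The test suite and acceptance script use networks of N = 30–400 and, for
ensemble comparisons, 10–200 repetitions per condition, chosen so the
full suite completes in minutes on one CPU while every qualitative
contrast retains ≥ 3-SE separation. Exact structural distance is capped
at N = 8 (8! permutations); exact ERGM enumeration at N = 4 (4096
digraphs). Matrix symmetry tolerance is 1e−9; Laplacian connectivity is
λ₂ > 1e−9; range normalization refuses references closer than 1e−12.

## Known limitations

* Weighted generalizations of L and C are fixed conventions (inverse
  weights, geometric-mean triangles), not a survey of the weighted-graph
  literature.
* The small-world index of weighted networks is computed on the binary
  pattern within `estimate_p_rewire`.
* Comparison measures require equal N by construction; nothing here
  compares graphs of different size directly.
* k-stars are supported as statistics via endpoint-degree binomials, but
  directed k-cycles are implemented for k = 3 only (cyclic triples).
* ERGM likelihood values are Monte-Carlo estimates; AIC differences
  smaller than a few units should not be over-read.
* Scale-free (preferential-attachment) networks are generated but not
  systematically swept over (N, k): the model does not allow independent
  manipulation of both.
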