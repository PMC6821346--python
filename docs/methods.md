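# Methods

## Model

A layout assigns each node *i* an isotropic two-dimensional Gaussian with
mean **r**ᵢ (the drawn position) and standard deviation σᵢ (the node
width).  The network is read as a probability distribution *P* over
unordered node pairs; the layout induces a second distribution *Q* on the
same pair set; the quality of the drawing is the information lost when *Q*
stands in for *P*:

    KL(P ‖ Q) = Σ_{pairs, p>0} p · ln(p / q)        [nats]

reported as the normalized loss D = KL / H(P), with H(P) = −Σ p ln p.
Division by the target entropy makes D dimensionless and roughly
size-independent; it cancels in ratios, so fold comparisons between two
layouts of the same network are identical for raw and normalized losses.
For a single-pair target H(P) = 0 and the raw KL is reported, flagged in
the result.

**Target.**  With the plain adjacency, p ∝ w for each edge; non-adjacent
pairs have p = 0 but remain in the pair set.  With the squaring option the
symmetric weight matrix *W* (zero diagonal) is squared: (W²)ᵢⱼ is the
weighted count of shared neighbours, which emphasises interaction-profile
similarity and visibly sharpens modules.  The diagonal of W² (each node's
weighted degree mass) is either dropped (`ignore_square_diagonal`) or kept
as self-pair probability; in the kept mode the pair set gains the diagonal
pairs (i, i), whose representation value is the node's self-overlap
(4πσᵢ²)⁻¹.  Whether the original tool includes such self terms is not
documented; this mapping is this package's definition, chosen so the
"ignore" switch has a concrete complement.

**Representation.**  Pair (i, j) carries the overlap integral of the two
Gaussians, o_ij = (2π s_ij)⁻¹ exp(−d_ij²/(2 s_ij)) with s_ij = σᵢ²+σⱼ² and
d_ij the Euclidean distance; Q normalizes these over the pair set.
Overlaps are computed in log space and Q entries are floored at 1e-300, so
widely separated nodes underflow gracefully rather than producing zeros on
the support.  Because every overlap scales by c⁻² under a joint similarity
transform (translate/rotate/scale positions and widths together), Q — and
hence D — is invariant to such transforms; coordinates are unitless and no
canvas convention is imposed.

"Width" is interpreted as a standard deviation (the alternative readings —
variance or display diameter — only reparametrize the same family).
Dimension is fixed at 2: the artifact is a screen drawing.

## Gradients

With Z = Σ o_k over the pair set, ln q_k = ln o_k − ln Z, and since Σp = 1,

    ∂D/∂θ = Σ_k (q_k − p_k) · ∂ ln o_k/∂θ

for any layout parameter θ — the Z term contributes the q weight, which is
how the normalization coupling enters exactly.  The per-pair terms are
∂ln o/∂**r**ᵢ = −(**r**ᵢ−**r**ⱼ)/s_ij and
∂ln o/∂σᵢ = 2σᵢ(d²/(2s²) − 1/s); a self pair contributes −2/σᵢ.  All
gradients are exact and are verified against central finite differences in
the tests (relative error < 1e-5 across random graphs, both squaring
modes).

## Optimization

The loss is minimized by alternating blocks: a *position phase* moves all
**r**ᵢ with widths frozen, a *width phase* the reverse.  The default
schedule is P, W, P, W, P; D typically plateaus by the last phase, and a
longer alternation can be requested when it does not.  Each phase is
full-batch gradient descent with a Barzilai–Borwein (spectral) initial
step, safeguarded by Armijo backtracking, so every accepted step strictly
decreases the loss and each phase's trace is monotone.  A phase stops when
the per-iteration relative decrease falls below `rel_tol` (default 1e-9),
at `max_iter_per_phase` (default 500), or when no decreasing step exists.
A wall-clock `time_limit` is advisory and checked between iterations.

Initialization is seeded-random in the unit square with widths σ₀ = 0.1,
or user-provided coordinates; starting from a force-directed layout
(a bundled Fruchterman–Reingold helper, `networkx.spring_layout`) is
recommended — it shortens the optimization and avoids the occasional
mis-positioned node of a cold start.  Coincident initial positions are
separated by a seeded 1e-6 jitter so zero-distance symmetric
configurations cannot pin the gradient.  Widths are clamped below at
σ_min = 1e-6 × layout diameter (absolute floor 1e-12), with the width
gradient projected at the active floor.  `restarts` reruns the whole
schedule with derived seeds and keeps the lowest D; off by default.

The objective is non-convex; the optimizer is a local method and different
seeds can reach different local minima (the ring-of-cliques benchmark shows
a cold-start minimum about 2.8× above the pre-ordered one).  Each loss or
gradient evaluation costs Θ(n²) pair terms, so desk-scale inputs
(n ≲ 150) run in seconds; no n-body approximation is attempted.

## Scoring foreign layouts

Any fixed set of positions is scored by freezing them and optimizing only
the widths (from σ₀, not from the source tool's node sizes — the
comparison is then self-contained and identical for every tool), reporting
the converged D.  The width phase can only decrease the loss, so this is
the best D attainable for those positions within the model.  Fold
improvement between two layouts is the ratio of their D values on the same
graph and flags.  Module separation — the mean silhouette of node
positions under known module labels — is an auxiliary spatial diagnostic,
not part of the objective.

## Synthetic benchmarks

The planted-partition generator (equal-size stochastic block model:
within-module edge probability p_in, between-module p_out < p_in, unit or
uniform weights, seeded, connectivity enforced by bounded seed retries)
emulates the modular organization of interactomes, where modules play the
role of protein complexes.  The deterministic ring-of-cliques family gives
an exactly known small modular graph.  Benchmark sizes are kept at
n ≤ 150 nodes, matching the Θ(n²) iteration cost; the default comparison
benchmark is 4 modules × 25 nodes, p_in = 0.3, p_out = 0.01.

What these generators do *not* emulate: the heavy-tailed degree
distributions, overlapping complexes, size heterogeneity and thousands of
nodes of real interactomes.  Passing benchmarks here demonstrates the
correctness of the objective, gradients and optimizer and the direction of
the quality ordering (optimized < force-directed < random in D), not the
magnitude of gains achievable on real hairball networks — on small planted
partitions a force-directed layout already separates the modules nearly
optimally, so the measured fold improvements are much smaller than those
attainable on large dense interactomes.

## Numerical choices

* Natural logarithms throughout; D is in nats before normalization.
* 0·ln(0/q) ≡ 0; pairs with p = 0 contribute to D only through Q's
  normalization.
* KL values in (−1e-12, 0) arising from float rounding at exact
  representations are clamped to 0.
* Duplicate input edges merge by summing weights; self-loops are dropped
  (the squared-diagonal option reintroduces diagonal mass explicitly).
* Determinism: all randomness (initial positions, generators, restarts)
  flows from integer seeds through `numpy.random.default_rng`; repeated
  runs are bit-identical.

## Limitations

* Local optimization only; multimodality is real and pre-ordering or
  restarts matter on ring-like topologies.
* Aesthetics (edge crossings, edge lengths) are not optimized and can be
  worse than force-directed drawings, especially in squared mode.
* 3-D layouts, anisotropic node distributions, directed graphs and
  multigraphs are out of scope.
* The exact normalization and self-pair convention of the originating
  plug-in's reported score are not fully documented; absolute D values may
  differ from that tool while orderings and fold ratios remain comparable.
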