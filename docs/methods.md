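# Methods

## The model

`modgen` generates undirected, simple, connected random graphs with three
controlled structural ingredients: a degree distribution, a partition of the
nodes into K modules with prescribed sizes, and a target strength of
community structure measured by Newman modularity

    Q = Σ_k ( e_kk − a_k² ),

where `e_kk` is the fraction of edges with both endpoints in module `C_k`
and `a_k` the fraction of edge endpoints attached to `C_k`.  Q = 0 means
the within-module edge density matches a degree-preserving random graph
(the configuration model); Q approaches `Q_max = 1 − 1/K` when all edges
fall within modules.  Everything else about the graph is made as random as
the constraints allow, so the outputs serve as community-detection
benchmarks (the planted partition is ground truth) and as null models for
empirical networks (matching degrees, K and Q, random in all other
respects).

A target modularity is converted into a mean within-degree through

    E[Q] = Σ_k [ d̄_w · s_k / M − ( d̄ · s_k / M )² ],    M = n · d̄,

whose equal-size form is `E[Q] = d̄_w/d̄ − 1/K` and whose inversion is
`d̄_w = d̄ · (Q + Σ_k (s_k/n)²)`.  `M` is the total degree sum `2|E|`; this
is the only reading under which the equal-size reduction and the Q = 0 and
Q = Q_max limits hold exactly.  Negative targets (disassortative community
structure, fewer within-edges than expected at random) are supported down
to the bound where `d̄_w = 0`.

## Generation pipeline

1. **Module sizes.** Equal sizes (floor with the remainder spread one per
   module), explicit sizes, or rejection-sampled sizes from a distribution,
   always summing exactly to n.  Nodes are assigned to modules in
   contiguous index blocks; since degrees are drawn i.i.d. afterwards, the
   assignment carries no information.
2. **Degrees.** The degree sequence is rejection-sampled from the family
   (zero-truncated Poisson with the mean re-solved, geometric, or a
   discrete power law `k^-α` on `[k_min, n−1]` with α solved numerically
   for the requested mean) until it has no zeros, hits the requested mean
   within a tolerance (default `0.05·d̄`), has an even sum, and passes the
   Erdős–Gallai graphicality criterion.
3. **Within- and between-degrees.** Each node receives a within-degree
   `d_w ≤ d`, with `d_b = d − d_w`.  Within-degrees are drawn i.i.d. from
   the same family with mean `d̄_w`, truncated to `[·, min_k s_k − 1]`
   (a node cannot have more within-neighbours than its module has other
   members), and accepted when the sample mean lies within
   `ε_dw = ε·d̄` of `d̄_w`, the sorted sequence is dominated rank-by-rank
   by the sorted degree sequence (the dominance pairing — largest with
   largest — is also the assignment rule), every module's within-degree
   multiset has an even sum (repaired, if needed, by decrementing one
   random positive entry) and is graphical, and the implied between-degrees
   are realizable (below).
4. **Wiring.** Between-edges are built by a modified Havel–Hakimi pass:
   nodes are prioritized by their module's total residual between-degree,
   then their own residual, and the top node is connected to uniformly
   random eligible partners (different module, not already adjacent, and
   not both within-degree zero unless no other partner remains).  A stall
   triggers the standard relocation repair — an existing between-edge
   (x, y) is replaced by (top, x), (top, y) — before the pass restarts.
   Within-edges use the standard Havel–Hakimi construction per module,
   avoiding partners where both endpoints have between-degree zero (the
   rule is moot in modules without between-edges and is dropped after
   repeated stalls; connectivity is restored explicitly afterwards).  Both
   edge classes are randomized by degree-preserving double-edge swaps —
   (u,v),(x,y) → (u,x),(v,y), rejecting self loops, multi-edges and
   class-violating replacements — with a default of 10 accepted swaps per
   edge.  Finally the graph is made connected by same-class
   cross-component swaps, which change no node's within/between counts;
   per-module connectivity (Taylor-style cross-component rewiring inside a
   module) is available behind `connect_each_module` and off by default.

Because wiring realizes the assigned within/between degrees exactly, the
planted-partition modularity of the finished graph is already determined at
the triples stage: `Q = Σ_k [W_k/(2m) − (S_k/(2m))²]` with `W_k`, `S_k` the
module within-degree and degree sums.  The tolerance `|Q − target| ≤ ε`
(default ε = 0.01) is therefore enforced by rejection on the triples, and
the wired graph's modularity — recomputed independently from the edge
list — equals the accepted value to machine precision.  Retries are tiered
cheapest-first: rewire, then resample within-degrees, then resample the
degree sequence.

## Realizability machinery

* **Erdős–Gallai** decides simple-graph realizability of a degree multiset
  (even sum; for every prefix j, `Σ_{i≤j} d_i ≤ j(j−1) + Σ_{i>j} min(j, d_i)`).
* **Chungphaisan** decides realizability of the coarse module graph H —
  whose nodes are the modules and whose edge multiplicities are the counts
  of between-edges per module pair — as a loopless multigraph with
  multiplicity cap b (even sum; for j = 1..K−1,
  `Σ_{k≤j} d(C_k) − b·j(j−1) ≤ Σ_{k>j} min(jb, d(C_k))`).  The generator
  applies it with `b` equal to the product of the two largest module sizes:
  the number of between-edges a module pair (k, l) can carry in a simple
  graph is at most `s_k·s_l`, so this uniform cap yields a genuinely
  necessary condition.  (A cap equal to the maximum node between-degree is
  *not* necessary — at realistic parameters it rejects configurations the
  wiring stage realizes without difficulty — so it is not used.)
* **Distinct-partner capacity.**  The between-edges restricted to one
  module versus the rest form a bipartite simple graph, so for each module
  and each j the j largest between-degrees inside it must satisfy the
  Gale–Ryser-type bound `Σ_top-j d_b ≤ Σ_{u outside} min(d_b(u), j)`.
  This cheap filter rejects, at the sampling stage, heavy-tailed
  configurations in which a hub demands more distinct foreign partners
  than exist — the dominant cause of wiring stalls otherwise.

## The thinning fallback for within-degrees

Sampling within-degrees i.i.d. from the degree family and demanding sorted
dominance can be *impossible*: dominance of empirical distributions
requires `#{w ≥ t} ≤ #{d ≥ t}` at every t, and when the degree distribution
has a large mass at degree 1 while `d̄_w` is close to `d̄` (strong
communities on heavy-tailed degrees), no i.i.d. draw satisfies it.  In that
regime the generator switches to conditional binomial thinning: each node
draws `d_w ~ Binomial(d, p)` (capped at its module capacity), so dominance
holds per node by construction.  `p` starts at `d̄_w/d̄` and adapts
multiplicatively until the realized mean enters the `ε_dw` window; when
`p → 1` still cannot reach the target mean, the degree sequence itself
cannot carry the requested modularity and is redrawn.  For a Poisson degree
distribution a binomial thinning of a Poisson variable is again Poisson, so
there the fallback is distributionally identical to the primary route.
Module-level Erdős–Gallai violations under thinning (a capped hub next to
thinned near-zero members) are repaired by moving stubs from the largest
within-degree to under-capacity members of the same module, which preserves
the module sum, parity and the global mean.

## Parameters

| parameter | meaning | default |
| --- | --- | --- |
| `epsilon` | tolerance on achieved vs target Q | 0.01 |
| `epsilon_dw` | tolerance on the realized mean within-degree | `epsilon · d̄` |
| `degree_mean_tol` | tolerance on the realized mean degree | `0.05 · d̄` |
| `swaps_per_edge` | accepted double-edge swaps per edge | 10 |
| `connect_each_module` | require each module connected | off |
| `max_attempts` | budget per rejection loop | 1000 |
| `k_min` (power law) | lower end of the power-law support | 1 |

The ε-window on the triples is centred using the *realized* module
degree-sum shares `Σ_k (S_k/2m)²` rather than the size shares
`Σ_k (s_k/n)²`; under heavy-tailed degrees the two differ materially (a
single hub shifts its module's share), and centring on the realized shares
is what makes the rejection step efficient without changing what is
accepted.

One root seed drives every stochastic step through a single
`numpy.random.Generator`, and all writers emit canonically sorted edges, so
identical spec + seed reproduce outputs byte-for-byte.

## Feasibility limits worth knowing

* A target is rejected up front unless
  `−Σ(s_k/n)² ≤ Q < 1 − Σ(s_k/n)²` (for equal sizes, `Q < 1 − 1/K`).
* K = 1 forces Q = 0 exactly (the single-module path sets `d_w = d`,
  `d_b = 0`; this is also the configuration-model null counterpart).
* Heavy-tailed degrees constrain high modularity: a node of degree d in a
  module of size s is forced to carry `d − (s−1)` between-edges, and a
  module dominated by degree-1 leaves cannot absorb large within-degrees
  under Erdős–Gallai.  The discrete power law with mean 5 and support
  starting at 1 has roughly half its mass at degree 1, and no degree draw
  from it supports Q = 0.6 at n = 150, K = 3 — the package's
  Figure-2-style protocol therefore uses `k_min = 2`, which keeps the
  family while making all three settings (Q = 0.1, 0.3, 0.6) feasible.
  Similarly, zeta power laws with α < 2 (mean ≳ 7 on support from 1)
  produce hubs so large that most i.i.d. draws are not graphical at all.
* Small modules (`s̄ < ~50`) and high mean degree compress the feasible
  within-degree range; per the model's own structure this induces degree
  disassortativity and extra clustering at extreme settings.

## What the synthetic benchmarks do and do not show

All tests run on graphs generated by this package at desk scale
(n = 100–1000, ensembles of 10–20 replicates; the structural sweep uses
n = 500, K = 5, d̄ = 10).  They verify the generator's contracts — exact
degree realization, tolerance on Q, simplicity, connectivity, determinism —
and the statistical flatness of assortativity and path length across Q.
Mean local clustering is *not* flat in the strict sense: its baseline is
the configuration-model value ≈ d̄/n while a Q = 0.6 graph concentrates
~60% of neighbour pairs inside modules of density `p_in = d̄_w/(s̄−1)`,
giving a predictable ~2.5× rise at the sweep's scale.  The suite asserts
this band faithfully as specified and the assertion fails for the stated
closed-form reason; the surrounding properties (|mean r| ≤ 0.05, path
length variation < 20%) hold.  Real biological networks differ from these
synthetic ensembles in ways the generator deliberately does not model:
degree–degree correlations, triangle enrichment beyond the modular
byproduct, hierarchical or overlapping communities, and disconnected
empirical components (the metrics fall back to the largest component with
a warning).

## Null-model workflows

`spec_from_network(graph, partition)` extracts (degree sequence, observed
Q, K, mean module size) and returns a spec with equal module sizes and a
within-degree distribution whose mean solves the inversion — the
"class 1" null ensemble.  `preserve_structure=True` keeps the observed
module sizes and the observed within-degree multiset instead ("class 2");
the multiset is re-paired to nodes by the dominance rule, which may require
one parity repair per module, so the realized within multiset can differ
from the observed one by up to K unit decrements.  An observed Q sitting
exactly on the feasibility boundary (all edges within modules) is clipped
to the boundary rather than rejected.
`generate_configuration_counterpart(degrees)` produces the Q-unconstrained
configuration-model null with the same degree sequence.

## Numerical conventions

* Modularity uses exact integer edge counts; `q_max` is computed as
  `(K−1)/K`, which is exact in floating point.
* Clustering defaults to the mean local coefficient with degree-<2 nodes
  contributing 0; global transitivity is available as an option.
* Assortativity is the Pearson correlation over edges counted in both
  orientations; zero degree variance yields NaN with a warning.
* The pair-counting Jaccard index returns 1 with a warning when neither
  partition co-clusters any pair (both all-singletons).
* Variation of information uses natural logarithm (base configurable) and
  clips the tiny negative rounding residue at 0.
* Edges are canonical `(min, max)` pairs; node indices are 0-based on disk,
  module labels 1-based.
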