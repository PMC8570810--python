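# Methods

## Problem setting

A directed protein–protein interaction network is viewed as the structure
of a linear time-invariant system dx/dt = A·x + B·u: the state `x` holds
one value per protein, `A[i][j]` is generically nonzero exactly when the
interaction `j → i` exists (column = interaction source, row = interaction
target — this convention is fixed project-wide), and `B` has one unit
column per *input* (driver) node receiving an external signal. Given a set
`T` of target proteins (e.g. survivability-essential genes) the question
is *target controllability*: can the states of `T` be steered to arbitrary
values? Structurally, this must hold for almost every assignment of
nonzero weights to the edges of `A`, which is equivalent to the rows `T`
of the Kalman matrix `[B, AB, A²B, …, A^{n−1}B]` having generic rank |T|.

Because too few disease-relevant proteins are directly druggable, the
search is biased toward a user-supplied set `S` of preferred
(drug-targetable) sources: solutions are ranked by the lexicographic
objective (|I| ascending, |I ∩ S| descending), where `I` is the input set.

## The control-path certificate (layer condition)

Both solvers return one *control path* per target: a directed walk from an
input node to the target. Index positions from the target backwards — the
target has *backward layer* 0, the input sits at layer m for a walk of
length m. The certificate used throughout the package is:

> no node is occupied by two distinct paths at the same backward layer.

A single input may start several paths only if their lengths all differ
(one physical input can emit a time-varying signal, so reuse at different
layers is what makes single-input chains controllable). The condition is
sufficient for generic target controllability; the package never relies
on that claim silently — every solver output in the test suite is
re-certified by the independent rank oracle below.

Walks (repeated nodes within one path) are allowed: the backward-layer
construction naturally produces them and the condition is layer-based,
not simple-path-based. A target may serve as its own input via a length-0
path (occupying its node at layer 0 only); `allow_self_inputs=False`
forbids this where self-driving is not biologically meaningful.

## Greedy solver

One chain per target, initialized at the target. For each layer
d = 1…L (L = `max_path_length`, default 10): a maximum bipartite matching
is computed between still-active chains and their candidate predecessor
nodes, candidates already occupied at layer d being blocked; matched
chains extend backwards, unmatched chains terminate and designate their
current node as an input. Matching node-uniqueness per layer makes the
layer condition hold by construction. Candidate preference, in order:

1. nodes already designated inputs by terminated chains (reuse shrinks |I|);
2. preferred sources;
3. higher out-degree (hubs can serve more future chains);
4. a per-repeat random tie-break.

The matching itself is Kuhn augmentation scanning candidates in
preference order: always maximum-cardinality, preference respected
greedily through the augmentation order rather than globally optimised.
R independent randomized restarts (default 10) explore alternative
matchings; results are de-duplicated by input set and ranked by the
objective. `p_stop` (default 0) optionally terminates a chain early when
it sits on a preferred source, trading |I| for drug-targetability.

## Genetic solver

A chromosome assigns each target one input node from the target's
backward-reachable ancestors within L. Decoding builds the canonical
shortest walk per gene (lexicographically smallest successor at each
step), counts layer conflicts, and makes one repair pass re-routing
conflicting paths through the gene's next feasible walk length. Fitness
is (conflicts, |I|, −|I ∩ S|), compared lexicographically; infeasible
chromosomes stay in the population graded by conflict count, which keeps
the search space connected. The population (default 100) starts half
random, half seeded from greedy passes, and evolves by tournament
selection (size 3), uniform crossover, per-gene mutation (rate 0.05,
resampling from the ancestor pool) and 10% elitism, stopping after 200
generations or 50 without improvement. All feasible decodes ever seen are
archived, so the returned set is the best-found front, not just the final
population. A target with an empty admissible ancestor pool (possible
only when self-inputs are forbidden) yields an explicit "uncontrollable
under constraints" result rather than an exception.

These hyperparameter defaults are this package's own declared values,
chosen as ordinary mid-range settings for a small combinatorial GA; they
are deliberately conservative rather than tuned per instance.

## Rank oracle

Generic rank is computed exactly over GF(p), p = 2³¹ − 1 by default: edge
weights are drawn uniformly from the nonzero residues, the target rows of
the Kalman matrix are assembled by repeated modular matrix products (a
16-bit hi/lo split keeps every intermediate inside int64), and rank is
obtained by Gaussian elimination mod p. There is no floating-point rank
threshold to tune. By Schwartz–Zippel a single draw underestimates the
generic rank with probability ≤ n²/p; the maximum over 3 independent
draws (default) makes a false negative negligible at the problem sizes
the oracle serves (n ≤ a few dozen). `brute_force_minimum_inputs`
enumerates candidate subsets in increasing size (lexicographic within
size) and is guarded to ≤ 12 nodes.

## Subnetwork generation

Three constructions around a seed set: *neighbors* (any interaction
touching a seed), *direct* (both endpoints seeded), and *gap(k)* for
0 ≤ k ≤ 4 intermediaries, computed by the distance sandwich: keep edge
(u, v) iff d_out(u) + 1 + d_in(v) ≤ k + 1, with d_out/d_in the BFS
distances from/to the nearest seed. The seed-to-seed walk may start and
end at the *same* seed (cycles through one seed qualify) — the sandwich
gives this inclusive reading for free and it is the simplest consistent
semantics. gap(0) coincides exactly with *direct*. Output nodes are
exactly the endpoints of kept edges, so seeds incident to no kept edge
are dropped rather than emitted as isolated nodes. Multiple interaction
files are unioned before generation.

## Synthetic data

The toy fixtures (chain, star, diamond, unequal, cycle) are the named
instances whose optimal driver sets are known in closed form and verified
by the oracle. Random instances come from a directed Erdős–Rényi model
and a preferential-attachment growth model (core of max(2, m) isolated
nodes; each later node sends m edges to distinct nodes sampled ∝
in-degree + 1, hence exactly m·(n − max(2, m)) edges). The PA model
crudely emulates the heavy-tailed degree structure of curated
interactomes; it does not reproduce their motif composition, signed
edges, confidence scores or annotation biases, so passing tests
demonstrate algorithmic correctness and scaling, not biological recall
on any specific interactome. All generators are seed-deterministic.

## Reference study conditions and problem sizes

The validity suite runs both solvers on 100 er(n=20, p=0.1) problems with
5 targets and 3 preferred sources; the minimality suite compares against
exhaustive search on 50 instances with 5–7 nodes and 1–3 targets; the
generation algebra is checked on 30 er(n=30, p=0.07) universes; the
scaling run uses a PA network with 20 000 edges and 50 targets. These
sizes keep exhaustive verification exact where it is used and reflect the
desk-scale regime the library targets.

## Numerical and design choices

* Node identifiers are opaque, case-sensitive, whitespace-stripped
  strings; identifier mapping across HGNC/UniProt/Ensembl conventions is
  the user's responsibility (pre-map before loading).
* All randomness flows through numpy `SeedSequence` spawning, so every
  entry point is bit-reproducible for a fixed seed; solution JSON embeds
  seeds and parameters, sorts keys, and carries no timestamps, making
  repeated runs byte-identical.
* Ties everywhere (matching scan order, walk construction, solution
  ranking) are broken by lexicographic node id after the stated
  preference keys, never by hash order.
* Signed/weighted interaction annotations (e.g. activation vs inhibition
  labels in SIF) are parsed and ignored: structural controllability
  depends only on the zero pattern of `A`.

## Known limitations

* The greedy solver is a heuristic: it guarantees |I| ≤ |T| and a valid
  certificate, not minimality (minimal driver-set selection for target
  controllability is NP-hard); the cycle toy is a case where the GA finds
  a strictly smaller input set.
* The greedy solver ignores `allow_self_inputs`: a chain unmatched at its
  first layer legitimately terminates at the target itself. Use the GA
  when self-inputs must be excluded.
* The rank oracle certifies *generic* controllability; a specific
  weighted system on the same structure may still be uncontrollable on a
  measure-zero weight set.
* gap-k generation treats interactions as strictly directed; undirected
  records must be expanded at read time (`--undirected`).
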