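# Methods

## Model and procedure

NILP detects communities by asynchronous label propagation in which both
the *order* of node updates and the *weight* of each neighbor's vote are
fixed in advance by a local centrality, the α-degree neighborhood impact.

**Impact recursion.** For a node x with strength
s_x = Σ_{i∈Γ₁(x)} λ_ix, the first-order impact is the reciprocal strength
VI_x^(1) = 1/s_x, and each higher order is the weighted mean of the
neighbors' previous order, VI_x^(α) = Σ_i λ_ix · VI_i^(α−1) / s_x. In
operator form this is VI^(α) = T^(α−1) · VI^(1) with T the row-normalized
weighted adjacency matrix (the lazy-free random-walk operator). Three
consequences shape the algorithm's behaviour and are tested as closed
forms:

- on a k-regular unweighted graph, VI ≡ 1/k is a fixed point of T for all α;
- for α ≥ 2 every value lies between the min and max of its neighbors'
  previous-order values (averaging contracts toward local consensus);
- on a connected non-bipartite unweighted graph, VI^(α) → n/2m as α → ∞
  (the stationary average of 1/degree under the random walk), at which
  point the ordering carries no information. α therefore has a useful
  middle range; the default is α = 2, the value that is empirically
  optimal or near-optimal across benchmark families, and the package
  exposes it as a flag.

The implementation performs α−1 rounds of sparse averaging (O(αm + n));
the dense matrix-power form exists only as an independent test oracle,
which the sparse path must match to ≤1e−12 per node.

**Propagation.** Labels are initialized uniquely, nodes are sorted
ascending by impact (densest cores update first), and the order is frozen
for the whole run. One sweep updates every node asynchronously — each vote
sees neighbors' freshest labels — to the label maximizing
Σ_{i∈N(u)} VI_i^(α)·δ(l_i, l). Ties are resolved uniformly at random from
a single seeded stream, consumed in update order, so a (graph, α, seed)
triple determines the run completely. The node's own current label gets no
vote unless a neighbor carries it, and edge weights enter only through the
impacts, not the vote itself; both follow the update rule literally (see
Design choices).

**Stopping and rollback.** After each sweep the stable ratio p = N_c/|V|
is compared with the best previous value: the run continues while p does
not fall, stops immediately at p = 1 (no label moved, so no further sweep
can change anything up to tie re-rolls), and otherwise stops at the first
drop and rolls all labels back to the pre-sweep snapshot — a falling
stable ratio signals that propagation has begun churning rather than
refining. The literal "continue while p₁ ≥ p" rule alone never terminates
once p = 1 holds forever, so the fully-stable early stop and a
`max_rounds` cap (default 100, never reached in practice on the graphs
tested here) are added as loop guards. The trace (per-round ratios, stop
reason, rollback snapshot) is returned and exposed in the CLI's JSON
report.

**LPA baseline.** `run_lpa` is the same engine with all vote weights equal
and the canonical node order; on unweighted regular graphs all impacts
coincide, so NILP degenerates to LPA run-for-run at equal seeds — a
reduction the suite asserts exactly, including the tie-breaking stream.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (`--alpha`) | 2 | impact scope; 1 = reciprocal strength, large α flattens toward n/2m |
| seed (`--seed`) | required | tie-breaking (and generator) stream; no wall-clock default, so every published run is reproducible |
| `--max-rounds` | 100 | hard cap on sweeps; the stable-ratio rule normally stops within ~10 |
| μ (`--mu`) | — | benchmark mixing: expected fraction of a node's edges leaving its community |
| `--kavg` | — | benchmark target mean degree |

## Synthetic benchmark: what it emulates and what it does not

`planted_partition` is a degree-homogeneous planted-partition (stochastic
block) model: within a community of size s_c pairs are linked with
p_in = (1−μ)·k_avg/(s_c−1), across communities with a probability chosen
so the expected inter-degree is μ·k_avg (exact for equal block sizes; for
unequal sizes the cross-block probability averages the two blocks'
1/(n−s) factors, so realized mixing is approximate). Sampling is delegated
to `networkx.stochastic_block_model` and is a deterministic function of
the config, seed included. Infeasible configurations (intra-degree
exceeding community capacity, p_in > 1) fail fast.

This surrogate keeps the one parameter the benchmarks vary — μ — but has
Poisson degrees and fixed community sizes, unlike LFR-style benchmarks
with power-law degree and size distributions. The difference matters for
label propagation: power-law hubs act as label anchors, and without them
all impacts on a homogeneous graph are nearly equal, so the
impact-ordering mechanism loses most of its leverage and epidemic label
merging sets in at lower μ. Concretely, at n = 1000, four blocks of 250,
k_avg = 16, α = 2, mean NMI against ground truth over 10 seeds is ≈1 at
μ = 0.1 and then decays monotonically (≈0.3–0.6 at μ = 0.3, near 0 by
μ = 0.7; independent LPA implementations collapse on the same instances).
Passing tests therefore demonstrate correct mechanics and the qualitative
difficulty curve, not the absolute NMI levels reported for heterogeneous
benchmark graphs or real networks.

Problem sizes in the test suite and acceptance script (n ≤ 1000 for
propagation, n ≤ 100 for the α = 200 limit, n ≤ 50 for oracle
equivalence, 10 seeds per mixing level) were chosen as the smallest at
which each property is cleanly observable.

## Numerical choices

- Impacts are IEEE doubles; the worked-example fractions (1/4, 5/16,
  271/960 for node 7 of the sample network) are asserted against exact
  rational arithmetic and the float path to within 1e−15.
- Vote ties are *exact* float ties. Equal-count ties on unweighted regular
  graphs are exact because each candidate's sum accumulates the same
  float value the same number of times; no epsilon is applied, which
  preserves the NILP→LPA reduction bit-for-bit.
- Node identifiers are opaque strings with one canonical total order
  (numeric-aware when all ids parse as integers, else lexicographic) used
  for update-order tie-breaks, community-id canonicalization, and file
  output, making partition files byte-deterministic.
- NMI is the sum-normalized variant 2I/(H₁+H₂), natural logs, computed
  from the contingency table; 0/0 (both partitions one block) is defined
  as 1, and one-sided zero entropy yields 0 through I = 0. The value is
  clipped to [0, 1] to remove ~1e−16 residue.
- Isolated nodes: the recursion divides by s_x = 0, so they are assigned
  VI = 1, flagged, excluded from averaging, and keep their initial unique
  label (singleton communities).
- Duplicate edges and self-loops are rejected at input rather than
  merged: neither has a defined role in the impact recursion or the vote,
  and rejection surfaces data errors early.

## Design choices where the design was open

- **Impact base case.** Seeding the recursion with VI^(0) = 1 makes every
  first-order value 1 and the ordering vacuous; the base case used here is
  VI^(1) = 1/s_x, which reproduces the worked-example fractions exactly
  and gives the recursion its random-walk reading. Recorded because the
  alternative seed is a plausible mis-design a reimplementer could copy.
- **Asynchronous staleness.** Within a sweep a node sees neighbors'
  already-updated labels (classic asynchronous semantics); the frozen
  order makes this deterministic given the tie stream.
- **Vote weights on weighted graphs.** The update rule weights votes by
  the neighbor's impact only; edge weights influence the result through
  the impacts, not as an extra factor λ_iu in the vote. The literal rule
  is implemented; an additionally λ-weighted vote would be a different
  estimator.
- **Rejected-sweep bookkeeping.** The rollback returns the exact pre-sweep
  mapping (kept as a snapshot), verified in tests by replaying the run one
  round shorter and comparing partitions.

## Known limitations

- Hard (non-overlapping) communities on simple undirected graphs only; no
  directed, bipartite, multigraph, streaming, or dynamic variants.
- Label propagation is order- and tie-sensitive by nature; on homogeneous
  graphs at moderate mixing, runs can collapse to a single community (see
  above). Results should always be reported with their seed.
- The benchmark generator is not an LFR replacement: no power-law degrees,
  no community-size heterogeneity, no overlapping memberships.
- `nmi` is the partition-level diagnostic; no modularity or overlapping
  NMI variants are provided.
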