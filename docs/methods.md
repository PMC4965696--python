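# Methods

## The module-cover model

Given an undirected interaction network G(V, E) over gene identifiers and a
binary indicator matrix (genes × cases, 1 = "active case", e.g. the gene is
differentially expressed in that sample), the goal of de novo pathway
enrichment in the module-cover family is to extract maximal connected
subnetworks whose genes are active across as many cases as possible. A
gene's *case exceptions* are the cases in which it is inactive (the zeros
of its row); a gene with no row in the matrix is treated as inactive in
every case. Two exception models are implemented:

* **INES** (Individual Node ExceptionS). A gene is *active* when it has at
  most L case exceptions. A feasible solution is a connected node set in
  which every gene is active, except for up to K *exception nodes* that may
  be included to bridge active regions. INES tends to absorb hub nodes,
  which connect many active genes cheaply.
* **GLONE** (GLobal Node Exceptions). No per-gene constraint; instead the
  *sum* of case exceptions over all solution genes must not exceed a single
  global budget L. Because a hub with many inactive cases is expensive,
  GLONE selects fewer hubs. Note the global budget may legitimately exceed
  the case count, since it is summed over genes.

Solution size is node count; ranked lists are ordered by size descending
with ties broken by the lexicographically smallest sorted node-id tuple, a
convention applied uniformly so every run is reproducible.

### L as a percentage

L may be given as an absolute count or as a percentage of the number of
cases, which lets a single setting serve several datasets with different
case counts. A percentage resolves by ceiling: L = 20% of 38 cases allows
⌈7.6⌉ = 8 exceptions. The product is rounded to 9 decimals before the
ceiling so exact fractions (20% of 35 = 7) are not pushed up by binary
float noise. An absolute L larger than the case count is capped at the
case count with a warning.

### Combining datasets

Multiple indicator matrices combine case-wise through a boolean formula
over dataset ids (grammar: `id`, `AND`, `OR`, parentheses; AND binds
tighter than OR; no negation). Under AND a case is active only if active
in every dataset; under OR in any. Only case-aligned matrices (identical
case counts) can be combined; the gene universe is the union of gene ids
and a gene missing from one dataset contributes an all-zero row there, so
AND is conservative. A p-value matrix converts to an indicator matrix by a
strict threshold: entry 1 iff p < cutoff (a p exactly at the cutoff is not
significant).

Positive-list genes are pinned to zero case exceptions (always active);
negative-list genes are deleted from the network together with their
incident edges before any analysis.

## Extraction algorithms

**Greedy (default).** From every individually feasible seed node the
solution grows by repeatedly adding the feasibility-preserving neighbor
that is (1) active, then (2) adjacent to the most active genes outside the
current solution, then (3) smallest by id; growth stops when no feasible
neighbor remains. The node sets from all seeds are deduplicated, validated
and ranked. The expansion rule is this package's own design: it is simple,
fully deterministic, and is validated against the exact optimum rather
than against any particular published search heuristic.

**Exact (small instances).** All connected induced subgraphs are
enumerated by rooted growth with an exclusion set (each subgraph is
visited exactly once from its smallest member), pruning any branch whose
exception budget is already exceeded — both budgets are monotone in the
node set, so pruning is safe. The maximum-cardinality feasible subgraph is
returned. The enumeration is exponential and therefore refuses networks
above `node_limit` (default 15 nodes); its role is to serve as an optimality
oracle for the greedy search on small instances, and the test suite checks
it against a second, independent brute-force subset enumeration.

**Border exception node (BEN) filter.** With a generous K, exception nodes
are often appended at the periphery of a solution merely to grow it,
producing near-duplicate top solutions. The filter repeatedly pops a
random node v from the exception set V_e: connected components of the
solution minus v consisting solely of still-unpopped exception nodes are
discarded, and v itself is discarded when exactly one remaining component
contains a non-exception node (its removal then cannot disconnect active
regions); the loop ends when V_e is exhausted. Non-exception nodes are
always retained, connectivity is preserved, and the output is a fixpoint
under re-application. Which *exception* nodes survive can in principle
depend on the pop order, so the order is driven by an explicit seed; the
exhaustive small-graph test suite checks the guarantees across pop orders.

## Network perturbation

Four strategies emulate network noise and incompleteness, each with a
perturbation level in percent that maps to an item count by round-half-up:

| strategy | affected items | preserves |
|---|---|---|
| node label permutation | level% of nodes relabeled among themselves | topology and label multiset |
| degree-preserving rewiring | level% of edges replaced by endpoint swaps | every node's degree |
| node removal | level% of nodes deleted | — |
| edge removal | level% of edges deleted | node set |

The percentage→count semantics per strategy are a declared convention of
this package. Rewiring follows the Maslov–Sneppen convention: candidate
swaps creating self-loops or duplicate edges are rejected, and the run
counts *replaced edges* (each successful swap replaces two; re-swapped
edges are not double-counted) so levels are comparable across strategies.
After 100 × target unsuccessful attempts the run stops with a warning —
some graphs, e.g. stars, admit no valid swap at all. Label permutation
redraws the permutation if the identity comes up while at least two labels
should move. All strategies are deterministic given their seed.

## Robustness and validation analyses

Robustness of a result is the Jaccard similarity
J(S_perturbed, S_unperturbed) = |∩| / |∪| between the gene sets of the
largest solution on a perturbed network and on the original network;
validation replaces the unperturbed solution with a user-supplied
gold-standard gene set. For each requested level, `n_per_level` (default
10) independently perturbed replicate networks are analyzed with identical
extraction settings; per-level mean, standard deviation (sample sd; a
single value has sd 0), median, min and max are reported, with an optional
box plot.

Conventions: gold comparison uses all genes of a solution including its
exception nodes (a disease gene recovered as an exception node is a
success); J of two empty sets is 1.0 (equal sets, logged), empty vs
non-empty is 0. Indicator matrices are never relabeled under node-label
permutation: activity follows the gene label to its new topological
position, which is exactly the signal-scrambling the strategy is meant to
produce. A replicate whose extraction fails is recorded as an empty
solution rather than aborting the batch.

Replicate seeds derive from a SHA-256 hash of (master seed, strategy,
level, replicate index), truncated below 2^31, so extending the level grid
never shifts the random streams of existing replicates, and a manifest
(all parameters, input checksums, derived seeds) makes every run
bit-identically replayable via `--config manifest.json`.

## Synthetic planted-module instances

Because real interactomes and expression matrices are large external
downloads, the package ships a generator whose output exercises every
pipeline stage with a known ground truth. The background is a
Barabási–Albert preferential-attachment graph (interaction networks are
approximately scale-free; attachment parameter default 2 edges per new
node, giving a sparse hub-dominated topology). A connected module of
`module_size` nodes is chosen by breadth-first growth from a random root;
matrix entries are independent Bernoulli draws: a module gene is active in
a case with probability `p_active_in_module`, any other gene with
`p_active_background`. The module node set is the gold standard.

Defaults — 100 nodes, module of 10, 40 cases, 0.95 vs 0.05 — put a module
gene at ~2 expected exceptions out of 40 (comfortably inside an L = 20%
allowance of 8) while a background gene at ~38 exceptions essentially
never qualifies: a strong but noisy signal at desk scale. What the
generator does *not* emulate: correlated expression between interacting
genes, case-to-case correlation structure, multiple or overlapping
modules, and measured-gene coverage gaps; passing tests therefore
demonstrate algorithmic correctness and reproducibility, not recovery
performance on real omics data.

With these defaults and INES K = 2, L = 20%, the largest solution is the
planted module plus the two budgeted exception nodes (Jaccard 10/12 ≈
0.83 with the gold set; 1.0 after BEN filtering), and the mean robustness
Jaccard under edge removal decays with the perturbation level — the
qualitative behavior expected of a module-cover method on a scale-free
network, rehearsed at a size where the whole suite runs in seconds.

## Numerical and degenerate-input choices

* Self-loops are dropped on input (with a warning; the node is kept);
  duplicate edges collapse. Edge direction is ignored throughout.
* Header detection for indicator files: the first row is a header iff any
  field after the first is not `0`/`1`.
* Empty solution lists yield an empty pathway whose Jaccard against any
  non-empty set is 0.
* `exact_extract` on a network with no feasible node returns the empty
  pathway; `greedy_extract` returns an empty list.
* All randomness (perturbation, BEN pop order, generators) flows through
  explicit integer seeds; there is no hidden global RNG state.

## Known limitations

* Dataset combination requires case-aligned matrices; per-dataset L with
  unequal case counts is not supported.
* The exact extractor is exponential and intentionally capped at 15 nodes.
* No ant-colony or fixed-parameter-tractable search; the greedy search is
  the production algorithm and carries no optimality guarantee (the test
  suite only bounds it by the exact optimum on small instances).
* Robustness curves are descriptive; no significance testing is attempted.
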