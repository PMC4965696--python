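# modulecover

De novo pathway enrichment by **module cover**: given a biological
interaction network and one or more binary indicator matrices (genes ×
cases, 1 = the gene is "active" in that sample, e.g. differentially
expressed), extract maximal connected subnetworks enriched for active
genes — without restriction to annotated pathways — and quantify how
**robust** those subnetworks are when the underlying network is perturbed.

It is aimed at computational biologists analysing omics case/control
profiles on protein–protein interaction networks who need (a) interpretable
extraction parameters, (b) an answer to "will my result survive the next
interactome release?", and (c) a gold-standard quality score.

## Model

A gene's *case exceptions* are the cases where its matrix row is 0. Two
solution models define a feasible connected subnetwork S ⊆ V:

* **INES** — every gene in S has ≤ L case exceptions, except for up to K
  *exception nodes* (inactive genes bridging active regions);
* **GLONE** — Σ_{g∈S} exceptions(g) ≤ L, a single global budget that
  penalizes hub nodes.

L may be a count or a percentage of cases (ceiling). Robustness of a result
is the Jaccard overlap of the largest solutions found on perturbed and
unperturbed networks,

    J(S_perturbed, S_unperturbed) = |S_p ∩ S_u| / |S_p ∪ S_u|,

computed over replicate networks per perturbation level for four
strategies: node-label permutation, degree-preserving (Maslov–Sneppen)
rewiring, node removal, edge removal. With a gold-standard gene set,
J(S, S_gold) scores quality instead. Solutions can additionally be pruned
of *border exception nodes* — exception nodes at the solution periphery
whose removal disconnects no active region. See `docs/methods.md` for the
full account.

## Worked example

Generate a synthetic benchmark — a scale-free network with a planted
10-gene active module and a 40-case indicator matrix — then extract and
run a robustness analysis:

```sh
modulecover synth --seed 7 --out demo
modulecover extract --network demo/network.sif --matrix SYN=demo/matrix.tsv \
    --strategy INES -K 2 -L 20% --out demo/run
modulecover robustness --network demo/network.sif --matrix SYN=demo/matrix.tsv \
    --strategy INES -K 2 -L 20% --perturb edgeremove \
    --levels 10:50:10 --replicates 10 --seed 7 --out demo/rob
```

`demo/run/solutions.tsv` begins

```
rank	size	n_exception_nodes	total_case_exceptions	nodes_file
1	12	2	88	solution_001.txt
```

— the top solution has 12 genes: the 10 planted module genes plus the K = 2
exception nodes the budget allows (Jaccard 10/12 ≈ 0.83 with the planted
gold set; the BEN filter, `--ben-filter`, trims the two border exceptions).
`demo/rob/summary.tsv` reports the per-level overlap with the unperturbed
solution:

```
level	n	mean	sd	median	min	max
10	10	0.923077	0.081084	0.923077	0.846154	1.000000
20	10	0.773626	0.111460	0.741758	0.642857	1.000000
30	10	0.628022	0.122260	0.615385	0.428571	0.846154
40	10	0.563462	0.149514	0.538462	0.285714	0.769231
50	10	0.443407	0.146384	0.406593	0.285714	0.692308
```

The mean overlap decays as more edges are removed — the result is robust
to mild network incompleteness and degrades gracefully. Every run writes a
`manifest.json` (parameters, input checksums, derived seeds); re-running
with `--config manifest.json` reproduces the output byte for byte. A
two-matrix example (up-/down-regulation combined with an `OR` formula) is
in `examples/updown_demo.py`. The library API mirrors the CLI
(`modulecover.run_extraction`, `robustness_analysis`,
`validation_analysis`, ...).

Other useful flags: `--formula "UP OR DOWN"` to combine matrices,
`--strategy GLONE`, `--algorithm exact` (≤15-node oracle),
`-K 0:5:1` / `-L 10%:30%:10%` for batch grids, `--positive-list` /
`--negative-list`, `--gold` with the `validate` subcommand, and
`--perturb {labelswap,rewire,noderemove,edgeremove}`.

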