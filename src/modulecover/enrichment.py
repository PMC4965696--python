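"""Module-cover pathway extraction: activity, INES/GLONE models, extractors.

A gene is *active* when its indicator-matrix row contains a 1 in all but at
most L cases (its *case exceptions* are the 0 entries).  Two solution models
are supported:

INES (Individual Node ExceptionS)
    Each node must individually be active under L; up to K additional
    inactive *exception nodes* may be included to bridge active regions.

GLONE (GLobal Node Exceptions)
    A single budget L on the total number of case exceptions summed over
    all solution genes; K is ignored.  This penalizes hub nodes with many
    inactive cases.

A solution ("pathway") is a connected induced subnetwork satisfying its
model's constraint.  Extraction is greedy (seed-and-grow from every node)
or exact (connected-subgraph enumeration, small instances only).  The
optional border-exception-node (BEN) filter prunes exception nodes hanging
off the periphery of a solution that do not bridge active regions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .datasets import DatasetCollection, IndicatorMatrix, LSpec, combine_datasets, resolve_l
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

INES = "INES"
GLONE = "GLONE"


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of an extraction run.

    ``k`` is the exception-node budget (INES only; ignored under GLONE).
    ``l_spec`` is the case-exception allowance, absolute or percent.
    """

    strategy: str = INES
    algorithm: str = "greedy"
    k: int = 0
    l_spec: LSpec = field(default_factory=lambda: LSpec("absolute", 0))
    ben_filter: bool = False
    max_solutions: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in (INES, GLONE):
            raise ValueError(f"strategy must be INES or GLONE, got {self.strategy!r}")
        if self.algorithm not in ("greedy", "exact"):
            raise ValueError(f"algorithm must be greedy or exact, got {self.algorithm!r}")
        if self.k < 0:
            raise ValueError("K must be ≥ 0")
        if self.max_solutions < 1:
            raise ValueError("max_solutions must be ≥ 1")


class ActivityProfile:
    """Per-gene case-exception counts and active flags under a resolved L.

    A gene's exception count is its number of inactive (0) cases; genes
    absent from the matrix (network nodes without measurements) count as
    inactive in every case.  Positive-list genes are pinned to zero
    exceptions, hence always active.
    """

    __slots__ = ("_exceptions", "n_cases", "l", "positive")

    def __init__(
        self,
        exceptions: Mapping[str, int],
        n_cases: int,
        l: int,
        positive: frozenset[str] = frozenset(),
    ):
        # l may exceed n_cases: under GLONE it budgets the *sum* of
        # exception counts over all solution genes.
        self._exceptions = dict(exceptions)
        self.n_cases = n_cases
        self.l = l
        self.positive = positive
        for g in positive:
            self._exceptions[g] = 0

    def exception_count(self, gene: str) -> int:
        return self._exceptions.get(gene, self.n_cases)

    def is_active(self, gene: str) -> bool:
        return self.exception_count(gene) <= self.l

    def active_nodes(self, nodes: Iterable[str]) -> frozenset[str]:
        return frozenset(g for g in nodes if self.is_active(g))


def compute_activity(
    matrix: IndicatorMatrix, l: int, positive: Iterable[str] = ()
) -> ActivityProfile:
    """Count case exceptions per gene and flag activity under resolved *l*."""
    if l > matrix.n_cases:
        raise ValueError(f"l = {l} exceeds the matrix's {matrix.n_cases} cases")
    zeros = (matrix.values == 0).sum(axis=1)
    exceptions = {str(g): int(c) for g, c in zeros.items()}
    return ActivityProfile(exceptions, matrix.n_cases, l, frozenset(positive))


@dataclass(frozen=True, order=False)
class Pathway:
    """A connected extracted subnetwork.

    ``exception_nodes`` are the member genes that are individually inactive
    (the V_e of the INES model); ``node_exceptions`` carries each member's
    case-exception count so the GLONE budget survives filtering.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    exception_nodes: frozenset[str]
    node_exceptions: tuple[tuple[str, int], ...] = ()

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def total_case_exceptions(self) -> int:
        return sum(c for _, c in self.node_exceptions)

    def sort_key(self) -> tuple:
        # larger first, then lexicographically smallest node tuple
        return (-self.size, tuple(sorted(self.nodes)))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        return nx.is_connected(self.to_graph())


EMPTY_PATHWAY = Pathway(frozenset(), frozenset(), frozenset(), ())


def make_pathway(
    network: InteractionNetwork, nodes: Iterable[str], activity: ActivityProfile
) -> Pathway:
    nodeset = frozenset(nodes)
    sub = network.induced_subgraph(nodeset)
    edges = frozenset(tuple(sorted(e)) for e in sub.edges())
    exceptions = frozenset(g for g in nodeset if not activity.is_active(g))
    counts = tuple(sorted((g, activity.exception_count(g)) for g in nodeset))
    return Pathway(nodeset, edges, exceptions, counts)


def is_valid_solution(
    p: Pathway, config: ExtractionConfig, activity: ActivityProfile
) -> bool:
    """Feasibility test: connected, and within the model's exception budget."""
    if not p.nodes:
        return False
    if not p.is_connected():
        return False
    if config.strategy == INES:
        return len(p.exception_nodes) <= config.k
    return p.total_case_exceptions <= activity.l


# ---------------------------------------------------------------------------
# greedy extraction


def greedy_extract(
    network: InteractionNetwork,
    activity: ActivityProfile,
    config: ExtractionConfig,
) -> list[Pathway]:
    """Seed-and-grow greedy search for maximal valid solutions.

    Seeds from every individually feasible node; repeatedly adds the
    feasibility-preserving neighbor that is (1) active, (2) adjacent to the
    most active nodes outside the current solution, (3) smallest by id.
    Duplicate node sets collapse; results are ranked by size descending with
    lexicographic tie-break, at most ``max_solutions`` returned.
    """
    g = network.graph
    ines = config.strategy == INES
    budget_l = activity.l

    def n_new_active_neighbors(cand: str, current: set[str]) -> int:
        return sum(
            1 for nb in g.neighbors(cand) if nb not in current and activity.is_active(nb)
        )

    found: set[frozenset[str]] = set()
    for seed in sorted(g.nodes()):
        seed_active = activity.is_active(seed)
        if ines:
            if not seed_active and config.k < 1:
                continue
            inactive = 0 if seed_active else 1
        else:
            if activity.exception_count(seed) > budget_l:
                continue
            total_exc = activity.exception_count(seed)
        current: set[str] = {seed}
        frontier: set[str] = set(g.neighbors(seed))
        while True:
            best = None
            best_key = None
            for cand in frontier:
                cand_active = activity.is_active(cand)
                if ines:
                    if not cand_active and inactive + 1 > config.k:
                        continue
                else:
                    if total_exc + activity.exception_count(cand) > budget_l:
                        continue
                key = (not cand_active, -n_new_active_neighbors(cand, current), cand)
                if best_key is None or key < best_key:
                    best, best_key = cand, key
            if best is None:
                break
            current.add(best)
            if ines:
                if not activity.is_active(best):
                    inactive += 1
            else:
                total_exc += activity.exception_count(best)
            frontier.discard(best)
            frontier.update(nb for nb in g.neighbors(best) if nb not in current)
        found.add(frozenset(current))

    pathways = [make_pathway(network, nodes, activity) for nodes in found]
    pathways = [p for p in pathways if is_valid_solution(p, config, activity)]
    pathways.sort(key=Pathway.sort_key)
    pathways = pathways[: config.max_solutions]
    if config.ben_filter and config.strategy == INES:
        pathways = _apply_ben_filter(network, pathways, activity, config.seed)
    return pathways


def _apply_ben_filter(
    network: InteractionNetwork,
    pathways: list[Pathway],
    activity: ActivityProfile,
    seed: int,
) -> list[Pathway]:
    filtered = [remove_border_exception_nodes(p, rng_seed=seed) for p in pathways]
    dedup: dict[frozenset[str], Pathway] = {}
    for p in filtered:
        dedup.setdefault(p.nodes, p)
    out = list(dedup.values())
    out.sort(key=Pathway.sort_key)
    return out


# ---------------------------------------------------------------------------
# exact extraction (small-instance oracle)


def exact_extract(
    network: InteractionNetwork,
    activity: ActivityProfile,
    config: ExtractionConfig,
    node_limit: int = 15,
) -> Pathway:
    """Exhaustive maximum-cardinality valid solution on a small network.

    Enumerates all connected induced subgraphs by rooted growth with an
    exclusion set (each subgraph visited once from its smallest root),
    pruning branches whose exception budget is already exceeded — both
    budgets are monotone in the node set.  Raises on networks larger than
    ``node_limit``.
    """
    if network.n_nodes > node_limit:
        raise ValueError(
            f"exact extraction limited to {node_limit} nodes "
            f"(network has {network.n_nodes}); use the greedy algorithm"
        )
    g = network.graph
    ines = config.strategy == INES

    def cost(node: str) -> int:
        if ines:
            return 0 if activity.is_active(node) else 1
        return activity.exception_count(node)

    budget = config.k if ines else activity.l
    best: tuple[int, tuple[str, ...]] | None = None

    def consider(nodes: frozenset[str]) -> None:
        nonlocal best
        key = (-len(nodes), tuple(sorted(nodes)))
        if best is None or key < best:
            best = key

    order = sorted(g.nodes())
    for i, root in enumerate(order):
        root_cost = cost(root)
        if root_cost > budget:
            continue
        excluded = set(order[:i])

        def grow(current: set[str], frontier: list[str], spent: int, banned: set[str]):
            consider(frozenset(current))
            for j, cand in enumerate(frontier):
                c = cost(cand)
                if spent + c > budget:
                    continue
                new_banned = banned | set(frontier[:j])
                new_frontier = [f for f in frontier[j + 1 :]]
                for nb in g.neighbors(cand):
                    if nb not in current and nb != cand and nb not in new_banned and nb not in excluded and nb not in new_frontier:
                        new_frontier.append(nb)
                current.add(cand)
                grow(current, new_frontier, spent + c, new_banned)
                current.remove(cand)

        frontier0 = sorted(nb for nb in g.neighbors(root) if nb not in excluded)
        grow({root}, frontier0, root_cost, set())

    if best is None:
        return EMPTY_PATHWAY
    return make_pathway(network, best[1], activity)


# ---------------------------------------------------------------------------
# border exception node (BEN) filter


def remove_border_exception_nodes(p: Pathway, rng_seed: int = 0) -> Pathway:
    """Prune border exception nodes from a solution.

    Repeatedly pops a random node v from the exception set; connected
    components of the solution minus v consisting solely of (remaining)
    exception nodes are discarded, and v itself is discarded when exactly
    one component contains a non-exception node (removing v then cannot
    disconnect active regions).  All non-exception nodes are retained and
    the result stays connected.  The retained exception nodes may depend on
    the pop order, hence the explicit seed.
    """
    g = p.to_graph()
    ve = set(p.exception_nodes)
    rng = random.Random(rng_seed)
    while ve:
        v = rng.choice(sorted(ve))
        ve.discard(v)
        vben: set[str] = set()
        gtemp = g.subgraph(set(g.nodes()) - {v})
        s = 0
        for comp in nx.connected_components(gtemp):
            if comp <= ve:
                vben |= comp
            else:
                s += 1
        if s == 1:
            vben.add(v)
        ve -= vben
        g.remove_nodes_from(vben)
    nodes = frozenset(g.nodes())
    edges = frozenset(tuple(sorted(e)) for e in g.edges())
    exceptions = p.exception_nodes & nodes
    counts = tuple((n, c) for n, c in p.node_exceptions if n in nodes)
    return Pathway(nodes, edges, exceptions, counts)


# ---------------------------------------------------------------------------
# pipeline


def run_extraction(
    network: InteractionNetwork,
    collection: DatasetCollection,
    config: ExtractionConfig,
    positive: Iterable[str] = (),
) -> list[Pathway]:
    """End-to-end extraction: combine datasets, resolve L, compute activity,
    extract with the configured algorithm, optionally BEN-filter."""
    combined = combine_datasets(collection)
    l = resolve_l(config.l_spec, combined.n_cases)
    activity = compute_activity(combined, l, positive)
    if config.algorithm == "exact":
        best = exact_extract(network, activity, config)
        solutions = [best] if best.nodes else []
        if config.ben_filter and config.strategy == INES:
            solutions = _apply_ben_filter(network, solutions, activity, config.seed)
        return solutions
    return greedy_extract(network, activity, config)


def write_solutions(
    pathways: list[Pathway], outdir, graphml: bool = False
) -> "Path":
    """Write a solution index TSV plus one node-list file per solution.

    The index records rank, size, exception-node count and total case
    exceptions.  With ``graphml=True``, the union subnetwork of all
    solutions is also exported with an ``is_exception`` node attribute for
    Cytoscape-style inspection.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = outdir / "solutions.tsv"
    with open(index, "w") as fh:
        fh.write("rank\tsize\tn_exception_nodes\ttotal_case_exceptions\tnodes_file\n")
        for rank, p in enumerate(pathways, start=1):
            nodes_file = f"solution_{rank:03d}.txt"
            fh.write(
                f"{rank}\t{p.size}\t{len(p.exception_nodes)}\t"
                f"{p.total_case_exceptions}\t{nodes_file}\n"
            )
            with open(outdir / nodes_file, "w") as nf:
                for node in sorted(p.nodes):
                    marker = "\texception" if node in p.exception_nodes else ""
                    nf.write(f"{node}{marker}\n")
    if graphml and pathways:
        union = nx.Graph()
        exceptions = set()
        for p in pathways:
            union.add_nodes_from(p.nodes)
            union.add_edges_from(p.edges)
            exceptions |= p.exception_nodes
        nx.set_node_attributes(
            union, {n: (n in exceptions) for n in union.nodes()}, "is_exception"
        )
        nx.write_graphml(union, outdir / "solutions_union.graphml")
    return index
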