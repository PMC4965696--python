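"""Network perturbation strategies for robustness analysis.

Four common randomization strategies, each parameterized by a perturbation
level in percent:

* node label permutation — swaps gene labels among a random subset of
  nodes; topology is untouched, but active genes land in new positions,
* degree-preserving rewiring — Maslov–Sneppen endpoint swaps that keep
  every node's degree exactly, randomizing local structure,
* node removal — deletes a fraction of nodes with incident edges,
  emulating a less complete interactome,
* edge removal — deletes a fraction of edges, thinning network density.

The level maps to a count of affected items (nodes relabeled, edges
replaced, nodes removed, edges removed) by round-half-up of
level/100 × count.  All strategies are fully seed-deterministic.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

STRATEGIES = ("label_permutation", "rewire", "node_removal", "edge_removal")


@dataclass(frozen=True)
class PerturbedNetwork:
    """A perturbed copy of a network with its provenance."""

    network: InteractionNetwork
    strategy: str
    level: float
    seed: int


def _check_level(level: float) -> None:
    if not 0 <= level <= 100:
        raise ValueError(f"perturbation level must be in [0, 100], got {level}")


def _count(level: float, total: int) -> int:
    """Round-half-up of level percent of total."""
    return int(math.floor(level / 100.0 * total + 0.5))


def permute_node_labels(
    net: InteractionNetwork, level: float, rng_seed: int
) -> PerturbedNetwork:
    """Randomly permute the labels of a ``level``-percent subset of nodes.

    The edge structure as an unlabeled graph and the label multiset are
    unchanged; the identity permutation is rejected when at least two
    labels are to move.
    """
    _check_level(level)
    rng = random.Random(rng_seed)
    nodes = sorted(net.node_ids)
    m = _count(level, len(nodes))
    out = net.copy()
    if level == 0 or m < 2:
        return PerturbedNetwork(out, "label_permutation", level, rng_seed)
    chosen = rng.sample(nodes, m)
    shuffled = list(chosen)
    while True:
        rng.shuffle(shuffled)
        if any(a != b for a, b in zip(chosen, shuffled)):
            break
    mapping = dict(zip(chosen, shuffled))
    relabeled = InteractionNetwork()
    relabeled.graph.add_nodes_from(mapping.get(n, n) for n in out.graph.nodes())
    relabeled.graph.add_edges_from(
        (mapping.get(u, u), mapping.get(v, v)) for u, v in out.graph.edges()
    )
    return PerturbedNetwork(relabeled, "label_permutation", level, rng_seed)


def rewire_degree_preserving(
    net: InteractionNetwork, level: float, rng_seed: int
) -> PerturbedNetwork:
    """Maslov–Sneppen rewiring of a ``level``-percent fraction of edges.

    Repeats endpoint swaps of two random edges — rejecting swaps that would
    create self-loops or duplicate edges — until the target number of edges
    has been replaced (each successful swap replaces two; already-rewired
    edges are not recounted).  Every node's degree is preserved exactly.
    Gives up with a warning after 100 × target attempts, which happens on
    graphs admitting no valid swap (e.g. stars).
    """
    _check_level(level)
    rng = random.Random(rng_seed)
    out = net.copy()
    target = _count(level, net.n_edges)
    if level == 0 or target == 0 or net.n_edges < 2:
        return PerturbedNetwork(out, "rewire", level, rng_seed)
    g = out.graph
    edges = [tuple(sorted(e)) for e in g.edges()]
    edges.sort()
    rewired: set[tuple[str, str]] = set()
    n_rewired = 0
    attempts = 0
    max_attempts = 100 * target
    while n_rewired < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.sample(range(len(edges)), 2)
        (a, b), (c, d) = edges[i], edges[j]
        if rng.random() < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        new1, new2 = tuple(sorted(new1)), tuple(sorted(new2))
        if new1[0] == new1[1] or new2[0] == new2[1] or new1 == new2:
            continue
        if g.has_edge(*new1) or g.has_edge(*new2):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(*new1)
        g.add_edge(*new2)
        for old, new in ((edges[i], new1), (edges[j], new2)):
            rewired.discard(old)
        edges[i], edges[j] = new1, new2
        rewired.add(new1)
        rewired.add(new2)
        n_rewired = len(rewired)
    if n_rewired < target:
        logger.warning(
            "rewiring stopped after %d attempts with %d/%d edges replaced",
            attempts,
            n_rewired,
            target,
        )
    return PerturbedNetwork(out, "rewire", level, rng_seed)


def remove_nodes(
    net: InteractionNetwork, level: float, rng_seed: int
) -> PerturbedNetwork:
    """Delete a uniform ``level``-percent sample of nodes with their edges."""
    _check_level(level)
    rng = random.Random(rng_seed)
    nodes = sorted(net.node_ids)
    m = _count(level, len(nodes))
    out = net.copy()
    if m:
        out.graph.remove_nodes_from(rng.sample(nodes, m))
    return PerturbedNetwork(out, "node_removal", level, rng_seed)


def remove_edges(
    net: InteractionNetwork, level: float, rng_seed: int
) -> PerturbedNetwork:
    """Delete a uniform ``level``-percent sample of edges; nodes are kept."""
    _check_level(level)
    rng = random.Random(rng_seed)
    edges = sorted(tuple(sorted(e)) for e in net.graph.edges())
    m = _count(level, len(edges))
    out = net.copy()
    if m:
        out.graph.remove_edges_from(rng.sample(edges, m))
    return PerturbedNetwork(out, "edge_removal", level, rng_seed)


_DISPATCH = {
    "label_permutation": permute_node_labels,
    "rewire": rewire_degree_preserving,
    "node_removal": remove_nodes,
    "edge_removal": remove_edges,
}


def perturb(
    net: InteractionNetwork, strategy: str, level: float, rng_seed: int
) -> PerturbedNetwork:
    """Apply the named perturbation strategy."""
    try:
        fn = _DISPATCH[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        ) from None
    return fn(net, level, rng_seed)
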