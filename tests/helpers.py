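"""Independent brute-force oracles used to cross-check the extractors.

These deliberately share no code path with the package's enumeration: the
optimum is found by iterating over ALL node subsets as bitmasks, checking
connectivity by bitmask BFS, and charging budgets directly.
"""

from __future__ import annotations

import random

import networkx as nx

from modulecover import ActivityProfile, InteractionNetwork


def bitmask_connected(mask: int, adj: list[int]) -> bool:
    start = mask & -mask  # lowest set bit
    reach = start
    while True:
        grow = reach
        m = reach
        while m:
            bit = m & -m
            grow |= adj[bit.bit_length() - 1] & mask
            m ^= bit
        if grow == reach:
            return reach == mask
        reach = grow


def naive_optimum(
    network: InteractionNetwork,
    activity: ActivityProfile,
    strategy: str,
    budget: int,
) -> int:
    """Maximum size of a connected subset within the exception budget,
    found by full subset enumeration (networks ≤ ~15 nodes)."""
    nodes = sorted(network.node_ids)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in network.graph.edges():
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    if strategy == "INES":
        cost = [0 if activity.is_active(v) else 1 for v in nodes]
    else:
        cost = [activity.exception_count(v) for v in nodes]
    best = 0
    for mask in range(1, 1 << n):
        size = mask.bit_count()
        if size <= best:
            continue
        spent = 0
        m = mask
        ok = True
        while m:
            bit = m & -m
            spent += cost[bit.bit_length() - 1]
            if spent > budget:
                ok = False
                break
            m ^= bit
        if ok and bitmask_connected(mask, adj):
            best = size
    return best


def random_connected_graph(rng: random.Random, max_nodes: int = 10) -> InteractionNetwork:
    """A random connected labeled graph with 2..max_nodes nodes."""
    n = rng.randint(2, max_nodes)
    while True:
        g = nx.gnp_random_graph(n, rng.uniform(0.25, 0.7), seed=rng.randrange(2**31))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
    return InteractionNetwork(g)


def random_activity(
    rng: random.Random, network: InteractionNetwork, n_cases: int, l: int
) -> ActivityProfile:
    exceptions = {v: rng.randint(0, n_cases) for v in network.node_ids}
    return ActivityProfile(exceptions, n_cases, l)


def ben_condition_holds(graph: nx.Graph, exceptions: set[str], v: str) -> bool:
    """Brute-force re-check of the border-exception-node condition for *v*:
    after removing v, either some component consists solely of exception
    nodes (prunable) or exactly one component holds a non-exception node."""
    rest = graph.subgraph(set(graph.nodes()) - {v})
    others = exceptions - {v}
    s = 0
    any_all_exception = False
    for comp in nx.connected_components(rest):
        if comp <= others:
            any_all_exception = True
        else:
            s += 1
    return any_all_exception or s == 1
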