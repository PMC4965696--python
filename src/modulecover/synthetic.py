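"""Synthetic planted-module benchmark instances.

Biological interaction networks are approximately scale-free, so the
background is a Barabási–Albert preferential-attachment graph.  A connected
*planted module* of ``module_size`` nodes is picked by breadth-first growth
from a random root; indicator-matrix entries are independent Bernoulli
draws with a high active probability inside the module and a low one
outside.  The module's node set doubles as the gold standard, so the whole
extraction / perturbation / validation pipeline can be exercised offline
with a known ground truth.

Defaults (100-node background, 10-node module, 40 cases, per-case activity
0.95 in the module vs 0.05 outside) give a strong, realistically noisy
signal: a module gene is expected inactive in ~2/40 cases, well inside an
L = 20% allowance, while background genes essentially never reach it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import IndicatorMatrix
from .network import InteractionNetwork


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-module instance."""

    n_nodes: int = 100
    attachment: int = 2  # new edges per node in preferential attachment
    module_size: int = 10
    n_cases: int = 40
    p_active_in_module: float = 0.95
    p_active_background: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.module_size > self.n_nodes:
            raise ValueError("module_size cannot exceed n_nodes")
        for p in (self.p_active_in_module, self.p_active_background):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.attachment < 1 or self.attachment >= self.n_nodes:
            raise ValueError("attachment parameter must be in [1, n_nodes)")


def generate_synthetic_instance(
    spec: SyntheticSpec,
) -> tuple[InteractionNetwork, IndicatorMatrix, frozenset[str]]:
    """Generate (network, indicator matrix, gold set) for *spec*.

    Fully deterministic in ``spec.seed``: the same spec always yields the
    identical network, matrix and gold set.
    """
    rng = random.Random(spec.seed)
    bg = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=rng.randrange(2**31))
    width = len(str(spec.n_nodes - 1))
    mapping = {i: f"g{i:0{width}d}" for i in bg.nodes()}
    bg = nx.relabel_nodes(bg, mapping)
    network = InteractionNetwork(bg)

    # connected module by BFS from a random root, neighbors in random order
    root = rng.choice(sorted(network.node_ids))
    module: list[str] = [root]
    seen = {root}
    queue = [root]
    while queue and len(module) < spec.module_size:
        node = queue.pop(0)
        nbrs = sorted(n for n in network.neighbors(node) if n not in seen)
        rng.shuffle(nbrs)
        for nb in nbrs:
            seen.add(nb)
            module.append(nb)
            queue.append(nb)
            if len(module) == spec.module_size:
                break
    if len(module) < spec.module_size:
        raise ValueError(
            f"could not grow a connected module of {spec.module_size} nodes "
            f"from root {root!r}"
        )
    gold = frozenset(module)

    np_rng = np.random.default_rng(rng.randrange(2**31))
    genes = sorted(network.node_ids)
    probs = np.where(
        np.array([g in gold for g in genes]),
        spec.p_active_in_module,
        spec.p_active_background,
    )
    values = (np_rng.random((len(genes), spec.n_cases)) < probs[:, None]).astype(np.int8)
    df = pd.DataFrame(
        values, index=genes, columns=[f"s{j + 1}" for j in range(spec.n_cases)]
    )
    matrix = IndicatorMatrix(dataset_id="synthetic", values=df)
    return network, matrix, gold
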