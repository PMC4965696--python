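import random

import numpy as np
import pandas as pd
import pytest
from helpers import naive_optimum, random_activity, random_connected_graph

from modulecover import (
    ActivityProfile,
    ExtractionConfig,
    IndicatorMatrix,
    InteractionNetwork,
    LSpec,
    compute_activity,
    exact_extract,
    greedy_extract,
    is_valid_solution,
    make_pathway,
    remove_border_exception_nodes,
)
from conftest import uniform_activity


def matrix_from_rows(rows: dict[str, list[int]]) -> IndicatorMatrix:
    genes = list(rows)
    arr = np.asarray([rows[g] for g in genes], dtype=int)
    cols = [f"c{j + 1}" for j in range(arr.shape[1])]
    return IndicatorMatrix("D", pd.DataFrame(arr, index=genes, columns=cols))


class TestComputeActivity:
    @pytest.mark.parametrize(
        "row,l,active",
        [([1, 1, 1, 0], 1, True), ([1, 1, 1, 0], 0, False), ([1, 1, 1, 1], 0, True)],
    )
    def test_exception_threshold(self, row, l, active):
        act = compute_activity(matrix_from_rows({"g": row}), l)
        assert act.exception_count("g") == row.count(0)
        assert act.is_active("g") is active

    def test_gene_absent_from_matrix_fully_inactive(self):
        act = compute_activity(matrix_from_rows({"g": [1, 1]}), 1)
        assert act.exception_count("unmeasured") == 2
        assert not act.is_active("unmeasured")

    def test_positive_list_forces_active(self):
        act = compute_activity(matrix_from_rows({"g": [0, 0]}), 0, positive={"g"})
        assert act.exception_count("g") == 0 and act.is_active("g")


class TestIsValidSolution:
    def test_active_edge_k0(self, path_abc):
        act = uniform_activity(path_abc, {"A", "B"})
        cfg = ExtractionConfig(strategy="INES", k=0)
        p = make_pathway(path_abc, {"A", "B"}, act)
        assert is_valid_solution(p, cfg, act)

    def test_bridge_needs_budget(self, path_abc):
        act = uniform_activity(path_abc, {"A", "C"})
        p = make_pathway(path_abc, {"A", "B", "C"}, act)
        assert not is_valid_solution(p, ExtractionConfig(strategy="INES", k=0), act)
        assert is_valid_solution(p, ExtractionConfig(strategy="INES", k=1), act)

    def test_disconnected_invalid(self, path_abc):
        act = uniform_activity(path_abc, {"A", "C"})
        p = make_pathway(path_abc, {"A", "C"}, act)
        assert not is_valid_solution(p, ExtractionConfig(strategy="INES", k=1), act)

    def test_glone_budget_is_total_case_exceptions(self, path_abc):
        act = ActivityProfile({"A": 1, "B": 2, "C": 0}, n_cases=4, l=3)
        p = make_pathway(path_abc, {"A", "B", "C"}, act)
        assert p.total_case_exceptions == 3
        assert is_valid_solution(p, ExtractionConfig(strategy="GLONE"), act)
        act_tight = ActivityProfile({"A": 1, "B": 2, "C": 0}, n_cases=4, l=2)
        assert not is_valid_solution(
            make_pathway(path_abc, {"A", "B", "C"}, act_tight),
            ExtractionConfig(strategy="GLONE"),
            act_tight,
        )


class TestGreedyExtract:
    def test_all_active_returns_whole_network(self, path_abc):
        act = uniform_activity(path_abc, {"A", "B", "C"})
        sols = greedy_extract(path_abc, act, ExtractionConfig(strategy="INES", k=0))
        assert sols[0].nodes == {"A", "B", "C"}

    def test_no_active_nodes_no_solutions(self, path_abc):
        act = uniform_activity(path_abc, set())
        assert greedy_extract(path_abc, act, ExtractionConfig(strategy="INES", k=0)) == []

    def test_ranking_and_dedup(self, star_hub):
        act = uniform_activity(star_hub, {"h", "l1", "l2"})
        sols = greedy_extract(star_hub, act, ExtractionConfig(strategy="INES", k=0))
        sizes = [p.size for p in sols]
        assert sizes == sorted(sizes, reverse=True)
        assert len({p.nodes for p in sols}) == len(sols)
        assert sols[0].nodes == {"h", "l1", "l2"}

    def test_planted_module_recovered_and_matches_exact(self):
        rng = random.Random(99)
        net = random_connected_graph(rng, max_nodes=12)
        nodes = sorted(net.node_ids)
        module = set(nodes[:6])
        act = uniform_activity(net, module, n_cases=4)
        cfg = ExtractionConfig(strategy="INES", k=1)
        greedy_top = greedy_extract(net, act, cfg)[0]
        exact = exact_extract(net, act, cfg)
        assert exact.size >= greedy_top.size
        assert is_valid_solution(greedy_top, cfg, act)

    def test_glone_unbounded_budget_returns_component(self, star_hub):
        act = ActivityProfile(
            {v: 2 for v in star_hub.node_ids}, n_cases=2, l=2 * star_hub.n_nodes
        )
        sols = greedy_extract(star_hub, act, ExtractionConfig(strategy="GLONE"))
        assert sols[0].nodes == star_hub.node_ids


class TestExactExtract:
    def test_triangle_all_active(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        act = uniform_activity(net, {"a", "b", "c"})
        p = exact_extract(net, act, ExtractionConfig(strategy="INES", k=0))
        assert p.nodes == {"a", "b", "c"}

    def test_star_inactive_hub(self, star_hub):
        act = uniform_activity(star_hub, {"l1", "l2", "l3", "l4"})
        p0 = exact_extract(star_hub, act, ExtractionConfig(strategy="INES", k=0))
        assert p0.size == 1 and p0.nodes == {"l1"}  # smallest-id tie-break
        p1 = exact_extract(star_hub, act, ExtractionConfig(strategy="INES", k=1))
        assert p1.nodes == star_hub.node_ids

    def test_node_limit_enforced(self, star_hub):
        act = uniform_activity(star_hub, star_hub.node_ids)
        with pytest.raises(ValueError, match="greedy"):
            exact_extract(star_hub, act, ExtractionConfig(strategy="INES"), node_limit=3)


class TestBenFilter:
    def build(self, edges, active):
        net = InteractionNetwork.from_edges(edges)
        act = uniform_activity(net, set(active))
        return make_pathway(net, net.node_ids, act)

    def test_border_exception_leaf_removed(self):
        p = self.build([("a", "b"), ("b", "x")], active="ab")
        out = remove_border_exception_nodes(p, rng_seed=0)
        assert out.nodes == {"a", "b"}

    def test_articulation_exception_kept(self):
        p = self.build([("a", "x"), ("x", "b")], active="ab")
        out = remove_border_exception_nodes(p, rng_seed=0)
        assert out.nodes == {"a", "b", "x"}

    @pytest.mark.parametrize("seed", range(8))
    def test_exception_chain_removed_under_any_pop_order(self, seed):
        p = self.build([("a", "x1"), ("x1", "x2")], active="a")
        out = remove_border_exception_nodes(p, rng_seed=seed)
        assert out.nodes == {"a"}

    def test_nonexception_nodes_always_retained_and_connected(self):
        rng = random.Random(5)
        for _ in range(100):
            net = random_connected_graph(rng, max_nodes=7)
            act = random_activity(rng, net, n_cases=2, l=0)
            p = make_pathway(net, net.node_ids, act)
            out = remove_border_exception_nodes(p, rng_seed=rng.randrange(1000))
            assert p.nodes - p.exception_nodes <= out.nodes
            assert out.is_connected()
            again = remove_border_exception_nodes(out, rng_seed=rng.randrange(1000))
            assert again.nodes == out.nodes


class TestOracleEquivalence:
    """The exact extractor must match full subset enumeration, and bound
    the greedy search, on random small instances."""

    @pytest.mark.parametrize("trial", range(40))
    def test_exact_equals_naive_and_bounds_greedy(self, trial):
        rng = random.Random(1000 + trial)
        net = random_connected_graph(rng, max_nodes=8)
        n_cases = rng.randint(1, 4)
        for strategy, budget in (("INES", rng.randint(0, 2)), ("GLONE", rng.randint(0, 3))):
            l = rng.randint(0, n_cases) if strategy == "INES" else budget
            act = random_activity(rng, net, n_cases, l)
            cfg = ExtractionConfig(strategy=strategy, k=budget, algorithm="exact")
            exact = exact_extract(net, act, cfg)
            assert exact.size == naive_optimum(net, act, strategy, budget if strategy == "INES" else act.l)
            greedy = greedy_extract(net, act, ExtractionConfig(strategy=strategy, k=budget))
            if greedy:
                assert exact.size >= greedy[0].size
                assert is_valid_solution(greedy[0], cfg, act)
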