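import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modulecover import (
    jaccard,
    largest_solution,
    make_pathway,
    replicate_seed,
    robustness_analysis,
    summarize,
    validation_analysis,
)
from modulecover.evaluation import write_records_tsv, write_summary_tsv
from conftest import uniform_activity


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"x", "y"}, {"y", "z"}, 1 / 3),
            (set(), {"x"}, 0.0),
        ],
    )
    def test_worked_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_both_empty_counts_as_equal(self, caplog):
        with caplog.at_level("WARNING"):
            assert jaccard(set(), set()) == 1.0
        assert "empty" in caplog.text

    sets = st.frozensets(st.sampled_from("abcdefgh"), max_size=8)

    @settings(derandomize=True, max_examples=200)
    @given(sets, sets)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a == b)

    @settings(derandomize=True, max_examples=200)
    @given(sets, sets, sets)
    def test_distance_triangle_inequality(self, a, b, c):
        d = lambda x, y: 1 - jaccard(x, y)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


class TestLargestSolution:
    def test_tie_breaks_on_smallest_node_tuple(self, path_abc):
        act = uniform_activity(path_abc, path_abc.node_ids)
        p1 = make_pathway(path_abc, {"B", "C"}, act)
        p2 = make_pathway(path_abc, {"A", "B"}, act)
        assert largest_solution([p1, p2]).nodes == {"A", "B"}

    def test_empty_list_gives_empty_pathway(self):
        top = largest_solution([])
        assert top.size == 0
        assert jaccard(top.nodes, {"x"}) == 0.0


def test_replicate_seed_stable_and_bounded():
    s = replicate_seed(42, "edge_removal", 10, 0)
    assert s == replicate_seed(42, "edge_removal", 10, 0)
    assert 0 <= s < 2**31
    # adding a level or changing a component must not collide streams
    assert len({replicate_seed(42, "edge_removal", lv, r) for lv in (10, 20) for r in range(10)}) == 20


class TestBatchAnalyses:
    @pytest.fixture()
    def small_pipeline(self, planted_instance):
        network, collection, config, gold = planted_instance
        return network, collection, config, gold

    @pytest.mark.parametrize("strategy", ["label_permutation", "rewire", "node_removal", "edge_removal"])
    def test_level_zero_all_ones(self, small_pipeline, strategy):
        network, collection, config, _ = small_pipeline
        res = robustness_analysis(
            network, collection, config, strategy, [0], n_per_level=3, master_seed=1
        )
        assert res.values_at(0) == [1.0, 1.0, 1.0]

    def test_shape_and_determinism(self, small_pipeline):
        network, collection, config, _ = small_pipeline
        kwargs = dict(
            strategy="edge_removal", levels=[10, 30], n_per_level=4, master_seed=9
        )
        a = robustness_analysis(network, collection, config, **kwargs)
        b = robustness_analysis(network, collection, config, **kwargs)
        assert len(a.records) == 8
        assert a.records == b.records

    def test_validation_self_gold_at_level_zero(self, small_pipeline):
        network, collection, config, _ = small_pipeline
        base = robustness_analysis(
            network, collection, config, "edge_removal", [0], 1, master_seed=0
        ).baseline
        res = validation_analysis(
            network, collection, config, "edge_removal", [0], 2,
            gold=base.nodes, master_seed=0,
        )
        assert res.baseline_jaccard == 1.0
        assert res.values_at(0) == [1.0, 1.0]

    def test_validation_disjoint_gold_all_zero(self, small_pipeline):
        network, collection, config, _ = small_pipeline
        res = validation_analysis(
            network, collection, config, "edge_removal", [0], 2,
            gold={"not_a_gene"}, master_seed=0,
        )
        assert res.baseline_jaccard == 0.0 and res.values_at(0) == [0.0, 0.0]

    def test_full_label_permutation_degrades_gold_overlap(self, small_pipeline):
        network, collection, config, gold = small_pipeline
        res = validation_analysis(
            network, collection, config, "label_permutation", [0, 100], 3,
            gold=gold, master_seed=2,
        )
        mean = lambda xs: sum(xs) / len(xs)
        assert mean(res.values_at(0)) >= mean(res.values_at(100))


class TestSummaries:
    def make_result(self, values_by_level):
        from modulecover.evaluation import ReplicateRecord, RobustnessResult
        from modulecover.enrichment import EMPTY_PATHWAY

        res = RobustnessResult("edge_removal", list(values_by_level), 0, 0, EMPTY_PATHWAY)
        for level, values in values_by_level.items():
            for i, v in enumerate(values):
                res.records.append(ReplicateRecord(level, i, 0, v, 0))
        return res

    def test_mean_sd_median(self):
        res = self.make_result({10: [1.0, 1.0, 1.0], 20: [0.0, 1.0]})
        s10, s20 = summarize(res)
        assert (s10.mean, s10.sd) == (1.0, 0.0)
        assert s20.mean == 0.5 and s20.min == 0.0 and s20.max == 1.0

    def test_single_value_sd_zero(self):
        (s,) = summarize(self.make_result({10: [0.7]}))
        assert s.sd == 0.0 and s.median == pytest.approx(0.7)

    def test_tsv_writers_shape(self):
        res = self.make_result({10: [1.0, 0.5], 20: [0.25, 0.0]})
        records = io.StringIO()
        summary = io.StringIO()
        write_records_tsv(res, records)
        write_summary_tsv(res, summary)
        assert len(records.getvalue().strip().splitlines()) == 5  # header + 4
        assert len(summary.getvalue().strip().splitlines()) == 3  # header + 2
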