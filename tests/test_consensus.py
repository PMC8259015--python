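"""Threshold sweep, wMQ scoring, consensus selection and reassignment."""

from __future__ import annotations

import numpy as np
import pytest

from clustfuse import (
    ConsensusParams,
    InputClustering,
    IntegrationScenario,
    NoCandidateError,
    build_integration_graph,
    build_support_graph,
    filter_graph,
    reassign,
    run_consensus,
    sweep_and_select,
    wmq,
)
from clustfuse.consensus import ConsensusResult

from conftest import make_ig, random_partition, random_weighted_ig, wmq_brute


class TestFilterGraph:
    def test_threshold_one_keeps_everything(self):
        ig = make_ig("abcd", [("a", "b", 1), ("b", "c", 2), ("c", "d", 3)], 3)
        fg = filter_graph(ig, 1)
        assert sorted(fg.edges()) == sorted(ig.edges())

    def test_keeps_exactly_edges_at_or_above_threshold(self):
        ig = make_ig("abcd", [("a", "b", 1), ("b", "c", 2), ("c", "d", 3)], 3)
        fg = filter_graph(ig, 2)
        assert fg.n_edges == 2
        assert fg.weight("a", "b") == 0
        assert fg.nodes == ig.nodes  # nodes kept, possibly isolated

    def test_threshold_out_of_range(self):
        ig = make_ig("ab", [("a", "b", 1)], 2)
        for t in (0, 3):
            with pytest.raises(ValueError):
                filter_graph(ig, t)

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_sets_nest_as_threshold_increases(self, seed):
        ig = random_weighted_ig(np.random.default_rng(seed), 15, max_w=5)
        prev = None
        for t in range(1, 6):
            edges = {(u, v) for u, v, _ in filter_graph(ig, t).edges()}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestWMQ:
    def test_extremes(self):
        part = {s: ("1" if s in "abc" else "2") for s in "abcdef"}
        intra = [(u, v, 4) for u in "abc" for v in "abc" if u < v]
        intra += [(u, v, 4) for u in "def" for v in "def" if u < v]
        assert wmq(make_ig("abcdef", intra, 4), part, 4) == 1.0
        inter = [(u, v, 4) for u in "abc" for v in "def"]
        assert wmq(make_ig("abcdef", inter, 4), part, 4) == -1.0

    def test_hand_worked_example(self):
        # clusters {a,b},{c,d}, max_w=2: 1/(2*2) * [(2 - 1/4) + (1 - 1/4)] = 0.625
        ig = make_ig("abcd", [("a", "b", 2), ("c", "d", 1), ("a", "c", 1)], 2)
        part = {"a": "1", "b": "1", "c": "2", "d": "2"}
        assert wmq(ig, part, 2) == pytest.approx(0.625)
        assert wmq_brute(ig, part, 2) == pytest.approx(0.625)

    def test_edgeless_graph_scores_zero(self):
        ig = make_ig("abcd", [], 2)
        assert wmq(ig, {"a": "1", "b": "1", "c": "2", "d": "2"}, 2) == 0.0

    def test_single_cluster_and_singleton_conventions(self):
        ig = make_ig("abc", [("a", "b", 2)], 2)
        # k = 1: external term is 0, value = internal ratio / max_w
        assert wmq(ig, {"a": "1", "b": "1"}, 2) == pytest.approx((2 * 2 / 2) / 2)
        # singleton cluster contributes internal ratio 0
        val = wmq(ig, {"a": "1", "b": "1", "c": "2"}, 2)
        assert val == pytest.approx(wmq_brute(ig, {"a": "1", "b": "1", "c": "2"}, 2))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        max_w = int(rng.integers(1, 6))
        ig = random_weighted_ig(rng, n, max_w)
        part = random_partition(rng, sorted(ig.nodes), int(rng.integers(2, 5)))
        assert wmq(ig, part, max_w) == pytest.approx(wmq_brute(ig, part, max_w))
        assert -1.0 <= wmq(ig, part, max_w) <= 1.0

    def test_invariant_to_label_renaming(self):
        rng = np.random.default_rng(3)
        ig = random_weighted_ig(rng, 12, 3)
        part = random_partition(rng, sorted(ig.nodes), 3)
        renamed = {s: f"zz_{lab}" for s, lab in part.items()}
        assert wmq(ig, part, 3) == pytest.approx(wmq(ig, renamed, 3))

    def test_edges_outside_partition_ignored(self):
        ig = make_ig("abcde", [("a", "b", 2), ("d", "e", 2)], 2)
        part = {"a": "1", "b": "1", "c": "2"}
        # (d, e) must not contribute
        assert wmq(ig, part, 2) == pytest.approx(wmq_brute(ig, part, 2))

    def test_errors(self):
        ig = make_ig("ab", [("a", "b", 1)], 1)
        with pytest.raises(ValueError):
            wmq(ig, {}, 1)
        with pytest.raises(KeyError):
            wmq(ig, {"zz": "1", "a": "1"}, 1)


def _perfect_ensemble(n_clusterings=5):
    truth = {f"s{i}": ("x" if i < 6 else "y") for i in range(12)}
    clus = [InputClustering(name=f"c{i}", method=f"m{i}", omics=frozenset({"o"}),
                            assignment=dict(truth)) for i in range(n_clusterings)]
    return truth, clus


class TestSweepAndSelect:
    def test_perfect_agreement_returns_common_partition_with_wmq_one(self):
        truth, clus = _perfect_ensemble()
        ig = build_integration_graph(build_support_graph(clus),
                                     IntegrationScenario(tuple(c.name for c in clus)))
        res = sweep_and_select(ig, ConsensusParams(), seed=0)
        assert res.wmq == pytest.approx(1.0)
        got = {lab: {s for s, l in res.assignment.items() if l == lab}
               for lab in set(res.assignment.values())}
        want = {lab: {s for s, l in truth.items() if l == lab}
                for lab in set(truth.values())}
        assert set(map(frozenset, got.values())) == set(map(frozenset, want.values()))

    def test_sweep_table_covers_all_thresholds_and_algorithms(self):
        _, clus = _perfect_ensemble(5)
        ig = build_integration_graph(build_support_graph(clus),
                                     IntegrationScenario(tuple(c.name for c in clus)))
        res = sweep_and_select(ig, ConsensusParams(), seed=0)
        seen = {(r["threshold"], r["algorithm"]) for r in res.sweep_table}
        assert seen == {(t, a) for t in range(1, 6) for a in ("LCD", "MCL")}

    def test_tie_break_prefers_higher_threshold(self):
        _, clus = _perfect_ensemble(4)
        ig = build_integration_graph(build_support_graph(clus),
                                     IntegrationScenario(tuple(c.name for c in clus)))
        # every threshold scores 1.0 on the unfiltered dialect -> pick t = 4, LCD
        res = sweep_and_select(ig, ConsensusParams(), seed=0)
        assert res.threshold == 4
        assert res.algorithm == "LCD"

    def test_no_candidate_error_lists_reasons(self):
        _, clus = _perfect_ensemble()
        ig = build_integration_graph(build_support_graph(clus),
                                     IntegrationScenario(tuple(c.name for c in clus)))
        params = ConsensusParams(min_size_cluster=100)  # nothing can survive
        with pytest.raises(NoCandidateError) as exc:
            sweep_and_select(ig, params, seed=0)
        assert len(exc.value.reasons) == 10  # 5 thresholds x 2 algorithms

    def test_min_size_cluster_drops_small_clusters(self):
        truth = {f"s{i}": ("x" if i < 8 else "y") for i in range(10)}
        clus = [InputClustering(name=f"c{i}", method=f"m{i}",
                                omics=frozenset({"o"}), assignment=dict(truth))
                for i in range(3)]
        ig = build_integration_graph(build_support_graph(clus),
                                     IntegrationScenario(("c0", "c1", "c2")))
        res = sweep_and_select(ig, ConsensusParams(min_size_cluster=3, reassign=False),
                               seed=0)
        sizes = res.cluster_sizes()
        assert all(v >= 3 for v in sizes.values())
        assert res.unassigned == {"s8", "s9"}  # the dropped 2-cluster

    def test_fractional_sizes_resolve_against_reference_population(self):
        params = ConsensusParams(min_size_cluster=0.5,
                                 reference_population=[f"r{i}" for i in range(10)])
        ig = make_ig("abcd", [("a", "b", 1)], 1)
        assert params.resolved_sizes(ig) == (5, 1)
        with pytest.raises(ValueError):
            ConsensusParams(min_size_cluster=1.5).resolved_sizes(ig)
        with pytest.raises(ValueError):
            ConsensusParams(min_size_consensus=0).resolved_sizes(ig)

    def test_determinism_same_inputs_same_seed(self):
        rng = np.random.default_rng(9)
        ig = random_weighted_ig(rng, 20, 4, p_edge=0.4)
        r1 = run_consensus(ig, ConsensusParams(), seed=7)
        r2 = run_consensus(ig, ConsensusParams(), seed=7)
        assert r1.assignment == r2.assignment
        assert r1.sweep_table == r2.sweep_table
        assert (r1.threshold, r1.algorithm, r1.wmq) == (r2.threshold, r2.algorithm, r2.wmq)


class TestReassign:
    def _result(self, assignment, unassigned):
        return ConsensusResult(assignment=assignment, threshold=1, algorithm="LCD",
                               wmq=0.5, clustered=set(assignment), reassigned=set(),
                               unassigned=unassigned, sweep_table=[])

    def test_max_weight_neighbor_cluster_wins(self):
        ig = make_ig(list("abcu"), [("u", "a", 3), ("u", "b", 3)], 3)
        res = self._result({"a": "1", "b": "1", "c": "2"}, {"u"})
        out = reassign(ig, res)
        assert out.assignment["u"] == "1"
        assert out.reassigned == {"u"}

    def test_mean_supports_comparison(self):
        # u -> 3-cluster with weights (2,2,0): mean 4/3; u -> 2-cluster with (3,0): mean 3/2
        edges = [("u", "a", 2), ("u", "b", 2), ("u", "d", 3)]
        ig = make_ig(list("abcdeu"), edges, 3)
        res = self._result({"a": "1", "b": "1", "c": "1", "d": "2", "e": "2"}, {"u"})
        out = reassign(ig, res)
        assert out.assignment["u"] == "2"

    def test_isolated_sample_stays_unassigned(self):
        ig = make_ig(list("abu"), [("a", "b", 2)], 2)
        res = self._result({"a": "1", "b": "1"}, {"u"})
        out = reassign(ig, res)
        assert "u" not in out.assignment
        assert out.unassigned == {"u"}

    def test_core_labels_never_change_and_accounting_holds(self):
        rng = np.random.default_rng(2)
        ig = random_weighted_ig(rng, 25, 4, p_edge=0.3)
        res = run_consensus(ig, ConsensusParams(min_size_cluster=4), seed=1)
        for s in res.clustered:
            assert res.assignment[s] is not None
        assert res.clustered | res.reassigned | res.unassigned == ig.nodes
        assert not res.clustered & res.reassigned
        assert not res.clustered & res.unassigned
        assert not res.reassigned & res.unassigned


def test_planted_ensemble_recovery_beats_inputs():
    """On a noisy planted ensemble the consensus lands closer to truth than inputs."""
    from clustfuse import EnsembleConfig, ari, make_ensemble, plant_truth

    cfg = EnsembleConfig(n_samples=120, k_true=3, noise_rate=0.2, seed=13)
    truth = plant_truth(cfg)
    ens = make_ensemble(truth, cfg)
    ig = build_integration_graph(build_support_graph(ens),
                                 IntegrationScenario.select(ens))
    res = run_consensus(ig, ConsensusParams(min_size_cluster=5,
                                            min_size_consensus=0.5), seed=1)
    assert ari(res.assignment, truth) >= 0.9
    assert ari(res.assignment, truth) >= np.mean(
        [ari(c.assignment, truth) for c in ens])
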