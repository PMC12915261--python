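"""Causal-graph engine: construction, d-separation, single-door criterion."""

import itertools

import numpy as np
import pytest

from serialbias.causal_graph import (
    Dag,
    build_experiment_graph,
    descendants,
    is_d_separated,
    single_door_valid,
    window_graph,
)

from _dsep_oracle import dsep_by_paths, random_dag, random_query

CHAIN = Dag("abc", [("a", "b"), ("b", "c")])
COLLIDER = Dag("abc", [("a", "b"), ("c", "b")])


class TestDag:
    def test_rejects_cycle(self):
        with pytest.raises(ValueError, match="cycle"):
            Dag("ab", [("a", "b"), ("b", "a")])

    def test_rejects_dangling_edge(self):
        with pytest.raises(ValueError, match="outside node set"):
            Dag("ab", [("a", "c")])

    def test_edgelist_roundtrip(self):
        g = window_graph(autocorrelated=True)
        g2 = Dag.from_edgelist(g.to_edgelist())
        assert g2 == g

    def test_edgelist_keeps_isolated_nodes(self):
        g = Dag(["a", "b", "lonely"], [("a", "b")])
        assert Dag.from_edgelist(g.to_edgelist()) == g

    def test_remove_edge_missing(self):
        with pytest.raises(ValueError, match="not in graph"):
            CHAIN.remove_edge("a", "c")


class TestExperimentGraph:
    def test_edge_inventory_three_trials(self):
        # families per 3-trial window: 2 stimulus-chain + 3 CT + 2 SD1 + 2 carryover
        g = build_experiment_graph(3, autocorrelated=True)
        assert len(g.nodes) == 6
        assert len(g.edges) == 9

    def test_two_trials_no_autocorrelation(self):
        g = build_experiment_graph(2, autocorrelated=False)
        assert g.edges == frozenset(
            {("s1", "e1"), ("s2", "e2"), ("s1", "e2"), ("e1", "e2")}
        )

    @pytest.mark.parametrize("n,auto", [(2, True), (5, False), (8, True)])
    def test_always_acyclic(self, n, auto):
        # every edge points to an equal-or-later trial, error after stimulus
        g = build_experiment_graph(n, auto)

        def rank(label):
            return (int(label[1:]), 0 if label[0] == "s" else 1)

        assert all(rank(u) < rank(v) for u, v in g.edges)

    def test_window_graph_labels(self):
        g = window_graph(autocorrelated=True, n_back=2)
        assert g.nodes == frozenset(
            {"s[t-2]", "s[t-1]", "s[t]", "e[t-2]", "e[t-1]", "e[t]"}
        )
        assert ("s[t-1]", "s[t]") in g.edges
        assert ("s[t-1]", "s[t]") not in window_graph(autocorrelated=False).edges


class TestDescendants:
    def test_chain(self):
        assert descendants(CHAIN, "a") == {"b", "c"}

    def test_sink_is_empty(self):
        assert descendants(CHAIN, "c") == frozenset()

    def test_errors_never_cause_stimuli(self):
        g = window_graph(autocorrelated=True)
        desc = descendants(g, "e[t-1]")
        assert "e[t]" in desc
        assert not any(d.startswith("s") for d in desc)

    def test_unknown_node(self):
        with pytest.raises(ValueError, match="unknown node"):
            descendants(CHAIN, "zzz")


class TestDSeparation:
    def test_chain_blocked_by_middle(self):
        assert not is_d_separated(CHAIN, "a", "c", set())
        assert is_d_separated(CHAIN, "a", "c", {"b"})

    def test_collider_opens_when_conditioned(self):
        assert is_d_separated(COLLIDER, "a", "c", set())
        assert not is_d_separated(COLLIDER, "a", "c", {"b"})

    def test_conditioning_on_collider_descendant_opens(self):
        g = Dag("abcd", [("a", "b"), ("c", "b"), ("b", "d")])
        assert not is_d_separated(g, "a", "c", {"d"})

    def test_ct_identification_window(self):
        # with the CT edge removed, the previous stimulus blocks all paths
        g = window_graph(autocorrelated=True).remove_edge("s[t]", "e[t]")
        assert not is_d_separated(g, "s[t]", "e[t]", set())
        assert is_d_separated(g, "s[t]", "e[t]", {"s[t-1]"})

    def test_sd1_identification_window(self):
        g = window_graph(autocorrelated=True).remove_edge("s[t-1]", "e[t]")
        assert is_d_separated(g, "s[t-1]", "e[t]", {"s[t]", "e[t-1]"})

    def test_overlapping_query_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            is_d_separated(CHAIN, "a", "c", {"a"})
        with pytest.raises(ValueError, match="disjoint"):
            is_d_separated(CHAIN, "a", "a", set())

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            dag = random_dag(rng, int(rng.integers(2, 7)))
            x, y, z = random_query(rng, dag)
            assert is_d_separated(dag, x, y, z) == dsep_by_paths(dag, x, y, z)

    def test_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(8)
        for _ in range(500):
            dag = random_dag(rng, int(rng.integers(2, 7)))
            x, y, z = random_query(rng, dag)
            G = nx.DiGraph(dag.edges)
            G.add_nodes_from(dag.nodes)
            assert is_d_separated(dag, x, y, z) == nx.is_d_separator(G, {x}, {y}, set(z))

    def test_adding_safe_nodes_preserves_separation(self):
        # augmenting z with nodes that are neither colliders on any x-y path
        # nor descendants of such colliders cannot unblock anything
        from _dsep_oracle import all_undirected_paths

        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(800):
            dag = random_dag(rng, int(rng.integers(3, 7)))
            x, y, z = random_query(rng, dag)
            if not is_d_separated(dag, x, y, z):
                continue
            unsafe = set()
            for path in all_undirected_paths(dag, x, y):
                for i in range(1, len(path) - 1):
                    prev, v, nxt = path[i - 1], path[i], path[i + 1]
                    if (prev, v) in dag.edges and (nxt, v) in dag.edges:
                        unsafe |= {v} | descendants(dag, v)
            safe = dag.nodes - unsafe - {x, y} - z
            for v in safe:
                assert is_d_separated(dag, x, y, z | {v})
                checked += 1
        assert checked > 50  # the scenario actually occurred


class TestSingleDoor:
    AUTO = window_graph(autocorrelated=True)
    NOAUTO = window_graph(autocorrelated=False)

    def test_ct_adjustment_previous_stimulus(self):
        assert single_door_valid(self.AUTO, "s[t]", "e[t]", {"s[t-1]"})

    def test_sd1_adjustment(self):
        assert single_door_valid(self.AUTO, "s[t-1]", "e[t]", {"s[t]", "e[t-1]"})

    def test_unadjusted_ct_invalid_under_autocorrelation(self):
        # open path via the common cause s[t-1]
        assert not single_door_valid(self.AUTO, "s[t]", "e[t]", set())

    def test_unadjusted_ct_valid_without_autocorrelation(self):
        assert single_door_valid(self.NOAUTO, "s[t]", "e[t]", set())

    def test_sd1_needs_previous_error_without_autocorrelation(self):
        assert not single_door_valid(self.NOAUTO, "s[t-1]", "e[t]", set())
        assert single_door_valid(self.NOAUTO, "s[t-1]", "e[t]", {"e[t-1]"})

    def test_descendant_of_effect_disqualifies(self):
        g = Dag("abc", [("a", "b"), ("b", "c")])
        assert not single_door_valid(g, "a", "b", {"c"})

    def test_missing_edge_rejected(self):
        with pytest.raises(ValueError, match="not in graph"):
            single_door_valid(self.AUTO, "e[t]", "s[t]", set())

    def test_exhaustive_adjustment_sets_autocorrelated(self):
        """Enumerate all small candidate sets on the autocorrelated window.

        For CT the minimal valid set is {s[t-1]} (also valid with e[t-1]
        added, which opens no path — that is why one combined regression
        can estimate both effects); for SD1 only {s[t], e[t-1]} works.
        """
        candidates = ["s[t]", "s[t-1]", "e[t-1]"]

        def valid_sets(cause, effect):
            pool = [c for c in candidates if c not in (cause, effect)]
            found = set()
            for r in range(len(pool) + 1):
                for zs in itertools.combinations(pool, r):
                    if single_door_valid(self.AUTO, cause, effect, set(zs)):
                        found.add(frozenset(zs))
            return found

        assert valid_sets("s[t]", "e[t]") == {
            frozenset({"s[t-1]"}),
            frozenset({"s[t-1]", "e[t-1]"}),
        }
        assert valid_sets("s[t-1]", "e[t]") == {frozenset({"s[t]", "e[t-1]"})}
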