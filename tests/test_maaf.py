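"""Decision graphs, cycle breaking, GAF streaming, MAAF enumeration."""

import itertools

import networkx as nx
import pytest

from fasthn import (
    DUMMY,
    af_from_labelsets,
    augment_dummy,
    break_cycles,
    decision_graph,
    enumerate_maafs,
    enumerate_mafs,
    find_cycle,
    gaf_enumerate,
    hybridization_number,
    parse_newick,
    rspr_distance,
)
from fasthn.forest import size
from fasthn.maaf import DecisionGraph
from fasthn.simulate import is_af, oracle_maafs

from conftest import make_pair


def aug(s):
    return augment_dummy(parse_newick(s))


def keys(result):
    return [rec.canonical_key for rec in result.maafs]


class TestDecisionGraph:
    def test_single_component_is_trivially_acyclic(self):
        t1 = aug("((a,b),c);")
        f = af_from_labelsets(t1, [frozenset({"a", "b", "c", DUMMY})])
        g = decision_graph(f, t1, aug("((a,c),b);"))
        assert g.graph.number_of_nodes() == 1
        assert g.graph.number_of_edges() == 0
        assert g.acyclic

    def test_root_component_dominates_singleton(self):
        t1 = aug("((a,b),c);")
        t2 = aug("((a,c),b);")
        f = af_from_labelsets(t1, [frozenset("a"), frozenset({"b", "c", DUMMY})])
        g = decision_graph(f, t1, t2)
        assert g.graph.number_of_edges() == 1
        (arc,) = g.graph.edges
        assert DUMMY in f.subtree_taxa(arc[0])
        assert f.subtree_taxa(arc[1]) == frozenset("a")

    def test_all_singletons_have_no_arcs(self):
        t1 = aug("((a,b),c);")
        fam = [frozenset({x}) for x in "abc"] + [frozenset({DUMMY})]
        f = af_from_labelsets(t1, fam)
        g = decision_graph(f, t1, aug("((a,c),b);"))
        assert g.graph.number_of_edges() == 0


class TestFindCycle:
    def test_empty_graph(self):
        assert find_cycle(DecisionGraph(nx.DiGraph())) is None

    def test_two_cycle(self):
        g = nx.DiGraph([("x", "y"), ("y", "x")])
        cyc = find_cycle(DecisionGraph(g))
        assert sorted(cyc) == ["x", "y"]

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_topological_sort_oracle(self, seed):
        import random

        rng = random.Random(seed)
        g = nx.gnp_random_graph(8, 0.25, seed=rng.randint(0, 10**6), directed=True)
        has_cycle = find_cycle(DecisionGraph(g)) is not None
        # independent check: topological sort succeeds iff acyclic
        try:
            list(nx.topological_sort(g))
            toposortable = True
        except nx.NetworkXUnfeasible:
            toposortable = False
        assert has_cycle == (not toposortable)


class TestBreakCycles:
    def test_acyclic_input_returned_unchanged(self, fixture_pair):
        t1, t2 = fixture_pair
        f = af_from_labelsets(t1, [frozenset("a"), frozenset({"b", "c", DUMMY})])
        out = break_cycles(f, budget=3, t1=t1, t2=t2)
        assert [r.canonical_key for r in out] == [f.canonical_key()]

    def test_cyclic_with_zero_budget_yields_nothing(self):
        # n=6, r=5, seed=41 has d=2 < h=3: some maximum AF must be cyclic
        t1, t2 = make_pair(6, 5, 41)
        d = rspr_distance(t1, t2)
        cyclic = [
            rec for rec in gaf_enumerate(t1, t2, d) if not rec.acyclic and rec.size == d
        ]
        assert cyclic
        assert break_cycles(cyclic[0].forest, 0, t1, t2) == []

    def test_recovers_oracle_maafs_when_h_exceeds_d(self):
        # same pair: cycle breaking must supply exactly the oracle MAAF set
        t1, t2 = make_pair(6, 5, 41)
        orc = oracle_maafs(t1, t2)
        d = rspr_distance(t1, t2)
        assert orc.h > d
        found = {}
        for rec in gaf_enumerate(t1, t2, orc.h):
            if rec.acyclic:
                found.setdefault(rec.canonical_key, rec)
            else:
                for r in break_cycles(rec.forest, orc.h - rec.size, t1, t2):
                    found.setdefault(r.canonical_key, r)
        got = sorted(k for k, r in found.items() if r.size == orc.h)
        assert got == [r.canonical_key for r in orc.maafs]


class TestGafEnumerate:
    def test_identical_trees_emit_whole_tree(self):
        t = aug("((a,b),c);")
        recs = list(gaf_enumerate(t, t.copy(), 0))
        assert len(recs) == 1 and recs[0].size == 0

    def test_fixture_single_cut_families(self, fixture_pair):
        t1, t2 = fixture_pair
        got = sorted(r.canonical_key for r in gaf_enumerate(t1, t2, 1) if r.size == 1)
        assert got == [
            (("a",), ("b", "c")),
            (("a", "b"), ("c",)),
            (("a", "c"), ("b",)),
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_pruning_flag_leaves_emitted_set_unchanged(self, seed):
        # the rSPRDC test only cuts branches that could never emit, so the
        # stream is exactly invariant under it (for either pair-selection rule)
        t1, t2 = make_pair(6, 2, seed)
        k = rspr_distance(t1, t2) + 1
        for h2 in (False, True):
            plain = sorted({r.canonical_key for r in gaf_enumerate(t1, t2, k, h2=h2)})
            pruned = sorted({r.canonical_key for r in gaf_enumerate(t1, t2, k, h1=True, h2=h2)})
            assert plain == pruned

    @pytest.mark.parametrize("seed", range(5))
    def test_selection_rule_preserves_required_forests(self, seed):
        # the far-apart selection rule may emit a different *superset* of
        # agreement forests, but the minimum-size families are always there
        t1, t2 = make_pair(6, 2, seed)
        k = rspr_distance(t1, t2) + 1
        per_flag = []
        for h2 in (False, True):
            recs = list(gaf_enumerate(t1, t2, k, h2=h2))
            mins = min(r.size for r in recs)
            per_flag.append(sorted({r.canonical_key for r in recs if r.size == mins}))
        assert per_flag[0] == per_flag[1]

    @pytest.mark.parametrize("seed", range(5))
    def test_budget_monotonicity(self, seed):
        t1, t2 = make_pair(6, 2, seed)
        k = rspr_distance(t1, t2)
        small = {r.canonical_key for r in gaf_enumerate(t1, t2, k)}
        large = {r.canonical_key for r in gaf_enumerate(t1, t2, k + 1)}
        assert small <= large

    @pytest.mark.parametrize("seed", range(5))
    def test_every_emission_is_an_agreement_forest(self, seed):
        t1, t2 = make_pair(6, 2, seed)
        for rec in gaf_enumerate(t1, t2, 2):
            assert is_af(rec.forest, t1)
            assert is_af(rec.forest, t2)


class TestEnumerateMaafs:
    def test_identical_trees(self):
        t = aug("(((a,b),(c,d)),e);")
        res = enumerate_maafs(t, t.copy())
        assert res.h == 0 and len(res.maafs) == 1

    def test_fixture_three_maafs(self, fixture_pair):
        res = enumerate_maafs(*fixture_pair)
        assert res.h == 1
        assert keys(res) == [
            (("a",), ("b", "c")),
            (("a", "b"), ("c",)),
            (("a", "c"), ("b",)),
        ]

    def test_taxa_mismatch_rejected(self):
        from fasthn.forest import ForestError

        with pytest.raises(ForestError, match="taxa differ"):
            enumerate_maafs(aug("(a,b);"), aug("(a,c);"))

    @pytest.mark.parametrize("seed", range(10))
    def test_h_at_least_distance_and_outputs_valid(self, seed):
        t1, t2 = make_pair(7, 3, seed)
        res = enumerate_maafs(t1, t2)
        assert res.h >= rspr_distance(t1, t2)
        for rec in res.maafs:
            assert rec.size == res.h and rec.acyclic
            assert is_af(rec.forest, t1) and is_af(rec.forest, t2)
            assert decision_graph(rec.forest, t1, t2).acyclic
            assert frozenset({DUMMY}) not in rec.forest.labelset_family()

    @pytest.mark.parametrize("seed", range(6))
    def test_heuristic_invariance(self, seed):
        t1, t2 = make_pair(7, 3, seed)
        base = None
        for h1, h2 in itertools.product((False, True), repeat=2):
            res = enumerate_maafs(t1, t2, h1=h1, h2=h2)
            got = (res.h, keys(res))
            if base is None:
                base = got
            assert got == base

    def test_hybridization_number_matches_full_enumeration(self):
        for seed in range(5):
            t1, t2 = make_pair(7, 3, seed)
            assert hybridization_number(t1, t2) == enumerate_maafs(t1, t2).h


class TestEnumerateMafs:
    def test_fixture_mafs(self, fixture_pair):
        res = enumerate_mafs(*fixture_pair)
        assert res.h == 1 and len(res.maafs) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_maf_level_equals_distance(self, seed):
        t1, t2 = make_pair(6, 2, seed)
        res = enumerate_mafs(t1, t2)
        assert res.h == rspr_distance(t1, t2)
        assert all(r.size == res.h for r in res.maafs)
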