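"""Newick parsing, canonical writing, dummy augmentation, eNewick round-trips."""

import random

import dendropy
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fasthn import (
    DUMMY,
    NewickError,
    augment_dummy,
    parse_newick,
    strip_dummy,
    write_newick,
)
from fasthn.forest import size
from fasthn.simulate import SimulationConfig, random_tree

from conftest import make_pair


class TestParse:
    def test_simple_cherry_topology(self):
        t = parse_newick("((a,b),c);")
        assert t.num_components() == 1
        assert sorted(map(sorted, t.labels.values())) == [["a"], ["b"], ["c"]]
        # binary-tree identity: leaves = internal nodes + 1
        assert len(t.labels) == len(t.children) + 1

    def test_annotations_are_discarded(self):
        plain = parse_newick("((a,b),c);")
        fancy = parse_newick("((a:0.1,b:0.2)n1:0.3,c);")
        assert write_newick(plain) == write_newick(fancy)

    def test_whitespace_ignored(self):
        assert write_newick(parse_newick(" ( (a , b) ,\n c ) ; ")) == "((a,b),c);"

    @pytest.mark.parametrize(
        "text,match",
        [
            ("((a,b,c),d);", "not binary"),
            ("((a),b);", "not binary"),
            ("((a,b),a);", "duplicate taxon"),
            ("((a,b),c)", "expected ';'"),
            ("((a,b),);", "expected a label"),
            ("((a,b),c);x", "trailing"),
        ],
    )
    def test_malformed_input_is_rejected(self, text, match):
        with pytest.raises(NewickError, match=match):
            parse_newick(text)

    def test_illegal_label_character(self):
        with pytest.raises(NewickError):
            parse_newick("((a,b),c*d);")

    def test_parse_error_carries_offset(self):
        with pytest.raises(NewickError) as exc:
            parse_newick("((a,b)")
        assert exc.value.offset is not None


class TestWrite:
    def test_canonical_child_order(self):
        assert write_newick(parse_newick("((c,a),b);")) == "((a,c),b);"
        assert write_newick(parse_newick("(b,(a,c));")) == "((a,c),b);"

    def test_single_leaf(self):
        from fasthn.forest import Forest

        f = Forest()
        f.add_leaf({"x"})
        assert write_newick(f) == "x;"

    def test_multi_component_forest_rejected(self):
        from fasthn.forest import Forest, ForestError

        f = Forest()
        f.add_leaf({"x"})
        f.add_leaf({"y"})
        with pytest.raises(ForestError):
            write_newick(f)

    @pytest.mark.parametrize("seed", range(20))
    def test_roundtrip_is_identity(self, seed):
        t = random_tree(SimulationConfig(n_leaves=5 + seed % 8, seed=seed))
        s = write_newick(t)
        assert write_newick(parse_newick(s)) == s

    @given(
        labels=st.lists(
            st.text("0123456789abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ_.", min_size=1, max_size=6),
            unique=True,
            min_size=2,
            max_size=9,
        ),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_roundtrip_with_arbitrary_labels(self, labels, seed):
        """Serialization is a normal form over the full label alphabet."""
        from fasthn.forest import Forest

        rng = random.Random(seed)
        t = Forest()
        t.add_leaf({labels[0]})
        for name in labels[1:]:
            positions = sorted(t.parent) + ["root"]
            pos = rng.choice(positions)
            m = t.add_internal()
            if pos == "root":
                (old_root,) = [r for r in t.roots() if r != m]
                t.parent[old_root] = m
                t.children[m].append(old_root)
            else:
                p = t.parent[pos]
                t.children[p][t.children[p].index(pos)] = m
                t.parent[m] = p
                t.parent[pos] = m
                t.children[m].append(pos)
            t.add_leaf({name}, m)
        s = write_newick(t)
        reparsed = parse_newick(s)
        assert write_newick(reparsed) == s
        # binary-tree identity survives the round trip
        assert len(reparsed.labels) == len(reparsed.children) + 1

    @pytest.mark.parametrize("seed", range(10))
    def test_writer_agrees_with_dendropy(self, seed):
        """Cross-check topology against an independent Newick implementation."""
        t = random_tree(SimulationConfig(n_leaves=6 + seed % 5, seed=seed))
        s = write_newick(t)
        dt = dendropy.Tree.get(data=s, schema="newick")
        ours = {tuple(sorted(t.subtree_taxa(v))) for v in t.children}
        theirs = {
            tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))
            for node in dt.preorder_internal_node_iter()
        }
        assert ours == theirs


class TestAugment:
    def test_augment_adds_one_leaf_and_one_internal(self):
        t = parse_newick("((a,b),c);")
        a = augment_dummy(t)
        assert len(a.labels) == len(t.labels) + 1
        assert len(a.children) == len(t.children) + 1
        assert DUMMY in a.taxa()
        (root,) = a.roots()
        kids = a.children[root]
        assert any(a.labels.get(k) == frozenset({DUMMY}) for k in kids)

    def test_augment_single_leaf_gives_cherry(self):
        from fasthn.forest import Forest

        f = Forest()
        f.add_leaf({"x"})
        a = augment_dummy(f)
        assert size(a) == 0 and len(a.labels) == 2

    def test_double_augmentation_rejected(self):
        from fasthn.forest import ForestError

        t = augment_dummy(parse_newick("((a,b),c);"))
        with pytest.raises(ForestError):
            augment_dummy(t)

    def test_strip_inverts_augment(self):
        t = parse_newick("((a,b),c);")
        assert write_newick(strip_dummy(augment_dummy(t))) == write_newick(t)


class TestENewick:
    def test_tree_shaped_network_has_no_tags(self):
        from fasthn import enumerate_maafs, network_from_maaf, write_enewick

        t = augment_dummy(parse_newick("((a,b),c);"))
        res = enumerate_maafs(t, t.copy())
        net = network_from_maaf(res.maafs[0], t, t.copy())
        s = write_enewick(net)
        assert "#H" not in s
        assert write_newick(parse_newick(s)) == "((a,b),c);"

    def test_single_reticulation_tag_appears_twice(self, fixture_pair):
        from fasthn import enumerate_maafs, network_from_maaf, write_enewick

        t1, t2 = fixture_pair
        res = enumerate_maafs(t1, t2)
        s = write_enewick(network_from_maaf(res.maafs[0], t1, t2))
        assert s.count("#H1") == 2 and "#H2" not in s

    @pytest.mark.parametrize("seed", range(10))
    def test_reparse_isomorphism(self, seed):
        from fasthn import (
            enumerate_maafs,
            network_from_maaf,
            network_isomorphic,
            parse_enewick,
            write_enewick,
        )

        t1, t2 = make_pair(6, 2, seed)
        res = enumerate_maafs(t1, t2)
        for rec in res.maafs[:2]:
            net = network_from_maaf(rec, t1, t2)
            assert network_isomorphic(net, parse_enewick(write_enewick(net)))
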