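import itertools

import dendropy
import numpy as np
import pytest

from barcodiv.discriminate import discrimination_report, is_monophyletic
from barcodiv.errors import ValidationError
from barcodiv.seqio import SampleMetadata


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


def test_monophyly_on_the_mixed_clade_tree():
    tree = _tree("((a1,a2),(b1,(b2,a3)));")
    assert not is_monophyletic(tree, {"a1", "a2", "a3"})  # species a is scattered
    assert not is_monophyletic(tree, {"b1", "b2"})  # a3 intrudes in MRCA(b)
    assert is_monophyletic(tree, {"b2", "a3"})  # an actual clade
    assert is_monophyletic(tree, {"a1", "a2"})
    assert is_monophyletic(tree, {"b2"})  # singleton always passes


def test_unknown_leaf_is_an_error():
    tree = _tree("((a1,a2),(b1,b2));")
    with pytest.raises(ValidationError):
        is_monophyletic(tree, {"a1", "zz"})


def _random_rooted_tree(labels, rng):
    """Random rooted binary tree built by sequential random joins."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def test_monophyly_agrees_with_exhaustive_clade_enumeration():
    """Oracle: a leaf set is monophyletic iff it equals the leaf set of some
    node of the rooted tree; checked for every subset on trees up to 8 leaves."""
    rng = np.random.default_rng(2024)
    for n_leaves in (4, 6, 8):
        labels = [f"L{i}" for i in range(n_leaves)]
        for _ in range(5):
            tree = _random_rooted_tree(labels, rng)
            clades = {
                frozenset(l.taxon.label for l in node.leaf_iter())
                for node in tree.preorder_node_iter()
            }
            for r in range(1, n_leaves + 1):
                for subset in itertools.combinations(labels, r):
                    expected = frozenset(subset) in clades
                    assert is_monophyletic(tree, set(subset)) == expected


def _meta(species_members, outgroup="og"):
    rows = []
    for sp, members in species_members.items():
        for m in members:
            rows.append(SampleMetadata(m, sp, "ingroup", "genuine"))
    if outgroup:
        rows.append(SampleMetadata(outgroup, "outsp", "outgroup", "outgroup"))
    return rows


def test_rate_all_monophyletic_is_100():
    newick = "(" + ",".join(f"(s{i}a,s{i}b)" for i in range(8)) + ",og);"
    tree = _tree(newick)
    meta = _meta({f"sp{i}": [f"s{i}a", f"s{i}b"] for i in range(8)})
    report = discrimination_report(tree, meta, "clean")
    assert report.rate == 100.0
    assert all(v.monophyletic for v in report.per_species.values())


def test_rate_with_one_failing_species_is_87_5():
    # sp0's two individuals straddle sp1's clade
    inner = "((s0a,(s1a,s1b)),s0b)"
    rest = ",".join(f"(s{i}a,s{i}b)" for i in range(2, 8))
    tree = _tree(f"({inner},{rest},og);")
    meta = _meta({f"sp{i}": [f"s{i}a", f"s{i}b"] for i in range(8)})
    report = discrimination_report(tree, meta, "one-fail")
    assert report.rate == 87.5
    assert not report.per_species["sp0"].monophyletic


def test_rate_two_of_eight_resolved_is_25():
    # six species pairwise interleaved so only sp6 and sp7 form clades
    scrambled = ",".join(
        f"(s{i}a,s{j}b)" for i, j in [(0, 1), (1, 0), (2, 3), (3, 2), (4, 5), (5, 4)]
    )
    tree = _tree(f"({scrambled},(s6a,s6b),(s7a,s7b),og);")
    meta = _meta({f"sp{i}": [f"s{i}a", f"s{i}b"] for i in range(8)})
    report = discrimination_report(tree, meta, "two-pass")
    assert report.rate == 25.0


def test_rate_grid_for_eight_species():
    # with 8 ingroup species the rate is always a multiple of 12.5
    newick = "(" + ",".join(f"(s{i}a,s{i}b)" for i in range(8)) + ",og);"
    meta = _meta({f"sp{i}": [f"s{i}a", f"s{i}b"] for i in range(8)})
    report = discrimination_report(_tree(newick), meta, "grid")
    assert report.rate in {i * 12.5 for i in range(9)}


def test_singletons_flagged_trivial_and_outgroup_excluded():
    tree = _tree("((s0a,s0b),solo,og);")
    meta = _meta({"sp0": ["s0a", "s0b"], "sp1": ["solo"]})
    report = discrimination_report(tree, meta, "trivial")
    assert report.per_species["sp1"].trivial
    assert report.per_species["sp1"].monophyletic
    assert "outsp" not in report.per_species
    assert report.rate == 100.0


def test_group_verdicts_score_named_sample_sets():
    tree = _tree("(((g1,g2),(a1,a2)),og);")
    meta = [
        SampleMetadata("g1", "spG1", "ingroup", "genuine"),
        SampleMetadata("g2", "spG2", "ingroup", "genuine"),
        SampleMetadata("a1", "spA1", "ingroup", "adulterant"),
        SampleMetadata("a2", "spA2", "ingroup", "adulterant"),
        SampleMetadata("og", "outsp", "outgroup", "outgroup"),
    ]
    report = discrimination_report(
        tree, meta, "groups",
        groups={"genuine": ["g1", "g2"], "adulterant": ["a1", "a2"],
                "mixed": ["g1", "a1"]},
    )
    assert report.group_verdicts == {"genuine": True, "adulterant": True, "mixed": False}


def test_report_invariant_under_consistent_relabeling():
    tree = _tree("((s0a,(s1a,s1b)),s0b,og);")
    meta = _meta({"sp0": ["s0a", "s0b"], "sp1": ["s1a", "s1b"]})
    base = discrimination_report(tree, meta, "x")

    mapping = {"s0a": "p", "s0b": "q", "s1a": "r", "s1b": "s", "og": "og2"}
    relabeled = _tree("((p,(r,s)),q,og2);")
    meta2 = [
        SampleMetadata(mapping[m.sample_id], m.species, m.role, m.group) for m in meta
    ]
    again = discrimination_report(relabeled, meta2, "x")
    assert {sp: v.monophyletic for sp, v in base.per_species.items()} == {
        sp: v.monophyletic for sp, v in again.per_species.items()
    }
    assert base.rate == again.rate
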