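import dendropy
import numpy as np
import pytest

from barcodiv.distances import DistanceMatrix, p_distance_matrix
from barcodiv.errors import ParameterError
from barcodiv.njtree import (
    _unrooted_splits,
    bootstrap_support,
    neighbor_joining,
    root_with_outgroup,
    tree_path_distances,
)
from barcodiv.seqio import Alignment, SequenceRecord
from barcodiv.simulate import SimConfig, simulate_dataset

from oracles import brute_force_topology, random_additive_matrix


def _dm(labels, matrix):
    d = np.asarray(matrix, dtype=float)
    return DistanceMatrix(list(labels), d, np.ones_like(d, dtype=np.int64))


# ---------------------------------------------------------------------------


def test_three_taxon_closed_form():
    d = [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
    tree = neighbor_joining(_dm("abc", d))
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_additive_four_taxon_tree_recovered_exactly():
    # tree ((A:1,B:2):1,(C:3,D:1):1): internal edge 2 after unrooting
    labels = ["A", "B", "C", "D"]
    d = [
        [0, 3, 6, 4],
        [3, 0, 7, 5],
        [6, 7, 0, 4],
        [4, 5, 4, 0],
    ]
    dm = _dm(labels, d)
    tree = neighbor_joining(dm)
    assert _unrooted_splits(tree) == {frozenset({"C", "D"})}
    recovered = tree_path_distances(tree)
    order = [recovered.sample_ids.index(l) for l in labels]
    assert np.allclose(recovered.d[np.ix_(order, order)], d)
    pendant = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert pendant == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 1})


def test_additive_five_taxon_path_lengths_reproduced():
    rng = np.random.default_rng(31)
    labels = ["A", "B", "C", "D", "E"]
    d, true_splits = random_additive_matrix(labels, rng)
    tree = neighbor_joining(_dm(labels, d))
    assert _unrooted_splits(tree) == true_splits
    recovered = tree_path_distances(tree)
    order = [recovered.sample_ids.index(l) for l in labels]
    assert np.allclose(recovered.d[np.ix_(order, order)], d, atol=1e-9)


@pytest.mark.parametrize("n_taxa", [5, 6])
def test_nj_agrees_with_brute_force_search_on_additive_matrices(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    labels = [f"t{i}" for i in range(n_taxa)]
    for _ in range(5):
        d, _ = random_additive_matrix(labels, rng)
        nj_splits = _unrooted_splits(neighbor_joining(_dm(labels, d)))
        assert nj_splits == brute_force_topology(labels, d)


def test_nj_topology_matches_independent_implementation():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(77)
    labels = [f"x{i}" for i in range(7)]
    for _ in range(5):
        d, _ = random_additive_matrix(labels, rng)
        d += rng.uniform(0, 0.05, d.shape)  # perturb off additivity
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ours = _unrooted_splits(neighbor_joining(_dm(labels, d)))
        ref_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ref = dendropy.Tree.get(data=str(ref_tree), schema="newick")
        theirs = _unrooted_splits(ref)
        assert ours == theirs


def test_duplicate_samples_become_zero_length_siblings():
    aln = Alignment(
        [
            SequenceRecord("d1", "ACGTACGTAA"),
            SequenceRecord("d2", "ACGTACGTAA"),
            SequenceRecord("e", "ACCTACGAAA"),
            SequenceRecord("f", "TTTTACGAAA"),
        ]
    )
    tree = neighbor_joining(p_distance_matrix(aln))
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    assert leaves["d1"].parent_node is leaves["d2"].parent_node
    assert leaves["d1"].edge.length == pytest.approx(0.0)
    assert leaves["d2"].edge.length == pytest.approx(0.0)


def test_small_matrices_rejected():
    with pytest.raises(ParameterError):
        neighbor_joining(_dm("ab", [[0, 1], [1, 0]]))


def test_root_with_single_outgroup_and_idempotence():
    labels = ["A", "B", "C", "D"]
    d = [[0, 3, 6, 4], [3, 0, 7, 5], [6, 7, 0, 4], [4, 5, 4, 0]]
    tree = neighbor_joining(_dm(labels, d))
    rooted = root_with_outgroup(tree, ["D"])
    assert rooted.is_rooted
    children = rooted.seed_node.child_nodes()
    assert len(children) == 2
    sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
    assert frozenset({"D"}) in sides
    # re-rooting on the same outgroup leaves the topology unchanged
    again = root_with_outgroup(rooted, ["D"])
    assert {frozenset(l.taxon.label for l in c.leaf_iter())
            for c in again.seed_node.child_nodes()} == set(sides)
    # leaf set preserved through build/root
    assert {l.taxon.label for l in rooted.leaf_node_iter()} == set(labels)


def test_rooting_on_all_leaves_is_an_error():
    labels = ["A", "B", "C"]
    tree = neighbor_joining(_dm(labels, [[0, 1, 2], [1, 0, 3], [2, 3, 0]]))
    with pytest.raises(ParameterError):
        root_with_outgroup(tree, labels)


def test_non_monophyletic_outgroup_roots_at_mrca_with_warning(caplog):
    newick = "((A:1,B:1):1,(C:1,D:1):1,E:2);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    with caplog.at_level("WARNING"):
        rooted = root_with_outgroup(tree, ["A", "C"])
    assert rooted.is_rooted
    assert any("not monophyletic" in r.message for r in caplog.records)


def test_bootstrap_is_deterministic_and_confident_on_clean_clades():
    cfg = SimConfig(seed=11, n_species=3, individuals_per_species=3,
                    seq_length=4000, inter_divergence=0.05, intra_divergence=0.002)
    aln, meta, _ = simulate_dataset(cfg)
    t1 = bootstrap_support(aln, meta, replicates=100, seed=5)
    t2 = bootstrap_support(aln, meta, replicates=100, seed=5)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    by_species = {}
    for m in meta:
        by_species.setdefault(m.species, set()).add(m.sample_id)
    supports = []
    for node in t1.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        for sp, members in by_species.items():
            if sp != "outgroup" and below == members:
                supports.append(int(node.label))
    assert supports and all(s >= 95 for s in supports)

    # leaf set preserved through bootstrap annotation
    assert {l.taxon.label for l in t1.leaf_node_iter()} == {m.sample_id for m in meta}
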