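"""Neighbor-joining tree construction, outgroup rooting, and bootstrap support.

The agglomeration follows Saitou & Nei's algorithm: at each step the pair
(i, j) minimizing Q(i, j) = (m - 2) d(i, j) - R_i - R_j is joined (m = number
of active nodes, R_i = row sum of the working matrix), pendant branch lengths
come from the standard two-point formulas, and the reduced matrix uses
d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2.  Ties in Q are broken by the
smallest (i, j) index pair in input order, and negative branch lengths are
clamped to zero without redistributing the deficit.  Trees are dendropy
objects throughout; the unrooted NJ result has a trifurcating seed node.
"""

from __future__ import annotations

import logging
from typing import Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix, p_distance_matrix
from .errors import ParameterError, UndefinedPairError, ValidationError
from .seqio import Alignment, SampleMetadata, SequenceRecord

log = logging.getLogger(__name__)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build the unrooted neighbor-joining tree of a distance matrix."""
    n = dm.n
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dm.d, dm.d.T):
        raise ValidationError("distance matrix must be symmetric")

    taxa = dendropy.TaxonNamespace(dm.sample_ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for sid in dm.sample_ids:
        node = dendropy.Node(taxon=taxa.get_taxon(sid))
        nodes.append(node)

    active = list(range(n))  # indices into `nodes`; appended nodes keep input order
    D = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i != j}

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))] if (min(i, j), max(i, j)) in D else D[(i, j)]

    next_index = n
    while len(active) > 3:
        m = len(active)
        rowsum = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = None
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                q = (m - 2) * dist(i, j) - rowsum[i] - rowsum[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        dij = dist(i, j)
        li = dij / 2 + (rowsum[i] - rowsum[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            log.debug("clamping negative NJ branch length at join (%d,%d)", i, j)
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes.append(parent)

        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) + dist(j, k) - dij) / 2
            D[(min(k, next_index), max(k, next_index))] = duk
        active = [k for k in active if k not in (i, j)] + [next_index]
        next_index += 1

    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def root_with_outgroup(tree: dendropy.Tree, outgroup_leaves: Sequence[str]) -> dendropy.Tree:
    """Root a tree on the edge subtending the outgroup, splitting it midway.

    For a single outgroup leaf the root lands on its pendant edge; for a set,
    on the edge whose split separates exactly that set.  A non-monophyletic
    outgroup set falls back to the edge above its MRCA (warning logged).
    """
    outgroup = frozenset(outgroup_leaves)
    if not outgroup:
        raise ParameterError("empty outgroup set")
    tree = tree.clone(depth=1)
    all_leaves = _leaf_labels(tree.seed_node)
    unknown = outgroup - all_leaves
    if unknown:
        raise ValidationError(f"outgroup leaves not in tree: {sorted(unknown)}")
    if outgroup == all_leaves:
        raise ParameterError("outgroup set equals the full leaf set; cannot root")

    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = _leaf_labels(node)
        if below == outgroup or (all_leaves - below) == outgroup:
            target = node
            break
    if target is None:
        tree.is_rooted = True  # MRCA below is relative to the current seed node
        mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(l) for l in outgroup])
        log.warning("outgroup %s is not monophyletic; rooting above its MRCA", sorted(outgroup))
        target = mrca if mrca is not tree.seed_node else next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label in outgroup
        )

    edge_len = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=edge_len / 2, length2=edge_len / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def _unrooted_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each encoded by its smaller/canonical side."""
    all_leaves = _leaf_labels(tree.seed_node)
    anchor = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = _leaf_labels(node)
        side = below if anchor not in below else all_leaves - below
        if len(side) >= 2 and len(all_leaves - side) >= 2:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: Alignment,
    metadata: Sequence[SampleMetadata] | None = None,
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> dendropy.Tree:
    """NJ tree of the full alignment annotated with bootstrap support.

    Columns are resampled with replacement ``replicates`` times; each
    replicate is rebuilt with p-distance NJ and the support of an internal
    edge is the percentage of usable replicates containing its bipartition.
    Replicates in which some pair loses every comparable column are skipped
    with a warning and removed from the denominator.  If metadata designates
    an outgroup present in the alignment, the returned tree is rooted on it.
    """
    if replicates < 1:
        raise ParameterError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    base_dm = p_distance_matrix(alignment, deletion=deletion)
    tree = neighbor_joining(base_dm)
    all_leaves = _leaf_labels(tree.seed_node)
    if metadata is not None:
        og = [m.sample_id for m in metadata
              if m.role == "outgroup" and m.sample_id in all_leaves]
        if og and frozenset(og) != all_leaves:
            tree = root_with_outgroup(tree, og)

    counts: dict[frozenset[str], int] = {s: 0 for s in _unrooted_splits(tree)}
    usable = 0
    length = alignment.length
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = Alignment(
            [
                SequenceRecord(r.id, "".join(r.seq[c] for c in cols))
                for r in alignment.records
            ]
        )
        try:
            rep_dm = p_distance_matrix(resampled, deletion=deletion)
        except UndefinedPairError as exc:
            log.warning("bootstrap replicate skipped: %s", exc)
            continue
        usable += 1
        rep_splits = _unrooted_splits(neighbor_joining(rep_dm))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    if usable == 0:
        raise ParameterError("no usable bootstrap replicates")
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = _leaf_labels(node)
        side = below if anchor not in below else all_leaves - below
        if side in counts:
            node.label = str(round(100 * counts[side] / usable))
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(labels)
    d = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d, np.ones((n, n), dtype=np.int64))
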