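"""Synthetic multi-species sequence datasets with known ground truth.

The generator emulates the structure of a plastome barcoding study: a small
set of closely related species, a handful of individuals per species, and a
single more distant outgroup.  A random bifurcating species tree is drawn
and rescaled so that the expected divergence between individuals of
different species matches ``inter_divergence``; within each species,
individuals radiate from the species ancestor on a star with pendant
branches of ``intra_divergence / 2`` (so within-species pairs diverge by
``intra_divergence``).  Substitutions follow the Jukes-Cantor model realised
as Poisson substitution events, each replacing a base by one of the three
alternatives uniformly; at the divergences typical of congeneric plastomes
(< 0.03 substitutions/site) multiple hits are negligible.  Indels are
simulated as per-lineage deletion events with geometric lengths, so column
homology is known by construction and the emitted FASTA is a true alignment.

One species can be made polyphyletic: its individuals are split between two
donor lineages, grafted midway along each donor's terminal branch, mirroring
the situation where one nominal species contains two independent plastid
lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .errors import ParameterError, ValidationError
from .seqio import Alignment, SampleMetadata, SequenceRecord

_BASES = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T
_GAP = np.uint8(ord("-"))

OUTGROUP_SPECIES = "outgroup"


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Divergences are expected substitutions per site; the defaults sit inside
    the ranges seen for congeneric plastid datasets (intraspecific p-distance
    roughly 0-0.005, interspecific roughly 0.001-0.03).
    """

    seed: int
    n_species: int = 8
    individuals_per_species: int | Sequence[int] = 4
    seq_length: int = 20_000
    inter_divergence: float = 0.02
    intra_divergence: float = 0.002
    indel_rate: float = 0.0  # deletion events per site per lineage
    indel_mean_length: float = 3.0
    outgroup_divergence: float = 0.03
    n_genuine: int = 5  # leading species labelled "genuine"; the rest "adulterant"
    polyphyletic_species: Optional[str] = None
    donor_lineages: Optional[tuple[str, str]] = None
    hotspot: Optional[tuple[int, int, float]] = None  # (start, end, rate multiplier)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if self.n_species < 1:
            raise ParameterError("need at least one species")
        if self.seq_length < 1:
            raise ParameterError("seq_length must be >= 1")
        if not (0 <= self.intra_divergence < self.inter_divergence):
            raise ParameterError(
                "require 0 <= intra_divergence < inter_divergence "
                f"(got {self.intra_divergence} vs {self.inter_divergence})"
            )
        counts = self.individual_counts()
        if len(counts) != self.n_species or any(c < 1 for c in counts):
            raise ParameterError("individuals_per_species inconsistent with n_species")
        if (self.polyphyletic_species is None) != (self.donor_lineages is None):
            raise ParameterError(
                "polyphyletic_species and donor_lineages must be given together"
            )
        if self.polyphyletic_species is not None:
            names = self.species_names()
            a, b = self.donor_lineages
            if self.polyphyletic_species not in names:
                raise ParameterError(f"unknown polyphyletic species {self.polyphyletic_species!r}")
            if a == b or a not in names or b not in names or self.polyphyletic_species in (a, b):
                raise ParameterError("donor lineages must be two distinct other species")
        if self.hotspot is not None:
            s, e, m = self.hotspot
            if not (1 <= s <= e <= self.seq_length) or m <= 0:
                raise ParameterError(f"bad hotspot specification {self.hotspot}")

    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    def individual_counts(self) -> list[int]:
        if isinstance(self.individuals_per_species, int):
            return [self.individuals_per_species] * self.n_species
        return list(self.individuals_per_species)


class _Node:
    __slots__ = ("name", "blen", "children", "species")

    def __init__(self, name: str, blen: float = 0.0, species: str | None = None):
        self.name = name
        self.blen = blen
        self.children: list[_Node] = []
        self.species = species

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated alignment."""

    true_tree: dendropy.Tree
    sample_assignments: list[SampleMetadata]
    expected_monophyly: dict[str, bool]
    branch_substitutions: dict[str, int] = field(default_factory=dict)


def _random_species_topology(names: Sequence[str], rng: np.random.Generator) -> _Node:
    """Random bifurcating tree over species tips via random sequential joins.

    Branch lengths are uniform(0.5, 1.5) before rescaling: species are
    genuinely distinct lineages, with no near-zero stem branches that would
    make a species unidentifiable by construction.
    """
    lineages = [_Node(n, blen=float(rng.uniform(0.5, 1.5))) for n in names]
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = _Node(f"anc{counter}", blen=float(rng.uniform(0.5, 1.5)))
        counter += 1
        parent.children = [a, b]
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    root = lineages[0]
    root.blen = 0.0
    return root


def _tip_depths(node: _Node, depth: float = 0.0, out: dict[str, float] | None = None):
    if out is None:
        out = {}
    depth += node.blen
    if node.is_leaf():
        out[node.name] = depth
    for child in node.children:
        _tip_depths(child, depth, out)
    return out


def _pairwise_paths(root: _Node) -> list[float]:
    """All tip-tip path lengths (sum of branch lengths)."""
    paths: list[float] = []

    def collect(node: _Node) -> list[float]:
        # returns depths of tips below `node`, measured from node (excl. node.blen)
        if node.is_leaf():
            return [0.0]
        groups = []
        for child in node.children:
            groups.append([d + child.blen for d in collect(child)])
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        paths.append(a + b)
        return [d for g in groups for d in g]

    collect(root)
    return paths


def _scale(node: _Node, factor: float) -> None:
    node.blen *= factor
    for child in node.children:
        _scale(child, factor)


def _find_tip(root: _Node, name: str) -> tuple[_Node, _Node | None]:
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if node.name == name and node.is_leaf():
            return node, parent
        stack.extend((c, node) for c in node.children)
    raise KeyError(name)


def _prune_tip(root: _Node, name: str) -> _Node:
    tip, parent = _find_tip(root, name)
    if parent is None:
        raise ValidationError("cannot prune the root")
    parent.children.remove(tip)
    if len(parent.children) == 1:
        # splice out the now-unary parent: absorb it into its surviving child
        only = parent.children[0]
        parent.name = only.name
        parent.blen = parent.blen + only.blen
        parent.species = only.species
        parent.children = only.children
    return root


def simulate_dataset(config: SimConfig) -> tuple[Alignment, list[SampleMetadata], SimTruth]:
    """Generate one aligned dataset with metadata and ground truth.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.species_names()
    counts = dict(zip(names, config.individual_counts()))
    L = config.seq_length

    # species tree, rescaled so individual-level interspecific divergence
    # (species path + two intra/2 pendants) targets inter_divergence
    root = _random_species_topology(names, rng)
    if config.n_species > 1:
        paths = _pairwise_paths(root)
        target = config.inter_divergence - config.intra_divergence
        _scale(root, target / float(np.mean(paths)))
    depths = _tip_depths(root)
    mean_depth = float(np.mean(list(depths.values())))

    # outgroup joins above the ingroup root
    top = _Node("root", 0.0)
    og_branch = max(config.outgroup_divergence - mean_depth, config.outgroup_divergence / 2)
    og_tip = _Node("outgroup_tip", og_branch, species=OUTGROUP_SPECIES)
    top.children = [root, og_tip]

    # polyphyletic species: drop its tip, graft two half-cohorts midway along
    # the donors' terminal branches (sister to each donor, not inside it)
    poly = config.polyphyletic_species
    if poly is not None:
        _prune_tip(top, poly)
        cohort = counts[poly]
        first_half = (cohort + 1) // 2
        splits = [first_half, cohort - first_half]
        offset = 0
        for donor, m in zip(config.donor_lineages, splits):
            if m == 0:
                continue
            tip, parent = _find_tip(top, donor)
            half = tip.blen / 2
            knee = _Node(f"graft_{donor}", half)
            tip.blen = half
            parent.children[parent.children.index(tip)] = knee
            sub_anc = _Node(f"{poly}_anc_{donor}", half, species=None)
            knee.children = [tip, sub_anc]
            for k in range(m):
                ind = _Node(f"{poly}_{offset + k + 1}", config.intra_divergence / 2, species=poly)
                sub_anc.children.append(ind)
            offset += m

    # attach individuals of ordinary species as a star below each species tip
    for sp in names:
        if sp == poly:
            continue
        tip, _ = _find_tip(top, sp)
        tip.species = None
        for k in range(counts[sp]):
            tip.children.append(_Node(f"{sp}_{k + 1}", config.intra_divergence / 2, species=sp))
    og_tip.children.append(_Node("out_1", 0.0, species=OUTGROUP_SPECIES))
    og_tip.species = None

    # per-site substitution rate weights (optional hotspot block)
    weights = np.ones(L)
    if config.hotspot is not None:
        s, e, m = config.hotspot
        weights[s - 1 : e] = m
    w_total = float(weights.sum())
    site_p = weights / w_total

    branch_subs: dict[str, int] = {}
    sequences: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}

    root_seq = rng.integers(0, 4, size=L).astype(np.int8)

    def evolve(node: _Node, seq: np.ndarray, mask: np.ndarray) -> None:
        if node.blen > 0:
            n_events = rng.poisson(node.blen * w_total)
            if n_events:
                seq = seq.copy()
                sites = rng.choice(L, size=n_events, p=site_p)
                shifts = rng.integers(1, 4, size=n_events).astype(np.int8)
                for site, shift in zip(sites, shifts):
                    seq[site] = (seq[site] + shift) % 4
            branch_subs[node.name] = int(n_events)
        else:
            branch_subs[node.name] = 0
        if config.indel_rate > 0 and node.blen > 0:
            n_indels = rng.poisson(config.indel_rate * L)
            if n_indels:
                mask = mask.copy()
                starts = rng.integers(0, L, size=n_indels)
                lens = rng.geometric(1.0 / config.indel_mean_length, size=n_indels)
                for s0, ln in zip(starts, lens):
                    mask[s0 : s0 + ln] = True
        if node.is_leaf():
            sequences[node.name] = seq
            masks[node.name] = mask
        for child in node.children:
            evolve(child, seq, mask)

    evolve(top, root_seq, np.zeros(L, dtype=bool))

    # assemble records in metadata order: species blocks, then the outgroup
    metadata: list[SampleMetadata] = []
    records: list[SequenceRecord] = []
    for i, sp in enumerate(names):
        group = "genuine" if i < config.n_genuine else "adulterant"
        for k in range(counts[sp]):
            sid = f"{sp}_{k + 1}"
            metadata.append(SampleMetadata(sid, sp, "ingroup", group))
            chars = _BASES[sequences[sid]]
            chars = np.where(masks[sid], _GAP, chars)
            records.append(SequenceRecord(sid, chars.tobytes().decode("ascii")))
    metadata.append(SampleMetadata("out_1", OUTGROUP_SPECIES, "outgroup", "outgroup"))
    chars = np.where(masks["out_1"], _GAP, _BASES[sequences["out_1"]])
    records.append(SequenceRecord("out_1", chars.tobytes().decode("ascii")))

    alignment = Alignment(records)
    expected_monophyly = {sp: sp != poly for sp in names}
    truth = SimTruth(
        true_tree=_to_dendropy(top),
        sample_assignments=metadata,
        expected_monophyly=expected_monophyly,
        branch_substitutions=branch_subs,
    )
    return alignment, metadata, truth


def _to_dendropy(root: _Node) -> dendropy.Tree:
    leaf_names = [n.name for n in _iter_leaves(root)]
    taxa = dendropy.TaxonNamespace(leaf_names)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def convert(node: _Node) -> dendropy.Node:
        dn = dendropy.Node()
        dn.edge.length = node.blen
        if node.is_leaf():
            dn.taxon = taxa.get_taxon(node.name)
        else:
            dn.label = node.name
            for child in node.children:
                dn.add_child(convert(child))
        return dn

    tree.seed_node = convert(root)
    tree.is_rooted = True
    return tree


def _iter_leaves(node: _Node):
    if node.is_leaf():
        yield node
    for child in node.children:
        yield from _iter_leaves(child)


def true_pairwise_divergence(truth: SimTruth) -> dict[tuple[str, str], float]:
    """Expected substitutions/site between every pair of simulated samples."""
    pdm = truth.true_tree.phylogenetic_distance_matrix()
    taxa = list(truth.true_tree.taxon_namespace)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[(a.label, b.label)] = float(pdm.distance(a, b))
    return out


def expected_discrimination(truth: SimTruth) -> float:
    """Discrimination rate implied by the ground truth (percent)."""
    values = list(truth.expected_monophyly.values())
    if not values:
        raise ValidationError("truth carries no species")
    return 100.0 * sum(values) / len(values)


def jukes_cantor_p(d: float) -> float:
    """Expected p-distance after divergence ``d`` substitutions/site under JC."""
    return 0.75 * (1.0 - float(np.exp(-4.0 * d / 3.0)))
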