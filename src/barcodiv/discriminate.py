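"""Tree-based species discrimination by the monophyly criterion.

A species counts as successfully discriminated when all of its individuals
form a monophyletic group on the rooted tree.  The per-dataset discrimination
rate is the percentage of ingroup species that pass; the outgroup is excluded
from the rate.  Species represented by a single individual cannot fail the
criterion and are flagged as trivially monophyletic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .errors import ParameterError, ValidationError
from .seqio import SampleMetadata


@dataclass
class SpeciesVerdict:
    monophyletic: bool
    n_individuals: int
    trivial: bool  # single-individual species pass vacuously


@dataclass
class DiscriminationReport:
    """Per-species monophyly verdicts and the aggregate discrimination rate."""

    dataset_name: str
    per_species: dict[str, SpeciesVerdict]
    rate: float  # percentage of ingroup species monophyletic
    group_verdicts: dict[str, bool] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "dataset": self.dataset_name,
            "rate": self.rate,
            "per_species": {
                sp: {
                    "monophyletic": v.monophyletic,
                    "n_individuals": v.n_individuals,
                    "trivial": v.trivial,
                }
                for sp, v in self.per_species.items()
            },
            "group_verdicts": self.group_verdicts,
        }


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, leaf_set: Iterable[str]) -> bool:
    """True iff the MRCA of ``leaf_set`` subtends exactly that set.

    The test is root-dependent; the tree should be rooted (e.g. on the
    outgroup) before calling.  Singleton sets are monophyletic by definition.
    """
    wanted = set(leaf_set)
    if not wanted:
        raise ParameterError("empty leaf set")
    labels = _leaf_labels(tree)
    unknown = wanted - labels
    if unknown:
        raise ValidationError(f"leaves not in tree: {sorted(unknown)}")
    if len(wanted) == 1:
        return True
    taxa = [tree.taxon_namespace.get_taxon(l) for l in wanted]
    mrca = tree.mrca(taxa=taxa)
    below = {lf.taxon.label for lf in mrca.leaf_iter()}
    return below == wanted


def discrimination_report(
    tree: dendropy.Tree,
    metadata: Sequence[SampleMetadata],
    dataset_name: str = "",
    groups: Mapping[str, Iterable[str]] | None = None,
) -> DiscriminationReport:
    """Score every ingroup species for monophyly and aggregate the rate.

    ``groups`` optionally names extra sample-id sets (e.g. "adulterants") to
    be scored for monophyly as a whole, supporting coarser verdicts such as
    a barcode that separates adulterant species from the genuine medicine
    without resolving the genuine species individually.
    """
    leaves = _leaf_labels(tree)
    meta_by_id = {m.sample_id: m for m in metadata}
    missing = sorted(leaves - set(meta_by_id))
    if missing:
        raise ValidationError(f"tree leaves absent from metadata: {missing}")

    species_members: dict[str, list[str]] = {}
    for leaf in leaves:
        m = meta_by_id[leaf]
        if m.role == "outgroup":
            continue
        species_members.setdefault(m.species, []).append(leaf)
    if not species_members:
        raise ValidationError("no ingroup species present on the tree")

    per_species: dict[str, SpeciesVerdict] = {}
    for species in sorted(species_members):
        members = species_members[species]
        mono = is_monophyletic(tree, members)
        per_species[species] = SpeciesVerdict(
            monophyletic=mono, n_individuals=len(members), trivial=len(members) == 1
        )

    n_mono = sum(v.monophyletic for v in per_species.values())
    rate = 100.0 * n_mono / len(per_species)

    group_verdicts = {}
    if groups:
        for name, ids in groups.items():
            ids = [i for i in ids if i in leaves]
            if ids:
                group_verdicts[name] = is_monophyletic(tree, ids)

    return DiscriminationReport(
        dataset_name=dataset_name,
        per_species=per_species,
        rate=rate,
        group_verdicts=group_verdicts,
    )
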