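"""Alignment variability statistics.

Computes the classic DnaSP/MEGA-style summary of an aligned dataset: variable
and parsimony-informative sites, the minimum number of mutations eta, indel
events, GC content, and nucleotide diversity (pi).  Gaps and IUPAC ambiguity
codes are treated as missing data throughout; pi uses complete deletion by
default (every column containing a gap or ambiguous base in any sequence is
dropped before pairwise comparison), matching the common DnaSP convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedInputError, ValidationError
from .seqio import Alignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")

INVARIANT = "invariant"
VARIABLE = "variable"
PARSIMONY_INFORMATIVE = "parsimony_informative"


@dataclass
class SiteStatsRecord:
    """One row of the variability summary for a dataset."""

    n_sites: int
    n_variable: int
    n_parsimony_informative: int
    n_mutations: int
    n_indels: int
    gc_content: float
    pi: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_parsimony_informative <= self.n_variable <= self.n_sites):
            raise ValidationError("site counts violate informative <= variable <= sites")
        if self.n_mutations < self.n_variable:
            raise ValidationError("mutation count below variable-site count")
        if self.pi < 0:
            raise ValidationError("negative nucleotide diversity")


def _base_counts(arr: np.ndarray) -> np.ndarray:
    """Per-column counts of each unambiguous base; shape (4, n_columns)."""
    return np.stack([(arr == b).sum(axis=0) for b in _BASES])


def classify_sites(alignment: Alignment) -> list[str]:
    """Label each column invariant / variable / parsimony_informative.

    A column is variable when at least two distinct unambiguous bases occur
    among its non-gap, non-ambiguous characters, and parsimony-informative
    when at least two distinct bases each occur in at least two sequences.
    Informative implies variable; all-gap or single-state columns are
    invariant.
    """
    counts = _base_counts(alignment.to_array())
    n_states = (counts > 0).sum(axis=0)
    n_doubled = (counts >= 2).sum(axis=0)
    labels = []
    for k, k2 in zip(n_states, n_doubled):
        if k < 2:
            labels.append(INVARIANT)
        elif k2 >= 2:
            labels.append(PARSIMONY_INFORMATIVE)
        else:
            labels.append(VARIABLE)
    return labels


def count_variable_sites(alignment: Alignment) -> tuple[int, int]:
    """(n_variable, n_parsimony_informative) column counts."""
    labels = classify_sites(alignment)
    informative = labels.count(PARSIMONY_INFORMATIVE)
    return labels.count(VARIABLE) + informative, informative


def count_mutations(alignment: Alignment) -> int:
    """Minimum mutation count eta: sum over columns of (distinct bases - 1)."""
    n_states = (_base_counts(alignment.to_array()) > 0).sum(axis=0)
    return int(np.maximum(n_states - 1, 0).sum())


def count_indel_events(alignment: Alignment) -> int:
    """Number of distinct indel events in the alignment.

    An event is a maximal run of gap characters in one sequence, identified
    by its 1-based (start, end) column span; identical spans shared by
    several sequences count once, while nested or overlapping runs with
    different endpoints count separately.
    """
    gap = alignment.to_array() == _GAP
    events: set[tuple[int, int]] = set()
    for row in gap:
        padded = np.concatenate(([False], row, [False]))
        flips = np.flatnonzero(padded[1:] != padded[:-1])
        for start, end in zip(flips[::2], flips[1::2]):
            events.add((int(start) + 1, int(end)))
    return len(events)


def gc_content(alignment: Alignment) -> float:
    """(G+C) / (A+C+G+T) over the whole alignment, ignoring gaps/ambiguity."""
    counts = _base_counts(alignment.to_array()).sum(axis=1)
    total = counts.sum()
    if total == 0:
        raise UndefinedInputError("no unambiguous bases; GC content undefined")
    return float((counts[1] + counts[2]) / total)  # order A,C,G,T


def nucleotide_diversity(alignment: Alignment, deletion: str = "complete") -> float:
    """Nucleotide diversity pi: the mean pairwise difference proportion.

    With complete deletion (default) only columns free of gaps and ambiguity
    in every sequence are compared, and pi equals the average over all
    sequence pairs of (differing shared columns) / (shared columns).  This is
    computed from per-column base counts: at a column with n scored
    sequences, the number of differing pairs is C(n,2) - sum_b C(count_b, 2).
    """
    arr = alignment.to_array()
    n = arr.shape[0]
    counts = _base_counts(arr)
    if deletion == "complete":
        keep = counts.sum(axis=0) == n
        if not keep.any():
            raise UndefinedInputError(
                "no column is free of gaps/ambiguity in every sequence; pi undefined"
            )
        counts = counts[:, keep]
        n_pairs = n * (n - 1) // 2
        diff_pairs = n_pairs - (counts * (counts - 1) // 2).sum(axis=0)
        return float(diff_pairs.sum() / (n_pairs * counts.shape[1]))
    if deletion == "pairwise":
        # mean pairwise p-distance, each pair over its own comparable columns
        from .distances import p_distance_matrix

        dm = p_distance_matrix(alignment, deletion="pairwise")
        iu = np.triu_indices(n, k=1)
        return float(dm.d[iu].mean())
    raise ValueError(f"unknown deletion mode {deletion!r}")


def summarize(alignment: Alignment) -> SiteStatsRecord:
    """Aggregate all variability statistics for one aligned dataset."""
    n_variable, n_informative = count_variable_sites(alignment)
    return SiteStatsRecord(
        n_sites=alignment.length,
        n_variable=n_variable,
        n_parsimony_informative=n_informative,
        n_mutations=count_mutations(alignment),
        n_indels=count_indel_events(alignment),
        gc_content=gc_content(alignment),
        pi=nucleotide_diversity(alignment),
    )
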