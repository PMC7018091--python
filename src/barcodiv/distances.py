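"""Pairwise p-distances and DNA barcoding-gap analysis.

The p-distance between two aligned sequences is the proportion of compared
columns at which they differ; columns with a gap or ambiguous base in either
sequence (pairwise deletion, the default) or in any sequence (complete
deletion) are excluded.  Distances are partitioned into intra- and
inter-specific sets using the sample metadata, summarized as ranges and
mean +/- SE, and binned on a shared grid for barcoding-gap histograms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UndefinedInputError, UndefinedPairError, ValidationError
from .seqio import Alignment, SampleMetadata

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distances with per-pair compared-column counts."""

    sample_ids: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample count")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix diagonal is not zero")
        # p-distances live in [0,1]; the container also holds tree path
        # lengths, so only nonnegativity is enforced structurally
        if (self.d < 0).any():
            raise ValidationError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(
            list(ids), self.d[np.ix_(idx, idx)], self.comparable_sites[np.ix_(idx, idx)]
        )


@dataclass
class GapReport:
    """Intra-/inter-specific distance summary and barcoding-gap assessment."""

    intra: np.ndarray
    inter: np.ndarray
    intra_range: tuple[float, float] | None
    inter_range: tuple[float, float] | None
    intra_mean_se: tuple[float, float] | None
    inter_mean_se: tuple[float, float] | None
    strict_gap: bool
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    intra_hist: np.ndarray = field(default_factory=lambda: np.array([]))
    inter_hist: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        return {
            "n_intra": int(self.intra.size),
            "n_inter": int(self.inter.size),
            "intra_range": self.intra_range,
            "inter_range": self.inter_range,
            "intra_mean_se": self.intra_mean_se,
            "inter_mean_se": self.inter_mean_se,
            "strict_gap": self.strict_gap,
            "bin_edges": self.bin_edges.tolist(),
            "intra_hist": self.intra_hist.tolist(),
            "inter_hist": self.inter_hist.tolist(),
        }


def p_distance_matrix(alignment: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """All pairwise p-distances of an alignment.

    Parameters
    ----------
    alignment
        Gapped sequence matrix with >= 2 sequences.
    deletion
        ``"pairwise"`` (drop columns missing in either sequence of a pair) or
        ``"complete"`` (drop columns missing in any sequence).
    """
    arr = alignment.to_array()
    n, length = arr.shape
    valid = np.isin(arr, _BASES)
    if deletion == "complete":
        keep = valid.all(axis=0)
        if not keep.any():
            raise UndefinedInputError("complete deletion leaves zero columns")
        arr = arr[:, keep]
        valid = valid[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        comp[i, i] = valid[i].sum()
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise UndefinedPairError(
                    f"pair ({alignment.ids[i]!r}, {alignment.ids[j]!r}) shares no comparable columns"
                )
            mism = int((arr[i] != arr[j])[both].sum())
            d[i, j] = d[j, i] = mism / m
            comp[i, j] = comp[j, i] = m
    return DistanceMatrix(list(alignment.ids), d, comp)


def _mean_se(values: np.ndarray) -> tuple[float, float] | None:
    if values.size == 0:
        return None
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, se


def partition_distances(
    dm: DistanceMatrix,
    metadata: Sequence[SampleMetadata],
    exclude_outgroup: bool = True,
    bin_width: float = 0.001,
) -> GapReport:
    """Split pairwise distances into intra- and inter-specific sets.

    A pair is intraspecific iff both samples carry the same species label.
    The outgroup is excluded by default, matching the convention that the
    barcoding gap describes the focal species and their adulterants only.
    SE is the sample standard deviation over pairs divided by sqrt(n_pairs).
    """
    species = {m.sample_id: m.species for m in metadata}
    roles = {m.sample_id: m.role for m in metadata}
    missing = [s for s in dm.sample_ids if s not in species]
    if missing:
        raise ValidationError(f"samples absent from metadata: {missing}")

    ids = [
        s for s in dm.sample_ids if not (exclude_outgroup and roles[s] == "outgroup")
    ]
    intra, inter = [], []
    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            value = dm.pair(a, b)
            (intra if species[a] == species[b] else inter).append(value)
    intra_arr = np.asarray(intra, dtype=float)
    inter_arr = np.asarray(inter, dtype=float)

    single = [
        sp
        for sp in sorted({species[s] for s in ids})
        if sum(species[s] == sp for s in ids) < 2
    ]
    if single:
        log.warning("species with a single sample contribute no intra pairs: %s", single)

    if intra_arr.size and inter_arr.size:
        strict_gap = bool(inter_arr.min() > intra_arr.max())
    else:
        strict_gap = False
        log.warning("intra or inter distance set empty; strict_gap reported as False")

    upper = float(max(intra_arr.max(initial=0.0), inter_arr.max(initial=0.0)))
    n_bins = max(1, math.ceil(round(upper / bin_width, 9)) or 1)
    edges = np.arange(n_bins + 1) * bin_width
    intra_hist, _ = np.histogram(intra_arr, bins=edges)
    inter_hist, _ = np.histogram(inter_arr, bins=edges)

    def _range(v: np.ndarray):
        return (float(v.min()), float(v.max())) if v.size else None

    return GapReport(
        intra=intra_arr,
        inter=inter_arr,
        intra_range=_range(intra_arr),
        inter_range=_range(inter_arr),
        intra_mean_se=_mean_se(intra_arr),
        inter_mean_se=_mean_se(inter_arr),
        strict_gap=strict_gap,
        bin_edges=edges,
        intra_hist=intra_hist,
        inter_hist=inter_hist,
    )


def gap_overlap_metric(report: GapReport) -> float:
    """Fraction of interspecific distances <= the largest intraspecific one.

    0 means the two distributions are cleanly separated (a distributional
    barcoding gap); 1 means every interspecific distance falls inside the
    intraspecific range.
    """
    if report.intra.size == 0 or report.inter.size == 0:
        raise UndefinedInputError("gap overlap undefined with an empty distance set")
    return float((report.inter <= report.intra.max()).mean())
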