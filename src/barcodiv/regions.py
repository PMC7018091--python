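"""Extraction of named barcode regions from annotated plastomes.

A region is a gene (concatenated exons, strand-corrected), an intron (the
sequence strictly between two consecutive exons of a gene), an intergenic
spacer (the sequence strictly between the facing boundaries of two anchor
features), or an explicit coordinate span.  Per-region sequence sets are
assembled across genomes for external alignment, and aligned blocks sharing
a sample set can be concatenated into combination datasets (e.g. the classic
trnH-psbA + matK + rbcL (+ ITS) combinations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .errors import EmptyRegionError, MissingFeatureError, ValidationError
from .seqio import Alignment, FeatureAnnotation, SampleMetadata, SequenceRecord

log = logging.getLogger(__name__)

MODES = ("gene", "intron", "spacer", "span")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV-", "TGCANYRSWMKVHDB-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RegionSpec:
    """Names one extractable region and how to locate it.

    ``anchors`` holds one feature name (gene/intron modes), two feature names
    (spacer mode), or a ``(start, end)`` coordinate pair (span mode).
    """

    name: str
    mode: str
    anchors: tuple

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown region mode {self.mode!r}")
        n = len(self.anchors)
        if self.mode in ("gene", "intron") and n != 1:
            raise ValidationError(f"{self.mode} mode needs exactly 1 anchor, got {n}")
        if self.mode == "spacer" and n != 2:
            raise ValidationError(f"spacer mode needs exactly 2 anchors, got {n}")
        if self.mode == "span":
            if n != 2 or not all(isinstance(a, int) for a in self.anchors):
                raise ValidationError("span mode needs integer (start, end) anchors")
            if not (1 <= self.anchors[0] <= self.anchors[1]):
                raise ValidationError(f"bad span {self.anchors}")


def _find_feature(
    annotations: Sequence[FeatureAnnotation], name: str, region: str
) -> FeatureAnnotation:
    """First genome-order occurrence of a named feature (case-insensitive).

    Features duplicated in the inverted repeats yield several occurrences;
    the first is used and a warning logged.
    """
    hits = [a for a in annotations if a.name.lower() == name.lower()]
    # prefer gene records over CDS/tRNA duplicates of the same locus
    genes = [a for a in hits if a.kind == "gene"]
    pool = genes or hits
    if not pool:
        raise MissingFeatureError(
            f"feature {name!r} required by region {region!r} not found in annotations"
        )
    pool = sorted(pool, key=lambda a: a.start)
    if len(pool) > 1:
        log.warning(
            "feature %r occurs %d times (IR duplicate?); using first at %d..%d",
            name,
            len(pool),
            pool[0].start,
            pool[0].end,
        )
    return pool[0]


def extract_region(
    record: SequenceRecord,
    annotations: Sequence[FeatureAnnotation],
    spec: RegionSpec,
) -> SequenceRecord:
    """Extract one region from one annotated genome; keeps the sample id."""
    seq = record.seq
    if spec.mode == "span":
        start, end = spec.anchors
        if end > len(seq):
            raise ValidationError(f"span {start}..{end} exceeds genome length {len(seq)}")
        sub = seq[start - 1 : end]
    elif spec.mode == "gene":
        feat = _find_feature(annotations, spec.anchors[0], spec.name)
        sub = "".join(seq[s - 1 : e] for s, e in feat.parts)
        if feat.strand == "-":
            sub = reverse_complement(sub)
    elif spec.mode == "intron":
        feat = _find_feature(annotations, spec.anchors[0], spec.name)
        if len(feat.parts) < 2:
            raise EmptyRegionError(
                f"gene {spec.anchors[0]!r} has a single exon; no intron to extract"
            )
        # sequence strictly between consecutive exons (all introns, joined)
        pieces = []
        for (_, e1), (s2, _) in zip(feat.parts, feat.parts[1:]):
            if s2 - 1 >= e1 + 1:
                pieces.append(seq[e1 : s2 - 1])
        sub = "".join(pieces)
        if feat.strand == "-":
            sub = reverse_complement(sub)
    elif spec.mode == "spacer":
        a = _find_feature(annotations, spec.anchors[0], spec.name)
        b = _find_feature(annotations, spec.anchors[1], spec.name)
        first, second = (a, b) if a.start <= b.start else (b, a)
        lo, hi = first.end + 1, second.start - 1
        if lo > hi:
            raise EmptyRegionError(
                f"anchors {a.name!r} and {b.name!r} overlap or abut; spacer is empty"
            )
        sub = seq[lo - 1 : hi]
    if not sub:
        raise EmptyRegionError(f"region {spec.name!r} is empty in {record.id!r}")
    return SequenceRecord(record.id, sub, spec.name)


def build_region_dataset(
    genomes: Sequence[tuple[SequenceRecord, Sequence[FeatureAnnotation]]],
    spec: RegionSpec,
) -> list[SequenceRecord]:
    """Extract one region across many genomes; aggregate missing-feature errors."""
    out, failures = [], []
    for record, annotations in genomes:
        try:
            out.append(extract_region(record, annotations, spec))
        except (MissingFeatureError, EmptyRegionError) as exc:
            failures.append(f"{record.id}: {exc}")
    if failures:
        raise MissingFeatureError(
            f"region {spec.name!r} unavailable in {len(failures)} genome(s): "
            + "; ".join(failures)
        )
    return out


def concatenate_alignments(
    alignments: Sequence[Alignment],
    metadata: Sequence[SampleMetadata] | None = None,
) -> Alignment:
    """Horizontally concatenate aligned blocks sharing one sample set.

    Sequences are joined per sample in the given block order; the result
    length is the sum of block lengths.  Sample order follows the first block.
    """
    if not alignments:
        raise ValidationError("no alignments to concatenate")
    base_ids = alignments[0].ids
    base_set = set(base_ids)
    for i, aln in enumerate(alignments[1:], start=2):
        diff = base_set.symmetric_difference(aln.ids)
        if diff:
            raise ValidationError(
                f"block {i} sample set differs from block 1: {sorted(diff)}"
            )
    if metadata is not None:
        meta_ids = {m.sample_id for m in metadata}
        missing = sorted(base_set - meta_ids)
        if missing:
            raise ValidationError(f"concatenated samples absent from metadata: {missing}")
    by_id = [{r.id: r.seq for r in aln.records} for aln in alignments]
    return Alignment(
        [
            SequenceRecord(sid, "".join(block[sid] for block in by_id))
            for sid in base_ids
        ]
    )
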