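"""Input/output for the external formats the pipeline consumes and produces.

Sequences travel as :class:`SequenceRecord`, gapped sequence sets as
:class:`Alignment`, per-sample species assignments as :class:`SampleMetadata`,
and plastome annotations as :class:`FeatureAnnotation`.  FASTA and GenBank
parsing is delegated to Biopython; Newick trees to dendropy; tabular data to
pandas.  All coordinates exposed here are 1-based inclusive, following the
GenBank convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

#: Accepted sequence characters: the four bases, gap, N, and IUPAC ambiguity.
ALPHABET = frozenset("ACGTNRYSWKMBDHV-")

ROLES = frozenset({"ingroup", "outgroup"})
GROUPS = frozenset({"genuine", "adulterant", "outgroup"})


@dataclass
class SequenceRecord:
    """A single named nucleotide sequence (possibly gapped)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """A rectangular gapped sequence matrix, the substrate of every statistic."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValidationError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValidationError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids in alignment: {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def to_array(self) -> np.ndarray:
        """Byte matrix view (n_sequences x n_columns) of the alignment."""
        return np.frombuffer(
            "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.records), self.length)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment of 1-based inclusive column range [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValidationError(f"column range {start}..{end} outside 1..{self.length}")
        return Alignment(
            [SequenceRecord(r.id, r.seq[start - 1 : end], r.description) for r in self.records]
        )

    def subset(self, ids: Sequence[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment([r for r in self.records if r.id in wanted])


@dataclass(frozen=True)
class SampleMetadata:
    """Sample-to-species assignment with ingroup/outgroup and market-group flags."""

    sample_id: str
    species: str
    role: str
    group: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} (expected one of {sorted(ROLES)})")
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} (expected one of {sorted(GROUPS)})"
            )
        if (self.role == "outgroup") != (self.group == "outgroup"):
            raise ValidationError(
                f"sample {self.sample_id!r}: role {self.role!r} inconsistent with group {self.group!r}"
            )


@dataclass
class FeatureAnnotation:
    """A named plastome feature with 1-based inclusive coordinates.

    ``parts`` lists the ordered exon intervals for multi-exon (join) locations;
    for simple spans it holds the single interval ``(start, end)``.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str
    parts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("feature with empty name")
        if not (1 <= self.start <= self.end):
            raise ValidationError(f"feature {self.name!r}: bad span {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if not self.parts:
            self.parts = [(self.start, self.end)]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated records (order preserved)."""
    records = [
        SequenceRecord(rec.id, str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate sequence ids {dupes}")
    return records


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    return Alignment(read_fasta(path))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_KIND_MAP = {
    "gene": "gene",
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "intron": "intron",
    "misc_feature": "intergenic",
}


def _feature_name(feature) -> str | None:
    for key in ("gene", "locus_tag", "product", "note", "label"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return None


def read_genbank(path: str | Path) -> tuple[SequenceRecord, list[FeatureAnnotation]]:
    """Read an annotated GenBank flat file.

    Returns the genome sequence and one annotation per feature occurrence;
    a feature present in both inverted-repeat copies yields two annotations.
    join() locations are decomposed into ordered exon intervals in ``parts``.
    """
    try:
        gb = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a parseable GenBank record ({exc})") from exc
    try:
        seq = str(gb.seq)
    except Exception as exc:  # Bio.Seq.UndefinedSequenceError lacks a stable import path
        raise FormatError(f"{path}: GenBank record has no ORIGIN sequence") from exc
    if not seq:
        raise FormatError(f"{path}: GenBank record has no ORIGIN sequence")
    record = SequenceRecord(gb.id or gb.name, seq, gb.description)

    annotations: list[FeatureAnnotation] = []
    for feature in gb.features:
        kind = _KIND_MAP.get(feature.type)
        if kind is None:
            continue
        name = _feature_name(feature)
        if name is None:
            continue
        parts = sorted(
            (int(p.start) + 1, int(p.end)) for p in feature.location.parts
        )
        strand = "-" if feature.location.strand == -1 else "+"
        annotations.append(
            FeatureAnnotation(
                name=name,
                kind=kind,
                start=parts[0][0],
                end=parts[-1][1],
                strand=strand,
                parts=parts,
            )
        )
    return record, annotations


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (columns sample_id, species, role, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "species", "role", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata is missing columns {missing}")
    rows = [
        SampleMetadata(r.sample_id, r.species, r.role, r.group)
        for r in df.itertuples(index=False)
    ]
    return validate_metadata(rows)


def validate_metadata(rows: Sequence[SampleMetadata]) -> list[SampleMetadata]:
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id in metadata: {dupes}")
    outgroup_species = {r.species for r in rows if r.role == "outgroup"}
    if len(outgroup_species) > 1:
        raise ValidationError(
            f"more than one outgroup species designated: {sorted(outgroup_species)}"
        )
    return list(rows)


def write_metadata(rows: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in rows]).to_csv(path, sep="\t", index=False)


def check_metadata_cover(alignment: Alignment, metadata: Sequence[SampleMetadata]) -> None:
    """Every alignment sample must appear in metadata exactly once; fail fast."""
    meta_ids = {m.sample_id for m in metadata}
    missing = [i for i in alignment.ids if i not in meta_ids]
    if missing:
        raise ValidationError(f"alignment samples absent from metadata: {missing}")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths and integer support labels."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_table(obj: Mapping | pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write a report as TSV (``.tsv``) or JSON (anything else)."""
    path = Path(path)
    if path.suffix == ".tsv":
        df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)
        df.to_csv(path, sep="\t", index=False)
    else:
        if isinstance(obj, pd.DataFrame):
            obj = obj.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=_json_default)
            fh.write("\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (set, frozenset, tuple)):
        return sorted(value) if isinstance(value, (set, frozenset)) else list(value)
    raise TypeError(f"cannot serialize {type(value)!r}")
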