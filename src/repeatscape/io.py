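"""Readers/writers for the formats the pipeline touches, and the shared
coordinate conventions.

All interval arithmetic in this package is 0-based half-open
(``length == end - start``); GFF3 output converts to 1-based closed
coordinates on write and back on read.  Sequences are uppercased on read:
masking state is carried in annotations, never in case.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

#: Fixed repeat-class vocabulary (mirrors the composition-table rows).
REPEAT_CLASSES = frozenset(
    {
        "Ty1-Copia",
        "Ty3-Gypsy",
        "LINE_SINE",
        "ClassI-unclassified",
        "ClassI-novel",
        "DNA-nonMITE",
        "MITE",
        "DNA-unclassified",
        "rDNA",
        "centromeric",
        "telomeric",
        "SSR",
        "low_complexity",
        "unclassified",
        "novel",
    }
)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


class AnnotationError(ValueError):
    """Raised for invalid repeat annotations or annotation files."""


class CoverageTableError(ValueError):
    """Raised for malformed coverage tables."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence with provenance.

    ``seq`` is validated against the nucleotide alphabet unless
    ``amino_acid`` is set (phylogenetic inputs are protein).
    """

    id: str
    seq: str
    description: str = ""
    amino_acid: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record has an empty id")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        if not self.amino_acid:
            bad = set(self.seq) - NUCLEOTIDE_ALPHABET
            if bad:
                raise FastaFormatError(
                    f"record {self.id!r} contains non-nucleotide symbols: "
                    f"{sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a scaffold."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(
                f"invalid interval {self.scaffold_id}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold_id == other.scaffold_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold_id == other.scaffold_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class RepeatAnnotation:
    """A classified repeat interval on a scaffold."""

    interval: GenomicInterval
    repeat_class: str
    family_id: str | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise AnnotationError(
                f"unknown repeat class {self.repeat_class!r}; expected one of "
                f"{sorted(REPEAT_CLASSES)}"
            )
        if self.score < 0:
            raise AnnotationError("annotation score must be >= 0")


def _reraise_parse_errors(parser, path):
    """Convert Biopython parse errors (e.g. leading non-'>' content) into
    FastaFormatError naming the file."""
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastaFormatError(
                f"{path}: not FASTA (no '>' header found): {exc}"
            ) from exc
        yield rec


def read_fasta(path: str | Path, amino_acid: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; ``N`` is allowed.  Malformed records (empty
    sequence, duplicate or empty ids) raise :class:`FastaFormatError`
    naming the offending record.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1024)
    if head.strip() and not head.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: not FASTA (no '>' header found)")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    parser = SeqIO.parse(str(path), "fasta")
    for i, rec in enumerate(_reraise_parse_errors(parser, path), start=1):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FastaFormatError(f"{path}: record {i} has an empty header")
        if not seq:
            raise FastaFormatError(
                f"{path}: record {i} ({rec.id!r}) has an empty sequence"
            )
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=seq,
                description=rec.description[len(rec.id) :].strip(),
                amino_acid=amino_acid,
            )
        )
    if not records:
        # distinguish empty/garbage files from legitimate FASTA
        with open(path) as fh:
            head = fh.read(1)
        if head != ">":
            raise FastaFormatError(f"{path}: not FASTA (no '>' header found)")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column line wrapping."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def _annotation_sort_key(a: RepeatAnnotation):
    iv = a.interval
    return (iv.scaffold_id, iv.start, iv.end, a.repeat_class, a.family_id or "")


def write_annotations(
    annotations: Sequence[RepeatAnnotation],
    path: str | Path,
    dialect: str = "GFF3",
    scaffold_lengths: dict[str, int] | None = None,
) -> None:
    """Write annotations as GFF3 (1-based closed) or BED6 (0-based half-open).

    The repeat class goes in the GFF3 type column (BED name column as
    ``class|family``); family_id is a GFF3 attribute.  Output is
    deterministically sorted by (scaffold, start, end).
    """
    if dialect not in {"GFF3", "BED"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if scaffold_lengths is not None:
        for a in annotations:
            iv = a.interval
            limit = scaffold_lengths.get(iv.scaffold_id)
            if limit is not None and iv.end > limit:
                raise AnnotationError(
                    f"interval {iv.scaffold_id}:{iv.start}-{iv.end} exceeds "
                    f"scaffold length {limit}"
                )
    rows = sorted(annotations, key=_annotation_sort_key)
    with open(path, "w") as fh:
        if dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for a in rows:
                iv = a.interval
                attrs = [f"ID={iv.scaffold_id}:{iv.start}-{iv.end}"]
                if a.family_id:
                    attrs.append(f"family_id={a.family_id}")
                fh.write(
                    "\t".join(
                        [
                            iv.scaffold_id,
                            "repeatscape",
                            a.repeat_class,
                            str(iv.start + 1),
                            str(iv.end),
                            f"{a.score:g}",
                            iv.strand if iv.strand != "." else ".",
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
        else:
            for a in rows:
                iv = a.interval
                name = a.repeat_class + ("|" + a.family_id if a.family_id else "")
                fh.write(
                    "\t".join(
                        [
                            iv.scaffold_id,
                            str(iv.start),
                            str(iv.end),
                            name,
                            f"{a.score:g}",
                            iv.strand if iv.strand != "." else ".",
                        ]
                    )
                    + "\n"
                )


def read_annotations(path: str | Path, dialect: str = "GFF3") -> list[RepeatAnnotation]:
    """Read annotations written by :func:`write_annotations`."""
    if dialect not in {"GFF3", "BED"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "GFF3":
                if len(cols) != 9:
                    raise AnnotationError(f"{path}: expected 9 GFF3 columns: {line!r}")
                scaf, _src, klass, start1, end1, score, strand, _phase, attrs = cols
                family = None
                for kv in attrs.split(";"):
                    if kv.startswith("family_id="):
                        family = kv.split("=", 1)[1]
                iv = GenomicInterval(
                    scaf, int(start1) - 1, int(end1), strand if strand in "+-" else "."
                )
                out.append(
                    RepeatAnnotation(
                        iv, klass, family, float(score) if score != "." else 0.0
                    )
                )
            else:
                if len(cols) < 6:
                    raise AnnotationError(f"{path}: expected 6 BED columns: {line!r}")
                scaf, start, end, name, score, strand = cols[:6]
                klass, _, family = name.partition("|")
                iv = GenomicInterval(
                    scaf, int(start), int(end), strand if strand in "+-" else "."
                )
                out.append(RepeatAnnotation(iv, klass, family or None, float(score)))
    return out


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of per-element mean coverages, one column per library.

    The first column must be ``element_id``; all remaining columns are
    parsed as finite, non-negative reals.  Missing or non-numeric values
    raise :class:`CoverageTableError` naming the element.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "element_id":
        raise CoverageTableError(
            f"{path}: first column must be 'element_id', got {df.columns[0]!r}"
        )
    if df.shape[1] < 2:
        raise CoverageTableError(f"{path}: need at least one library column")
    if df["element_id"].duplicated().any():
        dupes = df.loc[df["element_id"].duplicated(), "element_id"].tolist()
        raise CoverageTableError(f"{path}: duplicate element ids {dupes}")
    df = df.set_index("element_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise CoverageTableError(
                f"{path}: non-numeric/missing coverage in column {col!r} "
                f"for elements {bad}"
            )
        if (vals < 0).any():
            bad = df.index[vals < 0].tolist()
            raise CoverageTableError(
                f"{path}: negative coverage in column {col!r} for elements {bad}"
            )
        df[col] = vals.astype(float)
    return df


def write_coverage_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a coverage table in the format :func:`read_coverage_table` reads."""
    df.to_csv(path, sep="\t", index_label="element_id")
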