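"""Annotation, sequence and tool-table I/O, plus the interval index.

All genomic coordinates are internal 0-based half-open intervals.  GTF uses
1-based closed coordinates; the conversion happens only at the read/write
edge, so every downstream overlap computation works on a single convention.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

VALID_STRANDS = ("+", "-", ".")

TOOL_DIALECTS = ("cpc", "pfam", "rfam", "repeatmasker")


class GtfParseError(ValueError):
    """Malformed line in a GTF/tabular input; message carries the line number."""


class ValidationError(ValueError):
    """Structurally invalid record (e.g. end < start, duplicate id)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One assembled transcript: ordered disjoint exons on one strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev_end = -1
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValidationError(
                    f"{self.transcript_id}: exon on {e.chrom}, transcript on {self.chrom}"
                )
            if e.start < prev_end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e.end

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths in nt."""
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcript_ids: list[str] = field(default_factory=list)
    biotype: str = "unknown"  # coding | noncoding | unknown


@dataclass
class AnnotationSet:
    """Transcripts keyed by id plus their genes with derived spans."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)

    def add(self, t: TranscriptModel, biotype: str | None = None) -> None:
        if t.transcript_id in self.transcripts:
            raise ValidationError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        g = self.genes.get(t.gene_id)
        if g is None:
            g = Gene(t.gene_id, t.chrom, t.strand)
            self.genes[t.gene_id] = g
        g.transcript_ids.append(t.transcript_id)
        if biotype is not None:
            g.biotype = biotype

    def gene_span(self, gene_id: str) -> GenomicInterval:
        g = self.genes[gene_id]
        ts = [self.transcripts[tid] for tid in g.transcript_ids]
        start = min(t.span.start for t in ts)
        end = max(t.span.end for t in ts)
        return GenomicInterval(g.chrom, start, end, g.strand)

    def gene_exons(self, gene_id: str) -> list[GenomicInterval]:
        g = self.genes[gene_id]
        exons: list[GenomicInterval] = []
        for tid in g.transcript_ids:
            exons.extend(self.transcripts[tid].exons)
        return sorted(exons, key=lambda e: (e.start, e.end))

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        if set(self.transcripts) != set(other.transcripts):
            return False
        for tid, t in self.transcripts.items():
            o = other.transcripts[tid]
            if (t.gene_id, t.chrom, t.strand, t.exons) != (o.gene_id, o.chrom, o.strand, o.exons):
                return False
        for gid, g in self.genes.items():
            og = other.genes.get(gid)
            if og is None or g.biotype != og.biotype:
                return False
        return True


class IntervalIndex:
    """Per-chromosome searchable interval container.

    Backed by flat numpy arrays per chromosome; a query is one vectorized
    mask, which is plenty for annotation-scale inputs and keeps behaviour
    trivially equivalent to a linear scan.
    """

    def __init__(self) -> None:
        self._pending: dict[str, list[tuple[int, int, object]]] = {}
        self._built: dict[str, tuple[np.ndarray, np.ndarray, list[object]]] = {}

    def add(self, chrom: str, start: int, end: int, payload: object) -> None:
        if not (0 <= start < end):
            raise ValidationError(f"invalid interval {chrom}:{start}-{end}")
        self._pending.setdefault(chrom, []).append((start, end, payload))
        self._built.pop(chrom, None)

    def _arrays(self, chrom: str):
        if chrom not in self._built:
            items = self._pending.get(chrom, [])
            starts = np.fromiter((i[0] for i in items), dtype=np.int64, count=len(items))
            ends = np.fromiter((i[1] for i in items), dtype=np.int64, count=len(items))
            self._built[chrom] = (starts, ends, [i[2] for i in items])
        return self._built[chrom]

    def query(self, chrom: str, start: int, end: int) -> list[tuple[int, int, object]]:
        """All stored intervals overlapping [start, end) on chrom."""
        if chrom not in self._pending:
            return []
        starts, ends, payloads = self._arrays(chrom)
        mask = (starts < end) & (ends > start)
        idx = np.nonzero(mask)[0]
        return [(int(starts[i]), int(ends[i]), payloads[i]) for i in idx]

    def __len__(self) -> int:
        return sum(len(v) for v in self._pending.values())


def build_index(
    intervals: Iterable[tuple[GenomicInterval, object]]
) -> IntervalIndex:
    """Build an IntervalIndex from (interval, payload) pairs."""
    ix = IntervalIndex()
    for iv, payload in intervals:
        ix.add(iv.chrom, iv.start, iv.end, payload)
    return ix


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(
    path: str | Path,
    feature_filter: set[str] | None = None,
) -> AnnotationSet:
    """Read an Ensembl-dialect GTF into an AnnotationSet.

    Only rows whose feature is in ``feature_filter`` (default: {"exon"})
    contribute exons; gene_biotype attributes, when present, set the gene's
    biotype (``protein_coding``/``coding`` map to coding).
    """
    if feature_filter is None:
        feature_filter = {"exon"}
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    biotypes: dict[str, str] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in feature_filter:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: end < start")
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if tid is None or gid is None:
                raise GtfParseError(
                    f"{path}:{lineno}: missing gene_id/transcript_id attribute"
                )
            if tid not in exons:
                exons[tid] = []
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            # GTF 1-based closed -> 0-based half-open
            exons[tid].append(GenomicInterval(chrom, start1 - 1, end1, strand))
            bt = attr.get("gene_biotype")
            if bt is not None:
                biotypes[gid] = (
                    "coding" if bt in ("protein_coding", "coding") else
                    "noncoding" if bt in ("noncoding", "lncRNA", "lincRNA") else bt
                )
    annset = AnnotationSet()
    for tid in order:
        gid, chrom, strand = meta[tid]
        annset.add(
            TranscriptModel(tid, gid, chrom, strand, exons[tid]),
            biotype=biotypes.get(gid),
        )
    return annset


def write_gtf(annset: AnnotationSet, path: str | Path, source: str = "lincseek") -> None:
    """Write exon rows (0-based half-open back to 1-based closed GTF)."""
    path = Path(path)
    rows = sorted(
        annset.transcripts.values(),
        key=lambda t: (t.chrom, t.span.start, t.transcript_id),
    )
    with path.open("w") as fh:
        for t in rows:
            bt = annset.genes[t.gene_id].biotype
            bt_attr = (
                ' gene_biotype "protein_coding";' if bt == "coding"
                else ' gene_biotype "noncoding";' if bt == "noncoding"
                else ""
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";{bt_attr}\n'
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id->sequence map.

    Sequences are uppercased and U is converted to T; the id is the first
    whitespace-delimited token of the header.  Duplicate ids and empty
    sequences are errors.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if record.id in out:
            raise ValidationError(f"duplicate sequence id {record.id}")
        if not seq:
            raise ValidationError(f"empty sequence for id {record.id}")
        out[record.id] = seq
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class ToolHit:
    """One normalized hit record from an external tool table."""

    query_id: str
    label: str
    accession: str | None = None
    score: float | None = None
    e_value: float | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None


def _float_or_error(value: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise GtfParseError(f"{path}:{lineno}: non-numeric {what} {value!r}") from exc


def read_tool_table(path: str | Path, dialect: str) -> list[ToolHit]:
    """Read a tool output table into normalized hit records.

    Dialect column contracts (tab-separated, ``#`` comments skipped):
      cpc          query_id, label in {coding, noncoding}, score
      pfam         query_id, domain_acc, domain_name, e_value
      rfam         query_id, family_acc, family_name, e_value
      repeatmasker chrom, start, end, repeat_class

    No threshold filtering is applied here; that belongs to the consumers.
    """
    if dialect not in TOOL_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {TOOL_DIALECTS}")
    path = Path(path)
    hits: list[ToolHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "cpc":
                if len(fields) < 3:
                    raise GtfParseError(f"{path}:{lineno}: cpc row needs 3 columns")
                hits.append(
                    ToolHit(
                        query_id=fields[0],
                        label=fields[1],
                        score=_float_or_error(fields[2], path, lineno, "score"),
                    )
                )
            elif dialect == "pfam":
                if len(fields) < 4:
                    raise GtfParseError(f"{path}:{lineno}: pfam row needs 4 columns")
                hits.append(
                    ToolHit(
                        query_id=fields[0],
                        accession=fields[1],
                        label=fields[2],
                        e_value=_float_or_error(fields[3], path, lineno, "e-value"),
                    )
                )
            elif dialect == "rfam":
                if len(fields) < 4:
                    raise GtfParseError(f"{path}:{lineno}: rfam row needs 4 columns")
                hits.append(
                    ToolHit(
                        query_id=fields[0],
                        accession=fields[1],
                        label=fields[2],
                        e_value=_float_or_error(fields[3], path, lineno, "e-value"),
                    )
                )
            else:  # repeatmasker
                if len(fields) < 4:
                    raise GtfParseError(f"{path}:{lineno}: repeatmasker row needs 4 columns")
                chrom = fields[0]
                start = int(_float_or_error(fields[1], path, lineno, "start"))
                end = int(_float_or_error(fields[2], path, lineno, "end"))
                hits.append(
                    ToolHit(
                        query_id=f"{chrom}:{start}-{end}",
                        label=fields[3],
                        chrom=chrom,
                        start=start,
                        end=end,
                    )
                )
    return hits


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED (>=4 columns) repeat intervals as (interval, name) pairs."""
    path = Path(path)
    out: list[tuple[GenomicInterval, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GtfParseError(f"{path}:{lineno}: BED row needs >= 4 columns")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(
    intervals: Sequence[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
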