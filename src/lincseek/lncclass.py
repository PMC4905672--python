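"""Positional classification of lncRNAs and feature/repeat summaries.

Classes are assigned with a fixed precedence:

1. antisense — >= 1 bp exon-exon overlap with a coding exon on the opposite
   strand;
2. intronic  — transcript span fully contained in a coding gene's span with
   zero exonic overlap (i.e. inside an intron), either strand by default;
3. lincRNA   — everything else.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .annio import AnnotationSet, GenomicInterval, IntervalIndex, TranscriptModel
from .lncfilter import OrfResult
from .util import format_percent

logger = logging.getLogger(__name__)

POSITIONAL_CLASSES = ("lincRNA", "intronic", "antisense")
SUBGENOMES = ("At", "Dt", "Un")


@dataclass(frozen=True)
class LncRNARecord:
    transcript_id: str
    positional_class: str
    subgenome: str
    length: int
    exon_count: int
    longest_orf_nt: int
    host_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.positional_class not in POSITIONAL_CLASSES:
            raise ValueError(f"unknown class {self.positional_class!r}")
        if (self.positional_class == "lincRNA") != (self.host_gene_id is None):
            raise ValueError(
                f"{self.transcript_id}: host_gene_id must be present iff class != lincRNA"
            )


class ReferenceIndex:
    """Coding-gene exon and span indexes used by the classifier."""

    def __init__(self, reference: AnnotationSet):
        self.exon_ix = IntervalIndex()
        self.span_ix = IntervalIndex()
        self.gene_exons: dict[str, list[GenomicInterval]] = {}
        for gid, gene in reference.genes.items():
            if gene.biotype == "noncoding":
                continue
            span = reference.gene_span(gid)
            self.span_ix.add(span.chrom, span.start, span.end, (gid, gene.strand))
            exons = reference.gene_exons(gid)
            self.gene_exons[gid] = exons
            for e in exons:
                self.exon_ix.add(e.chrom, e.start, e.end, (gid, gene.strand))


def classify_position(
    lnc: TranscriptModel,
    ref_index: ReferenceIndex,
    same_strand_intronic_only: bool = False,
) -> tuple[str, str | None]:
    """Assign (positional class, host gene) for one surviving lncRNA.

    Host ties break by largest overlap then lexicographic gene_id.
    Transcripts with strand "." skip the antisense test (logged).
    """
    # 1) antisense: exon-exon opposite-strand overlap
    if lnc.strand in ("+", "-"):
        overlap_by_gene: dict[str, int] = {}
        for e in lnc.exons:
            for s, t, (gid, strand) in ref_index.exon_ix.query(lnc.chrom, e.start, e.end):
                if strand != lnc.strand and strand in ("+", "-"):
                    ov = min(e.end, t) - max(e.start, s)
                    overlap_by_gene[gid] = overlap_by_gene.get(gid, 0) + ov
        if overlap_by_gene:
            host = min(overlap_by_gene, key=lambda g: (-overlap_by_gene[g], g))
            return "antisense", host
    else:
        logger.warning(
            "transcript %s has strand '.'; antisense test skipped", lnc.transcript_id
        )

    # 2) intronic: full span containment, zero exonic overlap
    span = lnc.span
    candidates: list[str] = []
    for s, t, (gid, strand) in ref_index.span_ix.query(lnc.chrom, span.start, span.end):
        if not (s <= span.start and t >= span.end):
            continue
        if same_strand_intronic_only and strand != lnc.strand:
            continue
        has_exon_overlap = any(
            ge.start < e.end and e.start < ge.end
            for ge in ref_index.gene_exons[gid]
            for e in lnc.exons
        )
        if not has_exon_overlap:
            candidates.append(gid)
    if candidates:
        return "intronic", sorted(candidates)[0]

    return "lincRNA", None


SubgenomeRule = Callable[[str], str] | Mapping[str, str] | None


def assign_subgenome(chrom: str, rule: SubgenomeRule = None) -> str:
    """Map a chromosome name to {At, Dt, Un}.

    Default rule: names starting with "At" -> At, "Dt" -> Dt, else Un.  A
    mapping rule matches the exact name first, then the longest matching
    prefix; a callable rule is applied directly.
    """
    if rule is None:
        if chrom.startswith("At"):
            return "At"
        if chrom.startswith("Dt"):
            return "Dt"
        return "Un"
    if callable(rule):
        label = rule(chrom)
    else:
        if chrom in rule:
            label = rule[chrom]
        else:
            matches = [p for p in rule if chrom.startswith(p)]
            label = rule[max(matches, key=len)] if matches else "Un"
    if label not in SUBGENOMES:
        raise ValueError(f"subgenome rule returned {label!r}, expected one of {SUBGENOMES}")
    return label


def classify_all(
    lncs: Iterable[TranscriptModel],
    reference: AnnotationSet,
    orf_results: Mapping[str, OrfResult] | None = None,
    subgenome_rule: SubgenomeRule = None,
    same_strand_intronic_only: bool = False,
) -> list[LncRNARecord]:
    """Classify every surviving transcript into an LncRNARecord."""
    ref_index = ReferenceIndex(reference)
    records = []
    for t in sorted(lncs, key=lambda x: x.transcript_id):
        cls, host = classify_position(t, ref_index, same_strand_intronic_only)
        orf_nt = 0
        if orf_results is not None and t.transcript_id in orf_results:
            orf_nt = orf_results[t.transcript_id].longest_orf_nt
        records.append(
            LncRNARecord(
                transcript_id=t.transcript_id,
                positional_class=cls,
                subgenome=assign_subgenome(t.chrom, subgenome_rule),
                length=t.length,
                exon_count=t.exon_count,
                longest_orf_nt=orf_nt,
                host_gene_id=host,
            )
        )
    return records


@dataclass
class ClassSummary:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]
    per_subgenome: dict[str, dict[str, int]]  # class -> subgenome -> count
    length_stats: dict[str, dict[str, float]]  # class -> min/max/mean
    histograms: dict[str, dict[str, tuple[list[float], list[int]]]] = field(
        default_factory=dict
    )


def summarize_classes(
    records: Sequence[LncRNARecord],
    length_bins: Sequence[float] | None = None,
    orf_bins: Sequence[float] | None = None,
    pct_decimals: int = 1,
    small_pct_decimals: int | None = 2,
) -> ClassSummary:
    """Counts, rounded percentages, per-subgenome counts and per-class
    length/exon/ORF distributions.

    Percentages use half-up rounding at ``pct_decimals``; sub-10% values are
    printed at ``small_pct_decimals`` when set (matching two-decimal
    reporting for minority classes).
    """
    total = len(records)
    counts = {c: 0 for c in POSITIONAL_CLASSES}
    per_sub: dict[str, dict[str, int]] = {
        c: {s: 0 for s in SUBGENOMES} for c in POSITIONAL_CLASSES
    }
    for r in records:
        counts[r.positional_class] += 1
        per_sub[r.positional_class][r.subgenome] += 1
    if total == 0:
        return ClassSummary(0, counts, {c: 0.0 for c in counts}, per_sub, {})

    percentages = {
        c: format_percent(100.0 * n / total, pct_decimals, small_pct_decimals)
        for c, n in counts.items()
    }
    if length_bins is None:
        length_bins = [200, 400, 600, 800, 1000, 1500, 2000, 3000, 5000, 15000]
    if orf_bins is None:
        orf_bins = [0, 100, 200, 300, 400, 500, 1000]

    length_stats: dict[str, dict[str, float]] = {}
    histograms: dict[str, dict[str, tuple[list[float], list[int]]]] = {}
    for c in POSITIONAL_CLASSES:
        lens = np.array([r.length for r in records if r.positional_class == c])
        if lens.size == 0:
            continue
        orfs = np.array([r.longest_orf_nt for r in records if r.positional_class == c])
        exs = np.array([r.exon_count for r in records if r.positional_class == c])
        length_stats[c] = {
            "min": float(lens.min()),
            "max": float(lens.max()),
            "mean": float(lens.mean()),
        }
        lh, _ = np.histogram(lens, bins=length_bins)
        oh, _ = np.histogram(orfs, bins=orf_bins)
        eb = np.arange(1, max(10, exs.max() + 2))
        ehist, _ = np.histogram(exs, bins=eb)
        histograms[c] = {
            "length": (list(map(float, length_bins)), lh.tolist()),
            "orf": (list(map(float, orf_bins)), oh.tolist()),
            "exons": (list(map(float, eb)), ehist.tolist()),
        }
    return ClassSummary(total, counts, percentages, per_sub, length_stats, histograms)


def repeat_overlap_summary(
    lncs: Iterable[TranscriptModel],
    repeats: Sequence[tuple[GenomicInterval, str]],
    subgenome_rule: SubgenomeRule = None,
) -> dict[str, dict[str, float | None]]:
    """Fraction of lncRNAs whose genomic span overlaps (>= 1 bp) an interval
    of each repeat family, overall and per subgenome.

    Subgenomes with zero lncRNAs report None rather than 0/0.
    """
    lnc_list = list(lncs)
    families = sorted({name for _iv, name in repeats})
    ix = IntervalIndex()
    for iv, name in repeats:
        ix.add(iv.chrom, iv.start, iv.end, name)

    denom = {s: 0 for s in SUBGENOMES}
    hit = {f: {s: 0 for s in SUBGENOMES} for f in families}
    n_total = len(lnc_list)
    hit_total = {f: 0 for f in families}
    for t in lnc_list:
        sub = assign_subgenome(t.chrom, subgenome_rule)
        denom[sub] += 1
        span = t.span
        fams_here = {p for _s, _e, p in ix.query(t.chrom, span.start, span.end)}
        for f in fams_here:
            hit[f][sub] += 1
            hit_total[f] += 1

    out: dict[str, dict[str, float | None]] = {}
    for f in families:
        row: dict[str, float | None] = {
            "overall": (hit_total[f] / n_total) if n_total else None
        }
        for s in SUBGENOMES:
            row[s] = (hit[f][s] / denom[s]) if denom[s] else None
        out[f] = row
    return out
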