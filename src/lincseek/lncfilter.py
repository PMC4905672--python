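"""Five-step filtration of assembled transcripts into high-confidence lncRNAs.

Step order is fixed: size/exon screen, expression screen, removal of known
same-strand mRNA isoforms, ORF-length screen, coding-potential decision.
Every threshold is explicit in :class:`IdentifyConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annio import AnnotationSet, IntervalIndex, ToolHit, TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfResult:
    """Longest complete sense-strand ORF of one transcript."""

    transcript_id: str | None
    longest_orf_nt: int  # includes the stop codon; 0 if no complete ORF
    frame: int = 0
    start_offset: int | None = None


@dataclass
class StepReport:
    name: str
    n_input: int
    n_retained: int
    removed_ids: list[str]


@dataclass
class FiltrationReport:
    steps: list[StepReport] = field(default_factory=list)

    def append(self, step: StepReport) -> None:
        if self.steps and self.steps[-1].n_retained != step.n_input:
            raise ValueError(
                f"step chain broken: {self.steps[-1].name} retained "
                f"{self.steps[-1].n_retained} but {step.name} saw {step.n_input}"
            )
        self.steps.append(step)

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_input, s.n_retained) for s in self.steps]


@dataclass(frozen=True)
class CodingCall:
    transcript_id: str
    cpc_coding: bool | None  # None = no CPC table provided
    pfam_hit: bool | None
    orf_flag: bool
    final: str  # "coding" | "noncoding"


@dataclass
class IdentifyConfig:
    min_len: int = 200
    min_exons: int = 1
    min_fpkm: float = 0.5
    min_reps: int = 3
    orf_threshold_nt: int = 300
    pfam_evalue: float = 0.001

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "IdentifyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown identify config keys: {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]


def find_longest_orf(sequence: str, transcript_id: str | None = None) -> OrfResult:
    """Longest ATG..stop ORF over the three sense-strand frames.

    The reported length includes the stop codon.  Codons containing N
    invalidate any ORF spanning them.  Ties break toward the smallest start
    offset, then the smallest frame.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    best_len, best_frame, best_start = 0, 0, None
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                open_start = None  # ORFs containing an N codon are skipped
                continue
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if length > best_len or (
                    length == best_len
                    and best_start is not None
                    and (open_start, frame) < (best_start, best_frame)
                ):
                    best_len, best_frame, best_start = length, frame, open_start
                open_start = None
    return OrfResult(transcript_id, best_len, best_frame, best_start)


def _as_list(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    return list(transcripts)


def step1_size_exon(
    transcripts: Iterable[TranscriptModel],
    min_len: int = 200,
    min_exons: int = 1,
) -> tuple[list[TranscriptModel], StepReport]:
    """Retain transcripts with spliced length >= min_len (and >= min_exons)."""
    ts = _as_list(transcripts)
    kept, removed = [], []
    for t in ts:
        if t.length >= min_len and t.exon_count >= min_exons:
            kept.append(t)
        else:
            removed.append(t.transcript_id)
    return kept, StepReport("size_exon", len(ts), len(kept), removed)


def step2_expression(
    transcripts: Iterable[TranscriptModel],
    expr,  # ExpressionMatrix
    min_fpkm: float = 0.5,
    min_reps: int = 3,
) -> tuple[list[TranscriptModel], StepReport]:
    """Retain transcripts expressed (FPKM >= min_fpkm) in >= min_reps replicates
    of at least one condition."""
    ts = _as_list(transcripts)
    missing = [t.transcript_id for t in ts if t.transcript_id not in expr.counts.index]
    if missing:
        raise KeyError(f"transcripts missing from expression matrix: {missing}")
    fpkm = expr.fpkm()
    cond_of = expr.design["condition"]
    kept, removed = [], []
    for t in ts:
        row = fpkm.loc[t.transcript_id]
        ok = False
        for cond in cond_of.unique():
            samples = cond_of.index[cond_of == cond]
            if int((row[samples] >= min_fpkm).sum()) >= min_reps:
                ok = True
                break
        if ok:
            kept.append(t)
        else:
            removed.append(t.transcript_id)
    return kept, StepReport("expression", len(ts), len(kept), removed)


def _coding_exon_index(reference: AnnotationSet) -> IntervalIndex:
    ix = IntervalIndex()
    for t in reference:
        if reference.genes[t.gene_id].biotype == "noncoding":
            continue
        for e in t.exons:
            ix.add(t.chrom, e.start, e.end, (t.gene_id, t.strand))
    return ix


def step3_known_overlap(
    transcripts: Iterable[TranscriptModel],
    reference: AnnotationSet,
) -> tuple[list[TranscriptModel], StepReport]:
    """Remove putative mRNA isoforms: transcripts with same-strand exonic
    overlap against a (non-noncoding) reference transcript.

    Opposite-strand and intron-contained transcripts survive for later
    positional classing.
    """
    ts = _as_list(transcripts)
    ix = _coding_exon_index(reference)
    kept, removed = [], []
    for t in ts:
        is_isoform = False
        for e in t.exons:
            for _s, _e, (gid, strand) in ix.query(t.chrom, e.start, e.end):
                if strand == t.strand and t.strand in ("+", "-"):
                    is_isoform = True
                    break
            if is_isoform:
                break
        if is_isoform:
            removed.append(t.transcript_id)
        else:
            kept.append(t)
    return kept, StepReport("known_overlap", len(ts), len(kept), removed)


def step4_orf(
    transcripts: Iterable[TranscriptModel],
    sequences: Mapping[str, str],
    orf_threshold_nt: int = 300,
) -> tuple[list[TranscriptModel], StepReport, dict[str, OrfResult]]:
    """Remove transcripts whose longest complete ORF reaches the threshold."""
    ts = _as_list(transcripts)
    kept, removed = [], []
    orf_map: dict[str, OrfResult] = {}
    for t in ts:
        seq = sequences.get(t.transcript_id)
        if seq is None:
            raise KeyError(f"no sequence for transcript {t.transcript_id}")
        res = find_longest_orf(seq, t.transcript_id)
        orf_map[t.transcript_id] = res
        if res.longest_orf_nt < orf_threshold_nt:
            kept.append(t)
        else:
            removed.append(t.transcript_id)
    return kept, StepReport("orf", len(ts), len(kept), removed), orf_map


def coding_potential(
    transcripts: Iterable[TranscriptModel],
    cpc_records: Sequence[ToolHit] | None = None,
    pfam_records: Sequence[ToolHit] | None = None,
    sequences: Mapping[str, str] | None = None,
    orf_results: Mapping[str, OrfResult] | None = None,
    orf_threshold_nt: int = 300,
    pfam_evalue: float = 0.001,
) -> tuple[dict[str, CodingCall], dict[str, int]]:
    """Combine CPC labels, Pfam hits and the ORF heuristic into a final call.

    Union rule: when at least one tool table is supplied, final = coding iff
    CPC labels the transcript coding OR it has a Pfam hit at the e-value
    threshold.  With no table, the ORF-length heuristic decides (fallback
    mode).  Venn counts tally evidence overlap among evidence-flagged
    transcripts.
    """
    ts = _as_list(transcripts)
    evidence_mode = cpc_records is not None or pfam_records is not None
    if not evidence_mode and sequences is None and orf_results is None:
        raise ValueError("need CPC/Pfam tables or transcript sequences")

    cpc_coding_ids: set[str] | None = None
    if cpc_records is not None:
        cpc_coding_ids = {h.query_id for h in cpc_records if h.label == "coding"}
    pfam_ids: set[str] | None = None
    if pfam_records is not None:
        pfam_ids = {
            h.query_id
            for h in pfam_records
            if h.e_value is not None and h.e_value <= pfam_evalue
        }

    calls: dict[str, CodingCall] = {}
    venn = {"cpc_only": 0, "pfam_only": 0, "both": 0}
    for t in ts:
        tid = t.transcript_id
        if orf_results is not None and tid in orf_results:
            orf_nt = orf_results[tid].longest_orf_nt
        elif sequences is not None:
            orf_nt = find_longest_orf(sequences[tid], tid).longest_orf_nt
        else:
            orf_nt = 0
        orf_flag = orf_nt >= orf_threshold_nt
        cpc = tid in cpc_coding_ids if cpc_coding_ids is not None else None
        pfam = tid in pfam_ids if pfam_ids is not None else None
        if evidence_mode:
            final = "coding" if (bool(cpc) or bool(pfam)) else "noncoding"
        else:
            final = "coding" if orf_flag else "noncoding"
        if cpc and pfam:
            venn["both"] += 1
        elif cpc:
            venn["cpc_only"] += 1
        elif pfam:
            venn["pfam_only"] += 1
        calls[tid] = CodingCall(tid, cpc, pfam, orf_flag, final)
    return calls, venn


def run_identification(
    transcripts: Iterable[TranscriptModel],
    reference: AnnotationSet,
    expr,
    sequences: Mapping[str, str],
    config: IdentifyConfig | None = None,
    cpc_records: Sequence[ToolHit] | None = None,
    pfam_records: Sequence[ToolHit] | None = None,
) -> tuple[list[TranscriptModel], FiltrationReport, dict[str, OrfResult]]:
    """Run the full five-step filtration; survivors are the lncRNA set.

    The survivor list is sorted by transcript_id so the result does not
    depend on input ordering.
    """
    cfg = config or IdentifyConfig()
    report = FiltrationReport()

    ts = sorted(_as_list(transcripts), key=lambda t: t.transcript_id)
    ts, rep1 = step1_size_exon(ts, cfg.min_len, cfg.min_exons)
    report.append(rep1)

    ts, rep2 = step2_expression(ts, expr, cfg.min_fpkm, cfg.min_reps)
    report.append(rep2)

    ts, rep3 = step3_known_overlap(ts, reference)
    report.append(rep3)

    ts, rep4, orf_map = step4_orf(ts, sequences, cfg.orf_threshold_nt)
    report.append(rep4)

    calls, _venn = coding_potential(
        ts,
        cpc_records=cpc_records,
        pfam_records=pfam_records,
        orf_results=orf_map,
        orf_threshold_nt=cfg.orf_threshold_nt,
        pfam_evalue=cfg.pfam_evalue,
    )
    kept, removed = [], []
    for t in ts:
        if calls[t.transcript_id].final == "noncoding":
            kept.append(t)
        else:
            removed.append(t.transcript_id)
    report.append(StepReport("coding_potential", len(ts), len(kept), removed))
    return kept, report, orf_map
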