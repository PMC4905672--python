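"""Cis- and trans-target prediction, intronic/host concordance and the
small-RNA precursor summary."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annio import AnnotationSet, IntervalIndex, ToolHit, TranscriptModel
from .express import ContrastResult
from .lncclass import LncRNARecord
from .util import round_half_up

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (10_000, 100_000)


@dataclass(frozen=True)
class TargetPair:
    lnc_id: str
    gene_id: str
    mode: str  # cis10k | cis100k | trans
    distance: int | None = None  # genomic gap, cis modes only
    r: float | None = None  # Pearson correlation, trans mode only


def _window_mode(window: int) -> str:
    return f"cis{window // 1000}k" if window % 1000 == 0 else f"cis{window}"


def cis_targets(
    lncs: Iterable[TranscriptModel],
    genes: AnnotationSet,
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> list[TargetPair]:
    """Coding genes within each genomic window of a lncRNA span.

    Distance is the gap between spans (0 on overlap), strand-agnostic, same
    chromosome only.  Each (lnc, gene) pair is reported once, at the
    smallest qualifying window.
    """
    windows = sorted(windows)
    max_w = windows[-1]
    span_ix = IntervalIndex()
    for gid, gene in genes.genes.items():
        if gene.biotype == "noncoding":
            continue
        span = genes.gene_span(gid)
        span_ix.add(span.chrom, span.start, span.end, gid)

    pairs: list[TargetPair] = []
    for lnc in sorted(lncs, key=lambda t: t.transcript_id):
        span = lnc.span
        q_start = max(0, span.start - max_w)
        q_end = span.end + max_w
        for g_start, g_end, gid in span_ix.query(lnc.chrom, q_start, q_end):
            gap = max(0, max(span.start, g_start) - min(span.end, g_end))
            for w in windows:
                if gap <= w:
                    pairs.append(TargetPair(lnc.transcript_id, gid, _window_mode(w), gap))
                    break
    return pairs


def trans_targets(
    lnc_fpkm: pd.DataFrame,
    gene_fpkm: pd.DataFrame,
    r_threshold: float = 0.9,
) -> list[TargetPair]:
    """Pairs with |Pearson r| >= threshold on log2(FPKM + 1) profiles.

    Sample columns must match in the same order; constant profiles yield no
    pair (r undefined).
    """
    if list(lnc_fpkm.columns) != list(gene_fpkm.columns):
        raise ValueError("sample order mismatch between lncRNA and gene profiles")
    if lnc_fpkm.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    lx = np.log2(lnc_fpkm.to_numpy(dtype=float) + 1.0)
    gx = np.log2(gene_fpkm.to_numpy(dtype=float) + 1.0)
    n = lx.shape[1]

    def standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        z = np.zeros_like(x)
        np.divide(x - mu, sd, out=z, where=sd > 0)
        return z, ok

    lz, l_ok = standardize(lx)
    gz, g_ok = standardize(gx)
    r = (lz @ gz.T) / n
    pairs: list[TargetPair] = []
    for i, lid in enumerate(lnc_fpkm.index):
        if not l_ok[i]:
            continue
        for j in np.nonzero(np.abs(r[i]) >= r_threshold)[0]:
            if not g_ok[j]:
                continue
            pairs.append(
                TargetPair(str(lid), str(gene_fpkm.index[j]), "trans", r=float(r[i, j]))
            )
    return pairs


def intronic_host_concordance(
    intronic_records: Sequence[LncRNARecord],
    res: ContrastResult,
) -> tuple[float, pd.DataFrame]:
    """Fraction of intronic lncRNA / host-gene pairs with equal DE calls
    (up=up, down=down, ns=ns) in the given contrast.

    Pairs whose host is absent from the result are skipped with a warning;
    the returned table lists every evaluated pair.  With no evaluable pairs
    the fraction is NaN.
    """
    rows = []
    for rec in intronic_records:
        if rec.host_gene_id is None:
            continue
        if rec.host_gene_id not in res.table.index or rec.transcript_id not in res.table.index:
            logger.warning(
                "skipping pair (%s, %s): missing from contrast result",
                rec.transcript_id,
                rec.host_gene_id,
            )
            continue
        lnc_call = res.table.at[rec.transcript_id, "call"]
        host_call = res.table.at[rec.host_gene_id, "call"]
        rows.append(
            {
                "lnc_id": rec.transcript_id,
                "host_gene_id": rec.host_gene_id,
                "lnc_call": lnc_call,
                "host_call": host_call,
                "concordant": lnc_call == host_call,
            }
        )
    table = pd.DataFrame(rows, columns=["lnc_id", "host_gene_id", "lnc_call", "host_call", "concordant"])
    frac = float(table["concordant"].mean()) if len(table) else float("nan")
    return frac, table


@dataclass
class PrecursorSummary:
    total: int
    counts: dict[str, int]  # family -> count (one best family per lncRNA)
    percentages: dict[str, float]  # rounded half-up, one decimal


def precursor_summary(
    rfam_hits: Sequence[ToolHit], e_cutoff: float = 1e-5
) -> PrecursorSummary:
    """Summarize putative small-RNA precursors from rfam-scan hits.

    Hits above the e-value cutoff are dropped; each lncRNA is counted once
    under its best (lowest-E, ties by family name) family.
    """
    best: dict[str, ToolHit] = {}
    for h in rfam_hits:
        if h.e_value is None or h.e_value > e_cutoff:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, h.label) < (cur.e_value, cur.label):
            best[h.query_id] = h
    counts: dict[str, int] = {}
    for h in best.values():
        counts[h.label] = counts.get(h.label, 0) + 1
    total = len(best)
    percentages = {
        fam: round_half_up(100.0 * n / total, 1) for fam, n in sorted(counts.items())
    } if total else {}
    return PrecursorSummary(total, dict(sorted(counts.items())), percentages)
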