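"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the package's own algorithms: linear scans,
exhaustive enumeration and textbook definitions only.
"""
from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq: str) -> tuple[int, int, int | None]:
    """Enumerate every ATG/stop pair in all 3 frames; return
    (longest_nt, frame, start) with ties broken by smallest start then frame."""
    seq = seq.upper().replace("U", "T")
    best = (0, 0, None)
    candidates = []
    for frame in range(3):
        for p in range(frame, len(seq) - 2, 3):
            if seq[p : p + 3] != "ATG":
                continue
            q = p + 3
            while q + 3 <= len(seq):
                codon = seq[q : q + 3]
                if "N" in codon:
                    break  # ORF would contain an N codon: skip it
                if codon in STOPS:
                    candidates.append((q + 3 - p, p, frame))
                    break
                q += 3
    if not candidates:
        return best
    length = max(c[0] for c in candidates)
    start, frame = min((c[1], c[2]) for c in candidates if c[0] == length)
    return (length, frame, start)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up: adj_i = min over ranks t >= rank_i of min(1, m p_(t)/t)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(1.0, m * sorted_p[t] / (t + 1)) for t in range(i, m)
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def brute_force_overlaps(
    intervals: list[tuple[str, int, int, object]],
    chrom: str,
    start: int,
    end: int,
) -> set[object]:
    """Linear scan for intervals overlapping [start, end) on chrom."""
    return {
        payload
        for (c, s, e, payload) in intervals
        if c == chrom and s < end and e > start
    }


def brute_force_cis_pairs(
    lnc_spans: dict[str, tuple[str, int, int]],
    gene_spans: dict[str, tuple[str, int, int]],
    windows: tuple[int, ...] = (10_000, 100_000),
) -> set[tuple[str, str, int, int]]:
    """All-pairs distance check: (lnc, gene, smallest window, gap)."""
    out = set()
    for lid, (lc, ls, le) in lnc_spans.items():
        for gid, (gc, gs, ge) in gene_spans.items():
            if lc != gc:
                continue
            gap = max(0, max(ls, gs) - min(le, ge))
            for w in sorted(windows):
                if gap <= w:
                    out.add((lid, gid, w, gap))
                    break
    return out


def fpkm_formula(count: float, length_nt: float, total_fragments: float) -> float:
    return count / ((length_nt / 1e3) * (total_fragments / 1e6))
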