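"""Synthetic-data generator with planted ground truth.

Emulates the pipeline's inputs end to end: a two-subgenome chromosome set
(At_*/Dt_* plus unplaced scaffolds), intron-containing coding genes, planted
lncRNAs of the three positional classes, decoy mRNA isoforms, sub-length and
silent transcripts, NB counts over a 3-condition x 3-replicate design with
planted response patterns, and consistent CPC/Pfam/rfam/repeat tables.

Every structural fact is recorded in the truth table so each pipeline stage
can be checked against planted labels.  All randomness flows from
``SynthConfig.seed``; re-running with the same config yields byte-identical
files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annio import (
    AnnotationSet,
    GenomicInterval,
    ToolHit,
    TranscriptModel,
    write_bed,
    write_fasta,
    write_gtf,
)
from .lncfilter import STOP_CODONS, find_longest_orf

NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)

DEFAULT_PATTERN_PROPS = {
    "sustained_up": 0.12,
    "drought_specific_up": 0.10,
    "delayed_up": 0.10,
    "sustained_down": 0.06,
    "drought_specific_down": 0.06,
    "delayed_down": 0.06,
}

PATTERN_MULTIPLIERS = {
    # pattern -> (C, D, ReW) condition-mean multipliers (m = effect multiplier)
    "none": (1.0, 1.0, 1.0),
    "sustained_up": (1.0, "m", "m"),
    "drought_specific_up": (1.0, "m", 1.0),
    "delayed_up": (1.0, 1.0, "m"),
    "sustained_down": (1.0, "1/m", "1/m"),
    "drought_specific_down": (1.0, "1/m", 1.0),
    "delayed_down": (1.0, 1.0, "1/m"),
}


@dataclass
class SynthConfig:
    seed: int = 0
    n_chrom_per_subgenome: int = 2
    n_scaffolds: int = 1
    chrom_length: int | None = None  # None = unbounded coordinate line
    n_coding_genes: int = 60
    n_linc: int = 40
    n_intronic: int = 10
    n_antisense: int = 10
    n_decoy_isoforms: int = 15
    n_short: int = 8
    n_silent: int = 8
    n_coding_like: int = 8
    # anchored on observed lncRNA features: mean length ~686 nt within
    # [200, 12057], ~46% single-exon
    lnc_len_log_mean: float = math.log(600.0)
    lnc_len_log_sd: float = 0.45
    lnc_len_range: tuple[int, int] = (200, 12_057)
    single_exon_frac: float = 0.46
    max_lnc_exons: int = 9
    gene_exon_count_range: tuple[int, int] = (2, 12)
    gene_exon_len_range: tuple[int, int] = (150, 400)
    gene_intron_len_range: tuple[int, int] = (600, 2_000)
    gene_gap_range: tuple[int, int] = (5_000, 20_000)
    lnc_gap_range: tuple[int, int] = (2_000, 8_000)
    orf_threshold_nt: int = 300
    nb_dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (50.0, 500.0)
    effect_multiplier: float = 4.0
    pattern_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_PROPS)
    )
    gene_pattern_frac: float = 0.2
    concordance_rate: float = 0.76
    n_trans_pairs: int = 10
    trans_noise_sd: float = 0.05
    repeat_density: dict[str, float] = field(
        default_factory=lambda: {"Satellite": 0.4, "LTR/Copia": 0.3, "LTR/Gypsy": 0.1}
    )
    precursor_counts: dict[str, int] = field(
        default_factory=lambda: {"miRNA": 8, "tRNA": 3, "snoRNA": 2}
    )
    cpc_noise: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.pattern_props.values())
        if not 0 <= total <= 1 + 1e-9:
            raise ValueError("pattern proportions must sum to <= 1")
        if sum(self.precursor_counts.values()) > self.n_linc + self.n_intronic + self.n_antisense:
            raise ValueError("more precursors requested than lncRNAs")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SynthConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("lnc_len_range", "gene_exon_count_range", "gene_exon_len_range",
                    "gene_intron_len_range", "gene_gap_range", "lnc_gap_range",
                    "base_mean_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)  # type: ignore[arg-type]


TRUTH_COLUMNS = [
    "kind", "is_lnc", "positional_class", "coding", "expressed", "pattern",
    "host_gene", "trans_partner", "precursor_family", "length", "chrom", "strand",
]


def _chrom_names(cfg: SynthConfig) -> list[str]:
    names = [f"At_chr{i + 1}" for i in range(cfg.n_chrom_per_subgenome)]
    names += [f"Dt_chr{i + 1}" for i in range(cfg.n_chrom_per_subgenome)]
    names += [f"scaffold{i + 1}" for i in range(cfg.n_scaffolds)]
    return names


def _lnc_length(rng: np.random.Generator, cfg: SynthConfig) -> int:
    lo, hi = cfg.lnc_len_range
    return int(np.clip(rng.lognormal(cfg.lnc_len_log_mean, cfg.lnc_len_log_sd), lo, hi))


def _lnc_exon_layout(
    rng: np.random.Generator, cfg: SynthConfig, chrom: str, strand: str,
    start: int, length: int,
) -> list[GenomicInterval]:
    """Split a spliced length into 1..max exons starting at `start`."""
    if length < 2 * cfg.max_lnc_exons or rng.random() < cfg.single_exon_frac:
        n_ex = 1
    else:
        n_ex = int(rng.integers(2, cfg.max_lnc_exons + 1))
        n_ex = min(n_ex, length // 50)
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_ex - 1, replace=False)) if n_ex > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [length]])).astype(int)
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append(GenomicInterval(chrom, pos, pos + int(size), strand))
        pos += int(size)
        if i < len(sizes) - 1:
            pos += int(rng.integers(80, 500))  # intron
    return exons


def generate_annotation(
    cfg: SynthConfig,
) -> tuple[AnnotationSet, AnnotationSet, pd.DataFrame]:
    """Build (reference annotation, assembled-transcripts annotation, truth).

    Coding genes are packed per chromosome without overlap; lincRNAs (and
    the other intergenic transcript kinds) follow the last gene on each
    chromosome at controlled gaps; intronic lncRNAs sit wholly inside gene
    introns; antisense lncRNAs overlap coding exons on the opposite strand.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = _chrom_names(cfg)
    cursor = {c: 1_000 for c in chroms}
    ref = AnnotationSet()
    asm = AnnotationSet()
    truth_rows: dict[str, dict] = {}

    def check_length(chrom: str) -> None:
        if cfg.chrom_length is not None and cursor[chrom] > cfg.chrom_length:
            raise ValueError(
                f"infeasible packing: {chrom} exceeds chrom_length={cfg.chrom_length}; "
                "increase chrom_length or reduce feature counts"
            )

    # --- coding genes -----------------------------------------------------
    gene_info: list[dict] = []
    for gi in range(cfg.n_coding_genes):
        chrom = chroms[gi % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor[chrom] + int(rng.integers(*cfg.gene_gap_range))
        n_ex = int(rng.integers(cfg.gene_exon_count_range[0], cfg.gene_exon_count_range[1] + 1))
        exons, introns = [], []
        pos = start
        for ei in range(n_ex):
            elen = int(rng.integers(*cfg.gene_exon_len_range))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if ei < n_ex - 1:
                ilen = int(rng.integers(*cfg.gene_intron_len_range))
                introns.append((pos, pos + ilen))
                pos += ilen
        cursor[chrom] = pos
        check_length(chrom)
        gid = f"gene{gi + 1:05d}"
        tid = f"{gid}.t1"
        ref.add(TranscriptModel(tid, gid, chrom, strand, exons), biotype="coding")
        gene_info.append(
            {"gene_id": gid, "tid": tid, "chrom": chrom, "strand": strand,
             "exons": exons, "introns": introns}
        )
        truth_rows[tid] = {
            "kind": "coding_gene", "is_lnc": False, "positional_class": "",
            "coding": True, "expressed": True, "pattern": "none",
            "host_gene": "", "trans_partner": "", "precursor_family": "",
            "length": sum(len(e) for e in exons), "chrom": chrom, "strand": strand,
        }

    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:06d}"

    def add_asm(t: TranscriptModel, **truth) -> None:
        asm.add(t)
        truth_rows[t.transcript_id] = {
            "kind": truth["kind"], "is_lnc": truth.get("is_lnc", False),
            "positional_class": truth.get("positional_class", ""),
            "coding": truth.get("coding", False),
            "expressed": truth.get("expressed", True),
            "pattern": "none", "host_gene": truth.get("host_gene", ""),
            "trans_partner": "", "precursor_family": "",
            "length": t.length, "chrom": t.chrom, "strand": t.strand,
        }

    # --- decoy same-strand mRNA isoforms (removed at the known-overlap step)
    if cfg.n_decoy_isoforms and not gene_info:
        raise ValueError("cannot plant decoy isoforms without coding genes")
    for _ in range(cfg.n_decoy_isoforms):
        g = gene_info[int(rng.integers(len(gene_info)))]
        exons = list(g["exons"])
        if len(exons) >= 3 and rng.random() < 0.5:
            exons = exons[:-1]  # drop last exon
        else:
            e0 = exons[0]
            trim = min(len(e0) // 3, len(e0) - 50)
            exons[0] = GenomicInterval(e0.chrom, e0.start + trim, e0.end, e0.strand)
        tid = next_id("iso")
        length = sum(len(e) for e in exons)
        add_asm(
            TranscriptModel(tid, tid, g["chrom"], g["strand"], exons),
            kind="decoy_isoform", coding=length >= cfg.orf_threshold_nt + 9,
        )

    # --- intergenic transcripts: lincRNAs, short, silent, coding-like ------
    intergenic_plan = (
        [("linc", True)] * cfg.n_linc
        + [("short", False)] * cfg.n_short
        + [("silent", False)] * cfg.n_silent
        + [("coding_like", False)] * cfg.n_coding_like
    )
    for i, (kind, is_lnc) in enumerate(intergenic_plan):
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "short":
            length = int(rng.integers(150, 200))
        elif kind == "coding_like":
            length = max(_lnc_length(rng, cfg), cfg.orf_threshold_nt + 120)
        else:
            length = _lnc_length(rng, cfg)
        start = cursor[chrom] + int(rng.integers(*cfg.lnc_gap_range))
        exons = _lnc_exon_layout(rng, cfg, chrom, strand, start, length)
        cursor[chrom] = exons[-1].end
        check_length(chrom)
        tid = next_id("lnc" if kind in ("linc", "silent") else kind)
        add_asm(
            TranscriptModel(tid, tid, chrom, strand, exons),
            kind=kind,
            is_lnc=(kind == "linc"),
            positional_class="lincRNA" if kind == "linc" else "",
            coding=(kind == "coding_like"),
            expressed=(kind != "silent"),
        )

    # --- intronic lncRNAs ---------------------------------------------------
    host_pool = [
        (g, k) for g in gene_info for k in range(len(g["introns"]))
        if g["introns"][k][1] - g["introns"][k][0] >= 204
    ]
    if cfg.n_intronic > len(host_pool):
        raise ValueError("not enough introns to host the requested intronic lncRNAs")
    picks = rng.choice(len(host_pool), size=cfg.n_intronic, replace=False)
    for p in picks:
        g, k = host_pool[int(p)]
        ist, ien = g["introns"][k]
        avail = ien - ist - 2
        length = min(_lnc_length(rng, cfg), avail)
        start = ist + 1 + int(rng.integers(0, avail - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tid = next_id("lnc")
        add_asm(
            TranscriptModel(
                tid, tid, g["chrom"], strand,
                [GenomicInterval(g["chrom"], start, start + length, strand)],
            ),
            kind="intronic", is_lnc=True, positional_class="intronic",
            host_gene=g["gene_id"],
        )
        truth_rows[tid]["host_gene"] = g["gene_id"]

    # --- antisense lncRNAs --------------------------------------------------
    exon_pool = [(g, e) for g in gene_info for e in g["exons"]]
    if cfg.n_antisense > len(exon_pool):
        raise ValueError("not enough coding exons to host antisense lncRNAs")
    picks = rng.choice(len(exon_pool), size=cfg.n_antisense, replace=False)
    for p in picks:
        g, exon = exon_pool[int(p)]
        strand = "-" if g["strand"] == "+" else "+"
        length = int(rng.integers(200, 801))
        min_ov = min(50, len(exon))
        lo = exon.start - (length - min_ov)
        hi = exon.end - min_ov
        start = max(0, int(rng.integers(lo, hi + 1)))
        tid = next_id("lnc")
        add_asm(
            TranscriptModel(
                tid, tid, g["chrom"], strand,
                [GenomicInterval(g["chrom"], start, start + length, strand)],
            ),
            kind="antisense", is_lnc=True, positional_class="antisense",
            host_gene=g["gene_id"],
        )
        truth_rows[tid]["host_gene"] = g["gene_id"]

    truth = pd.DataFrame.from_dict(truth_rows, orient="index")[TRUTH_COLUMNS]
    truth.index.name = "transcript_id"
    _plant_patterns(rng, cfg, truth)
    _plant_trans_pairs(rng, cfg, truth)
    _plant_precursors(rng, cfg, truth)
    return ref, asm, truth


def _plant_patterns(rng: np.random.Generator, cfg: SynthConfig, truth: pd.DataFrame) -> None:
    """Assign DE response patterns to lncRNAs, hosts and background genes."""
    patterns = list(cfg.pattern_props)
    probs = np.array([cfg.pattern_props[p] for p in patterns])
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    choices = patterns + ["none"]

    lnc_ids = truth.index[truth["is_lnc"] & truth["expressed"]]
    drawn = rng.choice(len(choices), size=len(lnc_ids), p=probs)
    truth.loc[lnc_ids, "pattern"] = [choices[i] for i in drawn]

    # hosts of intronic lncRNAs: concordant on the D-vs-C call with planted rate
    d_call = {
        "none": "ns",
        "sustained_up": "up", "drought_specific_up": "up",
        "sustained_down": "down", "drought_specific_down": "down",
        "delayed_up": "ns", "delayed_down": "ns",
    }
    call_to_pattern = {"up": "sustained_up", "down": "sustained_down", "ns": "none"}
    intronic = truth[(truth["kind"] == "intronic")]
    for tid, row in intronic.iterrows():
        host_tid = f"{row['host_gene']}.t1"
        lnc_d = d_call[row["pattern"]]
        if rng.random() < cfg.concordance_rate:
            host_d = lnc_d
        else:
            host_d = rng.choice([c for c in ("up", "down", "ns") if c != lnc_d])
        truth.at[host_tid, "pattern"] = call_to_pattern[host_d]

    # background genes: a fraction get random patterns for realism
    host_tids = {f"{h}.t1" for h in intronic["host_gene"]}
    gene_ids = [
        t for t in truth.index[truth["kind"] == "coding_gene"] if t not in host_tids
    ]
    for tid in gene_ids:
        if rng.random() < cfg.gene_pattern_frac:
            truth.at[tid, "pattern"] = choices[int(rng.choice(len(choices), p=probs))]


def _plant_trans_pairs(rng: np.random.Generator, cfg: SynthConfig, truth: pd.DataFrame) -> None:
    lnc_ids = [
        t for t in truth.index
        if truth.at[t, "kind"] == "linc" and truth.at[t, "pattern"] != "none"
    ]
    host_tids = {
        f"{h}.t1" for h in truth.loc[truth["kind"] == "intronic", "host_gene"]
    }
    gene_tids = [
        t for t in truth.index[truth["kind"] == "coding_gene"] if t not in host_tids
    ]
    n = min(cfg.n_trans_pairs, len(lnc_ids), len(gene_tids))
    li = rng.choice(len(lnc_ids), size=n, replace=False)
    gi = rng.choice(len(gene_tids), size=n, replace=False)
    for a, b in zip(li, gi):
        truth.at[lnc_ids[int(a)], "trans_partner"] = gene_tids[int(b)]
        truth.at[gene_tids[int(b)], "trans_partner"] = lnc_ids[int(a)]


def _plant_precursors(rng: np.random.Generator, cfg: SynthConfig, truth: pd.DataFrame) -> None:
    lnc_ids = list(truth.index[truth["is_lnc"]])
    total = sum(cfg.precursor_counts.values())
    picks = rng.choice(len(lnc_ids), size=total, replace=False)
    it = iter(picks)
    for family, n in cfg.precursor_counts.items():
        for _ in range(n):
            truth.at[lnc_ids[int(next(it))], "precursor_family"] = family


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _suppress_orfs(seq: str, threshold: int) -> str:
    """Insert in-frame stops until no complete ORF reaches the threshold."""
    while True:
        res = find_longest_orf(seq)
        if res.longest_orf_nt < threshold:
            return seq
        n_codons = res.longest_orf_nt // 3
        mid = res.start_offset + 3 * (n_codons // 2)
        seq = seq[:mid] + "TAA" + seq[mid + 3 :]


def _plant_orf(rng: np.random.Generator, seq: str, threshold: int) -> str:
    """Overwrite a window with an ATG + non-stop codons + stop ORF >= threshold."""
    orf_nt = 3 * math.ceil(threshold / 3) + 3 * int(rng.integers(0, 20))
    orf_nt = min(orf_nt, 3 * ((len(seq) - 3) // 3))
    if orf_nt < threshold:
        raise ValueError(f"sequence of {len(seq)} nt too short to plant a {threshold} nt ORF")
    n_mid = orf_nt // 3 - 2
    codons = ["ATG"] + [
        NON_STOP_CODONS[int(i)]
        for i in rng.integers(0, len(NON_STOP_CODONS), size=n_mid)
    ] + ["TAA"]
    orf = "".join(codons)
    start = int(rng.integers(0, len(seq) - len(orf) + 1))
    return seq[:start] + orf + seq[start + len(orf) :]


def generate_sequences(
    annotation: AnnotationSet, truth: pd.DataFrame, cfg: SynthConfig
) -> dict[str, str]:
    """Per-transcript nucleotide sequences consistent with planted coding flags.

    Planted-coding transcripts carry a complete ORF of at least the
    threshold; planted-noncoding transcripts are ORF-suppressed below it.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    out: dict[str, str] = {}
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        seq = _random_seq(rng, t.length)
        if bool(truth.at[tid, "coding"]):
            seq = _plant_orf(rng, seq, cfg.orf_threshold_nt)
        else:
            seq = _suppress_orfs(seq, cfg.orf_threshold_nt)
        out[tid] = seq
    return out


def make_design(n_reps: int = 3) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{cond}_{r}", "condition": cond, "replicate": r}
        for cond in ("C", "D", "ReW")
        for r in range(1, n_reps + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def generate_counts(
    truth: pd.DataFrame, cfg: SynthConfig, design: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """NB(mu, phi) counts realizing the planted patterns.

    Returns (counts, design, library totals).  Planted trans partners share
    per-sample Poisson rates (up to lognormal noise) so their log-FPKM
    profiles are strongly correlated; silent transcripts are all-zero.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if design is None:
        design = make_design()
    samples = list(design.index)
    conds = design["condition"].to_numpy()
    m = cfg.effect_multiplier
    ids = list(truth.index)
    n_t, n_s = len(ids), len(samples)

    base_mu = np.exp(
        rng.uniform(np.log(cfg.base_mean_range[0]), np.log(cfg.base_mean_range[1]), size=n_t)
    )
    mult = np.ones((n_t, n_s))
    for i, tid in enumerate(ids):
        spec = PATTERN_MULTIPLIERS[truth.at[tid, "pattern"]]
        per_cond = {
            "C": spec[0],
            "D": m if spec[1] == "m" else (1 / m if spec[1] == "1/m" else spec[1]),
            "ReW": m if spec[2] == "m" else (1 / m if spec[2] == "1/m" else spec[2]),
        }
        mult[i] = [per_cond[c] for c in conds]

    mu = base_mu[:, None] * mult
    phi = cfg.nb_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)

    # trans partners: the gene re-uses the lncRNA's per-sample rates
    idx_of = {tid: i for i, tid in enumerate(ids)}
    for tid in ids:
        partner = truth.at[tid, "trans_partner"]
        if partner and truth.at[tid, "kind"] == "coding_gene":
            li = idx_of[partner]
            noise = np.exp(rng.normal(0.0, cfg.trans_noise_sd, size=n_s))
            lam[idx_of[tid]] = 2.0 * lam[li] * noise

    counts = rng.poisson(lam)
    expressed = truth["expressed"].to_numpy(dtype=bool)
    counts[~expressed] = 0
    df = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"), columns=samples)
    totals = df.sum(axis=0).astype(float)
    return df, design, totals


@dataclass
class AuxTables:
    cpc: list[ToolHit]
    pfam: list[ToolHit]
    rfam: list[ToolHit]
    repeats: list[tuple[GenomicInterval, str]]


def generate_aux_tables(
    truth: pd.DataFrame,
    cfg: SynthConfig,
    annotation: AnnotationSet,
) -> AuxTables:
    """Synthetic CPC/Pfam/rfam/repeat tables consistent with the truth table.

    CPC labels follow the coding flag with optional flip noise; Pfam hits at
    E=1e-6 mark planted-coding transcripts (plus above-threshold decoys);
    rfam hits mark planted precursors below the e-value cutoff with decoys
    above it; repeat intervals are placed inside lncRNA spans at the planted
    per-family densities, plus off-transcript background intervals.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    asm_ids = [t for t in sorted(annotation.transcripts) ]

    cpc: list[ToolHit] = []
    pfam: list[ToolHit] = []
    for tid in asm_ids:
        coding = bool(truth.at[tid, "coding"])
        label_coding = coding if rng.random() >= cfg.cpc_noise else not coding
        cpc.append(
            ToolHit(tid, "coding" if label_coding else "noncoding",
                    score=round(float(rng.uniform(0.5, 5.0)), 3))
        )
        if coding:
            pfam.append(ToolHit(tid, label="SynthDomain", accession="PF00001", e_value=1e-6))
        elif rng.random() < 0.05:
            # decoy hit above the e-value threshold: must be ignored downstream
            pfam.append(ToolHit(tid, label="WeakDomain", accession="PF09999", e_value=1e-2))

    rfam: list[ToolHit] = []
    fam_acc = {"miRNA": "RF00001", "tRNA": "RF00005", "snoRNA": "RF00012", "other": "RF09999"}
    lnc_ids = [t for t in asm_ids if bool(truth.at[t, "is_lnc"])]
    for tid in lnc_ids:
        family = truth.at[tid, "precursor_family"]
        if family:
            e = 10.0 ** rng.uniform(-9, -6)
            rfam.append(ToolHit(tid, label=family, accession=fam_acc.get(family, "RF09999"), e_value=float(e)))
            if rng.random() < 0.2:  # secondary, worse-family hit (best-hit rule)
                other = "other" if family != "other" else "snoRNA"
                rfam.append(
                    ToolHit(tid, label=other, accession=fam_acc[other],
                            e_value=float(10.0 ** rng.uniform(-5.9, -5.2)))
                )
        elif rng.random() < 0.1:
            rfam.append(
                ToolHit(tid, label="other", accession="RF09999",
                        e_value=float(10.0 ** rng.uniform(-4, -2)))
            )

    repeats: list[tuple[GenomicInterval, str]] = []
    max_end: dict[str, int] = {}
    for t in annotation:
        span = t.span
        max_end[t.chrom] = max(max_end.get(t.chrom, 0), span.end)
    for family in sorted(cfg.repeat_density):
        density = cfg.repeat_density[family]
        k = int(round(density * len(lnc_ids)))
        picks = rng.choice(len(lnc_ids), size=k, replace=False) if k else []
        for p in picks:
            t = annotation.transcripts[lnc_ids[int(p)]]
            span = t.span
            width = min(100, len(span))
            start = span.start + int(rng.integers(0, len(span) - width + 1))
            repeats.append((GenomicInterval(t.chrom, start, start + width, "."), family))
        # background intervals clear of any transcript span
        for chrom in sorted(max_end):
            off = max_end[chrom] + 50_000 + int(rng.integers(0, 10_000))
            repeats.append((GenomicInterval(chrom, off, off + 500, "."), family))
    return AuxTables(cpc, pfam, rfam, repeats)


def write_tool_table(hits: Sequence[ToolHit], path: str | Path, dialect: str) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            if dialect == "cpc":
                fh.write(f"{h.query_id}\t{h.label}\t{h.score}\n")
            elif dialect in ("pfam", "rfam"):
                fh.write(f"{h.query_id}\t{h.accession}\t{h.label}\t{h.e_value!r}\n")
            else:
                raise ValueError(f"unsupported dialect {dialect}")


@dataclass
class SynthDataset:
    cfg: SynthConfig
    reference: AnnotationSet
    assembled: AnnotationSet
    truth: pd.DataFrame
    sequences: dict[str, str]
    counts: pd.DataFrame
    design: pd.DataFrame
    totals: pd.Series
    aux: AuxTables
    paths: dict[str, Path] = field(default_factory=dict)


def generate_dataset(cfg: SynthConfig, outdir: str | Path | None = None) -> SynthDataset:
    """Generate the full synthetic dataset; optionally write all files."""
    ref, asm, truth = generate_annotation(cfg)
    seqs = generate_sequences(asm, truth, cfg)
    counts, design, totals = generate_counts(truth, cfg)
    aux = generate_aux_tables(truth, cfg, asm)
    ds = SynthDataset(cfg, ref, asm, truth, seqs, counts, design, totals, aux)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref_gtf": outdir / "ref.gtf",
            "gtf": outdir / "transcripts.gtf",
            "fasta": outdir / "transcripts.fa",
            "counts": outdir / "counts.tsv",
            "design": outdir / "design.csv",
            "totals": outdir / "library_totals.tsv",
            "truth": outdir / "truth.tsv",
            "cpc": outdir / "cpc.tsv",
            "pfam": outdir / "pfam.tsv",
            "rfam": outdir / "rfam.tsv",
            "repeats": outdir / "repeats.bed",
        }
        write_gtf(ref, paths["ref_gtf"])
        write_gtf(asm, paths["gtf"])
        write_fasta(seqs, paths["fasta"])
        counts.to_csv(paths["counts"], sep="\t")
        design.reset_index().to_csv(paths["design"], index=False)
        totals.rename("total_fragments").to_csv(paths["totals"], sep="\t")
        truth.to_csv(paths["truth"], sep="\t")
        write_tool_table(aux.cpc, paths["cpc"], "cpc")
        write_tool_table(aux.pfam, paths["pfam"], "pfam")
        write_tool_table(aux.rfam, paths["rfam"], "rfam")
        write_bed(aux.repeats, paths["repeats"])
        ds.paths = paths
    return ds
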