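"""End-to-end pipeline driver, run configuration and the summary report."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import annio, express, lncclass, lncfilter, targets as targets_mod
from .annio import AnnotationSet
from .express import ContrastResult, ExpressionMatrix
from .lncfilter import FiltrationReport, IdentifyConfig
from .lncclass import ClassSummary, LncRNARecord
from .util import format_percent

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run.

    Unknown keys in a YAML config are rejected; every threshold used is
    echoed into the output directory for provenance.
    """

    gtf: str
    ref_gtf: str
    fasta: str
    counts: str
    design: str
    out_dir: str
    totals: str | None = None
    cpc: str | None = None
    pfam: str | None = None
    rfam: str | None = None
    repeats: str | None = None
    seed: int = 0
    identify: IdentifyConfig = field(default_factory=IdentifyConfig)
    alpha: float = 0.05
    min_lfc: float = 1.0
    r_threshold: float = 0.9
    cis_windows: tuple[int, int] = (10_000, 100_000)
    rfam_evalue: float = 1e-5
    pct_decimals: int = 1
    small_pct_decimals: int | None = 2

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "identify" in d and isinstance(d["identify"], Mapping):
            d["identify"] = IdentifyConfig.from_dict(d["identify"])
        if "cis_windows" in d and isinstance(d["cis_windows"], list):
            d["cis_windows"] = tuple(d["cis_windows"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cis_windows"] = list(self.cis_windows)
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SummaryReport:
    filtration: list[tuple[str, int, int]]
    class_counts: dict[str, int]
    class_percentages: dict[str, float]
    per_subgenome: dict[str, dict[str, int]]
    de_counts: dict[str, dict[str, int]]  # contrast -> {up, down}
    pattern_counts: dict[str, int]
    directional_fractions: dict[str, dict[str, dict[str, float | None]]]
    target_counts: dict[str, int]  # mode -> n pairs
    precursor_total: int
    precursor_counts: dict[str, int]
    precursor_percentages: dict[str, float]
    repeat_fractions: dict[str, dict[str, float | None]]
    intronic_host_concordance: float | None
    thresholds: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        """Re-assert internal identities before rendering."""
        total = sum(self.class_counts.values())
        sub_total = sum(sum(v.values()) for v in self.per_subgenome.values())
        if total and sub_total != total:
            raise ValueError("per-subgenome counts do not sum to the class total")
        pc = self.pattern_counts
        if pc:
            a_up = self.de_counts.get("D_vs_C", {}).get("up")
            b_up = self.de_counts.get("ReW_vs_C", {}).get("up")
            if a_up is not None and pc["sustained_up"] + pc["drought_specific_up"] != a_up:
                raise ValueError("pattern identity violated for the drought contrast")
            if b_up is not None and pc["sustained_up"] + pc["delayed_up"] != b_up:
                raise ValueError("pattern identity violated for the rewatering contrast")
        if sum(self.precursor_counts.values()) != self.precursor_total:
            raise ValueError("precursor family counts do not sum to the total")


def _load_expression(cfg: RunConfig, annotations: list[AnnotationSet]) -> ExpressionMatrix:
    counts = express.read_counts_tsv(cfg.counts)
    design = express.read_design_csv(cfg.design)
    lengths = {}
    for ann in annotations:
        for t in ann:
            lengths[t.transcript_id] = t.length
    lengths_s = pd.Series(lengths)
    # tolerate count rows without annotation (dropped with a warning)
    known = counts.index.intersection(lengths_s.index)
    if len(known) < len(counts):
        logger.warning("dropping %d count rows without annotation", len(counts) - len(known))
        counts = counts.loc[known]
    totals = None
    if cfg.totals:
        totals = pd.read_csv(cfg.totals, sep="\t", index_col=0).iloc[:, 0].astype(float)
    return ExpressionMatrix(counts, design, lengths_s.loc[counts.index], totals)


def gene_level_counts(counts: pd.DataFrame, annotation: AnnotationSet) -> pd.DataFrame:
    """Sum member-transcript count rows into per-gene rows."""
    rows = {}
    for gid, gene in annotation.genes.items():
        tids = [t for t in gene.transcript_ids if t in counts.index]
        if tids:
            rows[gid] = counts.loc[tids].sum(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def run_all(cfg: RunConfig) -> SummaryReport:
    """Execute identify -> classify -> DE/patterns -> targets -> summaries.

    Writes the surviving-lncRNA GTF, per-stage TSV tables, report.json and a
    resolved-config copy into ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")

    def _stage(name: str):
        logger.info("stage: %s", name)

    for path_attr in ("gtf", "ref_gtf", "fasta", "counts", "design"):
        p = getattr(cfg, path_attr)
        if not Path(p).exists():
            raise FileNotFoundError(f"input {path_attr} not found: {p}")

    _stage("load")
    asm = annio.read_gtf(cfg.gtf)
    ref = annio.read_gtf(cfg.ref_gtf)
    seqs = annio.read_fasta(cfg.fasta)
    expr = _load_expression(cfg, [asm, ref])
    cpc = annio.read_tool_table(cfg.cpc, "cpc") if cfg.cpc else None
    pfam = annio.read_tool_table(cfg.pfam, "pfam") if cfg.pfam else None
    rfam = annio.read_tool_table(cfg.rfam, "rfam") if cfg.rfam else None
    repeats = annio.read_bed(cfg.repeats) if cfg.repeats else None

    _stage("identify")
    survivors, filt_report, orf_map = lncfilter.run_identification(
        asm, ref, expr, seqs, cfg.identify, cpc_records=cpc, pfam_records=pfam
    )
    lnc_ids = [t.transcript_id for t in survivors]
    lnc_ann = AnnotationSet()
    for t in survivors:
        lnc_ann.add(t, biotype="noncoding")
    annio.write_gtf(lnc_ann, out / "lncrna.gtf")
    pd.DataFrame(
        [(s.name, s.n_input, s.n_retained, len(s.removed_ids)) for s in filt_report.steps],
        columns=["step", "n_input", "n_retained", "n_removed"],
    ).to_csv(out / "filtration.tsv", sep="\t", index=False)

    _stage("classify")
    records = lncclass.classify_all(survivors, ref, orf_results=orf_map)
    summary = lncclass.summarize_classes(
        records, pct_decimals=cfg.pct_decimals, small_pct_decimals=cfg.small_pct_decimals
    )
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        out / "lncrna_records.tsv", sep="\t", index=False
    )

    _stage("differential expression")
    contrasts: dict[str, ContrastResult] = {}
    gene_counts = gene_level_counts(expr.counts, ref)
    gene_lengths = pd.Series(
        {gid: sum(len(e) for e in ref.gene_exons(gid)) for gid in gene_counts.index}
    )
    de_universe = pd.concat([expr.counts.loc[lnc_ids], gene_counts])
    de_lengths = pd.concat([expr.lengths.loc[lnc_ids], gene_lengths])
    de_expr = ExpressionMatrix(de_universe, expr.design, de_lengths, expr.totals)
    for pair in (("D", "C"), ("ReW", "C"), ("ReW", "D")):
        res = express.nb_de_test(de_expr, pair, alpha=cfg.alpha, min_lfc=cfg.min_lfc)
        contrasts[res.name] = res
        res.table.to_csv(out / f"de_{res.name}.tsv", sep="\t")

    def lnc_subset(res: ContrastResult) -> ContrastResult:
        return ContrastResult(res.name, res.table.loc[lnc_ids])

    de_counts = {
        name: {"up": len(lnc_subset(res).up_ids()), "down": len(lnc_subset(res).down_ids())}
        for name, res in contrasts.items()
    }

    _stage("patterns")
    pattern = express.categorize_patterns(
        lnc_subset(contrasts["D_vs_C"]), lnc_subset(contrasts["ReW_vs_C"])
    )
    pattern.table.to_csv(out / "patterns.tsv", sep="\t")

    by_class = {
        c: [r.transcript_id for r in records if r.positional_class == c]
        for c in lncclass.POSITIONAL_CLASSES
    }
    fractions = express.directional_fraction(
        by_class, {k: contrasts[k] for k in ("D_vs_C", "ReW_vs_D")}
    )

    _stage("targets")
    cis = targets_mod.cis_targets(survivors, ref, cfg.cis_windows)
    lnc_fpkm = de_expr.fpkm().loc[lnc_ids]
    gene_fpkm = de_expr.fpkm().loc[gene_counts.index]
    trans = targets_mod.trans_targets(lnc_fpkm, gene_fpkm, cfg.r_threshold)
    pd.DataFrame([dataclasses.asdict(p) for p in cis + trans]).to_csv(
        out / "targets.tsv", sep="\t", index=False
    )
    target_counts: dict[str, int] = {}
    for p in cis + trans:
        target_counts[p.mode] = target_counts.get(p.mode, 0) + 1

    intronic_records = [r for r in records if r.positional_class == "intronic"]
    concordance, pair_table = targets_mod.intronic_host_concordance(
        intronic_records, contrasts["D_vs_C"]
    )
    pair_table.to_csv(out / "intronic_host_pairs.tsv", sep="\t", index=False)

    _stage("precursors & repeats")
    if rfam is not None:
        lnc_set = set(lnc_ids)
        prec = targets_mod.precursor_summary(
            [h for h in rfam if h.query_id in lnc_set], cfg.rfam_evalue
        )
    else:
        prec = targets_mod.PrecursorSummary(0, {}, {})
    repeat_fracs = (
        lncclass.repeat_overlap_summary(survivors, repeats) if repeats else {}
    )

    report = SummaryReport(
        filtration=filt_report.counts(),
        class_counts=summary.counts,
        class_percentages=summary.percentages,
        per_subgenome=summary.per_subgenome,
        de_counts=de_counts,
        pattern_counts=pattern.counts,
        directional_fractions=fractions,
        target_counts=target_counts,
        precursor_total=prec.total,
        precursor_counts=prec.counts,
        precursor_percentages=prec.percentages,
        repeat_fractions=repeat_fracs,
        intronic_host_concordance=concordance if concordance == concordance else None,
        thresholds={
            "identify": dataclasses.asdict(cfg.identify),
            "alpha": cfg.alpha,
            "min_lfc": cfg.min_lfc,
            "r_threshold": cfg.r_threshold,
            "cis_windows": list(cfg.cis_windows),
            "rfam_evalue": cfg.rfam_evalue,
        },
    )
    report.validate()
    render_report(report, "json", out)
    render_report(report, "tsv", out)
    render_report(report, "markdown", out)
    return report


def report_to_dict(report: SummaryReport) -> dict[str, Any]:
    d = dataclasses.asdict(report)
    d["filtration"] = [list(x) for x in report.filtration]
    return d


def report_from_dict(d: Mapping[str, Any]) -> SummaryReport:
    d = dict(d)
    d["filtration"] = [tuple(x) for x in d["filtration"]]
    return SummaryReport(**d)


def render_report(report: SummaryReport, fmt: str, outdir: str | Path) -> Path:
    """Write the summary report as report.{json,tsv,md}."""
    report.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = outdir / "report.json"
        with path.open("w") as fh:
            json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        path = outdir / "report.tsv"
        rows: list[tuple[str, str]] = []
        for name, n_in, n_out in report.filtration:
            rows.append((f"filtration/{name}", f"{n_in}->{n_out}"))
        for c, n in report.class_counts.items():
            rows.append((f"class_count/{c}", str(n)))
        for c, p in report.class_percentages.items():
            rows.append((f"class_pct/{c}", str(p)))
        for k, v in report.pattern_counts.items():
            rows.append((f"pattern/{k}", str(v)))
        for mode, n in report.target_counts.items():
            rows.append((f"targets/{mode}", str(n)))
        rows.append(("precursor/total", str(report.precursor_total)))
        for fam, n in report.precursor_counts.items():
            rows.append((f"precursor/{fam}", str(n)))
        with path.open("w") as fh:
            for k, v in rows:
                fh.write(f"{k}\t{v}\n")
    elif fmt == "markdown":
        path = outdir / "report.md"
        lines = ["# lncRNA pipeline summary", "", "## Filtration"]
        for name, n_in, n_out in report.filtration:
            lines.append(f"- {name}: {n_in} -> {n_out}")
        lines += ["", "## Positional classes"]
        for c, n in report.class_counts.items():
            lines.append(f"- {c} {n} ({report.class_percentages.get(c, 0)}%)")
        lines += ["", "## Response patterns"]
        for k, v in report.pattern_counts.items():
            lines.append(f"- {k}: {v}")
        if report.precursor_total:
            lines += ["", f"## Small-RNA precursors: {report.precursor_total}"]
            for fam, n in report.precursor_counts.items():
                lines.append(f"- {fam}: {n} ({report.precursor_percentages[fam]}%)")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path
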