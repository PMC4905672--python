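"""Expression quantification, NB differential-expression testing and
multi-contrast response-pattern categorization.

The DE test is a declared stand-in for a count-model pipeline run as a black
box in typical workflows: median-of-ratios normalization, method-of-moments
dispersion shrunk toward a fitted mean-dispersion trend, and a Wald-style
test on the log2 fold change under NB variance, with BH adjustment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("C", "D", "ReW")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples counts with design and FPKM derivation.

    design: DataFrame indexed by sample id with columns condition, replicate.
    lengths: per-transcript spliced length (nt).
    totals: per-sample total mapped fragments (library sizes for FPKM).
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        missing_len = set(self.counts.index) - set(self.lengths.index)
        if missing_len:
            raise ValueError(f"transcripts missing lengths: {sorted(missing_len)[:5]}...")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0).astype(float)

    def fpkm(self) -> pd.DataFrame:
        return compute_fpkm(self.counts, self.lengths.loc[self.counts.index], self.totals)

    def condition_samples(self, condition: str) -> list[str]:
        cond = self.design["condition"]
        return [s for s in self.counts.columns if cond[s] == condition]


def compute_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series
) -> pd.DataFrame:
    """fpkm[t, s] = counts[t, s] / ((length_t / 1e3) * (total_s / 1e6))."""
    lengths = lengths.loc[counts.index].astype(float)
    totals = totals.loc[counts.columns].astype(float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (totals <= 0).any():
        raise ValueError("zero library size")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with enforced monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0, 1)
    return out


@dataclass
class ContrastResult:
    """Per-transcript DE result for one condition contrast (A vs B)."""

    name: str
    table: pd.DataFrame  # columns: log2fc, p_value, padj, call

    def up_ids(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    def down_ids(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios over transcripts nonzero in all samples."""
    nz = (counts > 0).all(axis=1)
    if not nz.any():
        return np.ones(counts.shape[1])
    sub = counts[nz].astype(float)
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))  # geometric-mean centred


def _dispersion_trend(mu: np.ndarray, phi_raw: np.ndarray) -> np.ndarray:
    """Fit phi(mu) = b + a/mu by least squares on positive estimates."""
    ok = (mu > 0) & (phi_raw > 0)
    if ok.sum() < 10:
        med = float(np.median(phi_raw[phi_raw > 0])) if (phi_raw > 0).any() else 0.1
        return np.full_like(mu, max(med, 1e-8))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, phi_raw[ok], rcond=None)
    b, a = max(coef[0], 1e-8), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = b + a / np.where(mu > 0, mu, np.inf)
    return np.clip(trend, 1e-8, 10.0)


def nb_de_test(
    expr: ExpressionMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    min_lfc: float = 1.0,
) -> ContrastResult:
    """Wald-style NB test of condition ``contrast[0]`` vs ``contrast[1]``.

    With replicates in both groups: padj < alpha and log2fc >= min_lfc calls
    "up" (symmetric for "down").  Without replicates the call falls back to
    |log2fc| >= min_lfc alone and padj is reported absent (NaN).
    """
    group_a, group_b = contrast
    samples_a = expr.condition_samples(group_a)
    samples_b = expr.condition_samples(group_b)
    if not samples_a or not samples_b:
        missing = [g for g, s in ((group_a, samples_a), (group_b, samples_b)) if not s]
        raise ValueError(f"conditions absent from design: {missing}")
    name = f"{group_a}_vs_{group_b}"
    sub = expr.counts[samples_a + samples_b].to_numpy(dtype=float)
    n_a, n_b = len(samples_a), len(samples_b)

    sf = _size_factors(sub)
    q = sub / sf  # normalized counts
    qa, qb = q[:, :n_a], q[:, n_a:]
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)

    replicate_path = n_a >= 2 and n_b >= 2
    pseudo = 0.5
    log2fc = np.log2((mu_a + pseudo) / (mu_b + pseudo))
    both_zero = (mu_a == 0) & (mu_b == 0)
    log2fc[both_zero] = 0.0

    if replicate_path:
        var_a = qa.var(axis=1, ddof=1)
        var_b = qb.var(axis=1, ddof=1)
        w_a, w_b = n_a - 1, n_b - 1
        var_w = (w_a * var_a + w_b * var_b) / (w_a + w_b)
        mu_bar = q.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_raw = np.where(mu_bar > 0, (var_w - mu_bar) / mu_bar**2, 0.0)
        phi_raw = np.clip(phi_raw, 0.0, 10.0)
        phi = 0.5 * phi_raw + 0.5 * _dispersion_trend(mu_bar, phi_raw)

        inv_sf_a = float(np.mean(1.0 / sf[:n_a]))
        inv_sf_b = float(np.mean(1.0 / sf[n_a:]))
        var_mean_a = (mu_a * inv_sf_a + phi * mu_a**2) / n_a
        var_mean_b = (mu_b * inv_sf_b + phi * mu_b**2) / n_b
        # delta method on log of shifted means
        var_log_a = var_mean_a / (mu_a + pseudo) ** 2
        var_log_b = var_mean_b / (mu_b + pseudo) ** 2
        se_lfc = np.sqrt(var_log_a + var_log_b) / np.log(2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se_lfc > 0, log2fc / se_lfc, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p[both_zero] = 1.0
        p = np.clip(p, 0.0, 1.0)
        padj = bh_adjust(p)
        sig = padj < alpha
        call = np.where(
            sig & (log2fc >= min_lfc), "up",
            np.where(sig & (log2fc <= -min_lfc), "down", "ns"),
        )
    else:
        p = np.full(sub.shape[0], np.nan)
        padj = np.full(sub.shape[0], np.nan)
        call = np.where(
            log2fc >= min_lfc, "up", np.where(log2fc <= -min_lfc, "down", "ns")
        )

    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "padj": padj, "call": call},
        index=expr.counts.index,
    )
    return ContrastResult(name, table)


PATTERN_CATEGORIES = (
    "sustained_up",
    "drought_specific_up",
    "delayed_up",
    "sustained_down",
    "drought_specific_down",
    "delayed_down",
    "recovered_up",
    "recovered_down",
)


@dataclass
class PatternTable:
    """Per-transcript response-pattern flags over a contrast pair.

    ``table`` has one boolean column per category; counts are column sums.
    Identities |A_up| = sustained_up + drought_specific_up and
    |B_up| = sustained_up + delayed_up are asserted at construction.
    """

    contrast_a: str
    contrast_b: str
    table: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {c: int(self.table[c].sum()) for c in PATTERN_CATEGORIES}


def categorize_patterns(res_a: ContrastResult, res_b: ContrastResult) -> PatternTable:
    """Categorize transcripts by their calls in contrasts A (drought vs
    control) and B (rewatering vs control).

    sustained = called in both; drought-specific = called in A only;
    delayed = called in B only (per direction).  "recovered" additionally
    requires the B call to be ns (back to control level).
    """
    ids_a, ids_b = set(res_a.table.index), set(res_b.table.index)
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"transcript universes differ; symmetric difference: {diff[:10]}")

    idx = res_a.table.index
    call_a = res_a.table["call"]
    call_b = res_b.table["call"].reindex(idx)
    up_a, up_b = call_a == "up", call_b == "up"
    dn_a, dn_b = call_a == "down", call_b == "down"
    ns_b = call_b == "ns"

    table = pd.DataFrame(
        {
            "call_a": call_a,
            "call_b": call_b,
            "sustained_up": up_a & up_b,
            "drought_specific_up": up_a & ~up_b,
            "delayed_up": ~up_a & up_b,
            "sustained_down": dn_a & dn_b,
            "drought_specific_down": dn_a & ~dn_b,
            "delayed_down": ~dn_a & dn_b,
            "recovered_up": up_a & ns_b,
            "recovered_down": dn_a & ns_b,
        },
        index=idx,
    )
    pt = PatternTable(res_a.name, res_b.name, table)
    assert int(up_a.sum()) == pt.counts["sustained_up"] + pt.counts["drought_specific_up"]
    assert int(up_b.sum()) == pt.counts["sustained_up"] + pt.counts["delayed_up"]
    assert int(dn_a.sum()) == pt.counts["sustained_down"] + pt.counts["drought_specific_down"]
    assert int(dn_b.sum()) == pt.counts["sustained_down"] + pt.counts["delayed_down"]
    return pt


def directional_fraction(
    records_by_class: Mapping[str, Sequence[str]],
    contrasts: Mapping[str, ContrastResult],
) -> dict[str, dict[str, dict[str, float | None]]]:
    """Per positional class and contrast, the fraction of members called
    up / down.  Classes with zero members report None, not 0/0."""
    out: dict[str, dict[str, dict[str, float | None]]] = {}
    for cls, ids in records_by_class.items():
        out[cls] = {}
        for cname, res in contrasts.items():
            members = [i for i in ids if i in res.table.index]
            if not members:
                out[cls][cname] = {"up": None, "down": None}
                continue
            calls = res.table.loc[members, "call"]
            n = len(members)
            out[cls][cname] = {
                "up": float((calls == "up").sum()) / n,
                "down": float((calls == "down").sum()) / n,
            }
    return out


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Counts TSV: first column transcript_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_design_csv(path: str | Path) -> pd.DataFrame:
    """Design CSV with columns sample_id, condition, replicate."""
    df = pd.read_csv(path)
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"design file must have columns {sorted(required)}")
    return df.set_index("sample_id")
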