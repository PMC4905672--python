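from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_cis_pairs
from conftest import make_expr
from lincseek import express, lncclass, targets
from lincseek.annio import AnnotationSet, GenomicInterval, ToolHit, TranscriptModel
from lincseek.express import ContrastResult
from lincseek.lncclass import LncRNARecord
from lincseek.report import gene_level_counts
from lincseek.targets import (
    cis_targets,
    intronic_host_concordance,
    precursor_summary,
    trans_targets,
)


def _single_exon(tid, chrom, start, length, strand="+"):
    return TranscriptModel(
        tid, tid, chrom, strand, [GenomicInterval(chrom, start, start + length, strand)]
    )


def _gene_set(genes):
    """genes: list of (gene_id, chrom, start, end)."""
    ann = AnnotationSet()
    for gid, chrom, start, end in genes:
        ann.add(
            TranscriptModel(
                f"{gid}.t1", gid, chrom, "+", [GenomicInterval(chrom, start, end, "+")]
            ),
            biotype="coding",
        )
    return ann


class TestCisTargets:
    def test_gap_inside_small_window(self):
        lnc = _single_exon("l", "c", 0, 1000)
        genes = _gene_set([("g", "c", 6000, 7000)])
        (pair,) = cis_targets([lnc], genes)
        assert (pair.mode, pair.distance) == ("cis10k", 5000)

    def test_gap_in_large_window_only(self):
        lnc = _single_exon("l", "c", 0, 1000)
        genes = _gene_set([("g", "c", 51_000, 52_000)])
        (pair,) = cis_targets([lnc], genes)
        assert (pair.mode, pair.distance) == ("cis100k", 50_000)

    def test_overlap_distance_zero(self):
        lnc = _single_exon("l", "c", 500, 1000)
        genes = _gene_set([("g", "c", 1000, 2000)])
        (pair,) = cis_targets([lnc], genes)
        assert pair.distance == 0 and pair.mode == "cis10k"

    def test_different_chromosome_excluded(self):
        lnc = _single_exon("l", "c1", 0, 1000)
        genes = _gene_set([("g", "c2", 2000, 3000)])
        assert cis_targets([lnc], genes) == []

    def test_random_layout_vs_brute_force(self):
        rng = np.random.default_rng(17)
        genes, gene_spans = [], {}
        for i in range(100):
            chrom = f"c{rng.integers(1, 4)}"
            s = int(rng.integers(0, 2_000_000))
            e = s + int(rng.integers(500, 5000))
            genes.append((f"g{i}", chrom, s, e))
            gene_spans[f"g{i}"] = (chrom, s, e)
        lncs, lnc_spans = [], {}
        for i in range(30):
            chrom = f"c{rng.integers(1, 4)}"
            s = int(rng.integers(0, 2_000_000))
            n = int(rng.integers(200, 3000))
            lncs.append(_single_exon(f"l{i}", chrom, s, n))
            lnc_spans[f"l{i}"] = (chrom, s, s + n)
        got = {
            (p.lnc_id, p.gene_id, 10_000 if p.mode == "cis10k" else 100_000, p.distance)
            for p in cis_targets(lncs, _gene_set(genes))
        }
        assert got == brute_force_cis_pairs(lnc_spans, gene_spans)

    def test_window_nesting(self):
        rng = np.random.default_rng(18)
        genes = [(f"g{i}", "c", int(rng.integers(0, 500_000)), 0) for i in range(50)]
        genes = [(g, c, s, s + 1000) for g, c, s, _e in genes]
        lncs = [_single_exon(f"l{i}", "c", int(rng.integers(0, 500_000)), 500) for i in range(20)]
        ann = _gene_set(genes)
        small = {(p.lnc_id, p.gene_id) for p in cis_targets(lncs, ann, [10_000])}
        large = {(p.lnc_id, p.gene_id) for p in cis_targets(lncs, ann, [100_000])}
        assert small <= large


class TestTransTargets:
    def _profiles(self, rows, ids):
        return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(9)])

    def test_exact_linear_dependence(self):
        lnc = self._profiles([[1, 2, 3, 4, 5, 6, 7, 8, 9]], ["l"])
        gene = self._profiles([[2, 4, 6, 8, 10, 12, 14, 16, 18]], ["g"])
        (pair,) = trans_targets(lnc, gene)
        # log2(x+1) makes a 2x profile only near-linear
        assert pair.r == pytest.approx(1.0, abs=5e-3)
        (exact,) = trans_targets(lnc, lnc.rename(index={"l": "g"}))
        assert exact.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_yields_no_pair(self):
        lnc = self._profiles([[1, 2, 3, 4, 5, 6, 7, 8, 9]], ["l"])
        gene = self._profiles([[5] * 9], ["g"])
        assert trans_targets(lnc, gene) == []
        assert trans_targets(gene.rename(index={"g": "l"}), lnc.rename(index={"l": "g"})) == []

    def test_sample_order_mismatch_errors(self):
        lnc = self._profiles([[1] * 9], ["l"])
        gene = lnc.copy()
        gene.columns = list(gene.columns[::-1])
        with pytest.raises(ValueError, match="order"):
            trans_targets(lnc, gene.rename(index={"l": "g"}))

    def test_symmetry_and_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        a = self._profiles(rng.uniform(0, 100, (10, 9)), [f"l{i}" for i in range(10)])
        b = self._profiles(rng.uniform(0, 100, (10, 9)), [f"g{i}" for i in range(10)])
        fwd = {(p.lnc_id, p.gene_id): p.r for p in trans_targets(a, b, 0.5)}
        rev = {(p.gene_id, p.lnc_id): p.r for p in trans_targets(b, a, 0.5)}
        assert set(fwd) == set(rev)
        for k in fwd:
            assert fwd[k] == pytest.approx(rev[k])
        loose = {(p.lnc_id, p.gene_id) for p in trans_targets(a, b, 0.5)}
        tight = {(p.lnc_id, p.gene_id) for p in trans_targets(a, b, 0.8)}
        assert tight <= loose

    def test_planted_pairs_recall(self, ds_big):
        truth = ds_big.truth
        expr = make_expr(ds_big)
        fpkm = expr.fpkm()
        lnc_ids = list(truth.index[truth.is_lnc])
        gene_ids = [t for t in truth.index if truth.at[t, "kind"] == "coding_gene"]
        pairs = trans_targets(fpkm.loc[lnc_ids], fpkm.loc[gene_ids])
        got = {(p.lnc_id, p.gene_id) for p in pairs}
        planted = {
            (t, truth.at[t, "trans_partner"])
            for t in lnc_ids
            if truth.at[t, "trans_partner"]
        }
        recall = sum(p in got for p in planted) / len(planted)
        assert recall >= 0.9


def _res_from_calls(calls: dict[str, str]) -> ContrastResult:
    table = pd.DataFrame(
        {
            "log2fc": [2.0 if c == "up" else -2.0 if c == "down" else 0.0 for c in calls.values()],
            "p_value": 0.5,
            "padj": 0.5,
            "call": list(calls.values()),
        },
        index=list(calls),
    )
    return ContrastResult("D_vs_C", table)


def _intronic(tid, host):
    return LncRNARecord(tid, "intronic", "At", 400, 1, 0, host_gene_id=host)


class TestIntronicHostConcordance:
    def test_up_up_concordant(self):
        frac, table = intronic_host_concordance(
            [_intronic("l", "g")], _res_from_calls({"l": "up", "g": "up"})
        )
        assert frac == 1.0 and bool(table["concordant"].iloc[0])

    def test_up_down_discordant(self):
        frac, _ = intronic_host_concordance(
            [_intronic("l", "g")], _res_from_calls({"l": "up", "g": "down"})
        )
        assert frac == 0.0

    def test_missing_host_skipped(self):
        frac, table = intronic_host_concordance(
            [_intronic("l", "absent")], _res_from_calls({"l": "up"})
        )
        assert math.isnan(frac) and len(table) == 0

    def test_self_concordance_is_one(self):
        recs = [_intronic(f"l{i}", f"l{i}") for i in range(5)]  # host = itself
        calls = {f"l{i}": c for i, c in enumerate(["up", "down", "ns", "up", "ns"])}
        frac, _ = intronic_host_concordance(recs, _res_from_calls(calls))
        assert frac == 1.0

    def test_planted_75pct_within_band(self):
        rng = np.random.default_rng(31)
        rate, n = 0.75, 80
        calls, recs = {}, []
        for i in range(n):
            lnc_call = rng.choice(["up", "down", "ns"])
            host_call = lnc_call if rng.random() < rate else rng.choice(
                [c for c in ("up", "down", "ns") if c != lnc_call]
            )
            calls[f"l{i}"] = lnc_call
            calls[f"g{i}"] = host_call
            recs.append(_intronic(f"l{i}", f"g{i}"))
        frac, _ = intronic_host_concordance(recs, _res_from_calls(calls))
        band = 1.96 * np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) <= band

    def test_pipeline_concordance_near_planted(self, ds_big):
        """End-to-end: DE on counts, measured concordance near the config rate."""
        truth = ds_big.truth
        expr = make_expr(ds_big)
        lnc_ids = list(truth.index[truth.is_lnc])
        gl = gene_level_counts(ds_big.counts, ds_big.reference)
        comb = pd.concat([ds_big.counts.loc[lnc_ids], gl])
        lengths = pd.concat(
            [expr.lengths.loc[lnc_ids], pd.Series(1000.0, index=gl.index)]
        )
        cexpr = express.ExpressionMatrix(comb, ds_big.design, lengths, ds_big.totals)
        res = express.nb_de_test(cexpr, ("D", "C"))
        lncs = [t for t in ds_big.assembled if truth.at[t.transcript_id, "is_lnc"]]
        records = lncclass.classify_all(lncs, ds_big.reference)
        intronic = [r for r in records if r.positional_class == "intronic"]
        frac, table = intronic_host_concordance(intronic, res)
        n = len(table)
        rate = ds_big.cfg.concordance_rate
        band = 1.96 * np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) <= band + 0.05  # small allowance for DE miscalls


class TestPrecursorSummary:
    def _hits(self, fams: dict[str, int], e=1e-8):
        hits, k = [], 0
        for fam, n in fams.items():
            for _ in range(n):
                hits.append(ToolHit(f"l{k}", label=fam, e_value=e))
                k += 1
        return hits

    def test_printed_family_percentages(self):
        hits = self._hits({"miRNA": 70, "tRNA": 19, "other": 107})
        out = precursor_summary(hits)
        assert out.total == 196
        assert out.percentages["miRNA"] == 35.7
        assert out.percentages["tRNA"] == 9.7

    def test_all_above_cutoff_empty(self):
        hits = self._hits({"miRNA": 5}, e=1e-3)
        out = precursor_summary(hits)
        assert out.total == 0 and out.counts == {}

    def test_best_hit_rule(self):
        hits = [
            ToolHit("l", label="tRNA", e_value=1e-6),
            ToolHit("l", label="miRNA", e_value=1e-8),
        ]
        out = precursor_summary(hits)
        assert out.counts == {"miRNA": 1}

    def test_percentages_sum_to_100(self):
        out = precursor_summary(self._hits({"miRNA": 13, "tRNA": 7, "snoRNA": 3}))
        assert sum(out.percentages.values()) == pytest.approx(100, abs=0.3)
        assert sum(out.counts.values()) == out.total
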