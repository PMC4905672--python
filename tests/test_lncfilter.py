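from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_longest_orf
from conftest import make_expr
from lincseek import lncfilter
from lincseek.annio import AnnotationSet, GenomicInterval, ToolHit, TranscriptModel
from lincseek.express import ExpressionMatrix
from lincseek.lncfilter import (
    FiltrationReport,
    IdentifyConfig,
    StepReport,
    coding_potential,
    find_longest_orf,
    run_identification,
    step1_size_exon,
    step2_expression,
    step3_known_overlap,
)
from lincseek.synthio import make_design


def _single_exon(tid, chrom, start, length, strand="+", gid=None):
    return TranscriptModel(
        tid, gid or tid, chrom, strand,
        [GenomicInterval(chrom, start, start + length, strand)],
    )


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFindLongestOrf:
    def test_no_start_codon(self):
        assert find_longest_orf("CCCCCC").longest_orf_nt == 0

    def test_single_forced_orf(self):
        res = find_longest_orf("ATGAAATAG")
        assert (res.longest_orf_nt, res.frame, res.start_offset) == (9, 0, 0)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            find_longest_orf("")

    def test_n_codon_invalidates_orf(self):
        # ATG ANA TAG: middle codon has N, so the ORF is skipped
        assert find_longest_orf("ATGANATAG").longest_orf_nt == 0

    def test_u_accepted(self):
        assert find_longest_orf("AUGAAAUAG").longest_orf_nt == 9

    def test_fixed_600nt_vs_exhaustive(self):
        rng = np.random.default_rng(600)
        seq = _random_seq(rng, 600)
        res = find_longest_orf(seq)
        length, frame, start = brute_force_longest_orf(seq)
        assert (res.longest_orf_nt, res.frame, res.start_offset) == (length, frame, start)

    def test_1000_random_sequences_vs_exhaustive(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(10, 200))
            seq = _random_seq(rng, n)
            if rng.random() < 0.2:  # sprinkle Ns
                pos = rng.integers(0, n, size=max(1, n // 30))
                seq = "".join(
                    "N" if i in set(map(int, pos)) else c for i, c in enumerate(seq)
                )
            res = find_longest_orf(seq)
            length, frame, start = brute_force_longest_orf(seq)
            assert (res.longest_orf_nt, res.frame, res.start_offset) == (
                length, frame, start,
            ), seq


class TestStep1:
    def test_boundary_at_200(self):
        ts = [_single_exon("a", "c1", 0, 199), _single_exon("b", "c1", 1000, 200)]
        kept, rep = step1_size_exon(ts)
        assert [t.transcript_id for t in kept] == ["b"]
        assert rep.removed_ids == ["a"]

    def test_empty_input(self):
        kept, rep = step1_size_exon([])
        assert kept == [] and rep.n_input == 0 and rep.n_retained == 0

    def test_uniform_lengths_count_oracle(self):
        rng = np.random.default_rng(5)
        lengths = rng.integers(150, 251, size=100)
        ts = [
            _single_exon(f"t{i}", "c1", 1000 * i, int(n)) for i, n in enumerate(lengths)
        ]
        kept, rep = step1_size_exon(ts)
        assert rep.n_retained == int((lengths >= 200).sum())


def _expr_from_fpkm_targets(rows: dict[str, list[float]]) -> ExpressionMatrix:
    """Build a matrix whose FPKM equals the given per-sample values
    (length 1000 nt, totals 1e6 => fpkm == counts)."""
    design = make_design()
    counts = pd.DataFrame(rows, index=design.index).T
    lengths = pd.Series(1000.0, index=counts.index)
    totals = pd.Series(1e6, index=counts.columns)
    return ExpressionMatrix(counts, design, lengths, totals)


class TestStep2:
    def test_all_zero_removed(self):
        expr = _expr_from_fpkm_targets({"z": [0] * 9})
        kept, rep = step2_expression([_single_exon("z", "c1", 0, 1000)], expr)
        assert kept == [] and rep.removed_ids == ["z"]

    def test_one_condition_rule(self):
        expr = _expr_from_fpkm_targets({"d": [0, 0, 0, 0.6, 0.7, 0.9, 0, 0, 0]})
        kept, _ = step2_expression([_single_exon("d", "c1", 0, 1000)], expr)
        assert [t.transcript_id for t in kept] == ["d"]

    def test_missing_transcript_errors(self):
        expr = _expr_from_fpkm_targets({"a": [1] * 9})
        with pytest.raises(KeyError, match="ghost"):
            step2_expression([_single_exon("ghost", "c1", 0, 1000)], expr)

    def test_planted_40_60(self):
        rng = np.random.default_rng(9)
        rows = {}
        for i in range(40):
            rows[f"on{i}"] = list(rng.uniform(1, 5, 9))
        for i in range(60):
            rows[f"off{i}"] = [0.0] * 9
        expr = _expr_from_fpkm_targets(rows)
        ts = [_single_exon(tid, "c1", 2000 * i, 1000) for i, tid in enumerate(rows)]
        kept, rep = step2_expression(ts, expr)
        assert rep.n_retained == 40
        assert all(t.transcript_id.startswith("on") for t in kept)


class TestStep3:
    @pytest.fixture()
    def reference(self):
        ref = AnnotationSet()
        # coding gene: exons [1000,1500) and [3000,3500) on +
        ref.add(
            TranscriptModel(
                "g1.t1", "g1", "c1", "+",
                [GenomicInterval("c1", 1000, 1500, "+"), GenomicInterval("c1", 3000, 3500, "+")],
            ),
            biotype="coding",
        )
        return ref

    def test_same_strand_exon_overlap_removed(self, reference):
        t = _single_exon("iso", "c1", 1200, 400, "+")
        kept, rep = step3_known_overlap([t], reference)
        assert kept == [] and rep.removed_ids == ["iso"]

    def test_intronic_same_strand_retained(self, reference):
        t = _single_exon("intr", "c1", 1600, 300, "+")
        kept, _ = step3_known_overlap([t], reference)
        assert [x.transcript_id for x in kept] == ["intr"]

    def test_opposite_strand_retained(self, reference):
        t = _single_exon("anti", "c1", 1200, 400, "-")
        kept, _ = step3_known_overlap([t], reference)
        assert [x.transcript_id for x in kept] == ["anti"]

    def test_planted_fixture(self, reference):
        ts = [_single_exon(f"ov{i}", "c1", 1000 + 50 * i, 300, "+") for i in range(4)]
        ts += [_single_exon(f"far{i}", "c1", 10_000 + 1000 * i, 300, "+") for i in range(6)]
        kept, rep = step3_known_overlap(ts, reference)
        assert rep.n_retained == 6
        assert {t.transcript_id for t in kept} == {f"far{i}" for i in range(6)}


class TestCodingPotential:
    def _t(self, tid):
        return _single_exon(tid, "c1", 0, 500)

    def test_pfam_hit_flags_coding(self):
        calls, _ = coding_potential(
            [self._t("a")],
            cpc_records=[],
            pfam_records=[ToolHit("a", label="dom", e_value=1e-6)],
        )
        assert calls["a"].final == "coding"

    def test_pfam_above_threshold_ignored(self):
        calls, _ = coding_potential(
            [self._t("a")],
            cpc_records=[],
            pfam_records=[ToolHit("a", label="dom", e_value=0.01)],
        )
        assert calls["a"].final == "noncoding"

    def test_fallback_short_orf_noncoding(self):
        seq = "ATG" + "AAA" * 28 + "TAG"  # 90 nt ORF
        seq += "C" * (500 - len(seq))
        calls, _ = coding_potential([self._t("a")], sequences={"a": seq})
        assert calls["a"].final == "noncoding" and calls["a"].orf_flag is False

    def test_error_without_tables_or_sequences(self):
        with pytest.raises(ValueError):
            coding_potential([self._t("a")])

    def test_planted_50_50_with_venn(self, ds):
        calls, venn = coding_potential(
            list(ds.assembled), cpc_records=ds.aux.cpc, pfam_records=ds.aux.pfam
        )
        truth = ds.truth
        for tid, call in calls.items():
            assert (call.final == "coding") == bool(truth.at[tid, "coding"])
        n_coding = int(truth.loc[list(calls), "coding"].sum())
        # synthetic evidence marks every coding transcript in both tables
        assert venn == {"cpc_only": 0, "pfam_only": 0, "both": n_coding}

    def test_fallback_evidence_consistency(self, ds):
        """With noise-free tables generated from the same truth as the ORF
        content, fallback mode and evidence mode agree."""
        ts = list(ds.assembled)
        ev, _ = coding_potential(ts, cpc_records=ds.aux.cpc, pfam_records=ds.aux.pfam)
        fb, _ = coding_potential(ts, sequences=ds.sequences)
        assert {t: c.final for t, c in ev.items()} == {t: c.final for t, c in fb.items()}


class TestFiltrationReport:
    def test_chain_mismatch_rejected(self):
        rep = FiltrationReport()
        rep.append(StepReport("a", 10, 8, ["x", "y"]))
        with pytest.raises(ValueError):
            rep.append(StepReport("b", 9, 9, []))


class TestRunIdentification:
    def test_planted_truth_recovery(self, ds, expr):
        survivors, report, _ = run_identification(
            ds.assembled, ds.reference, expr, ds.sequences
        )
        got = {t.transcript_id for t in survivors}
        want = set(ds.truth.index[ds.truth.is_lnc])
        assert got == want
        assert len(report.steps) == 5

    def test_monotone_chained_counts(self, ds, expr):
        _, report, _ = run_identification(ds.assembled, ds.reference, expr, ds.sequences)
        for prev, cur in zip(report.steps, report.steps[1:]):
            assert cur.n_input == prev.n_retained
            assert cur.n_retained <= cur.n_input
            assert cur.n_input - cur.n_retained == len(cur.removed_ids)

    def test_degenerate_threshold_empty_but_five_steps(self, ds, expr):
        survivors, report, _ = run_identification(
            ds.assembled, ds.reference, expr, ds.sequences,
            IdentifyConfig(min_len=10**9),
        )
        assert survivors == [] and len(report.steps) == 5

    def test_idempotence(self, ds, expr):
        survivors, _, _ = run_identification(ds.assembled, ds.reference, expr, ds.sequences)
        again, _, _ = run_identification(survivors, ds.reference, expr, ds.sequences)
        assert {t.transcript_id for t in again} == {t.transcript_id for t in survivors}

    def test_order_invariance(self, ds, expr):
        ts = list(ds.assembled)
        a, _, _ = run_identification(ts, ds.reference, expr, ds.sequences)
        b, _, _ = run_identification(ts[::-1], ds.reference, expr, ds.sequences)
        assert [t.transcript_id for t in a] == [t.transcript_id for t in b]

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            IdentifyConfig.from_dict({"min_len": 200, "bogus": 1})
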