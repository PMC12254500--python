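"""Hit-table parsing, the four filter rules, and the desk-scale local search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrbpkit.ortholog import (
    FilterConfig,
    HitRecord,
    apply_evalue_cutoff,
    coverage_filter,
    filter_candidates,
    folded_region_filter,
    format_hit_table,
    local_search,
    parse_hit_table,
    reciprocal_filter,
)


def make_hit(query="q", subject="s", s_start=1, s_end=100, evalue=1e-50, bits=200.0,
             q_start=1, q_end=100):
    return HitRecord(query, subject, 90.0, s_end - s_start + 1, 5, 0,
                     q_start, q_end, s_start, s_end, evalue, bits)


class TestParsing:
    def test_parses_twelve_columns(self):
        line = "q1\ts1\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-50\t200"
        (hit,) = parse_hit_table([line])
        assert hit.query_id == "q1" and hit.subject_id == "s1"
        assert hit.evalue == 1e-50 and hit.bit_score == 200.0
        assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (1, 100, 1, 100)

    def test_empty_input_gives_empty_list(self):
        assert parse_hit_table([]) == []
        assert parse_hit_table(["# comment", ""]) == []

    @pytest.mark.parametrize("bad,msg", [
        ("q\ts\t90\t100\t10\t0\t1\t100\t1\t100\t1e-50", "12 tab-separated"),
        ("q\ts\tNOTNUM\t100\t10\t0\t1\t100\t1\t100\t1e-50\t200", "line 1"),
    ])
    def test_malformed_line_reports_line_number(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            parse_hit_table([bad])

    def test_round_trip(self):
        lines = [
            "q1\ts1\t90.00\t100\t10\t0\t1\t100\t1\t100\t1.00e-50\t200.0",
            "q2\ts1\t80.00\t90\t18\t1\t5\t94\t2\t91\t1.00e-30\t120.0",
        ]
        hits = parse_hit_table(lines)
        assert format_hit_table(parse_hit_table(format_hit_table(hits).splitlines())) \
            == format_hit_table(hits)


class TestEvalueCutoff:
    @pytest.mark.parametrize("evalue,kept", [(1e-30, True), (1e-20, False), (1e-28, True)])
    def test_cutoff_is_inclusive(self, evalue, kept):
        hits = [make_hit(evalue=evalue)]
        assert (len(apply_evalue_cutoff(hits, 1e-28)) == 1) is kept

    def test_order_preserved_and_idempotent(self):
        hits = [make_hit(query=f"q{i}", evalue=10.0 ** -i) for i in range(40)]
        once = apply_evalue_cutoff(hits, 1e-28)
        assert [h.query_id for h in once] == [f"q{i}" for i in range(28, 40)]
        assert apply_evalue_cutoff(once, 1e-28) == once


class TestReciprocal:
    def test_top_hit_in_references_accepts(self):
        rev = [make_hit("c1", "NRBP1_HUMAN", bits=200), make_hit("c1", "KINX", bits=150)]
        assert reciprocal_filter({"c1"}, rev, {"NRBP1_HUMAN", "NRBP2_HUMAN"}) == {"c1"}

    def test_unrelated_top_hit_rejects(self):
        rev = [make_hit("c1", "KINX", bits=300), make_hit("c1", "NRBP1_HUMAN", bits=250)]
        assert reciprocal_filter({"c1"}, rev, {"NRBP1_HUMAN"}) == set()

    def test_tie_at_top_accepts(self):
        rev = [make_hit("c1", "KINX", bits=200), make_hit("c1", "NRBP1_HUMAN", bits=200)]
        assert reciprocal_filter({"c1"}, rev, {"NRBP1_HUMAN"}) == {"c1"}

    def test_candidate_without_reverse_hits_rejected(self):
        assert reciprocal_filter({"c1"}, [], {"NRBP1_HUMAN"}) == set()


class TestCoverage:
    lengths = {"s": 500}

    @pytest.mark.parametrize("span,passes", [((1, 400), True), ((1, 399), False)])
    def test_exact_boundary_inclusive(self, span, passes):
        hits = [make_hit(s_start=span[0], s_end=span[1])]
        assert (len(coverage_filter(hits, self.lengths, 0.80)) == 1) is passes

    def test_multiple_hsps_pool_spans(self):
        hits = [make_hit(s_start=1, s_end=250), make_hit(s_start=200, s_end=450)]
        # union covers 450/500 = 0.90
        assert coverage_filter(hits, self.lengths, 0.80) == hits
        assert coverage_filter(hits, self.lengths, 0.901) == []

    def test_missing_reference_length_errors(self):
        with pytest.raises(KeyError, match="nolen"):
            coverage_filter([make_hit(subject="nolen")], self.lengths, 0.8)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        spans=st.lists(
            st.tuples(st.integers(1, 1000), st.integers(0, 60)), min_size=1, max_size=8
        ),
        ref_len=st.integers(100, 1000),
        threshold=st.floats(0.05, 1.0),
    )
    def test_interval_union_matches_per_residue_brute_force(self, spans, ref_len, threshold):
        hits = [
            make_hit(s_start=min(a, ref_len), s_end=min(a + w, ref_len))
            for a, w in spans
        ]
        covered = set()
        for h in hits:
            covered.update(range(h.s_start, h.s_end + 1))
        brute = len(covered) / ref_len >= threshold
        fast = len(coverage_filter(hits, {"s": ref_len}, threshold)) == len(hits)
        assert fast is brute


class TestFoldedRegion:
    def test_full_coverage_passes(self):
        hits = [make_hit(s_start=44, s_end=500)]
        assert folded_region_filter(hits, (44, 500), 40) == hits

    def test_boundary_41_uncovered_fails(self):
        hits = [make_hit(s_start=85, s_end=500)]
        assert folded_region_filter(hits, (44, 500), 40) == []
        assert folded_region_filter(hits, (44, 500), 41) == hits

    def test_both_termini_count_toward_budget(self):
        hits = [make_hit(s_start=60, s_end=490)]
        # uncovered: 44..59 (16) + 491..500 (10) = 26
        assert folded_region_filter(hits, (44, 500), 40) == hits
        assert folded_region_filter(hits, (44, 500), 25) == []

    def test_region_outside_reference_errors(self):
        with pytest.raises(ValueError, match="folded region"):
            folded_region_filter(
                [make_hit()], (44, 600), 40, reference_lengths={"s": 500}
            )


class TestLocalSearch:
    def test_self_hit_has_full_coverage_and_identity(self):
        seq = "MKVLITDDWQPRSTKDDLEAFHKQW"
        hit = local_search(seq, seq)
        assert hit.percent_identity == 100.0
        assert (hit.q_start, hit.q_end) == (1, len(seq))
        assert hit.mismatches == 0 and hit.gap_opens == 0

    def test_motif_location_on_subject(self):
        hit = local_search("KDDAAAA", "KDD")
        assert (hit.s_start, hit.s_end) == (1, 3)
        assert hit.alignment_length == 3

    def test_evalue_grows_with_search_space(self):
        q = "MKVLITDDWQPRSTKDD"
        short = local_search(q, q)
        long = local_search(q, q + "X" * 60)
        assert long.evalue > short.evalue

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            local_search("", "KDD")


class TestChain:
    def test_toy_fixture_keeps_documented_subset(self, toy_filter):
        forward, reverse, expected, config, lengths = toy_filter
        accepted, table = filter_candidates(forward, reverse, lengths, config)
        assert accepted == set(expected.loc[expected["accepted"], "candidate"])
        merged = table.merge(expected, on="candidate", suffixes=("", "_exp"))
        for col in ("pass_evalue", "pass_reciprocal", "pass_coverage",
                    "pass_folded_region", "accepted"):
            assert (merged[col] == merged[f"{col}_exp"]).all(), col

    def test_relaxing_thresholds_never_shrinks_accepted_set(self, toy_filter):
        forward, reverse, _, config, lengths = toy_filter
        base, _ = filter_candidates(forward, reverse, lengths, config)
        for relaxed in (
            FilterConfig(evalue_cutoff=1e-10, min_reference_coverage=0.80,
                         folded_region=(44, 480), folded_tolerance=40,
                         accepted_reference_ids={"REF1"}),
            FilterConfig(evalue_cutoff=1e-28, min_reference_coverage=0.50,
                         folded_region=(44, 480), folded_tolerance=40,
                         accepted_reference_ids={"REF1"}),
            FilterConfig(evalue_cutoff=1e-28, min_reference_coverage=0.80,
                         folded_region=(44, 480), folded_tolerance=100,
                         accepted_reference_ids={"REF1"}),
        ):
            wider, _ = filter_candidates(forward, reverse, lengths, relaxed)
            assert base <= wider
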