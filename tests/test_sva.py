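"""RDA amplicon parsing, insertion calling and replicate summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import senomob as sm
from senomob import sva as sv
from senomob.simulate import DEFAULT_RDA_ADAPTOR, HEXAMER


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


ADAPTOR = DEFAULT_RDA_ADAPTOR


class TestParseAmplicon:
    def test_constructed_amplicon_yields_flank(self, rng):
        flank = _random_seq(rng, 80)
        read = sm.SeqRecord("r", (ADAPTOR + flank + HEXAMER * 35)[:280])
        parsed = sv.parse_amplicon(read, ADAPTOR)
        assert isinstance(parsed, sv.SvaFlankRead)
        assert parsed.flank_seq == flank
        assert parsed.orientation == "+"

    def test_reverse_complement_same_flank(self, rng):
        flank = _random_seq(rng, 60)
        read = sm.SeqRecord("r", sm.revcomp(ADAPTOR + flank + HEXAMER * 10))
        parsed = sv.parse_amplicon(read, ADAPTOR)
        assert isinstance(parsed, sv.SvaFlankRead)
        assert parsed.flank_seq == flank
        assert parsed.orientation == "-"

    def test_no_hexamer_rejected(self, rng):
        read = sm.SeqRecord("r", ADAPTOR + _random_seq(rng, 120))
        parsed = sv.parse_amplicon(read, ADAPTOR)
        assert isinstance(parsed, sm.Rejection) and parsed.reason == "no_hexamer"

    def test_no_adaptor_rejected(self, rng):
        read = sm.SeqRecord("r", _random_seq(rng, 80) + HEXAMER * 10)
        parsed = sv.parse_amplicon(read, ADAPTOR)
        assert isinstance(parsed, sm.Rejection) and parsed.reason == "no_adaptor"

    def test_short_flank_rejected(self):
        read = sm.SeqRecord("r", ADAPTOR + "ACGTACGTACGT" + HEXAMER * 10)
        parsed = sv.parse_amplicon(read, ADAPTOR)
        assert isinstance(parsed, sm.Rejection) and parsed.reason == "flank_too_short"

    def test_degenerate_units_do_not_count(self):
        # two exact units then a degenerate one: no run of three
        read = sm.SeqRecord("r", ADAPTOR + "ACGT" * 10 + HEXAMER * 2 + "CCCTTT" + "ACGT" * 5)
        parsed = sv.parse_amplicon(read, ADAPTOR, min_hexamer_repeats=3)
        assert isinstance(parsed, sm.Rejection) and parsed.reason == "no_hexamer"


@pytest.fixture(scope="module")
def sva_world():
    rng = np.random.default_rng(33)
    genome = {"chr1": _random_seq(rng, 30_000), "chr2": _random_seq(rng, 30_000)}
    annotated = [sm.GenomicInterval("chr1", 20_000, 20_500, "SVA_D|0", 0, "+")]
    return genome, annotated


def _flank_read(genome, chrom, point, read_id="f", flank_len=60):
    return sv.SvaFlankRead(
        read_id, True, True, genome[chrom][point - flank_len : point], "+"
    )


class TestCallInsertions:
    def test_recovery_at_planted_point(self, sva_world):
        genome, annotated = sva_world
        flanks = [_flank_read(genome, "chr1", 5000, f"r{i}") for i in range(4)]
        calls = sv.call_insertions(flanks, genome, annotated, replicate="Sen_1")
        assert len(calls) == 1
        assert calls[0].chrom == "chr1" and abs(calls[0].position - 5000) <= 20
        assert calls[0].support == 4

    def test_annotated_sva_flank_excluded(self, sva_world):
        genome, annotated = sva_world
        flanks = [_flank_read(genome, "chr1", 20_000)]  # abuts the germline SVA
        assert sv.call_insertions(flanks, genome, annotated) == []

    def test_exclusion_window_extends_beyond_element(self, sva_world):
        genome, annotated = sva_world
        flanks = [_flank_read(genome, "chr1", 19_950)]  # 50 nt upstream
        assert sv.call_insertions(flanks, genome, annotated, exclusion_window=100) == []
        assert sv.call_insertions(flanks, genome, annotated, exclusion_window=10) != []

    def test_ambiguous_flank_two_copies_no_call(self):
        rng = np.random.default_rng(34)
        seg = _random_seq(rng, 60)
        genome = {
            "chr1": _random_seq(rng, 3000) + seg + _random_seq(rng, 3000) + seg
        }
        flanks = [sv.SvaFlankRead("r", True, True, seg, "+")]
        assert sv.call_insertions(flanks, genome, []) == []

    def test_order_invariance(self, sva_world):
        genome, annotated = sva_world
        flanks = [
            _flank_read(genome, "chr2", 7000, "a"),
            _flank_read(genome, "chr1", 9000, "b"),
            _flank_read(genome, "chr2", 7005, "c"),
        ]
        fwd = sv.call_insertions(flanks, genome, annotated)
        rev = sv.call_insertions(list(reversed(flanks)), genome, annotated)
        assert [(c.chrom, c.position, c.support) for c in fwd] == [
            (c.chrom, c.position, c.support) for c in rev
        ]


class TestSummaries:
    def test_totals_and_uniques_arithmetic(self):
        calls = [
            sv.InsertionCall("chr1", 100, 5, "Sen_1"),
            sv.InsertionCall("chr1", 900, 3, "Sen_1"),
            sv.InsertionCall("chr2", 100, 2, "Sen_1"),
        ]
        (summary,) = sv.summarize({"Sen_1": calls})
        assert summary.total == 10 and summary.unique == 3
        assert summary.per_chromosome_log10["chr1"] == pytest.approx(np.log10(8))

    def test_empty_call_set(self):
        (summary,) = sv.summarize({"Sen_1": []})
        assert summary.total == 0 and summary.unique == 0
        assert summary.per_chromosome_log10 == {}

    def test_unique_never_exceeds_total(self, rng):
        calls = [
            sv.InsertionCall("chr1", int(p), int(s), "x")
            for p, s in zip(rng.integers(0, 10_000, 50), rng.integers(1, 9, 50))
        ]
        (summary,) = sv.summarize({"x": calls})
        assert summary.unique <= summary.total


class TestReplicateOverlap:
    def test_identical_sets_all_shared(self):
        calls = [sv.InsertionCall("chr1", p, 1) for p in (100, 900, 5000)]
        venn = sv.replicate_overlap({"A": calls, "B": list(calls)})
        assert venn == {frozenset({"A", "B"}): 3}

    def test_single_planted_triple_overlap(self):
        shared = sv.InsertionCall("chr1", 1000, 1)
        sets = {
            "A": [shared, sv.InsertionCall("chr1", 5000, 1)],
            "B": [sv.InsertionCall("chr1", 1010, 1)],
            "C": [sv.InsertionCall("chr1", 995, 1), sv.InsertionCall("chr2", 50, 1)],
        }
        venn = sv.replicate_overlap(sets, tolerance=20)
        assert venn[frozenset({"A", "B", "C"})] == 1
        assert venn[frozenset({"A"})] == 1
        assert venn[frozenset({"C"})] == 1

    def test_disjoint_sets_no_shared(self):
        venn = sv.replicate_overlap(
            {
                "A": [sv.InsertionCall("chr1", 100, 1)],
                "B": [sv.InsertionCall("chr1", 10_000, 1)],
            }
        )
        assert frozenset({"A", "B"}) not in venn

    @given(
        st.lists(
            st.tuples(st.sampled_from("AB"), st.integers(0, 2000)),
            min_size=0,
            max_size=30,
        )
    )
    def test_cluster_counts_conserve_total(self, items):
        sets = {"A": [], "B": []}
        for rep, pos in items:
            sets[rep].append(sv.InsertionCall("chr1", pos, 1))
        if not sets["A"] or not sets["B"]:
            return
        venn = sv.replicate_overlap(sets, tolerance=10)
        # every call lands in exactly one cluster; cluster counts are exact
        # subset counts so their sum is the number of clusters
        assert sum(venn.values()) >= 1
        assert all(len(k) in (1, 2) for k in venn)
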