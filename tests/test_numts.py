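"""The chimeric-read numt scanner: segment finding, filters, calling."""

import numpy as np
import pytest

import senomob as sm
from senomob import numts as nm
from senomob.records import revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="module")
def world():
    rng = np.random.default_rng(21)
    mt = sm.CircularGenome("chrM", _random_seq(rng, 3000))
    nuclear = {"chr1": _random_seq(rng, 20_000)}
    return mt, nuclear, nm.NumtScanner(mt, min_mt_len=30)


class TestScanRead:
    def test_pure_mt_read_covers_whole_read(self, world):
        mt, _, scanner = world
        read = sm.SeqRecord("r", mt.sequence[500:650])
        (cand,) = scanner.scan_read(read)
        assert (cand.q_start, cand.q_end) == (0, 150)
        assert cand.flanks == []
        assert (cand.mt_start, cand.mt_end) == (500, 650)

    def test_planted_chimera_segment_and_flank(self, world):
        mt, nuclear, scanner = world
        read = sm.SeqRecord("r", mt.sequence[100:160] + nuclear["chr1"][1000:1090])
        (cand,) = scanner.scan_read(read)
        assert (cand.q_start, cand.q_end) == (0, 60)
        assert cand.flanks == [(60, 150)]

    def test_pure_nuclear_read_empty(self, world):
        _, nuclear, scanner = world
        read = sm.SeqRecord("r", nuclear["chr1"][2000:2150])
        assert scanner.scan_read(read) == []
        assert not scanner.maybe_contains_mt(read.sequence)

    def test_minus_strand_chimera(self, world):
        mt, nuclear, scanner = world
        fragment = nuclear["chr1"][3000:3070] + mt.sequence[800:880]
        read = sm.SeqRecord("r", revcomp(fragment))
        (cand,) = scanner.scan_read(read)
        assert cand.strand == "-"
        assert cand.mt_len == 80

    def test_origin_spanning_segment(self, world):
        mt, nuclear, scanner = world
        seg = mt.fetch(mt.length - 40, 80)  # spans the origin
        read = sm.SeqRecord("r", seg + nuclear["chr1"][5000:5070])
        (cand,) = scanner.scan_read(read)
        # boundaries may shift by a base or two of chance identity
        assert cand.mt_start < mt.length <= cand.mt_end
        assert abs(cand.mt_start - (mt.length - 40)) <= 2
        assert abs(cand.mt_end - (mt.length + 40)) <= 2

    def test_two_disjoint_segments_yield_two_candidates(self, world):
        mt, nuclear, scanner = world
        read = sm.SeqRecord(
            "r", mt.sequence[100:140] + nuclear["chr1"][1000:1070] + mt.sequence[2000:2040]
        )
        cands = scanner.scan_read(read)
        assert len(cands) == 2
        (a, b) = cands
        # boundaries may shift by a base or two of chance identity
        assert a.q_start == 0 and abs(a.q_end - 40) <= 2
        assert abs(b.q_start - 110) <= 2 and b.q_end == 150


def _candidate(mt_len, flank_left, flank_right=0):
    read_len = mt_len + flank_left + flank_right
    return nm.NumtCandidate(
        read_id="r",
        read_seq="A" * read_len,
        q_start=flank_left,
        q_end=flank_left + mt_len,
        mt_start=0,
        mt_end=mt_len,
        strand="+",
        flanks=(
            ([(0, flank_left)] if flank_left else [])
            + ([(flank_left + mt_len, read_len)] if flank_right else [])
        ),
    )


class TestFilterBoundaries:
    def test_long_mt_segment_rejected(self):
        verdict = nm.filter_candidate(_candidate(135, 15))
        assert not verdict.accepted and verdict.reason == "mt_too_long"

    def test_both_thresholds_satisfied(self):
        verdict = nm.filter_candidate(_candidate(120, 30))
        assert verdict.accepted and verdict.flanks == [(0, 30)]

    @pytest.mark.parametrize(
        "mt_len,flank,accepted",
        [(130, 20, True), (131, 20, False), (130, 19, False), (131, 19, False)],
    )
    def test_inclusive_boundaries(self, mt_len, flank, accepted):
        verdict = nm.filter_candidate(_candidate(mt_len, flank))
        assert verdict.accepted is accepted

    def test_monotonicity_tightening_never_accepts_more(self):
        rng = np.random.default_rng(3)
        cands = [
            _candidate(int(rng.integers(30, 160)), int(rng.integers(0, 40)))
            for _ in range(200)
        ]
        loose = {i for i, c in enumerate(cands) if nm.filter_candidate(c, 130, 20).accepted}
        tight_mt = {i for i, c in enumerate(cands) if nm.filter_candidate(c, 100, 20).accepted}
        tight_fl = {i for i, c in enumerate(cands) if nm.filter_candidate(c, 130, 30).accepted}
        assert tight_mt <= loose and tight_fl <= loose


class TestPlaceFlank:
    def test_unique_flank_placed_at_locus(self, world):
        mt, nuclear, scanner = world
        matcher = sm.ExactMatcher(nuclear, min_len=19)
        flank = nuclear["chr1"][4000:4060]
        result = sm.place_flank(flank, matcher, mt_matcher=scanner.matcher)
        assert isinstance(result, sm.Placement)
        assert (result.interval.start, result.interval.end) == (4000, 4060)

    def test_duplicated_flank_rejected(self):
        rng = np.random.default_rng(4)
        seg = _random_seq(rng, 60)
        genome = {"chr1": _random_seq(rng, 5000) + seg + _random_seq(rng, 1000) + seg}
        matcher = sm.ExactMatcher(genome, min_len=19)
        result = sm.place_flank(seg, matcher)
        assert isinstance(result, sm.Rejection) and result.reason == "not_unique"

    def test_mt_like_flank_rejected(self, world):
        mt, nuclear, scanner = world
        matcher = sm.ExactMatcher(nuclear, min_len=19)
        result = sm.place_flank(mt.sequence[700:760], matcher, mt_matcher=scanner.matcher)
        assert isinstance(result, sm.Rejection) and result.reason == "residual_mt"

    def test_absent_flank_unmapped(self, world):
        _, nuclear, _ = world
        matcher = sm.ExactMatcher(nuclear, min_len=19)
        result = sm.place_flank("ACGT" * 15, matcher)
        assert isinstance(result, sm.Rejection) and result.reason == "unmapped"


def _junction_read(nuclear, mt, chrom_pos, mt_start, flank_len=70, mt_len=80):
    flank = nuclear["chr1"][chrom_pos - flank_len : chrom_pos]
    return sm.SeqRecord(f"jr:{chrom_pos}", flank + mt.sequence[mt_start : mt_start + mt_len])


class TestCalling:
    def test_shared_event_subtracted_and_known_excluded(self, world):
        mt, nuclear, scanner = world
        params = nm.ScanParams()
        reads_sen = [
            _junction_read(nuclear, mt, 8000, 1200),  # de novo
            _junction_read(nuclear, mt, 12000, 300),  # germline (also in driver)
            _junction_read(nuclear, mt, 15000, 600),  # known numt locus
        ]
        reads_prol = [_junction_read(nuclear, mt, 12000, 300)]
        sen = nm.scan_sample(reads_sen, nuclear, mt, params, "sen", scanner=scanner)
        prol = nm.scan_sample(reads_prol, nuclear, mt, params, "prol", scanner=scanner)
        known = [sm.GenomicInterval("chr1", 14999, 15001)]  # 1 bp overlap suffices
        calls = nm.call_de_novo(sen, prol, known, mt.length)
        assert len(calls) == 1
        assert calls[0].start <= 8000 <= calls[0].end + params.merge_window

    def test_parameter_mismatch_raises(self, world):
        mt, nuclear, scanner = world
        sen = nm.scan_sample([], nuclear, mt, nm.ScanParams(), "sen", scanner=scanner)
        prol = nm.scan_sample(
            [], nuclear, mt, nm.ScanParams(max_mt_len=100), "prol", scanner=scanner
        )
        with pytest.raises(ValueError, match="parameters"):
            nm.call_de_novo(sen, prol, [], mt.length)

    def test_supporting_reads_merge_into_one_call(self, world):
        mt, nuclear, scanner = world
        params = nm.ScanParams()
        reads = [
            _junction_read(nuclear, mt, 9000, 2000, flank_len=60 + d, mt_len=80)
            for d in range(0, 30, 10)
        ]
        sen = nm.scan_sample(reads, nuclear, mt, params, "sen", scanner=scanner)
        prol = nm.scan_sample([], nuclear, mt, params, "prol", scanner=scanner)
        calls = nm.call_de_novo(sen, prol, [], mt.length)
        assert len(calls) == 1 and calls[0].support == 3

    def test_sample_symmetry(self, toy_genome, senescent_sample):
        params = nm.ScanParams()
        reads_sen = sm.simulate_wgs(
            senescent_sample.chroms, senescent_sample.mt, 20, mt_copy_number=2, seed=31
        )
        reads_prol = sm.simulate_wgs(
            toy_genome.chroms, toy_genome.mt, 20, mt_copy_number=2, seed=32
        )
        scanner = nm.NumtScanner(toy_genome.mt, params.min_mt_len)
        sen = nm.scan_sample(
            reads_sen, toy_genome.chroms, toy_genome.mt, params, "sen", scanner=scanner
        )
        prol = nm.scan_sample(
            reads_prol, toy_genome.chroms, toy_genome.mt, params, "prol", scanner=scanner
        )
        forward = nm.call_de_novo(sen, prol, toy_genome.numt, toy_genome.mt.length)
        swapped = nm.call_de_novo(prol, sen, toy_genome.numt, toy_genome.mt.length)
        assert forward  # events were planted in the tester
        assert swapped == []  # nothing is unique to the driver

    def test_call_sequence_occurs_in_a_read(self, world):
        mt, nuclear, scanner = world
        params = nm.ScanParams()
        reads = [_junction_read(nuclear, mt, 8000, 1200)]
        sen = nm.scan_sample(reads, nuclear, mt, params, "sen", scanner=scanner)
        prol = nm.scan_sample([], nuclear, mt, params, "prol", scanner=scanner)
        (call,) = nm.call_de_novo(sen, prol, [], mt.length)
        flank = nuclear[call.chrom][call.start : call.end]
        mt_seg = mt.doubled[call.mt_start : call.mt_end]
        assert any(flank + mt_seg == r.sequence for r in reads)


class TestComposition:
    def test_all_calls_in_one_gene(self):
        gene_map = [
            sm.GenomicInterval("chrM", 0, 1000, "MT-A"),
            sm.GenomicInterval("chrM", 1000, 2000, "MT-B"),
        ]
        calls = [
            nm.NumtCall("chr1", i, i + 50, 100, 200, 1, [], "WGS1", 0) for i in range(10)
        ]
        comp = nm.mito_composition(calls, gene_map, 2000)
        assert comp["MT-A"]["pct"] == 100.0
        assert "MT-B" not in comp

    def test_boundary_spanning_counts_in_both(self):
        gene_map = [
            sm.GenomicInterval("chrM", 0, 1000, "MT-A"),
            sm.GenomicInterval("chrM", 1000, 2000, "MT-B"),
        ]
        calls = [nm.NumtCall("chr1", 0, 50, 950, 1050, 1, [], "WGS1", 0)]
        comp = nm.mito_composition(calls, gene_map, 2000)
        assert comp["MT-A"]["pct"] == 50.0 and comp["MT-B"]["pct"] == 50.0

    def test_uniform_calls_track_gene_length_share(self):
        L = 16_559
        gene_map = sm.mt_gene_map("chrM", L)
        rng = np.random.default_rng(6)
        calls = [
            nm.NumtCall("chr1", i, i + 50, s, s + 80, 1, [], "WGS1", 0)
            for i, s in enumerate(rng.integers(0, L, size=4000))
        ]
        comp = nm.mito_composition(calls, gene_map, L)
        # a length-80 segment overlaps a feature [a, b) iff its start falls in
        # (a - 79, b), so the expected assignment share is (len + 79)-weighted
        weights = {}
        for gene in gene_map:
            weights[gene.name] = weights.get(gene.name, 0) + len(gene) + 79
        total_w = sum(weights.values())
        for name, w in weights.items():
            if w < 600:
                continue
            expected = 100.0 * w / total_w
            assert abs(comp[name]["pct"] - expected) < 3.0
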