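"""Determinism, truth re-extraction and read-product contracts."""

import numpy as np
import pytest

import senomob as sm
from senomob import simulate as sim


class TestToyGenome:
    def test_determinism_byte_identical(self, tmp_path):
        spec = sm.ToyGenomeSpec(
            seed=1, chrom_length=30_000, mt_length=4_000, n_alu=8, n_line=3, n_genes=2
        )
        a = sm.make_toy_genome(spec)
        b = sm.make_toy_genome(spec)
        assert a.chroms == b.chroms
        assert a.mt.sequence == b.mt.sequence
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("proliferating.fa", "mt.fa", "sva.bed", "numt.bed", "repeats.bed", "genes.bed"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_size_contract(self):
        toy = sm.make_toy_genome(
            sm.ToyGenomeSpec(seed=2, n_chroms=2, chrom_length=50_000)
        )
        assert sorted(toy.chroms) == ["chr1", "chr2"]
        assert all(len(seq) == 50_000 for seq in toy.chroms.values())

    def test_germline_numts_match_mtdna_exactly(self, toy_genome):
        assert len(toy_genome.numt) == toy_genome.spec.n_germline_numt
        for iv in toy_genome.numt:
            tags = dict(kv.split("=") for kv in iv.name.split(";")[1:])
            expected = toy_genome.mt.fetch(int(tags["mt_start"]), int(tags["mt_len"]))
            assert toy_genome.chroms[iv.chrom][iv.start : iv.end] == expected

    def test_capacity_error_names_required_length(self):
        spec = sm.ToyGenomeSpec(seed=3, n_chroms=1, chrom_length=5_000, n_germline_sva=40)
        with pytest.raises(ValueError, match="capacity"):
            sm.make_toy_genome(spec)

    def test_annotation_tracks_nonempty(self, toy_genome):
        classes = {iv.name.split("|")[0] for iv in toy_genome.repeats}
        assert {"Alu", "LINE", "LTR", "Satellite"} <= classes
        sub = {iv.name.split("|")[0] for iv in toy_genome.genes}
        assert {"promoter", "exon", "intron", "3UTR", "TTS"} <= sub


class TestPlanting:
    def test_null_case_identical(self, toy_genome):
        sen = sm.plant_de_novo_events(toy_genome, 0, 0, seed=9)
        assert sen.chroms == toy_genome.chroms
        assert sen.truth == []

    def test_truth_reextraction(self, toy_genome):
        sen = sm.plant_de_novo_events(
            toy_genome, 4, 10, sm.PlantParams(mt_len_range=(50, 130)), seed=10
        )
        numts = [e for e in sen.truth if e.kind == "de_novo_numt"]
        assert len(numts) == 10
        for ev in sen.truth:
            assert sen.chroms[ev.chrom][ev.sen_start : ev.sen_end] == ev.seq
        for ev in numts:
            assert ev.seq == toy_genome.mt.fetch(ev.mt_start, ev.mt_len)

    def test_planted_microhomology_is_genuine(self, toy_genome):
        sen = sm.plant_de_novo_events(toy_genome, 0, 12, seed=11)
        for ev in sen.truth:
            m = ev.microhomology_len
            if m > 0:
                ref = toy_genome.chroms[ev.chrom]
                assert ref[ev.ref_point - m : ev.ref_point] == ev.seq[:m]

    def test_driver_lacks_event_sequence(self, toy_genome, senescent_sample):
        for ev in senescent_sample.truth:
            window = toy_genome.chroms[ev.chrom][
                max(0, ev.ref_point - 200) : ev.ref_point + 200
            ]
            assert ev.seq[:40] not in window

    def test_repeat_target_bias_one_lands_in_repeats(self, toy_genome):
        sen = sm.plant_de_novo_events(
            toy_genome, 5, 0, sm.PlantParams(repeat_target_bias=1.0), seed=12
        )
        trees = {}
        for iv in toy_genome.repeats:
            trees.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for ev in sen.truth:
            assert any(s <= ev.ref_point < e for s, e in trees[ev.chrom])

    def test_truth_roundtrip(self, tmp_path, senescent_sample):
        path = tmp_path / "truth.bed"
        sm.write_truth(senescent_sample.truth, path)
        back = sm.read_truth(path)
        assert len(back) == len(senescent_sample.truth)
        for a, b in zip(back, senescent_sample.truth):
            assert (a.kind, a.chrom, a.ref_point, a.mt_start, a.tsd_len) == (
                b.kind,
                b.chrom,
                b.ref_point,
                b.mt_start,
                b.tsd_len,
            )

    def test_lift_maps_reference_to_senescent(self, toy_genome, senescent_sample):
        for iv in toy_genome.sva:
            lifted = senescent_sample.lift(iv)
            ref_seq = toy_genome.chroms[iv.chrom][iv.start : iv.end]
            sen_seq = senescent_sample.chroms[lifted.chrom][lifted.start : lifted.end]
            assert ref_seq == sen_seq


class TestWgs:
    def test_read_count_tracks_coverage(self, rng):
        chroms = {"chr1": "".join(rng.choice(list("ACGT"), 150_000))}
        reads = sm.simulate_wgs(chroms, None, coverage=1.0, seed=1)
        assert abs(len(reads) - 1000) <= 20  # within 2%

    def test_mt_copy_number_sets_relative_depth(self, toy_genome):
        copy = 20
        reads = sm.simulate_wgs(
            toy_genome.chroms, toy_genome.mt, coverage=30, mt_copy_number=copy, seed=2
        )
        n_mt = sum(1 for r in reads if f":{toy_genome.mt.id}:" in r.id)
        n_nuc = len(reads) - n_mt
        nuclear_len = sum(len(s) for s in toy_genome.chroms.values())
        depth_ratio = (n_mt / toy_genome.mt.length) / (n_nuc / nuclear_len)
        assert abs(depth_ratio - copy) / copy < 0.1

    def test_error_free_reads_match_genome(self, toy_genome):
        reads = sm.simulate_wgs(toy_genome.chroms, None, coverage=0.5, seed=3)
        for read in reads[:50]:
            _, _, chrom, pos, strand = read.id.split(":")
            expected = toy_genome.chroms[chrom][int(pos) : int(pos) + 150]
            if strand == "-":
                expected = sm.revcomp(expected)
            assert read.sequence == expected

    def test_determinism(self, toy_genome):
        a = sm.simulate_wgs(toy_genome.chroms, toy_genome.mt, coverage=1, seed=4)
        b = sm.simulate_wgs(toy_genome.chroms, toy_genome.mt, coverage=1, seed=4)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]


class TestRda:
    def test_perfect_subtraction_only_de_novo_loci(self, toy_genome, senescent_sample):
        params = sim.RdaParams(subtraction_efficiency=1.0)
        reads = sim.simulate_rda(senescent_sample, toy_genome, params, seed=5)
        assert reads  # de novo SVAs were planted
        de_novo_flanks = [
            senescent_sample.chroms[ev.chrom][ev.sen_start - 40 : ev.sen_start]
            for ev in senescent_sample.truth
            if ev.kind == "de_novo_sva"
        ]
        for read in reads:
            for orient in (read.sequence, sm.revcomp(read.sequence)):
                if orient.startswith(params.adaptor):
                    flank40 = orient[len(params.adaptor) + 40 : len(params.adaptor) + 80]
                    assert any(flank40 == f[-40:] for f in de_novo_flanks)

    def test_no_events_no_reads(self, toy_genome):
        sen = sm.plant_de_novo_events(toy_genome, 0, 0, seed=6)
        params = sim.RdaParams(subtraction_efficiency=1.0)
        assert sim.simulate_rda(sen, toy_genome, params, seed=7) == []

    def test_unique_loci_dominate_under_leaky_subtraction(self):
        spec = sm.ToyGenomeSpec(
            seed=8, chrom_length=120_000, n_germline_sva=100,
            n_alu=0, n_line=0, n_ltr=0, n_satellite=0, n_genes=0, n_germline_numt=0,
        )
        toy = sm.make_toy_genome(spec)
        sen = sm.plant_de_novo_events(toy, 10, 0, seed=9)
        params = sim.RdaParams(subtraction_efficiency=0.99, amplification=50)
        reads = sim.simulate_rda(sen, toy, params, seed=10)
        # count reads per locus id embedded in read names (rda:<locus>:...)
        per_locus = {}
        for r in reads:
            locus = r.id.split(":")[1]
            per_locus[locus] = per_locus.get(locus, 0) + 1
        counts = sorted(per_locus.values())
        n_unique = 10
        assert len(per_locus) >= n_unique
        unique_min = sorted(counts, reverse=True)[:n_unique][-1]
        leaked = [c for c in counts if c < unique_min]
        assert all(unique_min >= 10 * c for c in leaked)


class TestAluScan:
    def _genome(self, rng, length=12_000):
        return {"chr1": "".join(rng.choice(list("ACGT"), length))}

    def _alus(self, positions_strands):
        return [
            sm.GenomicInterval("chr1", p, p + 300, f"Alu|{i}", 0, s)
            for i, (p, s) in enumerate(positions_strands)
        ]

    def test_single_convergent_pair(self, rng):
        genome = self._genome(rng)
        alus = self._alus([(1000, "+"), (2300, "-")])
        reads = sim.simulate_aluscan(genome, alus, seed=1)
        assert reads
        for read in reads:
            found = genome["chr1"].find(read.sequence)
            if found == -1:
                found = genome["chr1"].find(sm.revcomp(read.sequence))
            assert 1000 <= found <= 2600 - 150

    def test_distant_pair_yields_nothing(self, rng):
        genome = self._genome(rng)
        alus = self._alus([(1000, "+"), (9300, "-")])
        assert sim.simulate_aluscan(genome, alus, max_amplicon=5000, seed=2) == []

    def test_divergent_pair_yields_nothing(self, rng):
        genome = self._genome(rng)
        alus = self._alus([(1000, "-"), (2300, "+")])
        assert sim.simulate_aluscan(genome, alus, seed=3) == []
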