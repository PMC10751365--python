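"""Spike-in recovery experiments: plant events, run the callers, score them.

These are the package's benchmark harnesses: a numt experiment (WGS reads
over a two-chromosome toy genome with germline and de novo numts) and an
SVA experiment (RDA amplicons over germline and de novo SVA loci). Both
return planted/detectable/recovered/false-call counts against the truth
table.

"Geometrically detectable" for a numt means the simulated read set
contains at least one junction read satisfying the scanner's own length
contract: >= min_mt_len of the (chance-extended) mt segment inside the
read, at most max_mt_len of it, and >= min_flank nt of nuclear flank on
one side. Sensitivity is scored over those events; an event no read
covers informatively cannot be called by any read-based method.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import numts as nm
from . import sva as sv
from .align import ExactMatcher
from .records import CircularGenome
from .simulate import (
    PlantParams,
    PlantedEvent,
    RdaParams,
    SenescentSample,
    ToyGenomeSpec,
    make_toy_genome,
    plant_de_novo_events,
    simulate_rda,
    simulate_wgs,
)


@dataclass
class SpikeInResult:
    n_planted: int
    n_detectable: int
    n_recovered_detectable: int
    n_recovered_total: int
    n_false_calls: int
    n_reads: int

    @property
    def sensitivity_detectable(self) -> float:
        if self.n_detectable == 0:
            return 1.0
        return self.n_recovered_detectable / self.n_detectable


def _effective_segment(
    sen: SenescentSample, ev: PlantedEvent, mt: CircularGenome
) -> tuple[int, int]:
    """Chance-extend the planted segment while it keeps matching mtDNA."""
    seq = sen.chroms[ev.chrom]
    s, e = ev.sen_start, ev.sen_end
    q0, q1 = ev.mt_start, ev.mt_start + ev.mt_len
    while s > 0 and seq[s - 1] == mt.fetch((q0 - 1) % mt.length, 1):
        s -= 1
        q0 -= 1
    while e < len(seq) and seq[e] == mt.fetch(q1 % mt.length, 1):
        e += 1
        q1 += 1
    return s, e


def numt_spikein(
    seed: int,
    n_de_novo: int = 10,
    n_germline: int = 5,
    coverage: float = 50.0,
    mt_len_range: tuple[int, int] = (50, 130),
    mt_copy_number: float = 2.0,
    chrom_length: int = 50_000,
    read_len: int = 150,
    params: nm.ScanParams | None = None,
) -> SpikeInResult:
    """Plant de novo numts, sequence both samples, scan, call, score."""
    params = params or nm.ScanParams()
    spec = ToyGenomeSpec(
        seed=seed,
        n_chroms=2,
        chrom_length=chrom_length,
        n_germline_sva=0,
        n_germline_numt=n_germline,
        n_alu=10,
        n_line=4,
        n_ltr=3,
        n_satellite=2,
        n_genes=2,
    )
    toy = make_toy_genome(spec)
    sen = plant_de_novo_events(
        toy,
        n_sva=0,
        n_numt=n_de_novo,
        params=PlantParams(mt_len_range=mt_len_range),
        seed=seed + 1000,
    )
    reads_sen = simulate_wgs(
        sen.chroms, sen.mt, coverage, read_len, mt_copy_number,
        seed=seed + 2000, id_prefix="wgs_sen",
    )
    reads_prol = simulate_wgs(
        toy.chroms, toy.mt, coverage, read_len, mt_copy_number,
        seed=seed + 3000, id_prefix="wgs_prol",
    )
    scanner = nm.NumtScanner(toy.mt, params.min_mt_len)
    min_span = max(8, int(params.min_query_cov * params.min_flank))
    matcher = ExactMatcher(toy.chroms, min_len=min_span)
    res_sen = nm.scan_sample(
        reads_sen, toy.chroms, toy.mt, params, "sen", scanner=scanner, nuclear_matcher=matcher
    )
    res_prol = nm.scan_sample(
        reads_prol, toy.chroms, toy.mt, params, "prol", scanner=scanner, nuclear_matcher=matcher
    )
    calls = nm.call_de_novo(res_sen, res_prol, toy.numt, toy.mt.length, params.merge_window)

    # read start positions in senescent coordinates, from the read ids
    starts: dict[str, list[int]] = {}
    for read in reads_sen:
        _, _, chrom, pos, _ = read.id.split(":")
        starts.setdefault(chrom, []).append(int(pos))
    truth = [ev for ev in sen.truth if ev.kind == "de_novo_numt"]
    detectable: set[int] = set()
    for i, ev in enumerate(truth):
        s, e = _effective_segment(sen, ev, toy.mt)
        for r in starts.get(ev.chrom, []):
            ov = min(r + read_len, e) - max(r, s)
            if not (params.min_mt_len <= ov <= params.max_mt_len):
                continue
            left = s - r
            right = (r + read_len) - e
            if left >= params.min_flank or right >= params.min_flank:
                detectable.add(i)
                break

    recovered: set[int] = set()
    false_calls = 0
    w = params.merge_window
    for call in calls:
        hit = False
        for i, ev in enumerate(truth):
            if call.chrom == ev.chrom and call.start - w <= ev.ref_point <= call.end + w:
                recovered.add(i)
                hit = True
        if not hit:
            false_calls += 1
    return SpikeInResult(
        n_planted=len(truth),
        n_detectable=len(detectable),
        n_recovered_detectable=len(detectable & recovered),
        n_recovered_total=len(recovered),
        n_false_calls=false_calls,
        n_reads=len(reads_sen) + len(reads_prol),
    )


def sva_spikein(
    seed: int,
    n_de_novo: int = 10,
    n_germline: int = 50,
    subtraction_efficiency: float = 1.0,
    chrom_length: int = 50_000,
    tolerance: int = 20,
) -> SpikeInResult:
    """Plant de novo SVAs, run the RDA readout, call insertions, score."""
    spec = ToyGenomeSpec(
        seed=seed,
        n_chroms=2,
        chrom_length=chrom_length,
        n_germline_sva=n_germline,
        n_germline_numt=0,
        n_alu=10,
        n_line=4,
        n_ltr=3,
        n_satellite=2,
        n_genes=2,
    )
    toy = make_toy_genome(spec)
    sen = plant_de_novo_events(toy, n_sva=n_de_novo, n_numt=0, seed=seed + 1000)
    rda = RdaParams(subtraction_efficiency=subtraction_efficiency)
    reads = simulate_rda(sen, toy, rda, seed=seed + 2000)
    flanks = []
    for read in reads:
        parsed = sv.parse_amplicon(read, rda.adaptor)
        if not isinstance(parsed, sv.Rejection):
            flanks.append(parsed)
    calls = sv.call_insertions(flanks, toy.chroms, toy.sva, replicate="Sen")
    truth = [ev for ev in sen.truth if ev.kind == "de_novo_sva"]
    recovered: set[int] = set()
    false_calls = 0
    for call in calls:
        hit = False
        for i, ev in enumerate(truth):
            if call.chrom == ev.chrom and abs(call.position - ev.ref_point) <= tolerance:
                recovered.add(i)
                hit = True
        if not hit:
            false_calls += 1
    # every planted SVA locus emits amplicons under the RDA model
    return SpikeInResult(
        n_planted=len(truth),
        n_detectable=len(truth),
        n_recovered_detectable=len(recovered),
        n_recovered_total=len(recovered),
        n_false_calls=false_calls,
        n_reads=len(reads),
    )
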