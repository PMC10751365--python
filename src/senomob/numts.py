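"""De novo numt detection from chimeric reads (the WGS / AluScan scanner).

A numt junction read consists of a 100%-identity mtDNA segment plus nuclear
flank sequence. The filter chain, applied per candidate segment:

1. maximal exact mtDNA segment of length >= ``min_mt_len`` (both strands,
   circular origin spanned transparently);
2. segments longer than ``max_mt_len`` (130 nt) are discarded — a full-read
   mtDNA hit is an mtDNA read, not a junction;
3. subtracting the segment from the read must leave a nuclear flank of at
   least ``min_flank`` (20 nt); both thresholds are inclusive;
4. the flank must place uniquely on the nuclear genome (gapless, >= 95%
   query coverage, single best pslScore) and contain no residual mtDNA.

Two-sample calling then drops every senescent placement overlapping a
proliferating placement or a known-numt interval (>= 1 bp, membership
semantics), and merges the survivors into calls: placements within
``merge_window`` nt whose mtDNA intervals overlap support one event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import ExactMatcher
from .intervals import exclude
from .placement import Placement, Rejection, filter_psl_placements, place_flank
from .records import (
    CircularGenome,
    GenomicInterval,
    PslAlignment,
    SeqRecord,
    revcomp,
    sort_intervals,
)

_MH_CAP = 10  # longest junction microhomology we bother to measure


@dataclass
class ScanParams:
    min_mt_len: int = 30
    max_mt_len: int = 130
    min_flank: int = 20
    min_query_cov: float = 0.95
    max_n_fraction: float = 0.1
    merge_window: int = 100


@dataclass
class NumtCandidate:
    """One maximal mtDNA segment within a read, plus the leftover flanks."""

    read_id: str
    read_seq: str
    q_start: int  # mt segment on the read, + strand coords
    q_end: int
    mt_start: int  # on the doubled mt linearization, start < L
    mt_end: int
    strand: str
    flanks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def mt_len(self) -> int:
        return self.q_end - self.q_start


@dataclass
class FilterVerdict:
    accepted: bool
    reason: str | None
    flanks: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class FlankPlacement:
    read_id: str
    interval: GenomicInterval
    strand: str
    mt_start: int
    mt_end: int
    flank_side: str  # left | right (relative to the mt segment in the read)
    microhomology_len: int
    dataset: str


@dataclass
class NumtCall:
    """A de novo numt: nuclear target plus its mtDNA-derived segment."""

    chrom: str
    start: int
    end: int
    mt_start: int
    mt_end: int
    support: int
    read_ids: list[str]
    dataset: str
    microhomology_len: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, f"numt;support={self.support}", self.support
        )


@dataclass
class ScanResult:
    label: str
    placements: list[FlankPlacement]
    funnel: dict[str, int]
    params: ScanParams


class NumtScanner:
    """Finds 100%-identity mtDNA segments in reads, with a cheap prefilter."""

    def __init__(self, mt: CircularGenome, min_mt_len: int = 30):
        self.mt = mt
        self.min_mt_len = min_mt_len
        self.matcher = ExactMatcher(mt, min_len=min_mt_len)
        k = min(16, min_mt_len)
        self._pk = k
        self._stride = min_mt_len - k + 1
        doubled = mt.doubled
        kmers: set[str] = set()
        for j in range(len(doubled) - k + 1):
            kmer = doubled[j : j + k]
            if "N" not in kmer:
                kmers.add(kmer)
                kmers.add(revcomp(kmer))
        self._kmers = kmers

    def maybe_contains_mt(self, seq: str) -> bool:
        """True unless the read provably has no mt segment >= min_mt_len.

        Checks k-mers on a stride chosen so that any qualifying segment
        must contain at least one checked k-mer.
        """
        k, kmers = self._pk, self._kmers
        n = len(seq)
        if n < self.min_mt_len:
            return False
        last = n - k
        for i in range(0, last + 1, self._stride):
            if seq[i : i + k] in kmers:
                return True
        # the strided walk can stop short of the read end
        return seq[last : last + k] in kmers

    def scan_read(self, read: SeqRecord, min_mt_len: int | None = None) -> list[NumtCandidate]:
        """One candidate per maximal 100%-identity mt segment in the read."""
        min_len = min_mt_len or self.min_mt_len
        n = len(read)
        candidates: dict[tuple[int, int], NumtCandidate] = {}
        for aln in self.matcher.find(read):
            if aln.span < min_len:
                continue
            key = (aln.q_start, aln.q_end)
            if key in candidates:
                continue  # same read segment, ambiguous mt placement
            flanks = []
            if aln.q_start > 0:
                flanks.append((0, aln.q_start))
            if aln.q_end < n:
                flanks.append((aln.q_end, n))
            candidates[key] = NumtCandidate(
                read_id=read.id,
                read_seq=read.sequence,
                q_start=aln.q_start,
                q_end=aln.q_end,
                mt_start=aln.t_start,
                mt_end=aln.t_end,
                strand=aln.strand,
                flanks=flanks,
            )
        return [candidates[k] for k in sorted(candidates)]


def filter_candidate(
    candidate: NumtCandidate,
    max_mt_len: int = 130,
    min_flank: int = 20,
) -> FilterVerdict:
    """Length filters: mt segment <= max_mt_len, leftover flank >= min_flank.

    Both boundaries are inclusive: a 130 nt segment and a 20 nt flank pass.
    """
    if candidate.mt_len > max_mt_len:
        return FilterVerdict(False, "mt_too_long")
    good = [(s, e) for s, e in candidate.flanks if e - s >= min_flank]
    if not good:
        return FilterVerdict(False, "flank_too_short")
    return FilterVerdict(True, None, good)


def _microhomology(
    candidate: NumtCandidate, flank: tuple[int, int]
) -> tuple[str, int]:
    """Measure junction microhomology in read space.

    At an NHEJ-style junction with microhomology m, the m bases on the
    nuclear side of the junction equal the m proximal bases of the mt
    segment, so the assignment of those bases is ambiguous. Both copies are
    visible in the read: the flank end and the mt segment start (left
    flank) or the mt segment end and the flank start (right flank).
    """
    fs, fe = flank
    read = candidate.read_seq
    ms, me = candidate.q_start, candidate.q_end
    cap = min(_MH_CAP, fe - fs, me - ms)
    if fe <= ms:  # flank | mt junction
        side = "left"
        for k in range(cap, 0, -1):
            if read[fe - k : fe] == read[ms : ms + k] and "N" not in read[ms : ms + k]:
                return side, k
    else:  # mt | flank junction
        side = "right"
        for k in range(cap, 0, -1):
            if read[me - k : me] == read[fs : fs + k] and "N" not in read[fs : fs + k]:
                return side, k
    return side, 0


def scan_sample(
    reads: Iterable[SeqRecord],
    nuclear: dict[str, str],
    mt: CircularGenome,
    params: ScanParams | None = None,
    label: str = "sample",
    scanner: NumtScanner | None = None,
    nuclear_matcher: ExactMatcher | None = None,
) -> ScanResult:
    """Run the full per-sample filter chain; returns placements + funnel."""
    params = params or ScanParams()
    scanner = scanner or NumtScanner(mt, params.min_mt_len)
    min_span = max(8, int(params.min_query_cov * params.min_flank))
    nuclear_matcher = nuclear_matcher or ExactMatcher(nuclear, min_len=min_span)
    funnel: Counter[str] = Counter()
    placements: list[FlankPlacement] = []
    for read in reads:
        funnel["reads_total"] += 1
        if read.n_fraction > params.max_n_fraction:
            funnel["reads_dropped_n"] += 1
            continue
        if not scanner.maybe_contains_mt(read.sequence):
            continue
        funnel["reads_prefilter_pass"] += 1
        for cand in scanner.scan_read(read):
            funnel["candidates_total"] += 1
            verdict = filter_candidate(cand, params.max_mt_len, params.min_flank)
            if not verdict.accepted:
                funnel[f"rejected_{verdict.reason}"] += 1
                continue
            for flank in verdict.flanks:
                fs, fe = flank
                flank_seq = read.sequence[fs:fe]
                result = place_flank(
                    flank_seq,
                    nuclear_matcher,
                    params.min_query_cov,
                    mt_matcher=scanner.matcher,
                )
                if isinstance(result, Rejection):
                    funnel[f"flanks_{result.reason}"] += 1
                    continue
                funnel["flanks_placed"] += 1
                side, mh = _microhomology(cand, flank)
                placements.append(
                    FlankPlacement(
                        read_id=read.id,
                        interval=result.interval,
                        strand=result.strand,
                        mt_start=cand.mt_start,
                        mt_end=cand.mt_end,
                        flank_side=side,
                        microhomology_len=mh,
                        dataset=label,
                    )
                )
    funnel["placements"] = len(placements)
    return ScanResult(label=label, placements=placements, funnel=dict(funnel), params=params)


def _mt_pieces(start: int, end: int, length: int) -> list[tuple[int, int]]:
    """Split a doubled-linearization mt interval into pieces modulo L."""
    start %= length
    end = start + (end - start if end > start else 0)
    if end <= length:
        return [(start, end)]
    return [(start, length), (0, end - length)]


def _mt_overlap(a: tuple[int, int], b: tuple[int, int], length: int) -> bool:
    for s1, e1 in _mt_pieces(*a, length):
        for s2, e2 in _mt_pieces(*b, length):
            if s1 < e2 and s2 < e1:
                return True
    return False


def call_de_novo(
    senescent: ScanResult,
    proliferating: ScanResult,
    known_numts: Sequence[GenomicInterval],
    mt_length: int,
    merge_window: int = 100,
    extra_exclusion: Sequence[GenomicInterval] | None = None,
) -> list[NumtCall]:
    """Two-sample subtraction and merging into de novo numt calls."""
    if senescent.params != proliferating.params:
        raise ValueError(
            "tester and driver scans were run with different parameters; "
            "rerun both with identical settings"
        )
    keyed = {id(p.interval): p for p in senescent.placements}
    ivs = [p.interval for p in senescent.placements]
    prol_ivs = [p.interval for p in proliferating.placements]
    survivors = exclude(ivs, prol_ivs)
    survivors = exclude(survivors, list(known_numts))
    if extra_exclusion:
        survivors = exclude(survivors, list(extra_exclusion))
    placements = sorted(
        (keyed[id(iv)] for iv in survivors),
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end),
    )
    calls: list[NumtCall] = []
    cluster: list[FlankPlacement] = []

    def flush() -> None:
        if not cluster:
            return
        mh = Counter(p.microhomology_len for p in cluster).most_common(1)[0][0]
        calls.append(
            NumtCall(
                chrom=cluster[0].interval.chrom,
                start=min(p.interval.start for p in cluster),
                end=max(p.interval.end for p in cluster),
                mt_start=min(p.mt_start for p in cluster),
                mt_end=max(p.mt_end for p in cluster),
                support=len(cluster),
                read_ids=[p.read_id for p in cluster],
                dataset=cluster[0].dataset,
                microhomology_len=mh,
            )
        )

    for p in placements:
        if cluster and (
            p.interval.chrom == cluster[0].interval.chrom
            and p.interval.start - max(q.interval.end for q in cluster) <= merge_window
            and any(
                _mt_overlap(
                    (p.mt_start, p.mt_end), (q.mt_start, q.mt_end), mt_length
                )
                for q in cluster
            )
        ):
            cluster.append(p)
        else:
            flush()
            cluster = [p]
    flush()
    return calls


def placements_from_psl(
    flank_psl: Sequence[PslAlignment],
    flank_lengths: dict[str, int],
    min_query_cov: float = 0.95,
) -> dict[str, Placement | Rejection]:
    """Apply the placement filters to externally supplied PSL alignments.

    Alignments are grouped by query name; each group is filtered with the
    same coverage/gaplessness/uniqueness contract as the internal matcher.
    """
    groups: dict[str, list[PslAlignment]] = {}
    for aln in flank_psl:
        groups.setdefault(aln.q_name, []).append(aln)
    return {
        name: filter_psl_placements(alns, flank_lengths[name], min_query_cov)
        for name, alns in groups.items()
    }


def mito_composition(
    calls: Sequence[NumtCall],
    gene_map: Sequence[GenomicInterval],
    mt_length: int,
) -> dict[str, dict[str, float]]:
    """Per-mito-feature share of the called mtDNA segments.

    Each call's mt interval contributes one assignment to every feature it
    overlaps; percentages are taken over all assignments and sum to 100.
    """
    counts: Counter[str] = Counter()
    for call in calls:
        pieces = _mt_pieces(call.mt_start, call.mt_end, mt_length)
        hit: set[str] = set()
        for gene in gene_map:
            for s, e in pieces:
                if gene.start < e and s < gene.end:
                    hit.add(gene.name)
        for name in hit:
            counts[name] += 1
    total = sum(counts.values())
    return {
        name: {"count": float(c), "pct": 100.0 * c / total if total else 0.0}
        for name, c in sorted(counts.items())
    }


def calls_to_bed(calls: Sequence[NumtCall]) -> list[GenomicInterval]:
    return sort_intervals(
        GenomicInterval(
            c.chrom,
            c.start,
            c.end,
            f"numt;dataset={c.dataset};mt_start={c.mt_start};mt_end={c.mt_end};"
            f"support={c.support};microhomology={c.microhomology_len}",
            c.support,
        )
        for c in calls
    )
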