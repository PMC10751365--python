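"""De novo SVA insertion readout from RDA amplicon reads.

An informative amplicon read carries, in order: the RDA adaptor, the
nuclear sequence immediately upstream of the insertion, and the SVA 5'
head starting with the (CCCTCT)n hexamer repeat. The flank between the two
landmarks is placed uniquely on the nuclear genome; the insertion point is
the flank end adjacent to the hexamer. Placements near annotated
(germline) SVAs are discarded and nearby placements collapse into one
call, supporting a per-replicate summary (totals, uniques, chromosomal
log10 distribution) and subset overlap (Venn) counts across replicates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import ExactMatcher
from .intervals import near
from .placement import Placement, Rejection, place_flank
from .records import GenomicInterval, SeqRecord, revcomp
from .simulate import HEXAMER


@dataclass
class SvaFlankRead:
    read_id: str
    adaptor_found: bool
    hexamer_found: bool
    flank_seq: str
    orientation: str  # + if the read carried the amplicon forward


@dataclass
class InsertionCall:
    """A collapsed de novo SVA insertion point with read support."""

    chrom: str
    position: int  # width-1 insertion point
    support: int
    replicate: str = ""
    read_ids: list[str] = field(default_factory=list)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.position,
            self.position + 1,
            f"sva;replicate={self.replicate};support={self.support}",
            self.support,
        )


def parse_amplicon(
    read: SeqRecord,
    adaptor_seq: str,
    hexamer: str = HEXAMER,
    min_hexamer_repeats: int = 3,
    min_flank: int = 20,
) -> SvaFlankRead | Rejection:
    """Extract the nuclear flank between adaptor and hexamer run.

    The adaptor must be an exact prefix of the read in either orientation;
    the hexamer landmark is the first run of >= ``min_hexamer_repeats``
    exact CCCTCT units after it.
    """
    if not adaptor_seq:
        raise ValueError("adaptor_seq must be non-empty")
    for orientation, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        if seq.startswith(adaptor_seq):
            run = hexamer * min_hexamer_repeats
            pos = seq.find(run, len(adaptor_seq))
            if pos == -1:
                return Rejection("no_hexamer")
            flank = seq[len(adaptor_seq) : pos]
            if len(flank) < min_flank:
                return Rejection("flank_too_short")
            return SvaFlankRead(read.id, True, True, flank, orientation)
    return Rejection("no_adaptor")


def call_insertions(
    flanks: Iterable[SvaFlankRead],
    nuclear: dict[str, str],
    annotated_sva: Sequence[GenomicInterval],
    exclusion_window: int = 100,
    collapse_tolerance: int = 20,
    min_query_cov: float = 0.95,
    replicate: str = "",
    nuclear_matcher: ExactMatcher | None = None,
    funnel: dict[str, int] | None = None,
) -> list[InsertionCall]:
    """Place flanks, drop germline-adjacent sites, collapse into calls.

    The insertion point is the flank end adjacent to the hexamer (the
    flank's 3' end in amplicon orientation); placements within
    ``exclusion_window`` nt of an annotated SVA are germline-derived and
    discarded; surviving points within ``collapse_tolerance`` nt collapse
    into one call with summed support.
    """
    counts: Counter[str] = Counter()
    min_flank_guess = 20
    min_span = max(8, int(min_query_cov * min_flank_guess))
    matcher = nuclear_matcher or ExactMatcher(nuclear, min_len=min_span)
    points: list[tuple[str, int, str]] = []  # chrom, point, read_id
    for flank in flanks:
        counts["flanks_total"] += 1
        result = place_flank(flank.flank_seq, matcher, min_query_cov)
        if isinstance(result, Rejection):
            counts[f"flanks_{result.reason}"] += 1
            continue
        iv = result.interval
        # flank 3' end (amplicon orientation) abuts the hexamer
        point = iv.end if result.strand == "+" else iv.start
        point = min(max(point, 0), len(nuclear[iv.chrom]) - 1)
        points.append((iv.chrom, point, flank.read_id))
        counts["flanks_placed"] += 1
    point_ivs = [
        GenomicInterval(chrom, p, p + 1, str(i)) for i, (chrom, p, _) in enumerate(points)
    ]
    excluded = {
        int(iv.name)
        for iv in near(point_ivs, list(annotated_sva), exclusion_window)
    }
    counts["points_excluded_annotated_sva"] = len(excluded)
    kept = [pt for i, pt in enumerate(points) if i not in excluded]
    kept.sort(key=lambda t: (t[0], t[1]))
    calls: list[InsertionCall] = []
    cluster: list[tuple[str, int, str]] = []

    def flush() -> None:
        if not cluster:
            return
        chrom = cluster[0][0]
        position = int(round(sum(p for _, p, _ in cluster) / len(cluster)))
        calls.append(
            InsertionCall(
                chrom=chrom,
                position=position,
                support=len(cluster),
                replicate=replicate,
                read_ids=[rid for _, _, rid in cluster],
            )
        )

    for pt in kept:
        if cluster and pt[0] == cluster[0][0] and pt[1] - cluster[-1][1] <= collapse_tolerance:
            cluster.append(pt)
        else:
            flush()
            cluster = [pt]
    flush()
    counts["calls"] = len(calls)
    if funnel is not None:
        funnel.update(counts)
    return calls


@dataclass
class ReplicateSummary:
    replicate: str
    total: int
    unique: int
    per_chromosome_log10: dict[str, float]


def summarize(calls_per_replicate: dict[str, Sequence[InsertionCall]]) -> list[ReplicateSummary]:
    """Totals (read-level), uniques (collapsed coordinates), chrom log10."""
    out = []
    for rep, calls in calls_per_replicate.items():
        total = sum(c.support for c in calls)
        per_chrom: Counter[str] = Counter()
        for c in calls:
            per_chrom[c.chrom] += c.support
        log10 = {
            chrom: math.log10(n) for chrom, n in sorted(per_chrom.items()) if n > 0
        }
        out.append(ReplicateSummary(rep, total, len(calls), log10))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def replicate_overlap(
    call_sets: dict[str, Sequence[InsertionCall]],
    tolerance: int = 20,
) -> dict[frozenset[str], int]:
    """Venn-style subset counts of shared insertion coordinates.

    Two coordinates are shared when within ``tolerance`` nt on the same
    chromosome; transitive clusters count once, toward the subset of
    replicates represented in the cluster. Counts are per exact subset and
    therefore obey inclusion-exclusion by construction.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    flat: list[tuple[str, int, str]] = []  # chrom, pos, replicate
    for rep, calls in call_sets.items():
        for c in calls:
            flat.append((c.chrom, c.position, rep))
    flat.sort(key=lambda t: (t[0], t[1]))
    uf = _UnionFind(len(flat))
    for i in range(len(flat)):
        j = i + 1
        while j < len(flat) and flat[j][0] == flat[i][0] and flat[j][1] - flat[i][1] <= tolerance:
            uf.union(i, j)
            j += 1
    clusters: dict[int, set[str]] = {}
    for i, (_, _, rep) in enumerate(flat):
        clusters.setdefault(uf.find(i), set()).add(rep)
    counts: Counter[frozenset[str]] = Counter()
    for members in clusters.values():
        counts[frozenset(members)] += 1
    return dict(counts)


def calls_to_bed(calls: Sequence[InsertionCall]) -> list[GenomicInterval]:
    from .records import sort_intervals

    return sort_intervals(c.interval for c in calls)
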