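"""Deterministic exact and near-exact ungapped alignment at toy scale.

This is the package's stand-in for BLAT/blastn in the 100%- and
95%-identity screens the pipelines rely on. The model is deliberately
ungapped: those screens never require gapped hits, and gapped external
alignments can always be supplied as PSL and pushed through the same
filters.

* :class:`ExactMatcher` / :func:`align_exact` report every *maximal* exact
  substring match of length >= ``min_len`` between a query (both strands)
  and a set of targets, as gapless :class:`~senomob.records.PslAlignment`
  records.
* :func:`align_near` aligns the *full* query ungapped at every target
  offset reaching the requested identity (pigeonhole-seeded).

Circular targets (mtDNA) are searched on a doubled linearization and
deduplicated modulo L; PSL records for circular targets carry
``t_size = 2 L`` so origin-spanning hits remain valid PSL. There is no
randomness anywhere in this module; output order is fixed as
(t_name, t_start, q_start, strand).

``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .records import CircularGenome, PslAlignment, SeqRecord, revcomp


@dataclass(frozen=True)
class Target:
    name: str
    seq: str
    circular: bool

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def search_seq(self) -> str:
        return self.seq + self.seq if self.circular else self.seq

    @property
    def psl_size(self) -> int:
        # doubled linearization is explicit in the PSL for circular targets
        return 2 * self.length if self.circular else self.length


def as_targets(target) -> list[Target]:
    """Normalize a genome argument to a list of named targets.

    Accepts a :class:`CircularGenome`, a :class:`SeqRecord`, a mapping
    ``{name: sequence}``, or an iterable of SeqRecords.
    """
    if isinstance(target, Target):
        return [target]
    if isinstance(target, CircularGenome):
        return [Target(target.id, target.sequence, True)]
    if isinstance(target, SeqRecord):
        return [Target(target.id, target.sequence, False)]
    if isinstance(target, dict):
        return [Target(name, seq, False) for name, seq in sorted(target.items())]
    if isinstance(target, (list, tuple)):
        return [Target(rec.id, rec.sequence, False) for rec in target]
    raise TypeError(f"cannot interpret {type(target).__name__} as a genome")


def _query_seq(query) -> tuple[str, str]:
    if isinstance(query, SeqRecord):
        return query.id, query.sequence
    return "query", str(query).upper()


def psl_score(aln: PslAlignment) -> int:
    """UCSC pslScore: matches + repMatches - misMatches - gap openings."""
    return (
        aln.matches
        + aln.rep_matches
        - aln.mis_matches
        - aln.q_num_insert
        - aln.t_num_insert
    )


def percent_identity(aln: PslAlignment) -> float:
    """Fractional identity per the UCSC milliBad convention (DNA/DNA)."""
    q_ali = aln.q_end - aln.q_start
    t_ali = aln.t_end - aln.t_start
    ali = min(q_ali, t_ali)
    if ali <= 0:
        return 0.0
    size_dif = abs(q_ali - t_ali)
    insert_factor = aln.q_num_insert + aln.t_num_insert
    total = aln.matches + aln.rep_matches + aln.mis_matches
    if total == 0:
        return 0.0
    milli_bad = (
        1000.0
        * (aln.mis_matches + insert_factor + round(3 * math.log(1 + size_dif)))
        / total
    )
    return 1.0 - milli_bad / 1000.0


def _gapless_psl(
    *,
    q_name: str,
    q_len: int,
    strand: str,
    qs: int,
    qe: int,
    target: Target,
    ts: int,
    te: int,
    mis_matches: int = 0,
) -> PslAlignment:
    length = qe - qs
    if strand == "+":
        q_start, q_end = qs, qe
    else:
        # PSL keeps qStart/qEnd on the + strand; qStarts stay in - coords
        q_start, q_end = q_len - qe, q_len - qs
    return PslAlignment(
        matches=length - mis_matches,
        mis_matches=mis_matches,
        rep_matches=0,
        n_count=0,
        q_num_insert=0,
        q_base_insert=0,
        t_num_insert=0,
        t_base_insert=0,
        strand=strand,
        q_name=q_name,
        q_size=q_len,
        q_start=q_start,
        q_end=q_end,
        t_name=target.name,
        t_size=target.psl_size,
        t_start=ts,
        t_end=te,
        block_count=1,
        block_sizes=[length],
        q_starts=[qs],
        t_starts=[ts],
    )


def _sorted(alignments: list[PslAlignment]) -> list[PslAlignment]:
    alignments.sort(key=lambda a: (a.t_name, a.t_start, a.q_start, a.strand))
    return alignments


class ExactMatcher:
    """Reusable k-mer-seeded finder of maximal exact matches to a genome."""

    def __init__(self, target, min_len: int = 20):
        if min_len < 8:
            raise ValueError(f"min_len must be >= 8, got {min_len}")
        self.min_len = min_len
        self.k = min(16, min_len)
        self.targets = as_targets(target)
        self._indexes: list[dict[str, list[int]]] = []
        k = self.k
        for t in self.targets:
            s = t.search_seq
            idx: dict[str, list[int]] = {}
            for j in range(len(s) - k + 1):
                kmer = s[j : j + k]
                if "N" in kmer:
                    continue
                idx.setdefault(kmer, []).append(j)
            self._indexes.append(idx)

    def find(self, query) -> list[PslAlignment]:
        q_name, q_fwd = _query_seq(query)
        n = len(q_fwd)
        k = self.k
        out: list[PslAlignment] = []
        if n < self.min_len:
            return out
        for target, idx in zip(self.targets, self._indexes):
            s = target.search_seq
            m = len(s)
            for strand, q in (("+", q_fwd), ("-", revcomp(q_fwd))):
                seen_by_diag: dict[int, list[tuple[int, int]]] = {}
                matches: set[tuple[int, int, int, int]] = set()
                for i in range(n - k + 1):
                    kmer = q[i : i + k]
                    if "N" in kmer:
                        continue
                    hits = idx.get(kmer)
                    if not hits:
                        continue
                    for j in hits:
                        d = j - i
                        spans = seen_by_diag.get(d)
                        if spans and any(qs <= i and i + k <= qe for qs, qe in spans):
                            continue
                        qs, ts = i, j
                        while qs > 0 and ts > 0 and q[qs - 1] == s[ts - 1] != "N":
                            qs -= 1
                            ts -= 1
                        qe, te = i + k, j + k
                        while qe < n and te < m and q[qe] == s[te] != "N":
                            qe += 1
                            te += 1
                        seen_by_diag.setdefault(d, []).append((qs, qe))
                        if qe - qs >= self.min_len:
                            matches.add((qs, qe, ts, te))
                for qs, qe, ts, te in matches:
                    if target.circular:
                        if ts >= target.length:
                            continue  # duplicate modulo L
                        if ts == 0 and qs > 0 and q[qs - 1] == s[target.length - 1] != "N":
                            # shadow of an origin-spanning match found at ts < L
                            continue
                    out.append(
                        _gapless_psl(
                            q_name=q_name,
                            q_len=n,
                            strand=strand,
                            qs=qs,
                            qe=qe,
                            target=target,
                            ts=ts,
                            te=te,
                        )
                    )
        return _sorted(out)


def align_exact(query, target, min_len: int = 20) -> list[PslAlignment]:
    """All maximal exact matches of ``query`` (both strands) to ``target``."""
    return ExactMatcher(target, min_len=min_len).find(query)


def align_near(query, target, min_identity: float = 0.95) -> list[PslAlignment]:
    """Full-query ungapped alignments at identity >= ``min_identity``.

    The query is chunked into ``e_max + 1`` pieces; by pigeonhole every
    qualifying placement matches at least one chunk exactly, so chunk
    occurrences seed candidate offsets which are then verified by Hamming
    count. Falls back to scanning every offset when chunks get too short.
    """
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError(f"min_identity must be in [0.5, 1], got {min_identity}")
    q_name, q_fwd = _query_seq(query)
    n = len(q_fwd)
    out: list[PslAlignment] = []
    e_max = int(math.floor(n * (1.0 - min_identity) + 1e-9))
    for target in as_targets(target):
        s = target.search_seq
        if target.circular:
            max_off = target.length - 1
            if n > target.length:
                continue
        else:
            max_off = len(s) - n
        if max_off < 0:
            continue
        for strand, q in (("+", q_fwd), ("-", revcomp(q_fwd))):
            offsets: set[int] = set()
            n_chunks = e_max + 1
            chunk_len = n // n_chunks
            if chunk_len < 8:
                offsets.update(range(max_off + 1))
            else:
                cuts = [round(c * n / n_chunks) for c in range(n_chunks + 1)]
                for cs, ce in zip(cuts, cuts[1:]):
                    chunk = q[cs:ce]
                    if "N" in chunk:
                        continue
                    pos = s.find(chunk)
                    while pos != -1:
                        off = pos - cs
                        if 0 <= off <= max_off:
                            offsets.add(off)
                        pos = s.find(chunk, pos + 1)
            for off in sorted(offsets):
                window = s[off : off + n]
                if len(window) < n:
                    continue
                if e_max == 0:
                    if q != window or "N" in q:
                        continue
                    mm = 0
                else:
                    mm = 0
                    ok = True
                    for a, b in zip(q, window):
                        if a != b or a == "N":
                            mm += 1
                            if mm > e_max:
                                ok = False
                                break
                    if not ok:
                        continue
                out.append(
                    _gapless_psl(
                        q_name=q_name,
                        q_len=n,
                        strand=strand,
                        qs=0,
                        qe=n,
                        target=target,
                        ts=off,
                        te=off + n,
                        mis_matches=mm,
                    )
                )
    return _sorted(out)


def drop_ambiguous(
    reads: Iterable[SeqRecord], max_n_fraction: float = 0.1
) -> tuple[list[SeqRecord], int]:
    """Drop reads whose N fraction exceeds ``max_n_fraction``.

    Returns (kept reads, number dropped).
    """
    kept: list[SeqRecord] = []
    dropped = 0
    for read in reads:
        if read.n_fraction > max_n_fraction:
            dropped += 1
        else:
            kept.append(read)
    return kept, dropped
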