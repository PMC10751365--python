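"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately share no code with the implementation they check:
interval algebra is recomputed from per-base sets, alignment from full
substring enumeration, and pslScore from the written-out formula.
"""

from __future__ import annotations

from senomob.records import GenomicInterval, revcomp


def base_cover(intervals) -> dict[str, set[int]]:
    cover: dict[str, set[int]] = {}
    for iv in intervals:
        cover.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return cover


def oracle_subtract(a, b) -> list[tuple[str, int, int]]:
    """Per-base subtraction: uncovered runs within each interval of a."""
    cover = base_cover(b)
    out = []
    for iv in a:
        covered = cover.get(iv.chrom, set())
        run_start = None
        for pos in range(iv.start, iv.end + 1):
            inside = pos < iv.end and pos not in covered
            if inside and run_start is None:
                run_start = pos
            elif not inside and run_start is not None:
                out.append((iv.chrom, run_start, pos))
                run_start = None
    return sorted(out)


def oracle_intersect_members(a, b) -> list[tuple[str, int, int]]:
    cover = base_cover(b)
    out = [
        (iv.chrom, iv.start, iv.end)
        for iv in a
        if any(p in cover.get(iv.chrom, set()) for p in range(iv.start, iv.end))
    ]
    return sorted(out)


def random_intervals(rng, n, n_chroms=4, max_coord=1000, max_len=50):
    out = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, max_coord - 1))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, min(start + length, max_coord)))
    return out


def brute_maximal_matches(query: str, target: str, min_len: int, circular: bool = False):
    """Every maximal exact match (strand, qs, qe, ts, te), strand coords.

    For circular targets the search runs on the doubled sequence and
    matches starting in the second copy are dropped.
    """
    L = len(target)
    s = target + target if circular else target
    out = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        n, m = len(q), len(s)
        for i in range(n):
            for j in range(m):
                if q[i] != s[j] or q[i] == "N":
                    continue
                if i > 0 and j > 0 and q[i - 1] == s[j - 1] != "N":
                    continue  # inside a longer run
                k = 0
                while i + k < n and j + k < m and q[i + k] == s[j + k] != "N":
                    k += 1
                if k >= min_len and not (circular and j >= L):
                    out.add((strand, i, i + k, j, j + k))
    return out


def matcher_tuples(alignments):
    """Convert PslAlignment output to the oracle's tuple form."""
    return {
        (a.strand, a.q_starts[0], a.q_starts[0] + a.block_sizes[0], a.t_start, a.t_end)
        for a in alignments
    }


def oracle_psl_score(a) -> int:
    return a.matches + a.rep_matches - a.mis_matches - a.q_num_insert - a.t_num_insert
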