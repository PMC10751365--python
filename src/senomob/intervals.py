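"""Interval algebra over BED-style 0-based half-open intervals.

Two distinct semantics are exposed, mirroring how the pipeline uses them:

* :func:`subtract` is base-level: it returns the *portions* of each interval
  of ``a`` covered by no interval of ``b``.
* :func:`intersect` / :func:`exclude` are membership-level: they keep or
  drop whole members of ``a`` by >=1 bp overlap with ``b`` (the behaviour of
  ``bedtools intersect -u`` / ``-v`` used to subtract one sample's call set
  from the other's).

All outputs are sorted by (chrom, start, end).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .records import GenomicInterval, sort_intervals


def build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def intersect(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Members of ``a`` overlapping >=1 bp of any interval of ``b``."""
    trees = build_trees(b)
    out = [iv for iv in a if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)]
    return sort_intervals(out)


def exclude(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Members of ``a`` overlapping no interval of ``b``."""
    trees = build_trees(b)
    out = [
        iv
        for iv in a
        if iv.chrom not in trees or not trees[iv.chrom].overlaps(iv.start, iv.end)
    ]
    return sort_intervals(out)


def subtract(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level subtraction: portions of ``a`` covered by no ``b``."""
    trees = build_trees(b)
    out: list[GenomicInterval] = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            out.append(iv)
            continue
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.end))
        cursor = iv.start
        for hit in hits:
            if hit.begin > cursor:
                out.append(
                    GenomicInterval(iv.chrom, cursor, hit.begin, iv.name, iv.score, iv.strand)
                )
            cursor = max(cursor, hit.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(
                GenomicInterval(iv.chrom, cursor, iv.end, iv.name, iv.score, iv.strand)
            )
    return sort_intervals(out)


def near(
    a: Iterable[GenomicInterval],
    b: Iterable[GenomicInterval],
    window: int,
) -> list[GenomicInterval]:
    """Members of ``a`` within ``window`` nt of (or overlapping) any ``b``."""
    grown = [
        GenomicInterval(iv.chrom, max(0, iv.start - window), iv.end + window, iv.name)
        for iv in b
    ]
    return intersect(a, grown)


def merge_intervals(
    intervals: Sequence[GenomicInterval], distance: int = 0
) -> list[GenomicInterval]:
    """Merge intervals closer than ``distance`` (0 = touching/overlapping)."""
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= distance:
            last = out[-1]
            out[-1] = GenomicInterval(
                last.chrom,
                last.start,
                max(last.end, iv.end),
                last.name,
                last.score + iv.score,
                last.strand,
            )
        else:
            out.append(iv)
    return out
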