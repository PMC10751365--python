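"""Query-based read counting with RPM normalization and log2 fold change.

Supports the two quantifications the study design needs: a 1,000 nt tiling
of the circular mtDNA (copy-number profile between samples) and short 5'
subfamily queries (SVA transcript abundance). A read counts toward a query
when it has at least one ungapped alignment at the requested identity, with
read and query in either role so a read contained within a longer query
counts; each read counts once per query. RPM = count / (total reads / 1e6);
fold changes are log2 of the rate-corrected RPM ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import align_near
from .records import CircularGenome, SeqRecord


def tile(seq: CircularGenome, tile_len: int = 1000) -> list[SeqRecord]:
    """Non-overlapping tiles covering the whole circle; last may be short."""
    if tile_len <= 0:
        raise ValueError("tile_len must be positive")
    tiles = []
    for start in range(0, seq.length, tile_len):
        end = min(start + tile_len, seq.length)
        tiles.append(SeqRecord(f"{start + 1}-{end}", seq.sequence[start:end]))
    return tiles


def _matches(read_seq: str, query_seq: str, min_identity: float) -> bool:
    if len(read_seq) <= len(query_seq):
        return bool(align_near(read_seq, {"q": query_seq}, min_identity))
    return bool(align_near(query_seq, {"r": read_seq}, min_identity))


def count_query(
    reads: Sequence[SeqRecord],
    queries: Sequence[SeqRecord],
    min_identity: float = 1.0,
) -> pd.DataFrame:
    """Per-query read counts and RPM over a read set.

    A read matching several queries contributes to each of them.
    """
    total = len(reads)
    rows = []
    for query in queries:
        count = sum(1 for read in reads if _matches(read.sequence, query.sequence, min_identity))
        rpm = count / (total / 1e6) if total else 0.0
        rows.append({"query": query.id, "count": count, "rpm": rpm})
    return pd.DataFrame(rows)


def fold_change(
    rpm_test: float,
    rpm_ref: float,
    rate_test: float = 1.0,
    rate_ref: float = 1.0,
) -> float | None:
    """log2 fold change of rate-corrected RPM; None when the ref is empty.

    The per-sample overall alignment rate divides the respective RPM before
    the ratio is taken.
    """
    if not (0 < rate_test <= 1 and 0 < rate_ref <= 1):
        raise ValueError("alignment rates must be in (0, 1]")
    if rpm_ref <= 0 or rpm_test <= 0:
        return None
    return math.log2((rpm_test / rate_test) / (rpm_ref / rate_ref))


def abundance_profile(
    reads_test: Sequence[SeqRecord],
    reads_ref: Sequence[SeqRecord],
    queries: Sequence[SeqRecord],
    min_identity: float = 1.0,
    rate_test: float = 1.0,
    rate_ref: float = 1.0,
) -> pd.DataFrame:
    """Two-sample per-query profile: counts, RPM and log2 FC."""
    test = count_query(reads_test, queries, min_identity)
    ref = count_query(reads_ref, queries, min_identity)
    df = test.merge(ref, on="query", suffixes=("_test", "_ref"))
    df["log2fc"] = [
        fold_change(t, r, rate_test, rate_ref)
        for t, r in zip(df["rpm_test"], df["rpm_ref"])
    ]
    return df
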