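"""Unique placement of nuclear flank sequences, shared by both callers.

A flank placement must align gapless, cover >= 95% of the query, and be
unique: a single best pslScore with no tie. Optionally the flank is also
screened for residual mtDNA segments. These are the cDNA-filter style
criteria both the numt scanner and the SVA readout apply to their flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .align import ExactMatcher, psl_score
from .records import GenomicInterval, PslAlignment


@dataclass
class Placement:
    interval: GenomicInterval
    strand: str
    score: int
    alignment: PslAlignment


@dataclass
class Rejection:
    reason: str


def filter_psl_placements(
    alignments: list[PslAlignment],
    flank_len: int,
    min_query_cov: float = 0.95,
) -> Placement | Rejection:
    """Apply coverage / gaplessness / uniqueness to candidate alignments."""
    min_span = math.ceil(min_query_cov * flank_len)
    usable = [a for a in alignments if a.is_gapless and a.q_span >= min_span]
    if not usable:
        return Rejection("unmapped")
    scored = sorted(usable, key=psl_score, reverse=True)
    if len(scored) > 1 and psl_score(scored[0]) == psl_score(scored[1]):
        return Rejection("not_unique")
    best = scored[0]
    return Placement(
        interval=GenomicInterval(best.t_name, best.t_start, best.t_end),
        strand=best.strand,
        score=psl_score(best),
        alignment=best,
    )


def place_flank(
    flank_seq: str,
    nuclear_matcher: ExactMatcher,
    min_query_cov: float = 0.95,
    mt_matcher: ExactMatcher | None = None,
) -> Placement | Rejection:
    """Place one flank on the nuclear genome; reject non-unique or mt-like.

    ``nuclear_matcher`` must have been built with a ``min_len`` no larger
    than ``ceil(min_query_cov * len(flank))`` so qualifying partial matches
    are visible. ``mt_matcher``, when given, rejects flanks still containing
    a 100%-identity mtDNA segment.
    """
    if mt_matcher is not None and mt_matcher.find(flank_seq):
        return Rejection("residual_mt")
    return filter_psl_placements(
        nuclear_matcher.find(flank_seq), len(flank_seq), min_query_cov
    )
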