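"""Single-label genomic feature annotation of target sites.

Each site receives exactly one feature class under a fixed precedence
(Promoter > 3UTR > Exon > TTS > SINE > LINE > LTR > Satellite > DNA >
Intron > Intergenic), using the midpoint rule: a site is annotated by the
features containing its midpoint. Promoter windows are TSS -1 kb..+100 bp
and TTS windows -100 bp..+1 kb, as encoded in the gene sub-feature track.
Also provides replicate-wise fraction summaries and a deterministic scan
for the L1 endonuclease cleavage consensus (5'-TTTT/AA-3') around
insertion points.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .records import GenomicInterval, revcomp

FEATURE_PRECEDENCE = [
    "Promoter",
    "3UTR",
    "Exon",
    "TTS",
    "SINE",
    "LINE",
    "LTR",
    "Satellite",
    "DNA",
    "Intron",
    "Intergenic",
]

_GENE_TAGS = {
    "promoter": "Promoter",
    "3utr": "3UTR",
    "exon": "Exon",
    "tts": "TTS",
    "intron": "Intron",
}

_REPEAT_TAGS = {
    "sine": "SINE",
    "alu": "SINE",
    "line": "LINE",
    "l1": "LINE",
    "ltr": "LTR",
    "satellite": "Satellite",
    "dna": "DNA",
}


def _class_of(name: str, table: dict[str, str], kind: str) -> str:
    tag = name.split("|")[0].split("/")[0].split(":")[0].lower()
    if tag not in table:
        raise ValueError(
            f"unknown {kind} class tag {name!r}; accepted tags: "
            + ", ".join(sorted(table))
        )
    return table[tag]


class FeatureIndex:
    """Per-class interval trees for midpoint (or any-overlap) lookup."""

    def __init__(
        self,
        genes: Iterable[GenomicInterval],
        repeats: Iterable[GenomicInterval],
        midpoint_rule: bool = True,
    ):
        self.midpoint_rule = midpoint_rule
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        for iv in genes:
            cls = _class_of(iv.name, _GENE_TAGS, "gene sub-feature")
            self._add(cls, iv)
        for iv in repeats:
            cls = _class_of(iv.name, _REPEAT_TAGS, "repeat")
            self._add(cls, iv)

    def _add(self, cls: str, iv: GenomicInterval) -> None:
        self._trees.setdefault(cls, {}).setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end
        )

    def annotate(self, site: GenomicInterval) -> str:
        if self.midpoint_rule:
            point = site.midpoint
            lo, hi = point, point + 1
        else:
            lo, hi = site.start, site.end
        for cls in FEATURE_PRECEDENCE[:-1]:
            chrom_trees = self._trees.get(cls)
            if chrom_trees and site.chrom in chrom_trees:
                if chrom_trees[site.chrom].overlaps(lo, hi):
                    return cls
        return "Intergenic"


def annotate_site(
    site: GenomicInterval,
    genes: Iterable[GenomicInterval],
    repeats: Iterable[GenomicInterval],
    midpoint_rule: bool = True,
) -> str:
    return FeatureIndex(genes, repeats, midpoint_rule).annotate(site)


def annotate_sites(
    sites: Sequence[GenomicInterval],
    genes: Iterable[GenomicInterval],
    repeats: Iterable[GenomicInterval],
    midpoint_rule: bool = True,
) -> list[str]:
    index = FeatureIndex(genes, repeats, midpoint_rule)
    return [index.annotate(site) for site in sites]


@dataclass
class AnnotationSummary:
    classes: list[str]
    fraction_pct: dict[str, float]  # mean % across replicates
    stderr_pct: dict[str, float]


def summarize_fractions(labels_per_replicate: Sequence[Sequence[str]]) -> AnnotationSummary:
    """Per-class % of sites (mean across replicates) with standard error."""
    reps = [list(labels) for labels in labels_per_replicate if len(labels) > 0]
    if not reps:
        raise ValueError("no labelled sites to summarize")
    per_rep: list[dict[str, float]] = []
    for labels in reps:
        counts = Counter(labels)
        n = len(labels)
        per_rep.append({cls: 100.0 * counts.get(cls, 0) / n for cls in FEATURE_PRECEDENCE})
    n_rep = len(per_rep)
    mean = {
        cls: float(np.mean([r[cls] for r in per_rep])) for cls in FEATURE_PRECEDENCE
    }
    if n_rep > 1:
        se = {
            cls: float(np.std([r[cls] for r in per_rep], ddof=1) / np.sqrt(n_rep))
            for cls in FEATURE_PRECEDENCE
        }
    else:
        se = {cls: 0.0 for cls in FEATURE_PRECEDENCE}
    return AnnotationSummary(list(FEATURE_PRECEDENCE), mean, se)


def _tract_matches(window: str) -> bool:
    """TTTT immediately followed by AA, allowing <=1 mismatch in the tract."""
    for p in range(len(window) - 5):
        if window[p + 4 : p + 6] != "AA":
            continue
        mismatches = sum(1 for c in window[p : p + 4] if c != "T")
        if mismatches <= 1:
            return True
    return False


def site_matches_cleavage_consensus(
    seq: str, center: int, window: int = 10
) -> bool:
    """Does either strand near ``center`` carry the TTTT/AA consensus?

    The motif start must lie within ``window`` nt of the insertion point.
    """
    if window < 6:
        raise ValueError("window must be >= 6")
    lo = max(0, center - window)
    hi = min(len(seq), center + window + 6)
    region = seq[lo:hi]
    return _tract_matches(region) or _tract_matches(revcomp(region))


def scan_cleavage_consensus(
    flanks: Sequence[tuple[str, int]],
    window: int = 10,
) -> tuple[float, list[bool]]:
    """Fraction of insertion sites matching the L1 cleavage consensus.

    ``flanks`` is a sequence of (sequence, insertion point offset) pairs.
    """
    verdicts = [
        site_matches_cleavage_consensus(seq, center, window) for seq, center in flanks
    ]
    fraction = sum(verdicts) / len(verdicts) if verdicts else 0.0
    return fraction, verdicts
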