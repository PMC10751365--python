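"""Sequence, interval and alignment records shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the BED and
PSL writers/readers speak the matching standard dialects at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; ``N`` maps to ``N``."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named DNA sequence with optional per-base phred qualities.

    The sequence is uppercased on construction and must be non-empty over
    the alphabet ``{A, C, G, T, N}``. When qualities are present their
    length must equal the sequence length.
    """

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_fraction(self) -> float:
        return self.sequence.count("N") / len(self.sequence)

    def reverse_complement(self) -> "SeqRecord":
        qual = None if self.quality is None else list(reversed(self.quality))
        return SeqRecord(self.id, revcomp(self.sequence), qual)


_STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome (BED6 payload)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self):
        return (self.chrom, self.start, self.end)


def sort_intervals(intervals) -> list[GenomicInterval]:
    return sorted(intervals, key=GenomicInterval.sort_key)


@dataclass
class PslAlignment:
    """A block-structured local alignment in the 21-column PSL convention.

    Gapless alignments have ``block_count == 1`` and no inserts. For circular
    targets searched on a doubled linearization, ``t_size`` is the doubled
    length (2L) and origin-spanning hits satisfy ``t_start < L <= t_end``.
    """

    matches: int
    mis_matches: int
    rep_matches: int
    n_count: int
    q_num_insert: int
    q_base_insert: int
    t_num_insert: int
    t_base_insert: int
    strand: str
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    block_count: int
    block_sizes: list[int] = field(default_factory=list)
    q_starts: list[int] = field(default_factory=list)
    t_starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.matches,
            self.mis_matches,
            self.rep_matches,
            self.n_count,
            self.q_num_insert,
            self.t_num_insert,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"psl {self.q_name}->{self.t_name}: negative count")
        if sum(self.block_sizes) != (
            self.matches + self.mis_matches + self.rep_matches + self.n_count
        ):
            raise ValueError(
                f"psl {self.q_name}->{self.t_name}: block sizes "
                f"{self.block_sizes} do not sum to the aligned base count"
            )
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ValueError(
                f"psl {self.q_name}->{self.t_name}: bad query range "
                f"{self.q_start}-{self.q_end} (size {self.q_size})"
            )
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ValueError(
                f"psl {self.q_name}->{self.t_name}: bad target range "
                f"{self.t_start}-{self.t_end} (size {self.t_size})"
            )
        if not (
            len(self.block_sizes)
            == len(self.q_starts)
            == len(self.t_starts)
            == self.block_count
        ):
            raise ValueError(
                f"psl {self.q_name}->{self.t_name}: block lists must have "
                f"length block_count={self.block_count}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"psl strand must be + or -, got {self.strand!r}")

    @property
    def span(self) -> int:
        """Aligned span on the target."""
        return self.t_end - self.t_start

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def is_gapless(self) -> bool:
        return (
            self.block_count == 1
            and self.q_num_insert == 0
            and self.t_num_insert == 0
        )


@dataclass
class CircularGenome:
    """A circular sequence (mtDNA); positions are interpreted modulo L."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"circular genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"circular genome {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def doubled(self) -> str:
        """The doubled linearization used for origin-spanning search."""
        return self.sequence + self.sequence

    def fetch(self, start: int, length: int) -> str:
        """Extract ``length`` bases starting at ``start`` (modulo L)."""
        if length > self.length:
            raise ValueError("cannot fetch more than one full circle")
        start %= self.length
        return self.doubled[start : start + length]
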