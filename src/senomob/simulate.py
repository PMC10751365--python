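"""Synthetic genomes, planted events and read products with truth tables.

This module builds the study conditions the analysis assumes: a toy nuclear
genome with annotated germline features (SVAs, numts, Alu/LINE/LTR/Satellite
repeats, genes with sub-features) plus a circular mtDNA, then plants de novo
SVA insertions and de novo numts into a "senescent" copy only, and finally
emits the three read products the pipelines consume:

* single-end 150 nt WGS reads (mtDNA drawn at a configurable copy number),
* RDA amplicon reads (adaptor + upstream flank + (CCCTCT)n hexamer + SVA
  5' head), with driver-shared loci suppressed by a per-locus Bernoulli and
  tester-unique loci amplified multiplicatively,
* inter-Alu (AluScan) amplicon reads between inward-facing Alu pairs.

A fixed seed makes every output byte-identical across runs. Every planted
event is recorded in a truth table and is re-extractable from the senescent
genome.

The six SVA subfamily 5' sequences bundled here are synthetic stand-ins
(distinct 5' 200-mers generated from a fixed internal seed), not database
consensus sequences; real subfamily FASTA can be substituted by passing
``subfamily_seqs``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .records import CircularGenome, GenomicInterval, SeqRecord, revcomp
from .io import write_bed, read_bed, write_fasta

HEXAMER = "CCCTCT"
DEFAULT_RDA_ADAPTOR = "AGCACTCTCCAGCCTCTCACCGCA"

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASE_LOOKUP[idx].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def sva_subfamily_seqs(length: int = 300) -> dict[str, str]:
    """Bundled synthetic SVA subfamily bodies (A-F), distinct 5' 200-mers."""
    rng = np.random.default_rng(988_211)
    return {sub: _random_seq(rng, length, gc=0.55) for sub in "ABCDEF"}


# Approximate human mtDNA feature layout (rCRS-style coordinates trimmed to
# L = 16,559); gaps between features (tRNA clusters etc.) are filled with
# "MT-other" so the map covers the whole circle.
_MT_FEATURES = [
    ("D-Loop", 0, 576),
    ("MT-RNR1", 648, 1601),
    ("MT-RNR2", 1671, 3229),
    ("MT-ND1", 3307, 4262),
    ("MT-ND2", 4470, 5511),
    ("MT-CO1", 5904, 7445),
    ("MT-CO2", 7586, 8269),
    ("MT-ATP8", 8366, 8572),
    ("MT-ATP6", 8572, 9207),
    ("MT-CO3", 9207, 9990),
    ("MT-ND3", 10059, 10404),
    ("MT-ND4L", 10470, 10766),
    ("MT-ND4", 10766, 12137),
    ("MT-ND5", 12337, 14148),
    ("MT-ND6", 14149, 14673),
    ("MT-CYB", 14747, 15887),
    ("D-Loop", 16024, 16559),
]


def mt_gene_map(mt_id: str = "chrM", length: int = 16_559) -> list[GenomicInterval]:
    """Feature map of the mtDNA (genes + D-Loop + filler), covering [0, L)."""
    scale = length / 16_559
    out: list[GenomicInterval] = []
    cursor = 0
    for name, start, end in _MT_FEATURES:
        s = min(int(round(start * scale)), length)
        e = min(int(round(end * scale)), length)
        if s > cursor:
            out.append(GenomicInterval(mt_id, cursor, s, "MT-other"))
        if e > s:
            out.append(GenomicInterval(mt_id, s, e, name))
        cursor = max(cursor, e)
    if cursor < length:
        out.append(GenomicInterval(mt_id, cursor, length, "MT-other"))
    return out


@dataclass
class ToyGenomeSpec:
    """Parameters of the toy reference ("proliferating") genome."""

    n_chroms: int = 2
    chrom_length: int = 50_000
    gc_fraction: float = 0.5
    mt_length: int = 16_559
    n_germline_sva: int = 8
    n_germline_numt: int = 5
    n_alu: int = 20
    n_line: int = 6
    n_ltr: int = 4
    n_satellite: int = 2
    n_genes: int = 3
    germline_numt_len_range: tuple[int, int] = (60, 300)
    repeat_divergence: float = 0.05
    min_feature_gap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_length",
            "n_germline_sva",
            "n_germline_numt",
            "n_alu",
            "n_line",
            "n_ltr",
            "n_satellite",
            "n_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_chroms == 0 or self.chrom_length <= 0:
            raise ValueError("need at least one chromosome of positive length")


class _Allocator:
    """Samples non-overlapping feature positions with a minimum gap."""

    def __init__(self, rng, chrom_lengths: dict[str, int], gap: int, margin: int = 200):
        self.rng = rng
        self.lengths = chrom_lengths
        self.gap = gap
        self.margin = margin
        self._occ: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
        self.names = sorted(chrom_lengths)

    def occupy(self, chrom: str, start: int, end: int) -> None:
        occ = self._occ[chrom]
        bisect.insort(occ, (start, end))

    def _fits(self, chrom: str, start: int, end: int) -> bool:
        occ = self._occ[chrom]
        i = bisect.bisect_left(occ, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(occ):
                s, e = occ[j]
                if start < e + self.gap and s < end + self.gap:
                    return False
        return True

    def place(self, length: int, chrom: str | None = None) -> tuple[str, int]:
        for _ in range(5000):
            c = chrom or self.names[self.rng.integers(0, len(self.names))]
            hi = self.lengths[c] - length - self.margin
            if hi <= self.margin:
                continue
            start = int(self.rng.integers(self.margin, hi))
            if self._fits(c, start, start + length):
                self.occupy(c, start, start + length)
                return c, start
        total = sum(self.lengths.values())
        raise ValueError(
            "requested features exceed genome capacity: could not place a "
            f"{length} nt feature; increase chrom_length beyond "
            f"~{total // max(1, len(self.lengths)) + 10 * (length + self.gap)} nt "
            "or reduce feature counts"
        )


@dataclass
class ToyGenome:
    """The proliferating reference genome plus annotation tracks."""

    chroms: dict[str, str]
    mt: CircularGenome
    sva: list[GenomicInterval]
    numt: list[GenomicInterval]
    repeats: list[GenomicInterval]
    genes: list[GenomicInterval]
    spec: ToyGenomeSpec

    @property
    def records(self) -> list[SeqRecord]:
        return [SeqRecord(name, seq) for name, seq in sorted(self.chroms.items())]

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.records, os.path.join(outdir, "proliferating.fa"))
        write_fasta([SeqRecord(self.mt.id, self.mt.sequence)], os.path.join(outdir, "mt.fa"))
        write_bed(self.sva, os.path.join(outdir, "sva.bed"))
        write_bed(self.numt, os.path.join(outdir, "numt.bed"))
        write_bed(self.repeats, os.path.join(outdir, "repeats.bed"))
        write_bed(self.genes, os.path.join(outdir, "genes.bed"))


def make_toy_genome(spec: ToyGenomeSpec) -> ToyGenome:
    """Build the reference genome; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    mt = CircularGenome("chrM", _random_seq(rng, spec.mt_length, spec.gc_fraction))
    names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    raw = {
        name: bytearray(_random_seq(rng, spec.chrom_length, spec.gc_fraction).encode())
        for name in names
    }
    alloc = _Allocator(rng, {n: spec.chrom_length for n in names}, spec.min_feature_gap)
    sva_bed: list[GenomicInterval] = []
    numt_bed: list[GenomicInterval] = []
    rep_bed: list[GenomicInterval] = []
    gene_bed: list[GenomicInterval] = []

    def overwrite(chrom: str, start: int, seq: str) -> None:
        raw[chrom][start : start + len(seq)] = seq.encode()

    # genes: promoter / exon / intron / 3UTR / TTS sub-features
    for g in range(spec.n_genes):
        body = 2500
        chrom, start = alloc.place(body + 2000)
        g0 = start + 1000  # TSS; promoter window fits upstream
        ge = g0 + body
        gname = f"gene{g + 1}"
        gene_bed += [
            GenomicInterval(chrom, g0 - 1000, g0 + 100, f"promoter|{gname}", 0, "+"),
            GenomicInterval(chrom, g0, g0 + 400, f"exon|{gname}", 0, "+"),
            GenomicInterval(chrom, g0 + 400, g0 + 1700, f"intron|{gname}", 0, "+"),
            GenomicInterval(chrom, g0 + 1700, g0 + 2000, f"exon|{gname}", 0, "+"),
            GenomicInterval(chrom, g0 + 2000, ge, f"3UTR|{gname}", 0, "+"),
            GenomicInterval(chrom, ge - 100, ge + 1000, f"TTS|{gname}", 0, "+"),
        ]

    consensi = {
        "Alu": _random_seq(rng, 300, 0.6),
        "LINE": _random_seq(rng, 800, 0.4),
        "LTR": _random_seq(rng, 600, 0.5),
    }
    sat_unit = _random_seq(rng, 30, 0.5)
    repeat_plan = (
        [("Alu", consensi["Alu"])] * spec.n_alu
        + [("LINE", consensi["LINE"])] * spec.n_line
        + [("LTR", consensi["LTR"])] * spec.n_ltr
        + [("Satellite", sat_unit * 17)] * spec.n_satellite
    )
    for i, (cls, cons) in enumerate(repeat_plan):
        copy = _mutate(rng, cons, spec.repeat_divergence)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = alloc.place(len(copy))
        overwrite(chrom, start, copy if strand == "+" else revcomp(copy))
        rep_bed.append(
            GenomicInterval(chrom, start, start + len(copy), f"{cls}|{i}", 0, strand)
        )

    subfams = sva_subfamily_seqs()
    for i in range(spec.n_germline_sva):
        sub = "ABCDEF"[int(rng.integers(0, 6))]
        n_rep = int(rng.integers(30, 51))
        element = HEXAMER * n_rep + subfams[sub]
        chrom, start = alloc.place(len(element))
        overwrite(chrom, start, element)
        sva_bed.append(
            GenomicInterval(chrom, start, start + len(element), f"SVA_{sub}|{i}", 0, "+")
        )

    lo, hi = spec.germline_numt_len_range
    for i in range(spec.n_germline_numt):
        length = int(rng.integers(lo, hi + 1))
        mt_start = int(rng.integers(0, mt.length))
        seg = mt.fetch(mt_start, length)
        chrom, start = alloc.place(length)
        overwrite(chrom, start, seg)
        numt_bed.append(
            GenomicInterval(
                chrom,
                start,
                start + length,
                f"numt|{i};mt_start={mt_start};mt_len={length}",
                0,
                "+",
            )
        )

    chroms = {name: raw[name].decode() for name in names}
    from .records import sort_intervals

    return ToyGenome(
        chroms=chroms,
        mt=mt,
        sva=sort_intervals(sva_bed),
        numt=sort_intervals(numt_bed),
        repeats=sort_intervals(rep_bed),
        genes=sort_intervals(gene_bed),
        spec=spec,
    )


@dataclass
class PlantParams:
    """Parameters of de novo event planting."""

    mt_len_range: tuple[int, int] = (40, 400)
    microhomology_range: tuple[int, int] = (0, 5)
    tsd_range: tuple[int, int] = (4, 20)
    hexamer_repeat_range: tuple[int, int] = (30, 50)
    truncation_5p_max: int = 0
    repeat_target_bias: float = 0.0
    min_distance: int = 300


@dataclass
class PlantedEvent:
    """One planted de novo event; the unit row of the truth table.

    ``ref_point`` is the insertion point in reference (proliferating)
    coordinates; ``sen_start``/``sen_end`` delimit the inserted sequence in
    the senescent genome.
    """

    kind: str  # de_novo_sva | de_novo_numt
    chrom: str
    ref_point: int
    sen_start: int
    sen_end: int
    seq: str | None = None
    mt_start: int | None = None
    mt_len: int | None = None
    microhomology_len: int | None = None
    tsd_len: int | None = None
    truncation_5p: int | None = None
    subfamily: str | None = None
    hexamer_repeats: int | None = None

    def tags(self) -> str:
        parts = [f"kind={self.kind}", f"ref_point={self.ref_point}"]
        for key in (
            "mt_start",
            "mt_len",
            "microhomology_len",
            "tsd_len",
            "truncation_5p",
            "subfamily",
            "hexamer_repeats",
        ):
            value = getattr(self, key)
            if value is not None:
                parts.append(f"{key}={value}")
        return ";".join(parts)


@dataclass
class SenescentSample:
    """The tester genome: reference plus planted de novo events."""

    chroms: dict[str, str]
    mt: CircularGenome
    truth: list[PlantedEvent]
    shifts: dict[str, list[tuple[int, int]]]  # chrom -> [(ref_point, cum_len)]

    @property
    def records(self) -> list[SeqRecord]:
        return [SeqRecord(name, seq) for name, seq in sorted(self.chroms.items())]

    def lift_pos(self, chrom: str, pos: int) -> int:
        """Map a reference coordinate to senescent coordinates."""
        offset = 0
        for point, cum in self.shifts.get(chrom, []):
            if pos > point:
                offset = cum
            else:
                break
        return pos + offset

    def lift(self, iv: GenomicInterval) -> GenomicInterval:
        off = self.lift_pos(iv.chrom, iv.start) - iv.start
        return replace(iv, start=iv.start + off, end=iv.end + off)


def truth_to_intervals(events: Sequence[PlantedEvent]) -> list[GenomicInterval]:
    return [
        GenomicInterval(ev.chrom, ev.sen_start, max(ev.sen_end, ev.sen_start + 1), ev.tags())
        for ev in events
    ]


def write_truth(events: Sequence[PlantedEvent], path) -> None:
    write_bed(truth_to_intervals(events), path)


def read_truth(path) -> list[PlantedEvent]:
    events = []
    for iv in read_bed(path):
        tags = dict(kv.split("=", 1) for kv in iv.name.split(";"))
        events.append(
            PlantedEvent(
                kind=tags["kind"],
                chrom=iv.chrom,
                ref_point=int(tags["ref_point"]),
                sen_start=iv.start,
                sen_end=iv.end,
                mt_start=int(tags["mt_start"]) if "mt_start" in tags else None,
                mt_len=int(tags["mt_len"]) if "mt_len" in tags else None,
                microhomology_len=(
                    int(tags["microhomology_len"]) if "microhomology_len" in tags else None
                ),
                tsd_len=int(tags["tsd_len"]) if "tsd_len" in tags else None,
                truncation_5p=(
                    int(tags["truncation_5p"]) if "truncation_5p" in tags else None
                ),
                subfamily=tags.get("subfamily"),
                hexamer_repeats=(
                    int(tags["hexamer_repeats"]) if "hexamer_repeats" in tags else None
                ),
            )
        )
    return events


def _pick_insertion_points(
    rng,
    toy: ToyGenome,
    n: int,
    params: PlantParams,
) -> list[tuple[str, int]]:
    """Insertion points away from annotated features and from each other."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in toy.chroms}
    for iv in toy.sva + toy.numt + toy.repeats + toy.genes:
        occupied[iv.chrom].append((iv.start, iv.end))
    for c in occupied:
        occupied[c].sort()
    names = sorted(toy.chroms)
    points: list[tuple[str, int]] = []
    margin = 400
    gap = params.min_distance

    def clear(chrom: str, pos: int, *, ignore_features: bool) -> bool:
        if not ignore_features:
            for s, e in occupied[chrom]:
                if s - gap < pos < e + gap:
                    return False
        for c2, p2 in points:
            if c2 == chrom and abs(p2 - pos) < 2 * gap:
                return False
        return True

    repeats = toy.repeats
    for _ in range(n):
        placed = False
        for _ in range(5000):
            in_repeat = repeats and rng.random() < params.repeat_target_bias
            if in_repeat:
                rep = repeats[int(rng.integers(0, len(repeats)))]
                pos = int(rng.integers(rep.start + 1, rep.end))
                chrom = rep.chrom
            else:
                chrom = names[int(rng.integers(0, len(names)))]
                pos = int(rng.integers(margin, len(toy.chroms[chrom]) - margin))
            if clear(chrom, pos, ignore_features=in_repeat):
                points.append((chrom, pos))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place de novo insertion points: genome too crowded"
            )
    return points


def plant_de_novo_events(
    toy: ToyGenome,
    n_sva: int,
    n_numt: int,
    params: PlantParams | None = None,
    seed: int = 0,
    subfamily_seqs: dict[str, str] | None = None,
) -> SenescentSample:
    """Insert de novo events into a senescent copy; returns genome + truth.

    numts are mtDNA substrings (possibly origin-spanning) inserted with a
    planted junction microhomology: the first m bases of the mt segment
    equal the m reference bases immediately left of the insertion point.
    SVAs are hexamer-headed subfamily elements with a target site
    duplication and optional 5' truncation.
    """
    params = params or PlantParams()
    rng = np.random.default_rng(seed)
    subfams = subfamily_seqs or sva_subfamily_seqs()
    points = _pick_insertion_points(rng, toy, n_sva + n_numt, params)
    kinds = ["de_novo_sva"] * n_sva + ["de_novo_numt"] * n_numt
    mt_doubled = toy.mt.doubled
    L = toy.mt.length

    planned: list[PlantedEvent] = []
    mh_lo, mh_hi = params.microhomology_range
    for (chrom, pos), kind in zip(points, kinds):
        g = toy.chroms[chrom]
        if kind == "de_novo_numt":
            mt_len = int(rng.integers(params.mt_len_range[0], params.mt_len_range[1] + 1))
            m = int(rng.integers(mh_lo, mh_hi + 1))
            mt_start = None
            while m >= 0:
                if m == 0:
                    mt_start = int(rng.integers(0, L))
                    break
                probe = g[pos - m : pos]
                hits = []
                at = mt_doubled.find(probe)
                while at != -1 and at < L:
                    hits.append(at)
                    at = mt_doubled.find(probe, at + 1)
                if hits:
                    mt_start = int(hits[int(rng.integers(0, len(hits)))])
                    break
                m -= 1
            seg = mt_doubled[mt_start : mt_start + mt_len]
            planned.append(
                PlantedEvent(
                    kind=kind,
                    chrom=chrom,
                    ref_point=pos,
                    sen_start=-1,
                    sen_end=-1,
                    seq=seg,
                    mt_start=mt_start,
                    mt_len=mt_len,
                    microhomology_len=m,
                )
            )
        else:
            sub = "ABCDEF"[int(rng.integers(0, 6))]
            n_rep = int(
                rng.integers(
                    params.hexamer_repeat_range[0], params.hexamer_repeat_range[1] + 1
                )
            )
            trunc = (
                int(rng.integers(0, params.truncation_5p_max + 1))
                if params.truncation_5p_max > 0
                else 0
            )
            tsd = int(rng.integers(params.tsd_range[0], params.tsd_range[1] + 1))
            element = (HEXAMER * n_rep + subfams[sub])[trunc:]
            ins = element + g[pos - tsd : pos]
            planned.append(
                PlantedEvent(
                    kind=kind,
                    chrom=chrom,
                    ref_point=pos,
                    sen_start=-1,
                    sen_end=-1,
                    seq=ins,
                    tsd_len=tsd,
                    truncation_5p=trunc,
                    subfamily=sub,
                    hexamer_repeats=n_rep,
                )
            )

    # splice insertions chromosome by chromosome, tracking coordinate shifts
    sen_chroms: dict[str, str] = {}
    shifts: dict[str, list[tuple[int, int]]] = {}
    truth: list[PlantedEvent] = []
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in planned:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, seq in toy.chroms.items():
        events = sorted(by_chrom.get(chrom, []), key=lambda e: e.ref_point)
        parts: list[str] = []
        cursor = 0
        cum = 0
        chrom_shifts: list[tuple[int, int]] = []
        for ev in events:
            parts.append(seq[cursor : ev.ref_point])
            sen_start = ev.ref_point + cum
            parts.append(ev.seq)
            cum += len(ev.seq)
            chrom_shifts.append((ev.ref_point, cum))
            cursor = ev.ref_point
            truth.append(replace(ev, sen_start=sen_start, sen_end=sen_start + len(ev.seq)))
        parts.append(seq[cursor:])
        sen_chroms[chrom] = "".join(parts)
        shifts[chrom] = chrom_shifts
    truth.sort(key=lambda e: (e.chrom, e.ref_point))
    return SenescentSample(chroms=sen_chroms, mt=toy.mt, truth=truth, shifts=shifts)


def simulate_wgs(
    chroms: dict[str, str],
    mt: CircularGenome | None,
    coverage: float,
    read_len: int = 150,
    mt_copy_number: float = 10.0,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "wgs",
) -> list[SeqRecord]:
    """Uniform single-end reads; mtDNA drawn at ``mt_copy_number`` x depth.

    Read count = round(coverage * weighted genome length / read_len); read
    ids embed source, start and strand for downstream truth bookkeeping.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    sources: list[tuple[str, str, int, float, bool]] = []
    for name in sorted(chroms):
        seq = chroms[name]
        if len(seq) >= read_len:
            sources.append((name, seq, len(seq) - read_len, float(len(seq)), False))
    if mt is not None and mt.length >= read_len:
        sources.append((mt.id, mt.doubled, mt.length - 1, mt.length * mt_copy_number, True))
    weights = np.array([s[3] for s in sources])
    total_weight = weights.sum()
    n_reads = int(round(coverage * total_weight / read_len))
    src_idx = rng.choice(len(sources), size=n_reads, p=weights / total_weight)
    positions = np.empty(n_reads, dtype=np.int64)
    for s_i, src in enumerate(sources):
        mask = src_idx == s_i
        cnt = int(mask.sum())
        if cnt:
            positions[mask] = rng.integers(0, src[2] + 1, size=cnt)
    strands = rng.integers(0, 2, size=n_reads)
    reads: list[SeqRecord] = []
    for i in range(n_reads):
        name, seq, _, _, _ = sources[src_idx[i]]
        pos = int(positions[i])
        fragment = seq[pos : pos + read_len]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            fragment = revcomp(fragment)
        if error_rate > 0:
            fragment = _mutate(rng, fragment, error_rate)
        reads.append(
            SeqRecord(f"{id_prefix}:{i}:{name}:{pos}:{strand}", fragment)
        )
    return reads


def _fragment(
    amplicon: str,
    read_len: int,
    step: int,
    rng,
    prefix: str,
    reads: list[SeqRecord],
) -> None:
    if len(amplicon) < read_len:
        return
    for off in range(0, len(amplicon) - read_len + 1, step):
        frag = amplicon[off : off + read_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append(SeqRecord(f"{prefix}:{off}", frag))


@dataclass
class RdaParams:
    adaptor: str = DEFAULT_RDA_ADAPTOR
    flank_len: int = 80
    head_len: int = 120
    subtraction_efficiency: float = 0.99
    amplification: int = 50
    read_len: int = 150
    fragment_step: int = 60


def simulate_rda(
    tester: SenescentSample,
    reference: ToyGenome,
    params: RdaParams | None = None,
    seed: int = 0,
) -> list[SeqRecord]:
    """RDA amplicon reads for all SVA 5' loci in the tester genome.

    Germline loci (present in the driver) are suppressed with probability
    ``subtraction_efficiency``; tester-unique (de novo) loci are amplified
    ``amplification``-fold. Each amplicon is adaptor + upstream flank +
    hexamer-headed SVA 5' region, fragmented into tiled reads.
    """
    params = params or RdaParams()
    rng = np.random.default_rng(seed)
    loci: list[tuple[str, int, bool, str]] = []  # chrom, hexamer start, shared, label
    for iv in reference.sva:
        lifted = tester.lift(iv)
        loci.append((lifted.chrom, lifted.start, True, iv.name))
    for ev in tester.truth:
        if ev.kind == "de_novo_sva":
            loci.append((ev.chrom, ev.sen_start, False, f"de_novo|{ev.chrom}:{ev.ref_point}"))
    loci.sort(key=lambda x: (x[0], x[1]))
    reads: list[SeqRecord] = []
    for idx, (chrom, hs, shared, label) in enumerate(loci):
        if shared and rng.random() < params.subtraction_efficiency:
            continue
        seq = tester.chroms[chrom]
        if hs - params.flank_len < 0:
            continue
        flank = seq[hs - params.flank_len : hs]
        head = seq[hs : hs + params.head_len]
        amplicon = params.adaptor + flank + head
        copies = 1 if shared else params.amplification
        for c in range(copies):
            _fragment(
                amplicon,
                params.read_len,
                params.fragment_step,
                rng,
                f"rda:{idx}:{c}",
                reads,
            )
    return reads


def simulate_aluscan(
    chroms: dict[str, str],
    repeats: Iterable[GenomicInterval],
    max_amplicon: int = 5_000,
    read_len: int = 150,
    fragment_step: int = 75,
    copies: int = 2,
    seed: int = 0,
) -> list[SeqRecord]:
    """Inter-Alu amplicon reads between inward-facing Alu primer pairs.

    A (+) strand Alu and a downstream (-) strand Alu within
    ``max_amplicon`` nt delimit one amplicon (outer coordinates); regions
    with no such flanking pair are absent from the output.
    """
    rng = np.random.default_rng(seed)
    alus = [iv for iv in repeats if iv.name.split("|")[0].split("/")[0] in ("Alu", "SINE")]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in alus:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    reads: list[SeqRecord] = []
    k = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
        for i, a in enumerate(ivs):
            if a.strand != "+":
                continue
            for b in ivs[i + 1 :]:
                if b.end - a.start > max_amplicon:
                    break
                if b.strand != "-":
                    continue
                amplicon = chroms[chrom][a.start : b.end]
                for c in range(copies):
                    _fragment(
                        amplicon,
                        read_len,
                        fragment_step,
                        rng,
                        f"aluscan:{k}:{c}",
                        reads,
                    )
                k += 1
    return reads
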