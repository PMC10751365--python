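"""Standard-format I/O: FASTA, FASTQ (phred+33), BED6 and 21-column PSL.

FASTA/FASTQ parsing is delegated to Biopython; BED and PSL are simple
tab-separated dialects parsed here so that malformed lines can be reported
with file, line number and offending field. All writers emit files the
matching reader round-trips exactly on the fields the pipeline uses.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO

from .records import GenomicInterval, PslAlignment, SeqRecord


def read_fasta(path) -> list[SeqRecord]:
    try:
        return [SeqRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTA: {exc}") from exc


def write_fasta(records: Iterable[SeqRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> list[SeqRecord]:
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(
                SeqRecord(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ: {exc}") from exc
    return out


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [40] * len(rec)
            fh.write(
                f"@{rec.id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


def _bed_error(path, lineno: int, fieldname: str, value: str) -> ValueError:
    return ValueError(
        f"{path}, line {lineno}: malformed BED field {fieldname!r}: {value!r}"
    )


def read_bed(path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {lineno}: expected >=3 tab-separated BED "
                    f"fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
            except ValueError:
                raise _bed_error(path, lineno, "start", fields[1]) from None
            try:
                end = int(fields[2])
            except ValueError:
                raise _bed_error(path, lineno, "end", fields[2]) from None
            name = fields[3] if len(fields) > 3 else "."
            score = 0.0
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise _bed_error(path, lineno, "score", fields[4]) from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


_PSL_INT_FIELDS = (
    "matches",
    "misMatches",
    "repMatches",
    "nCount",
    "qNumInsert",
    "qBaseInsert",
    "tNumInsert",
    "tBaseInsert",
)


def _parse_int_list(text: str, path, lineno: int, fieldname: str) -> list[int]:
    items = [x for x in text.split(",") if x != ""]
    try:
        return [int(x) for x in items]
    except ValueError:
        raise _bed_error(path, lineno, fieldname, text) from None


def read_psl(path) -> list[PslAlignment]:
    """Read a 21-column PSL file; a psLayout header block is tolerated."""
    alignments: list[PslAlignment] = []
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if not in_body:
                # skip header lines until the first row starting with an int
                try:
                    int(fields[0])
                except ValueError:
                    continue
                in_body = True
            if len(fields) < 21:
                raise ValueError(
                    f"{path}, line {lineno}: expected 21 tab-separated PSL "
                    f"fields, got {len(fields)}"
                )
            ints = []
            for name, value in zip(_PSL_INT_FIELDS, fields[:8]):
                try:
                    ints.append(int(value))
                except ValueError:
                    raise _bed_error(path, lineno, name, value) from None
            strand = fields[8]
            q_name = fields[9]
            try:
                q_size, q_start, q_end = (int(x) for x in fields[10:13])
            except ValueError:
                raise _bed_error(path, lineno, "qSize/qStart/qEnd", "\t".join(fields[10:13])) from None
            t_name = fields[13]
            try:
                t_size, t_start, t_end = (int(x) for x in fields[14:17])
            except ValueError:
                raise _bed_error(path, lineno, "tSize/tStart/tEnd", "\t".join(fields[14:17])) from None
            try:
                block_count = int(fields[17])
            except ValueError:
                raise _bed_error(path, lineno, "blockCount", fields[17]) from None
            block_sizes = _parse_int_list(fields[18], path, lineno, "blockSizes")
            q_starts = _parse_int_list(fields[19], path, lineno, "qStarts")
            t_starts = _parse_int_list(fields[20], path, lineno, "tStarts")
            try:
                alignments.append(
                    PslAlignment(
                        *ints,
                        strand,
                        q_name,
                        q_size,
                        q_start,
                        q_end,
                        t_name,
                        t_size,
                        t_start,
                        t_end,
                        block_count,
                        block_sizes,
                        q_starts,
                        t_starts,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return alignments


def write_psl(alignments: Sequence[PslAlignment], path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            lists = (
                ",".join(str(x) for x in a.block_sizes) + ",",
                ",".join(str(x) for x in a.q_starts) + ",",
                ",".join(str(x) for x in a.t_starts) + ",",
            )
            row = (
                a.matches,
                a.mis_matches,
                a.rep_matches,
                a.n_count,
                a.q_num_insert,
                a.q_base_insert,
                a.t_num_insert,
                a.t_base_insert,
                a.strand,
                a.q_name,
                a.q_size,
                a.q_start,
                a.q_end,
                a.t_name,
                a.t_size,
                a.t_start,
                a.t_end,
                a.block_count,
                *lists,
            )
            fh.write("\t".join(str(x) for x in row) + "\n")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
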