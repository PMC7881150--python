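"""Genomic intervals and the overlap primitives the pipeline is built on.

All coordinates are 0-based half-open (BED convention). 1-based inputs are
not supported. Chromosome names are matched by exact string equality; no
"chr" aliasing is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "ReadRecord",
    "BedParseError",
    "read_bed",
    "write_bed",
    "find_overlaps",
    "subtract_blacklist",
    "tn5_shift",
]


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph records; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``.

    ``strand`` is '+', '-' or '.' (unstranded). Width must be positive.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def peak_id(self) -> str:
        """Canonical ``chrom:start-end`` identifier used in matrices."""
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies fully within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def ReadRecord(chrom: str, start: int, end: int, name: str | None = None,
               strand: str = "+") -> GenomicInterval:
    """An aligned read: a GenomicInterval whose strand is mandatory."""
    if strand not in ("+", "-"):
        raise ValueError("a read must be stranded ('+' or '-')")
    return GenomicInterval(chrom, start, end, name, strand)


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith("#") or s.startswith("track") or s.startswith("browser")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3–BED6 file into a list of intervals.

    Strand (column 6) is kept when present; track/browser/# lines are
    skipped; record order is preserved. Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; emits 6 columns when any record is stranded."""
    ivs = list(intervals)
    stranded = any(iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or stranded:
                cols.append(iv.name if iv.name is not None else ".")
            if stranded:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def find_overlaps(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs sharing >= 1 base.

    Half-open semantics: adjacent intervals ([0,10) vs [10,20)) do not
    overlap. Output is query-major, subject index ascending within a query.
    """
    by_chrom: dict[str, list[int]] = {}
    for j, iv in enumerate(subject):
        by_chrom.setdefault(iv.chrom, []).append(j)
    # sorted subject starts per chromosome for a binary-search sweep
    sweep: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for chrom, idx in by_chrom.items():
        idx.sort(key=lambda j: (subject[j].start, subject[j].end, j))
        starts = np.array([subject[j].start for j in idx])
        ends = np.array([subject[j].end for j in idx])
        # when subject runs are disjoint, ends are sorted too and the hits
        # form a contiguous range; otherwise fall back to a bounded scan
        disjoint = bool(np.all(ends[:-1] <= starts[1:])) if len(idx) > 1 else True
        sweep[chrom] = (starts, ends, idx, disjoint)

    pairs: list[tuple[int, int]] = []
    for i, q in enumerate(query):
        hit = sweep.get(q.chrom)
        if hit is None:
            continue
        starts, ends, idx, disjoint = hit
        hi = int(np.searchsorted(starts, q.end, side="left"))
        if disjoint:
            lo = int(np.searchsorted(ends, q.start, side="right"))
            pairs.extend((i, idx[pos]) for pos in range(lo, hi))
        else:
            for pos in range(hi):
                if ends[pos] > q.start:
                    pairs.append((i, idx[pos]))
    # within one query, emit subject indices in ascending original order
    out: list[tuple[int, int]] = []
    i0 = 0
    while i0 < len(pairs):
        i1 = i0
        while i1 < len(pairs) and pairs[i1][0] == pairs[i0][0]:
            i1 += 1
        out.extend(sorted(pairs[i0:i1], key=lambda p: p[1]))
        i0 = i1
    return out


def subtract_blacklist(
    peaks: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop every peak that overlaps any blacklist region by >= 1 bp.

    Peaks are removed whole, never truncated.
    """
    if not blacklist:
        return list(peaks)
    flagged = {i for i, _ in find_overlaps(peaks, blacklist)}
    return [p for i, p in enumerate(peaks) if i not in flagged]


def tn5_shift(read: GenomicInterval) -> GenomicInterval:
    """Correct read coordinates for the 9-bp Tn5 insertion footprint.

    Plus-strand reads shift +4 bp, minus-strand reads -5 bp; width is
    preserved. A shift below position 0 is clamped to 0 with a warning
    (the width then shrinks for those chromosome-start reads).
    """
    if read.strand == "+":
        return GenomicInterval(read.chrom, read.start + 4, read.end + 4,
                               read.name, read.strand)
    if read.strand == "-":
        start, end = read.start - 5, read.end - 5
        if start < 0:
            warnings.warn(
                f"tn5_shift clamped read {read.chrom}:{read.start}-{read.end} "
                "at chromosome start",
                stacklevel=2,
            )
            start = 0
            end = max(end, 1)
        return GenomicInterval(read.chrom, start, end, read.name, read.strand)
    raise ValueError("tn5_shift requires a stranded read")
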