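"""ATAC-seq sample quality control: FRiP and the TSS enrichment score.

FRiP (fraction of reads in peaks) counts a read once if it overlaps at
least one peak by one base. The TSS enrichment score aggregates reads in
a +/-2000 bp window around every annotated TSS (minus-strand TSS profiles
are reversed so upstream/downstream align), normalizes the profile by the
mean count over the two outermost 101-bp boundary segments
(offsets -2000..-1900 and +1900..+2000), smooths with a centered 51-bp
moving average (truncated at the window edges), and reports the maximum
smoothed value within +/-50 bp of the TSS. A well-enriched ATAC library
scores well above 1; the score is a ratio, so duplicating the read set
leaves it unchanged.

Reads enter the profile at their 5' cut-site position by default
(``anchor="cut"``); ``anchor="span"`` counts every covered base instead —
the field uses both conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, find_overlaps

__all__ = ["QcReport", "frip", "tss_enrichment", "tss_profile"]

WINDOW = 2000          # half-width of the TSS window
BOUNDARY = 1900        # |offset| >= BOUNDARY defines the boundary segments
SMOOTH = 51            # moving-average window (bp)
PEAK_SEARCH = 50       # max is taken within +/- this of the TSS


@dataclass
class QcReport:
    """Per-sample QC metrics."""

    sample_id: str
    tss_enrichment: float
    frip: float
    total_reads: int
    reads_in_peaks: int

    @staticmethod
    def write_table(reports: Sequence["QcReport"], path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in reports]).to_csv(
            path, sep="\t", index=False
        )


def frip(reads: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
         ) -> float:
    """Fraction of reads overlapping >= 1 peak by >= 1 bp."""
    if len(reads) == 0:
        raise ValueError("no reads")
    hit = {i for i, _ in find_overlaps(list(reads), list(peaks))}
    return len(hit) / len(reads)


def _read_positions(read: GenomicInterval, anchor: str) -> np.ndarray:
    if anchor == "cut":
        pos = read.start if read.strand != "-" else read.end - 1
        return np.array([pos])
    if anchor == "span":
        return np.arange(read.start, read.end)
    raise ValueError(f"unknown anchor {anchor!r}")


def tss_profile(
    reads: Sequence[GenomicInterval],
    tss_list: Sequence[GenomicInterval],
    anchor: str = "cut",
) -> np.ndarray:
    """Aggregate, strand-corrected read-count profile over offsets
    -WINDOW..+WINDOW (length 4001) around all TSSs."""
    if not tss_list:
        raise ValueError("no TSS provided")
    if not reads:
        raise ValueError("no reads")
    profile = np.zeros(2 * WINDOW + 1)
    by_chrom: dict[str, list[np.ndarray]] = {}
    for read in reads:
        by_chrom.setdefault(read.chrom, []).append(_read_positions(read, anchor))
    pos_by_chrom = {
        ch: np.sort(np.concatenate(parts)) for ch, parts in by_chrom.items()
    }
    for tss in tss_list:
        positions = pos_by_chrom.get(tss.chrom)
        if positions is None:
            continue
        center = tss.start
        lo = np.searchsorted(positions, center - WINDOW, side="left")
        hi = np.searchsorted(positions, center + WINDOW, side="right")
        offsets = positions[lo:hi] - center
        if tss.strand == "-":
            offsets = -offsets
        profile += np.bincount(offsets + WINDOW, minlength=2 * WINDOW + 1)
    return profile


def tss_enrichment(
    reads: Sequence[GenomicInterval],
    tss_list: Sequence[GenomicInterval],
    anchor: str = "cut",
) -> float:
    """Boundary-normalized, smoothed maximum of the aggregate TSS profile."""
    profile = tss_profile(reads, tss_list, anchor=anchor)
    offsets = np.arange(-WINDOW, WINDOW + 1)
    boundary = profile[np.abs(offsets) >= BOUNDARY]
    baseline = boundary.mean()
    if baseline == 0:
        raise ValueError("no reads at the TSS boundary; score undefined")
    enrich = profile / baseline
    # centered moving average, truncated at the edges
    kernel = np.ones(SMOOTH)
    sums = np.convolve(enrich, kernel, mode="same")
    counts = np.convolve(np.ones_like(enrich), kernel, mode="same")
    smoothed = sums / counts
    centre = np.abs(offsets) <= PEAK_SEARCH
    return float(smoothed[centre].max())


def qc_report(
    sample_id: str,
    reads: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    tss_list: Sequence[GenomicInterval],
    anchor: str = "cut",
) -> QcReport:
    """Convenience bundle of both metrics for one sample."""
    hit = {i for i, _ in find_overlaps(list(reads), list(peaks))}
    return QcReport(
        sample_id=sample_id,
        tss_enrichment=tss_enrichment(reads, tss_list, anchor=anchor),
        frip=len(hit) / len(reads) if reads else 0.0,
        total_reads=len(reads),
        reads_in_peaks=len(hit),
    )
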