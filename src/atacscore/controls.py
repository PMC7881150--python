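"""Universal control-peak discovery.

Control peaks are regions that are open in every reference CD8+ T-cell
subset, fall in annotated regulatory space (DNase-hypersensitive sites at
a TSS/5'-UTR), and show low cross-sample variability (CV < 0.3) and narrow
width (< 500 bp). The top-k of the survivors by mean raw area become the
normalization controls; k is typically 5, 20 or 50.

CV is computed on *raw* areas — control selection precedes depth
normalization, so sequencing-depth variation is part of the variability a
control must tolerate. The CV estimator uses the sample SD (n-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, find_overlaps, write_bed
from .tracks import AreaMatrix

__all__ = [
    "ControlSet",
    "consensus_peaks",
    "filter_by_annotation",
    "coefficient_of_variation",
    "select_controls",
]

DEFAULT_K_SET = (5, 20, 50)


@dataclass
class ControlSet:
    """Ordered control peaks with their selection metadata.

    Peaks are sorted descending by mean raw area; ``cv`` and ``mean_area``
    are parallel to ``peaks``.
    """

    peaks: list[GenomicInterval]
    cv: list[float]
    mean_area: list[float]

    @property
    def k(self) -> int:
        return len(self.peaks)

    def write(self, bed_path: str | Path, tsv_path: str | Path | None = None) -> None:
        write_bed(self.peaks, bed_path)
        if tsv_path is not None:
            pd.DataFrame(
                {
                    "peak": [p.peak_id for p in self.peaks],
                    "mean_area": self.mean_area,
                    "cv": self.cv,
                }
            ).to_csv(tsv_path, sep="\t", index=False)


def consensus_peaks(
    subset_peaksets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Peaks of the first set that overlap >= 1 peak in every other set.

    Coordinates are taken from the first set, mirroring consensus calling
    across reference cell subsets.
    """
    if not subset_peaksets:
        raise ValueError("need at least one peak set")
    base = list(subset_peaksets[0])
    keep = set(range(len(base)))
    for other in subset_peaksets[1:]:
        hit = {i for i, _ in find_overlaps(base, list(other))}
        keep &= hit
    return [p for i, p in enumerate(base) if i in keep]


def filter_by_annotation(
    peaks: Sequence[GenomicInterval],
    dh_peaks: Sequence[GenomicInterval],
    tss_utr_regions: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Keep peaks fully inside a DH site AND overlapping a TSS/5'-UTR.

    "Matched 100% with DH uniform peaks" is read as full containment of
    the candidate within a DH peak (the strictest reproducible reading);
    TSS/5'-UTR location as >= 1 bp overlap.
    """
    dh = list(dh_peaks)
    contained = set()
    for i, j in find_overlaps(list(peaks), dh):
        if dh[j].contains(peaks[i]):
            contained.add(i)
    on_tss = {i for i, _ in find_overlaps(list(peaks), list(tss_utr_regions))}
    return [p for i, p in enumerate(peaks) if i in contained and i in on_tss]


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD (n-1 denominator) divided by the mean.

    Undefined (error) when the mean is zero; scale-invariant.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def select_controls(
    matrix: AreaMatrix,
    k: int,
    cv_max: float = 0.3,
    width_max: int = 500,
) -> ControlSet:
    """Filter candidate peaks to stable, narrow ones and take the top k.

    Keeps peaks with CV < ``cv_max`` across samples and width <
    ``width_max`` (both strictly), ranks survivors by mean area descending
    (ties broken by genomic coordinate), and returns the top ``k``.
    Requires a raw (unnormalized) matrix.
    """
    if matrix.normalized:
        raise ValueError("control selection runs on raw areas")
    rows = []
    for peak in matrix.peaks:
        values = matrix.frame.loc[peak.peak_id].to_numpy(dtype=float)
        if peak.width >= width_max:
            continue
        cv = coefficient_of_variation(values) if values.mean() > 0 else np.inf
        if cv >= cv_max:
            continue
        rows.append((peak, cv, float(values.mean())))
    if len(rows) < k:
        raise ValueError(
            f"only {len(rows)} peaks pass the CV/width filters; need k={k}"
        )
    rows.sort(key=lambda r: (-r[2], r[0].chrom, r[0].start))
    top = rows[:k]
    return ControlSet(
        peaks=[r[0] for r in top],
        cv=[r[1] for r in top],
        mean_area=[r[2] for r in top],
    )
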