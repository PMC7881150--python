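"""Signal tracks (per-base coverage) and peak-area quantification.

Chromatin openness of a peak is measured as the area under the coverage
track inside the peak: A_q = sum over bases p in [start, end) of the height
d_pq at p. The formula's inclusive bound is realised over the half-open
interval [start, end) to stay consistent with BED coordinates — areas
therefore cover exactly ``width`` bases. Heights are real-valued (coverage
tracks may carry normalized read counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import BedParseError, GenomicInterval, _is_skippable

__all__ = [
    "SignalTrack",
    "read_bedgraph",
    "write_bedgraph",
    "peak_area",
    "average_height",
    "AreaMatrix",
    "build_area_matrix",
]


@dataclass
class SignalTrack:
    """Run-length per-base coverage for one sample.

    ``runs`` maps chromosome -> (starts, ends, heights) arrays; runs within
    a chromosome are sorted and non-overlapping, heights are >= 0, and any
    base not covered by a run has height 0.
    """

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        """Build a track from (chrom, start, end, height) tuples.

        Runs are sorted per chromosome; overlapping runs or negative
        heights are rejected.
        """
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, height in runs:
            if height < 0:
                raise ValueError(
                    f"negative height {height} at {chrom}:{start}-{end}"
                )
            if not (0 <= start < end):
                raise ValueError(f"invalid run {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(height)))
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rs in per_chrom.items():
            rs.sort()
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            heights = np.array([r[2] for r in rs], dtype=float)
            bad = np.nonzero(ends[:-1] > starts[1:])[0]
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"overlapping runs on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            out[chrom] = (starts, ends, heights)
        return cls(out)

    def scaled(self, c: float) -> "SignalTrack":
        """A copy with every height multiplied by ``c`` (c >= 0)."""
        if c < 0:
            raise ValueError("scale factor must be non-negative")
        return SignalTrack(
            {ch: (s.copy(), e.copy(), h * c) for ch, (s, e, h) in self.runs.items()}
        )

    def height_at(self, chrom: str, pos: int) -> float:
        """Height at a single base (0 where no run covers it)."""
        if chrom not in self.runs:
            return 0.0
        starts, ends, heights = self.runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(heights[i])
        return 0.0


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Parse a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping runs and negative values are rejected; comment/track lines
    are skipped.
    """
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: need 4 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: unparseable record") from exc
            if value < 0:
                raise BedParseError(f"{path}:{lineno}: negative value {value}")
            if not (0 <= start < end):
                raise BedParseError(f"{path}:{lineno}: invalid run coordinates")
            runs.append((chrom, start, end, value))
    try:
        return SignalTrack.from_runs(runs)
    except ValueError as exc:
        raise BedParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            starts, ends, heights = track.runs[chrom]
            for s, e, h in zip(starts, ends, heights):
                fh.write(f"{chrom}\t{s}\t{e}\t{h:g}\n")


def peak_area(track: SignalTrack, peak: GenomicInterval) -> float:
    """Sum of per-base heights over the peak range [start, end)."""
    if peak.chrom not in track.runs:
        return 0.0
    starts, ends, heights = track.runs[peak.chrom]
    lo = int(np.searchsorted(ends, peak.start, side="right"))
    hi = int(np.searchsorted(starts, peak.end, side="left"))
    if lo >= hi:
        return 0.0
    s = np.maximum(starts[lo:hi], peak.start)
    e = np.minimum(ends[lo:hi], peak.end)
    return float(np.sum((e - s) * heights[lo:hi]))


def average_height(track: SignalTrack, peak: GenomicInterval) -> float:
    """Mean per-base height over the peak: area divided by peak width."""
    return peak_area(track, peak) / peak.width


@dataclass
class AreaMatrix:
    """Peaks x samples table of peak areas.

    ``frame`` is indexed by canonical peak IDs (``chrom:start-end``) with
    one column per sample. ``normalized`` records whether depth
    normalization has been applied.
    """

    peaks: list[GenomicInterval]
    frame: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if list(self.frame.index) != ids:
            raise ValueError("frame index must equal the peak ID list")
        if (self.frame.to_numpy() < 0).any():
            raise ValueError("areas must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def peak_by_id(self, peak_id: str) -> GenomicInterval:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(peak_id)

    def subset_peaks(self, peak_ids: Sequence[str]) -> "AreaMatrix":
        keep = [p for p in self.peaks if p.peak_id in set(peak_ids)]
        return AreaMatrix(keep, self.frame.loc[[p.peak_id for p in keep]],
                          self.normalized)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("peak").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "AreaMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index.name = None
        peaks = []
        for pid in frame.index:
            chrom, span = pid.rsplit(":", 1)
            start, end = span.split("-")
            peaks.append(GenomicInterval(chrom, int(start), int(end)))
        return cls(peaks, frame, normalized)


def build_area_matrix(
    tracks: Mapping[str, SignalTrack],
    peaks: Sequence[GenomicInterval],
    samples: Sequence[str] | None = None,
) -> AreaMatrix:
    """Assemble the raw peaks x samples area matrix.

    ``tracks`` maps sample ID -> SignalTrack; column order follows
    ``samples`` when given (a sample without a track is an error naming
    it), otherwise the mapping's iteration order. Duplicate peak IDs are
    rejected.
    """
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValueError("peak IDs are not unique")
    if samples is None:
        samples = list(tracks)
    missing = [s for s in samples if s not in tracks]
    if missing:
        raise ValueError(f"no signal track for sample(s): {', '.join(missing)}")
    if not samples:
        raise ValueError("no sample tracks provided")
    data = {
        sample: [peak_area(tracks[sample], p) for p in peaks]
        for sample in samples
    }
    frame = pd.DataFrame(data, index=ids)
    return AreaMatrix(list(peaks), frame, normalized=False)
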