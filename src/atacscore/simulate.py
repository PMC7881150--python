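"""Synthetic ATAC-seq cohorts with planted responder signal.

The generator emits everything the analysis consumes: per-sample bedGraph
signal tracks, a candidate peak BED, three reference CD8+ T-cell-subset
peak sets (for consensus control discovery), DH/TSS annotations, a
blacklist, stranded reads for QC, a clinical sample sheet with censored
PFS, and a ground-truth JSON.

Generative model (single synthetic chromosome):

* Non-overlapping peaks are laid out in evenly spaced slots: control
  candidates, differential candidates, and a few blacklist decoys.
* Every peak q has a base per-base height G_q ~ Gamma(shape, scale).
  A sample's height at a null candidate is G_q times a lognormal noise
  multiplier (sigma 0.5, unit mean) — right-skewed, moderately dispersed
  openness, exchangeable between response groups.
* The planted differential peaks model consistently hyper-open chromatin
  in responders: responder heights are ``effect`` x G_q with low
  dispersion (lognormal sigma 0.1), non-responders stay null-like, and
  the base heights are drawn from the upper half of the height
  distribution. This is the structure the selection and ranking criteria
  assume of a genuine predictive peak.
* Control candidates carry tight multiplicative noise (normal, CV 0.05)
  so their cross-sample area CV stays below 0.3 even after the uniform
  0.8-1.2x per-sample depth factor that scales each whole track.
* PFS is exponential: mean 12 months for latently "openness-high"
  patients (all responders plus a 15% minority of non-responders, so the
  survival split is informative but imperfect), mean 3 months otherwise,
  censored administratively at 24 months.

The three reference subset peak sets are +/-20 bp jittered copies of the
control candidates; DH regions pad them by 50 bp, and each control
candidate carries a TSS at its midpoint, so annotation filtering is
non-trivial but complete by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, ReadRecord, write_bed
from .tracks import SignalTrack, write_bedgraph

__all__ = ["SimulationConfig", "TruthTable", "CohortBundle",
           "simulate_cohort", "simulate_validation", "load_bundle"]


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    # discovery cohort composition (RECIST)
    n_cr: int = 2
    n_pr: int = 8
    n_sd: int = 6
    n_pd: int = 16
    n_candidate_peaks: int = 500
    n_control_candidates: int = 60
    n_planted: int = 9
    n_decoys: int = 3               # candidates destroyed by the blacklist
    effect: float = 2.5             # responder multiplier at planted peaks
    depth_range: tuple[float, float] = (0.8, 1.2)
    control_noise_cv: float = 0.05
    peak_width_range: tuple[int, int] = (200, 480)
    base_height_shape: float = 1.5
    base_height_scale: float = 8.0
    null_noise_sigma: float = 0.5   # lognormal sigma, unit-mean noise
    planted_responder_sigma: float = 0.1
    pfs_mean_high: float = 12.0
    pfs_mean_low: float = 3.0
    censor_months: float = 24.0
    high_nonresponder_frac: float = 0.15
    n_reads: int = 20_000
    read_length: int = 75
    jitter_bp: int = 20

    def validate(self) -> None:
        if self.n_planted > self.n_candidate_peaks:
            raise ValueError("more planted peaks than candidates")
        if self.effect <= 0:
            raise ValueError("effect multiplier must be positive")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth range must be positive")
        if min(self.n_cr + self.n_pr, self.n_pd) < 2:
            raise ValueError("need >= 2 responders and >= 2 PD samples")
        total = (self.n_control_candidates + self.n_candidate_peaks
                 + self.n_decoys)
        slot = self.chrom_length // total
        if slot < self.peak_width_range[1] + 200:
            raise ValueError("chromosome too short for the requested peaks")


@dataclass
class TruthTable:
    """Ground truth shared between discovery and validation runs."""

    config: SimulationConfig
    candidate_peaks: list[GenomicInterval]
    control_peaks: list[GenomicInterval]
    decoy_peaks: list[GenomicInterval]
    planted_ids: list[str]
    base_heights: dict[str, float]          # candidate peak id -> G_q
    control_heights: dict[str, float]
    latent_high: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "candidate_peaks": [p.peak_id for p in self.candidate_peaks],
            "control_peaks": [p.peak_id for p in self.control_peaks],
            "decoy_peaks": [p.peak_id for p in self.decoy_peaks],
            "planted_ids": self.planted_ids,
            "base_heights": self.base_heights,
            "control_heights": self.control_heights,
            "latent_high": self.latent_high,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class CohortBundle:
    """Paths and in-memory handles for one simulated cohort."""

    out_dir: Path
    cohort_id: str
    truth: TruthTable
    tracks: dict[str, SignalTrack]
    reads: dict[str, list[GenomicInterval]]
    sample_sheet: "list[dict]"
    candidate_bed: Path
    blacklist_bed: Path
    refset_beds: list[Path]
    dh_bed: Path
    tss_region_bed: Path
    tss_site_bed: Path
    sheet_path: Path
    truth_path: Path

    @property
    def labels(self) -> dict[str, str]:
        return {r["sample_id"]: r["response"] for r in self.sample_sheet}


def _parse_peak_id(pid: str) -> GenomicInterval:
    chrom, span = pid.rsplit(":", 1)
    start, end = span.split("-")
    return GenomicInterval(chrom, int(start), int(end))


def _layout_peaks(config: SimulationConfig, rng: np.random.Generator
                  ) -> tuple[list, list, list]:
    """Place controls, candidates and decoys in disjoint slots."""
    total = (config.n_control_candidates + config.n_candidate_peaks
             + config.n_decoys)
    slot = config.chrom_length // total
    w_lo, w_hi = config.peak_width_range
    margin = config.jitter_bp + 60
    peaks = []
    for i in range(total):
        width = int(rng.integers(w_lo, w_hi + 1))
        lo = i * slot + margin
        hi = (i + 1) * slot - width - margin
        start = int(rng.integers(lo, hi))
        peaks.append(GenomicInterval(config.chrom, start, start + width))
    roles = np.array(
        ["control"] * config.n_control_candidates
        + ["candidate"] * config.n_candidate_peaks
        + ["decoy"] * config.n_decoys
    )
    rng.shuffle(roles)
    controls = [p for p, r in zip(peaks, roles) if r == "control"]
    candidates = [p for p, r in zip(peaks, roles) if r == "candidate"]
    decoys = [p for p, r in zip(peaks, roles) if r == "decoy"]
    return controls, candidates, decoys


def _draw_base_heights(config: SimulationConfig, rng: np.random.Generator,
                       truth_mean: float, n: int, upper_half: bool
                       ) -> np.ndarray:
    draws = rng.gamma(config.base_height_shape, config.base_height_scale,
                      size=4 * n if upper_half else n)
    if upper_half:
        draws = draws[draws >= truth_mean]
        while draws.size < n:
            extra = rng.gamma(config.base_height_shape,
                              config.base_height_scale, size=4 * n)
            draws = np.concatenate([draws, extra[extra >= truth_mean]])
        draws = draws[:n]
    return draws


def _lognormal_unit(rng: np.random.Generator, sigma: float, size: int
                    ) -> np.ndarray:
    """Lognormal multiplier with mean exactly 1."""
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def _peak_runs(peak: GenomicInterval, height: float) -> list:
    """Three-step profile over the peak whose mean height is ~``height``."""
    w = peak.width
    w1, w2 = w // 3, w // 3
    w3 = w - w1 - w2
    s = peak.start
    return [
        (peak.chrom, s, s + w1, height * 0.6),
        (peak.chrom, s + w1, s + w1 + w2, height * 1.4),
        (peak.chrom, s + w1 + w2, peak.end, height * 1.0),
    ]


def _sample_ids(cohort_id: str, config_sizes: Mapping[str, int]) -> list:
    rows = []
    i = 0
    for cat in ("CR", "PR", "SD", "PD"):
        for _ in range(config_sizes[cat]):
            i += 1
            rows.append((f"{cohort_id}S{i:02d}", cat))
    return rows


def _generate_cohort(
    config: SimulationConfig,
    truth: TruthTable,
    sizes: Mapping[str, int],
    cohort_id: str,
    rng: np.random.Generator,
) -> tuple[dict, dict, list]:
    """Tracks, reads and sample sheet for one cohort from shared truth."""
    samples = _sample_ids(cohort_id, sizes)
    planted = set(truth.planted_ids)
    tracks: dict[str, SignalTrack] = {}
    reads: dict[str, list] = {}
    sheet: list[dict] = []

    responders = {sid for sid, cat in samples if cat in ("CR", "PR")}
    nonresp = [sid for sid, cat in samples if cat in ("SD", "PD")]
    n_high_nr = int(round(config.high_nonresponder_frac * len(nonresp)))
    high_nr = set(
        rng.choice(nonresp, size=n_high_nr, replace=False)
    ) if n_high_nr else set()

    all_peaks = (truth.control_peaks + truth.candidate_peaks
                 + truth.decoy_peaks)
    tss_centers = [(p.chrom, (p.start + p.end) // 2)
                   for p in truth.control_peaks]

    for sid, cat in samples:
        depth = float(rng.uniform(*config.depth_range))
        runs: list = []
        is_resp = sid in responders
        # control candidates: tight noise, depth-scaled
        for p in truth.control_peaks:
            g = truth.control_heights[p.peak_id]
            noise = max(0.05, 1.0 + rng.normal(0.0, config.control_noise_cv))
            runs += _peak_runs(p, g * noise * depth)
        # differential candidates; an effect of exactly 1 disables planting
        # (null-simulation mode: planted peaks become indistinguishable)
        for p in truth.candidate_peaks:
            g = truth.base_heights[p.peak_id]
            if p.peak_id in planted and is_resp and config.effect != 1.0:
                h = (config.effect * g
                     * _lognormal_unit(rng, config.planted_responder_sigma, 1)[0])
            else:
                h = g * _lognormal_unit(rng, config.null_noise_sigma, 1)[0]
            runs += _peak_runs(p, h * depth)
        # decoys (blacklist fodder): null-like signal
        for p in truth.decoy_peaks:
            h = 5.0 * _lognormal_unit(rng, config.null_noise_sigma, 1)[0]
            runs += _peak_runs(p, h * depth)
        # sparse low background between peaks
        for p in truth.candidate_peaks[::25]:
            runs.append((config.chrom, p.end + 20, p.end + 120, 0.2 * depth))
        tracks[sid] = SignalTrack.from_runs(runs)

        # QC reads: half within random peaks (piling near control TSSs),
        # half uniform background
        n_peak_reads = config.n_reads // 2
        n_bg = config.n_reads - n_peak_reads
        rlist: list = []
        peak_idx = rng.integers(0, len(all_peaks), size=n_peak_reads)
        for k in peak_idx:
            p = all_peaks[int(k)]
            centre = (p.start + p.end) // 2
            offset = int(rng.integers(-p.width // 4, p.width // 4 + 1))
            start = max(0, centre + offset - config.read_length // 2)
            strand = "+" if rng.random() < 0.5 else "-"
            rlist.append(ReadRecord(config.chrom, start,
                                    start + config.read_length, None, strand))
        bg_starts = rng.integers(
            0, config.chrom_length - config.read_length, size=n_bg
        )
        bg_strands = rng.random(n_bg) < 0.5
        for start, plus in zip(bg_starts, bg_strands):
            rlist.append(ReadRecord(config.chrom, int(start),
                                    int(start) + config.read_length, None,
                                    "+" if plus else "-"))
        reads[sid] = rlist

        # survival
        high = is_resp or sid in high_nr
        truth.latent_high[sid] = bool(high)
        mean = config.pfs_mean_high if high else config.pfs_mean_low
        draw = float(rng.exponential(mean))
        pfs = min(draw, config.censor_months)
        event = draw <= config.censor_months
        sheet.append(
            {
                "sample_id": sid,
                "cohort": cohort_id,
                "response": cat,
                "pfs_months": round(pfs, 3),
                "event": int(event),
                "ebv": "pos" if rng.random() < 0.1 else "neg",
                "msi": "MSI-H" if rng.random() < 0.15 else "MSS",
            }
        )
    return tracks, reads, sheet


def _write_bundle(
    out_dir: Path,
    cohort_id: str,
    config: SimulationConfig,
    truth: TruthTable,
    tracks: Mapping[str, SignalTrack],
    reads: Mapping[str, Sequence[GenomicInterval]],
    sheet: Sequence[Mapping],
    refsets: Sequence[Sequence[GenomicInterval]],
) -> CohortBundle:
    out_dir = Path(out_dir)
    (out_dir / "samples").mkdir(parents=True, exist_ok=True)
    (out_dir / "reads").mkdir(parents=True, exist_ok=True)

    candidate_bed = out_dir / "candidate_peaks.bed"
    write_bed(truth.candidate_peaks + truth.decoy_peaks, candidate_bed)

    blacklist = [
        GenomicInterval(p.chrom, p.start + p.width // 2, p.end + 50)
        for p in truth.decoy_peaks
    ]
    blacklist_bed = out_dir / "blacklist.bed"
    write_bed(blacklist, blacklist_bed)

    refset_beds = []
    for i, rs in enumerate(refsets, start=1):
        path = out_dir / f"refset_{i}.bed"
        write_bed(rs, path)
        refset_beds.append(path)

    dh = [GenomicInterval(p.chrom, max(0, p.start - 50), p.end + 50)
          for p in truth.control_peaks]
    dh_bed = out_dir / "dh_peaks.bed"
    write_bed(dh, dh_bed)

    centers = [(p.start + p.end) // 2 for p in truth.control_peaks]
    tss_regions = [GenomicInterval(config.chrom, max(0, c - 100), c + 100)
                   for c in centers]
    tss_region_bed = out_dir / "tss_regions.bed"
    write_bed(tss_regions, tss_region_bed)

    rng_strand = np.random.default_rng(config.seed + 977)
    tss_sites = [
        GenomicInterval(config.chrom, c, c + 1, f"tss{i}",
                        "+" if rng_strand.random() < 0.5 else "-")
        for i, c in enumerate(centers)
    ]
    tss_site_bed = out_dir / "tss_sites.bed"
    write_bed(tss_sites, tss_site_bed)

    for sid, track in tracks.items():
        write_bedgraph(track, out_dir / "samples" / f"{sid}.bedgraph")
    for sid, rlist in reads.items():
        write_bed(rlist, out_dir / "reads" / f"{sid}.bed")

    sheet_path = out_dir / "sample_sheet.tsv"
    cols = ["sample_id", "cohort", "response", "pfs_months", "event",
            "ebv", "msi"]
    with open(sheet_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in sheet:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)

    return CohortBundle(
        out_dir=out_dir,
        cohort_id=cohort_id,
        truth=truth,
        tracks=dict(tracks),
        reads={k: list(v) for k, v in reads.items()},
        sample_sheet=list(sheet),
        candidate_bed=candidate_bed,
        blacklist_bed=blacklist_bed,
        refset_beds=refset_beds,
        dh_bed=dh_bed,
        tss_region_bed=tss_region_bed,
        tss_site_bed=tss_site_bed,
        sheet_path=sheet_path,
        truth_path=truth_path,
    )


def simulate_cohort(config: SimulationConfig, out_dir: str | Path,
                    cohort_id: str = "C1") -> CohortBundle:
    """Generate the discovery cohort bundle; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    controls, candidates, decoys = _layout_peaks(config, rng)
    gamma_mean = config.base_height_shape * config.base_height_scale
    null_heights = _draw_base_heights(config, rng, gamma_mean,
                                      len(candidates), upper_half=False)
    control_heights = _draw_base_heights(config, rng, gamma_mean,
                                         len(controls), upper_half=False)
    planted_idx = rng.choice(len(candidates), size=config.n_planted,
                             replace=False)
    planted_heights = _draw_base_heights(config, rng, gamma_mean,
                                         config.n_planted, upper_half=True)
    base = {p.peak_id: float(h) for p, h in zip(candidates, null_heights)}
    for k, h in zip(planted_idx, planted_heights):
        base[candidates[int(k)].peak_id] = float(h)
    planted_ids = [candidates[int(k)].peak_id for k in sorted(planted_idx)]

    truth = TruthTable(
        config=config,
        candidate_peaks=candidates,
        control_peaks=controls,
        decoy_peaks=decoys,
        planted_ids=planted_ids,
        base_heights=base,
        control_heights={p.peak_id: float(h)
                         for p, h in zip(controls, control_heights)},
    )

    refsets = []
    for _ in range(3):
        jit = rng.integers(-config.jitter_bp, config.jitter_bp + 1,
                           size=(len(controls), 2))
        refsets.append([
            GenomicInterval(p.chrom, max(0, p.start + int(a)), p.end + int(b))
            for p, (a, b) in zip(controls, jit)
        ])

    sizes = {"CR": config.n_cr, "PR": config.n_pr,
             "SD": config.n_sd, "PD": config.n_pd}
    tracks, reads, sheet = _generate_cohort(config, truth, sizes,
                                            cohort_id, rng)
    return _write_bundle(Path(out_dir), cohort_id, config, truth, tracks,
                         reads, sheet, refsets)


def simulate_validation(
    discovery: CohortBundle,
    out_dir: str | Path,
    seed: int,
    n_cr: int = 3,
    n_pr: int = 15,
    n_sd: int = 10,
    n_pd: int = 24,
    cohort_id: str = "C2",
) -> CohortBundle:
    """Fresh samples from the discovery run's generative truth.

    Planted peaks, base heights and the candidate list are shared (the
    candidate BED is byte-identical); only the samples are new.
    """
    if n_cr + n_pr + n_sd + n_pd <= 0:
        raise ValueError("validation cohort must contain samples")
    config = dataclasses.replace(discovery.truth.config, seed=seed)
    truth = TruthTable(
        config=config,
        candidate_peaks=discovery.truth.candidate_peaks,
        control_peaks=discovery.truth.control_peaks,
        decoy_peaks=discovery.truth.decoy_peaks,
        planted_ids=list(discovery.truth.planted_ids),
        base_heights=dict(discovery.truth.base_heights),
        control_heights=dict(discovery.truth.control_heights),
    )
    rng = np.random.default_rng(seed)
    sizes = {"CR": n_cr, "PR": n_pr, "SD": n_sd, "PD": n_pd}
    tracks, reads, sheet = _generate_cohort(config, truth, sizes,
                                            cohort_id, rng)
    # reference subsets belong to control discovery; reuse the originals
    refsets = [
        [iv for iv in _read_refset(path)] for path in discovery.refset_beds
    ]
    return _write_bundle(Path(out_dir), cohort_id, config, truth, tracks,
                         reads, sheet, refsets)


def _read_refset(path: Path) -> list[GenomicInterval]:
    from .intervals import read_bed

    return read_bed(path)


def load_bundle(out_dir: str | Path) -> CohortBundle:
    """Reconstruct a :class:`CohortBundle` from an on-disk directory."""
    from .intervals import read_bed
    from .tracks import read_bedgraph

    out_dir = Path(out_dir)
    payload = json.loads((out_dir / "truth.json").read_text())
    cfg = payload["config"]
    for key in ("depth_range", "peak_width_range"):
        cfg[key] = tuple(cfg[key])
    config = SimulationConfig(**cfg)
    truth = TruthTable(
        config=config,
        candidate_peaks=[_parse_peak_id(p) for p in payload["candidate_peaks"]],
        control_peaks=[_parse_peak_id(p) for p in payload["control_peaks"]],
        decoy_peaks=[_parse_peak_id(p) for p in payload["decoy_peaks"]],
        planted_ids=payload["planted_ids"],
        base_heights=payload["base_heights"],
        control_heights=payload["control_heights"],
        latent_high=payload.get("latent_high", {}),
    )
    sheet = []
    with open(out_dir / "sample_sheet.tsv") as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(cols, line.rstrip("\n").split("\t")))
            row["pfs_months"] = float(row["pfs_months"])
            row["event"] = int(row["event"])
            sheet.append(row)
    sample_ids = [r["sample_id"] for r in sheet]
    cohort_id = sheet[0]["cohort"] if sheet else "C1"
    tracks = {
        sid: read_bedgraph(out_dir / "samples" / f"{sid}.bedgraph")
        for sid in sample_ids
    }
    reads = {}
    for sid in sample_ids:
        path = out_dir / "reads" / f"{sid}.bed"
        if path.exists():
            reads[sid] = read_bed(path)
    return CohortBundle(
        out_dir=out_dir,
        cohort_id=cohort_id,
        truth=truth,
        tracks=tracks,
        reads=reads,
        sample_sheet=sheet,
        candidate_bed=out_dir / "candidate_peaks.bed",
        blacklist_bed=out_dir / "blacklist.bed",
        refset_beds=sorted(out_dir.glob("refset_*.bed")),
        dh_bed=out_dir / "dh_peaks.bed",
        tss_region_bed=out_dir / "tss_regions.bed",
        tss_site_bed=out_dir / "tss_sites.bed",
        sheet_path=out_dir / "sample_sheet.tsv",
        truth_path=out_dir / "truth.json",
    )
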