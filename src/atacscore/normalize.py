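"""Control-peak depth normalization.

Each sample's control signal level is summarised as h, the mean of the
average heights k_i = A_i / width_i over the m control peaks. A reference
cohort a defines S_a, the cohort mean of h. The normalization factor for
sample j of cohort b is

    F_ab = S_a / h_bj

and normalized areas are F_ab * A_q. Multiplying a sample's whole track by
a depth constant c scales h by c and F by 1/c, so normalized areas are
depth-invariant — the point of the construction. Within the reference
cohort F_aa,j * h_aj = S_a is an algebraic identity; to keep it an
identity at full precision the model stores each factor as an exact
rational (fractions.Fraction) of the float S_a and h, rounding to float
once when the factor multiplies an area.

Exactly two cohort roles are supported (discovery = reference, validation);
validation samples never contribute to S_a.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .controls import ControlSet
from .tracks import AreaMatrix, SignalTrack, average_height

__all__ = [
    "sample_mean_height",
    "cohort_reference",
    "normalization_factor",
    "normalize_areas",
    "NormalizationModel",
    "ControlNormalizer",
]


def sample_mean_height(track: SignalTrack, controls: ControlSet) -> float:
    """Mean of the control peaks' average heights for one sample."""
    if controls.k < 1:
        raise ValueError("need at least one control peak")
    return float(np.mean([average_height(track, p) for p in controls.peaks]))


def cohort_reference(h_values: Sequence[float]) -> float:
    """Cohort reference S_a: the arithmetic mean of per-sample h."""
    arr = np.asarray(h_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cohort")
    if (arr < 0).any():
        raise ValueError("h values must be non-negative")
    return float(arr.mean())


def normalization_factor(s_a: float, h_bj: float) -> float:
    """F_ab = S_a / h_bj for one target sample."""
    if h_bj <= 0:
        raise ValueError(
            "sample has no control signal (h = 0); it should fail QC upstream"
        )
    return s_a / h_bj


def normalize_areas(matrix: AreaMatrix, factors: Mapping[str, float]) -> AreaMatrix:
    """Multiply each sample's areas by its factor; flags the result."""
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    missing = [s for s in matrix.samples if s not in factors]
    if missing:
        raise ValueError(f"no factor for sample(s): {', '.join(missing)}")
    frame = matrix.frame.mul(
        [float(factors[s]) for s in matrix.samples], axis="columns"
    )
    return AreaMatrix(list(matrix.peaks), frame, normalized=True)


@dataclass
class NormalizationModel:
    """Fitted normalization state: controls, per-sample h, S_a, factors.

    ``factors`` holds exact rationals; use :func:`float` (done by
    normalize_areas) at application time.
    """

    control_ids: list[str]
    reference_cohort: str
    h: dict[str, float]
    s_ref: float
    factors: dict[str, Fraction] = field(default_factory=dict)

    def factor(self, sample: str) -> Fraction:
        return self.factors[sample]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "control_peaks": self.control_ids,
            "reference_cohort": self.reference_cohort,
            "h": self.h,
            "S_ref": self.s_ref,
            "factors": {
                s: [f.numerator, f.denominator] for s, f in self.factors.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            control_ids=payload["control_peaks"],
            reference_cohort=payload["reference_cohort"],
            h=payload["h"],
            s_ref=payload["S_ref"],
            factors={
                s: Fraction(n, d) for s, (n, d) in payload["factors"].items()
            },
        )


class ControlNormalizer(TransformerMixin, BaseEstimator):
    """Depth normalizer with a frozen reference cohort.

    ``fit`` learns per-sample control heights h and the reference S_a from
    the discovery cohort's tracks; ``transform`` normalizes an AreaMatrix,
    computing cross-cohort factors F_12 = S_1 / h for any sample not seen
    at fit time (its track must then be supplied). Validation samples
    never alter S_a.

    Parameters
    ----------
    controls:
        The :class:`~atacscore.controls.ControlSet` defining h.
    reference_cohort:
        Label stored with the model (e.g. ``"C1"``).
    """

    def __init__(self, controls: ControlSet | None = None,
                 reference_cohort: str = "C1") -> None:
        self.controls = controls
        self.reference_cohort = reference_cohort

    def fit(self, X: Mapping[str, SignalTrack], y: object = None
            ) -> "ControlNormalizer":
        """Learn h per reference sample and S_a from sample tracks."""
        if self.controls is None or self.controls.k < 1:
            raise ValueError("a non-empty ControlSet is required")
        if len(X) < 2:
            raise ValueError("a cohort needs at least two samples")
        h = {s: sample_mean_height(t, self.controls) for s, t in X.items()}
        for s, v in h.items():
            if v <= 0:
                raise ValueError(f"sample {s} has zero control signal")
        self.h_ = h
        self.s_ref_ = cohort_reference(list(h.values()))
        self.factors_ = {
            s: Fraction(self.s_ref_) / Fraction(v) for s, v in h.items()
        }
        return self

    def factors_for(
        self, tracks: Mapping[str, SignalTrack] | None = None
    ) -> dict[str, Fraction]:
        """Factors for fitted samples plus any new samples' tracks."""
        self._check_fitted()
        out = dict(self.factors_)
        if tracks:
            for s, t in tracks.items():
                if s in out:
                    continue
                h = sample_mean_height(t, self.controls)
                if h <= 0:
                    raise ValueError(f"sample {s} has zero control signal")
                out[s] = Fraction(self.s_ref_) / Fraction(h)
        return out

    def transform(
        self,
        X: AreaMatrix,
        tracks: Mapping[str, SignalTrack] | None = None,
    ) -> AreaMatrix:
        """Normalize an area matrix (raw -> normalized).

        Samples absent from the fit cohort get cross-cohort factors from
        ``tracks``; a sample with neither a fitted factor nor a track is
        an error.
        """
        self._check_fitted()
        factors = self.factors_for(tracks)
        unknown = [s for s in X.samples if s not in factors]
        if unknown:
            raise ValueError(
                f"no normalization factor for sample(s): {', '.join(unknown)}"
            )
        return normalize_areas(X, {s: float(factors[s]) for s in X.samples})

    @classmethod
    def from_model(cls, model: NormalizationModel) -> "ControlNormalizer":
        """Rebuild a fitted normalizer from persisted state.

        Control intervals are reconstructed from their canonical IDs; the
        frozen S_a keeps serving as the reference for new cohorts.
        """
        from .controls import ControlSet
        from .intervals import GenomicInterval

        peaks = []
        for pid in model.control_ids:
            chrom, span = pid.rsplit(":", 1)
            start, end = span.split("-")
            peaks.append(GenomicInterval(chrom, int(start), int(end)))
        controls = ControlSet(peaks=peaks, cv=[float("nan")] * len(peaks),
                              mean_area=[float("nan")] * len(peaks))
        est = cls(controls=controls, reference_cohort=model.reference_cohort)
        est.h_ = dict(model.h)
        est.s_ref_ = model.s_ref
        est.factors_ = dict(model.factors)
        return est

    def model_(self) -> NormalizationModel:
        """Export the fitted state as a serializable NormalizationModel."""
        self._check_fitted()
        return NormalizationModel(
            control_ids=[p.peak_id for p in self.controls.peaks],
            reference_cohort=self.reference_cohort,
            h=dict(self.h_),
            s_ref=self.s_ref_,
            factors=dict(self.factors_),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "s_ref_"):
            raise RuntimeError("ControlNormalizer is not fitted")
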