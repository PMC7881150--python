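"""Differential peak selection and representative-target ranking.

Responders (RECIST CR or PR) are compared against non-responders
(progressive disease only; stable disease is excluded from selection and
re-enters at evaluation). A peak is selected, per control set, when

  (i)  its mean normalized area over the selection samples exceeds the
       grand mean normalized area over all peaks and samples, and
  (ii) responder vs non-responder areas differ at p < alpha by a two-sided
       Mann-Whitney U test.

Peaks surviving under all three control-set normalizations (identity by
genomic coordinates) form the intersection, from which nine representative
targets are ranked by three criteria applied sequentially without
replacement: 3 with the highest responder mean, 3 with the lowest
responder variance, 3 with the largest relative distance (group difference
of max-scaled means). No multiple-testing correction is applied by
default; a Benjamini-Hochberg option exists but is off to match the
selection procedure this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .intervals import GenomicInterval
from .tracks import AreaMatrix

__all__ = [
    "RESPONDER_CATEGORIES",
    "SELECTION_NONRESPONDER_CATEGORIES",
    "mann_whitney_u",
    "relative_distance",
    "DifferentialResult",
    "DifferentialPeakSelector",
    "select_differential",
    "rank_representatives",
]

RESPONDER_CATEGORIES = frozenset({"CR", "PR"})
SELECTION_NONRESPONDER_CATEGORIES = frozenset({"PD"})


def mann_whitney_u(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group1, p).

    Uses the exact null distribution when both groups have <= 8
    observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def relative_distance(
    values: np.ndarray, resp_mask: np.ndarray, nonresp_mask: np.ndarray
) -> float:
    """Group difference of max-scaled means, in [-1, 1] for areas >= 0.

    Each sample's value at the peak is divided by the largest value among
    all samples at that peak; the relative distance is the responder mean
    minus the non-responder mean of these scaled values.
    """
    vmax = values.max()
    if vmax == 0:
        return 0.0
    scaled = values / vmax
    return float(scaled[resp_mask].mean() - scaled[nonresp_mask].mean())


@dataclass
class DifferentialResult:
    """Per-control-set selections, their intersection, and peak statistics."""

    per_set: dict[str, list[str]]
    intersection: list[str]
    stats: pd.DataFrame  # indexed by peak ID

    def to_tsv(self, path: str | Path) -> None:
        self.stats.rename_axis("peak").to_csv(path, sep="\t")


def _group_masks(
    samples: Sequence[str],
    labels: Mapping[str, str],
    responder: frozenset[str],
    nonresponder: frozenset[str],
) -> tuple[np.ndarray, np.ndarray]:
    resp = np.array([labels[s] in responder for s in samples])
    nonresp = np.array([labels[s] in nonresponder for s in samples])
    return resp, nonresp


class DifferentialPeakSelector(BaseEstimator):
    """Select differential peaks across several control-set normalizations.

    Parameters
    ----------
    alpha:
        Mann-Whitney significance level (two-sided), default 0.05.
    responder / nonresponder:
        RECIST categories defining the selection groups; defaults CR+PR
        vs PD. Samples in neither group are excluded from selection.
    require_mean_above_grand:
        Criterion (i); on by default.
    fdr:
        When set (e.g. 0.05), applies Benjamini-Hochberg per control set
        instead of the raw p < alpha rule. Default None (off).

    Attributes (after fit)
    ----------------------
    per_set_ : dict of control-set name -> selected peak IDs
    intersection_ : peak IDs selected under every control set
    stats_ : per-peak statistics from the first control set's matrix
    """

    def __init__(
        self,
        alpha: float = 0.05,
        responder: frozenset[str] = RESPONDER_CATEGORIES,
        nonresponder: frozenset[str] = SELECTION_NONRESPONDER_CATEGORIES,
        require_mean_above_grand: bool = True,
        fdr: float | None = None,
    ) -> None:
        self.alpha = alpha
        self.responder = responder
        self.nonresponder = nonresponder
        self.require_mean_above_grand = require_mean_above_grand
        self.fdr = fdr

    def fit(
        self,
        X: Mapping[str, AreaMatrix],
        y: Mapping[str, str],
    ) -> "DifferentialPeakSelector":
        """X: control-set name -> normalized AreaMatrix; y: sample -> RECIST."""
        if not X:
            raise ValueError("need at least one normalized matrix")
        ref_ids = None
        per_set: dict[str, list[str]] = {}
        stats_frames: dict[str, pd.DataFrame] = {}
        for name, matrix in X.items():
            if not matrix.normalized:
                raise ValueError(f"matrix for control set {name!r} is not normalized")
            ids = [p.peak_id for p in matrix.peaks]
            if ref_ids is None:
                ref_ids = ids
            elif set(ids) != set(ref_ids):
                raise ValueError("candidate peak lists differ between control sets")
            per_set[name], stats_frames[name] = self._select_one(matrix, y)
        inter = [
            pid for pid in ref_ids
            if all(pid in set(sel) for sel in per_set.values())
        ]
        self.per_set_ = per_set
        self.intersection_ = inter
        first = next(iter(stats_frames))
        stats = stats_frames[first].copy()
        for name, sel in per_set.items():
            stats[f"selected_{name}"] = stats.index.isin(set(sel))
        stats["in_intersection"] = stats.index.isin(set(inter))
        self.stats_ = stats
        return self

    def _select_one(
        self, matrix: AreaMatrix, labels: Mapping[str, str]
    ) -> tuple[list[str], pd.DataFrame]:
        samples = [s for s in matrix.samples
                   if labels.get(s) in self.responder | self.nonresponder]
        resp_mask, nonresp_mask = _group_masks(
            samples, labels, self.responder, self.nonresponder
        )
        if resp_mask.sum() < 2 or nonresp_mask.sum() < 2:
            raise ValueError("need >= 2 samples in each selection group")
        sub = matrix.frame[samples]
        grand_mean = float(sub.to_numpy().mean())
        rows = []
        selected = []
        for pid in sub.index:
            values = sub.loc[pid].to_numpy(dtype=float)
            rv, nv = values[resp_mask], values[nonresp_mask]
            if np.all(values == values[0]):
                u, p = float(len(rv) * len(nv)) / 2.0, 1.0
            else:
                u, p = mann_whitney_u(rv, nv)
            peak_mean = float(values.mean())
            rows.append(
                {
                    "peak": pid,
                    "mean_all": peak_mean,
                    "mean_responder": float(rv.mean()),
                    "mean_nonresponder": float(nv.mean()),
                    "var_responder": float(rv.var(ddof=1)),
                    "relative_distance": relative_distance(
                        values, resp_mask, nonresp_mask
                    ),
                    "U": u,
                    "p": p,
                }
            )
        frame = pd.DataFrame(rows).set_index("peak")
        if self.fdr is not None:
            reject = _benjamini_hochberg(frame["p"].to_numpy(), self.fdr)
            sig = pd.Series(reject, index=frame.index)
        else:
            sig = frame["p"] < self.alpha
        keep = sig
        if self.require_mean_above_grand:
            keep = keep & (frame["mean_all"] > grand_mean)
        selected = list(frame.index[keep])
        return selected, frame

    def result_(self) -> DifferentialResult:
        return DifferentialResult(
            per_set=dict(self.per_set_),
            intersection=list(self.intersection_),
            stats=self.stats_,
        )


def _benjamini_hochberg(p: np.ndarray, q: float) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    thresh = q * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        reject[order[: kmax + 1]] = True
    return reject


def select_differential(
    matrices: Mapping[str, AreaMatrix],
    labels: Mapping[str, str],
    alpha: float = 0.05,
    **kwargs,
) -> DifferentialResult:
    """Functional wrapper over :class:`DifferentialPeakSelector`."""
    sel = DifferentialPeakSelector(alpha=alpha, **kwargs).fit(matrices, labels)
    return sel.result_()


def rank_representatives(
    matrix: AreaMatrix,
    intersection: Sequence[str],
    labels: Mapping[str, str],
    n_per_criterion: int = 3,
    responder: frozenset[str] = RESPONDER_CATEGORIES,
    nonresponder: frozenset[str] = SELECTION_NONRESPONDER_CATEGORIES,
) -> list[str]:
    """Pick the representative targets from the intersection, in order.

    Sequentially, without replacement: ``n_per_criterion`` peaks with the
    highest responder mean; then the lowest responder variance; then the
    largest relative distance. Ties break by genomic coordinate. Requires
    at least ``3 * n_per_criterion`` intersection peaks.
    """
    need = 3 * n_per_criterion
    if len(intersection) < need:
        raise ValueError(
            f"only {len(intersection)} intersection peaks; need {need}"
        )
    samples = [s for s in matrix.samples
               if labels.get(s) in responder | nonresponder]
    resp_mask, nonresp_mask = _group_masks(samples, labels, responder, nonresponder)
    sub = matrix.frame[samples]
    coord = {p.peak_id: (p.chrom, p.start) for p in matrix.peaks}

    metrics = {}
    for pid in intersection:
        values = sub.loc[pid].to_numpy(dtype=float)
        rv = values[resp_mask]
        metrics[pid] = (
            float(rv.mean()),
            float(rv.var(ddof=1)),
            relative_distance(values, resp_mask, nonresp_mask),
        )

    chosen: list[str] = []
    remaining = list(intersection)

    def take(key) -> None:
        remaining.sort(key=key)
        for pid in remaining[:n_per_criterion]:
            chosen.append(pid)
        del remaining[:n_per_criterion]

    take(lambda pid: (-metrics[pid][0], coord[pid]))   # highest responder mean
    take(lambda pid: (metrics[pid][1], coord[pid]))    # lowest responder variance
    take(lambda pid: (-metrics[pid][2], coord[pid]))   # largest relative distance
    return chosen
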