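"""Per-target cutoffs, ROC metrics and the rank-weighted openness score.

Each of the nine target peaks gets a threshold chosen on the ROC curve by
the closest-to-corner rule: among candidate thresholds (midpoints between
adjacent sorted unique values, plus sentinels below the minimum and above
the maximum) pick the one minimizing

    sqrt((1 - sensitivity)^2 + (1 - specificity)^2),

the Euclidean distance from the ROC point to the perfect classifier at
(FPR 0, TPR 1). "Above threshold" is strict: a sample exactly at the
threshold predicts non-responder.

Targets are then ordered by descending accuracy and given integer rank
weights (panel size k down to 1; 9..1 for the default nine targets). A
sample's weighted openness score is the sum of weights over targets whose
normalized area exceeds the target threshold, spanning 0..k(k+1)/2
(0..45 for nine). A combined cutoff on the weighted score is fit with the
same corner rule.

Per-target thresholds are fit on the selection groups (R = CR+PR vs
NR = PD) and evaluated — accuracy, and hence rank — on the full grouping
(R vs PD+SD); both group choices are explicit parameters.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .tracks import AreaMatrix

__all__ = [
    "PANEL_SIZE",
    "EVALUATION_NONRESPONDER_CATEGORIES",
    "ClassificationMetrics",
    "roc_auroc",
    "find_cutoff",
    "classification_metrics",
    "weighted_score",
    "TargetPanel",
    "OpennessPanel",
]

PANEL_SIZE = 9
EVALUATION_NONRESPONDER_CATEGORIES = frozenset({"PD", "SD"})
_RESPONDER_CATEGORIES = frozenset({"CR", "PR"})


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or (~labels).all():
        raise ValueError("need both responders and non-responders")


def roc_auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve by pair counting (ties count 1/2).

    The fraction of (responder, non-responder) pairs where the responder
    scores higher, ties weighted 1/2 — equivalent to the trapezoidal area
    under the ROC curve.
    """
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    s = np.asarray(scores, dtype=float)
    r, n = s[y][:, None], s[~y][None, :]
    wins = int(np.sum(r > n))
    ties = int(np.sum(r == n))
    return (wins + 0.5 * ties) / (r.size * n.size)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mid = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mid, [uniq[-1] + 1.0]])


def classification_metrics(
    scores: Sequence[float], threshold: float, labels: Sequence[bool]
) -> ClassificationMetrics:
    """Confusion-table rates for 'predict responder iff score > threshold'."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = s > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / len(s)
    return ClassificationMetrics(sens, spec, acc, tp, fp, tn, fn)


def find_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Closest-to-corner threshold on the candidate grid.

    Ties in corner distance break by higher accuracy, then higher Youden
    index, then lower threshold. When all scores coincide the problem is
    degenerate; the threshold above the common value is returned with a
    warning (everything predicts non-responder).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    if np.unique(s).size == 1:
        warnings.warn("all scores identical; returning a threshold above them",
                      stacklevel=2)
        return float(s[0] + 1.0)
    best = None
    for t in _candidate_thresholds(s):
        m = classification_metrics(s, t, y)
        d = math.hypot(1.0 - m.sensitivity, 1.0 - m.specificity)
        key = (d, -m.accuracy, -m.youden, t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def weighted_score(
    bits: Sequence[int], weights: Sequence[int]
) -> int:
    """Sum of rank weights over above-threshold targets."""
    if len(bits) != len(weights):
        raise ValueError("binary vector and weights differ in length")
    return int(sum(int(b) * int(w) for b, w in zip(bits, weights)))


@dataclass
class TargetPanel:
    """Frozen panel state: targets in accuracy order with weights.

    ``targets`` rows are ordered descending by accuracy; ``weights`` runs
    k..1 down that order; ``combined_threshold`` applies to the weighted
    score.
    """

    target_ids: list[str]
    thresholds: list[float]
    sensitivities: list[float]
    specificities: list[float]
    accuracies: list[float]
    aurocs: list[float]
    weights: list[int]
    combined_threshold: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetPanel":
        return cls(**json.loads(Path(path).read_text()))


class OpennessPanel(ClassifierMixin, BaseEstimator):
    """Rank-weighted multi-peak openness classifier.

    ``fit`` takes a normalized AreaMatrix and per-sample RECIST labels:
    per-target thresholds are optimized on ``fit_nonresponder`` (default
    PD only), target accuracy/rank on ``eval_nonresponder`` (default
    PD+SD), and the combined weighted-score threshold on the evaluation
    grouping. ``decision_function`` returns weighted scores; ``predict``
    returns boolean responder calls at the frozen combined threshold — no
    refitting on new cohorts.
    """

    def __init__(
        self,
        targets: Sequence[str] | None = None,
        panel_size: int = PANEL_SIZE,
        responder: frozenset[str] = _RESPONDER_CATEGORIES,
        fit_nonresponder: frozenset[str] = frozenset({"PD"}),
        eval_nonresponder: frozenset[str] = EVALUATION_NONRESPONDER_CATEGORIES,
    ) -> None:
        self.targets = targets
        self.panel_size = panel_size
        self.responder = responder
        self.fit_nonresponder = fit_nonresponder
        self.eval_nonresponder = eval_nonresponder

    # -- fitting -----------------------------------------------------------

    def fit(self, X: AreaMatrix, y: Mapping[str, str]) -> "OpennessPanel":
        if self.targets is None or len(self.targets) != self.panel_size:
            raise ValueError(
                f"exactly {self.panel_size} target peaks are required"
            )
        missing = set(self.targets) - set(X.frame.index)
        if missing:
            raise ValueError(f"targets missing from matrix: {sorted(missing)}")

        fit_samples = [s for s in X.samples
                       if y.get(s) in self.responder | self.fit_nonresponder]
        eval_samples = [s for s in X.samples
                        if y.get(s) in self.responder | self.eval_nonresponder]
        fit_y = np.array([y[s] in self.responder for s in fit_samples])
        eval_y = np.array([y[s] in self.responder for s in eval_samples])
        _check_two_classes(fit_y)
        _check_two_classes(eval_y)

        coord = {p.peak_id: (p.chrom, p.start) for p in X.peaks}
        rows = []
        for pid in self.targets:
            fit_vals = X.frame.loc[pid, fit_samples].to_numpy(dtype=float)
            eval_vals = X.frame.loc[pid, eval_samples].to_numpy(dtype=float)
            thr = find_cutoff(fit_vals, fit_y)
            m = classification_metrics(eval_vals, thr, eval_y)
            rows.append(
                {
                    "target": pid,
                    "threshold": thr,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                    "auroc": roc_auroc(eval_vals, eval_y),
                }
            )
        frame = pd.DataFrame(rows)
        # rank: accuracy desc, then AUROC desc, then coordinate
        frame = frame.sort_values(
            by=["accuracy", "auroc", "target"],
            ascending=[False, False, True],
            key=lambda col: col.map(lambda t: coord[t]) if col.name == "target" else col,
        ).reset_index(drop=True)
        weights = list(range(self.panel_size, 0, -1))

        self.panel_ = TargetPanel(
            target_ids=list(frame["target"]),
            thresholds=[float(v) for v in frame["threshold"]],
            sensitivities=[float(v) for v in frame["sensitivity"]],
            specificities=[float(v) for v in frame["specificity"]],
            accuracies=[float(v) for v in frame["accuracy"]],
            aurocs=[float(v) for v in frame["auroc"]],
            weights=weights,
            combined_threshold=float("nan"),
        )
        scores = self.decision_function(X, samples=eval_samples)
        self.panel_.combined_threshold = find_cutoff(scores, eval_y)
        self.train_scores_ = pd.Series(scores, index=eval_samples)
        self.train_metrics_ = classification_metrics(
            scores, self.panel_.combined_threshold, eval_y
        )
        self.train_auroc_ = roc_auroc(scores, eval_y)
        return self

    @classmethod
    def from_panel(cls, panel: TargetPanel, **kwargs) -> "OpennessPanel":
        """Rebuild a frozen classifier from persisted panel state."""
        est = cls(targets=list(panel.target_ids),
                  panel_size=len(panel.target_ids), **kwargs)
        est.panel_ = panel
        return est

    # -- application -------------------------------------------------------

    def _binarize(self, X: AreaMatrix, samples: Sequence[str]) -> np.ndarray:
        panel = self.panel_
        missing = set(panel.target_ids) - set(X.frame.index)
        if missing:
            raise ValueError(
                f"matrix lacks panel target peak(s): {sorted(missing)}"
            )
        vals = X.frame.loc[panel.target_ids, samples].to_numpy(dtype=float)
        thr = np.asarray(panel.thresholds)[:, None]
        return (vals > thr).astype(int)

    def decision_function(
        self, X: AreaMatrix, samples: Sequence[str] | None = None
    ) -> np.ndarray:
        """Weighted openness score per sample (0..k(k+1)/2)."""
        if not hasattr(self, "panel_"):
            raise RuntimeError("panel is not fitted")
        if samples is None:
            samples = X.samples
        bits = self._binarize(X, samples)
        w = np.asarray(self.panel_.weights)
        return (bits * w[:, None]).sum(axis=0).astype(float)

    def predict(
        self, X: AreaMatrix, samples: Sequence[str] | None = None
    ) -> np.ndarray:
        """Boolean responder calls at the frozen combined threshold."""
        scores = self.decision_function(X, samples)
        return scores > self.panel_.combined_threshold

    def score_table(self, X: AreaMatrix) -> pd.DataFrame:
        """Per-sample weighted score and predicted class, as a table."""
        scores = self.decision_function(X)
        return pd.DataFrame(
            {
                "sample_id": X.samples,
                "weighted_score": scores.astype(int),
                "predicted_class": np.where(
                    scores > self.panel_.combined_threshold, "R", "NR"
                ),
            }
        )
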