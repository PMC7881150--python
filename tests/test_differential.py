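"""Mann-Whitney U, differential selection, and representative ranking."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from atacscore.differential import (DifferentialPeakSelector, mann_whitney_u,
                                    rank_representatives, relative_distance,
                                    select_differential)
from atacscore.intervals import GenomicInterval
from atacscore.tracks import AreaMatrix


def exact_mwu_p(group1, group2):
    """Two-sided p by exhaustive enumeration over all label splits."""
    pooled = list(group1) + list(group2)
    n1 = len(group1)
    mu = n1 * len(group2) / 2.0

    def u_stat(idx):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1.0 for a in g1 for b in g2 if a > b) + 0.5 * sum(
            1.0 for a in g1 for b in g2 if a == b
        )

    u_obs = u_stat(tuple(range(n1)))
    count = sum(
        1 for idx in combinations(range(len(pooled)), n1)
        if abs(u_stat(idx) - mu) >= abs(u_obs - mu) - 1e-12
    )
    from math import comb

    return count / comb(len(pooled), n1)


class TestMannWhitney:
    def test_identical_multisets_null(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration_for_n5(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(20)[:10].astype(float)  # distinct: no ties
        g1, g2 = vals[:5], vals[5:]
        _, p = mann_whitney_u(g1, g2)
        assert p == pytest.approx(exact_mwu_p(g1, g2), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestRelativeDistance:
    def test_extreme_separation_is_one(self):
        values = np.array([10.0, 10.0, 0.0, 0.0])
        r = np.array([True, True, False, False])
        assert relative_distance(values, r, ~r) == 1.0

    def test_bounded_and_zero_for_equal_means(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            values = rng.uniform(0, 100, size=10)
            r = np.zeros(10, bool)
            r[:5] = True
            d = relative_distance(values, r, ~r)
            assert -1.0 <= d <= 1.0
        same = np.array([3.0, 7.0, 3.0, 7.0])
        r = np.array([True, True, False, False])
        assert relative_distance(same, r, ~r) == 0.0


def _make_matrix(values, labels_order, peaks=None):
    n_peaks, n_samples = values.shape
    if peaks is None:
        peaks = [GenomicInterval("chr1", 1000 * i, 1000 * i + 300)
                 for i in range(n_peaks)]
    frame = pd.DataFrame(values, index=[p.peak_id for p in peaks],
                         columns=list(labels_order))
    return AreaMatrix(peaks, frame, normalized=True)


class TestSelectDifferential:
    def test_constant_peak_never_selected(self):
        labels = {"r1": "CR", "r2": "PR", "n1": "PD", "n2": "PD"}
        values = np.array([[5.0, 5.0, 5.0, 5.0],
                           [9.0, 8.0, 1.0, 2.0]])
        m = _make_matrix(values, labels)
        res = select_differential({"k20": m}, labels, alpha=0.9)
        assert m.peaks[0].peak_id not in res.per_set["k20"]

    def test_planted_peaks_recovered_in_intersection(self, discovery_bundle,
                                                     discovery_result):
        inter = set(discovery_result["differential"].intersection)
        for pid in discovery_bundle.truth.planted_ids:
            assert pid in inter

    def test_intersection_within_every_per_set_list(self, discovery_result):
        res = discovery_result["differential"]
        for sel in res.per_set.values():
            assert set(res.intersection) <= set(sel)

    def test_sd_samples_are_excluded_from_selection(self):
        # SD columns carry wild values; selection must ignore them
        labels = {"r1": "CR", "r2": "PR", "r3": "PR",
                  "n1": "PD", "n2": "PD", "n3": "PD", "x1": "SD"}
        rng = np.random.default_rng(1)
        base = rng.uniform(10, 20, size=(6, 7))
        base[0, :3] = 100.0   # peak 0 separates R from PD
        m1 = _make_matrix(base, labels)
        with_sd = base.copy()
        with_sd[:, 6] = 1e6
        m2 = _make_matrix(with_sd, labels)
        r1 = select_differential({"a": m1}, labels)
        r2 = select_differential({"a": m2}, labels)
        assert r1.per_set["a"] == r2.per_set["a"]

    def test_too_small_group_rejected(self):
        labels = {"r1": "CR", "n1": "PD", "n2": "PD"}
        m = _make_matrix(np.ones((2, 3)), labels)
        with pytest.raises(ValueError, match=">= 2"):
            select_differential({"a": m}, labels)


class TestRankRepresentatives:
    def test_nine_peak_intersection_saturates(self):
        labels = {f"r{i}": "PR" for i in range(3)} | {f"n{i}": "PD" for i in range(3)}
        rng = np.random.default_rng(2)
        values = rng.uniform(1, 50, size=(9, 6))
        m = _make_matrix(values, labels)
        ids = [p.peak_id for p in m.peaks]
        out = rank_representatives(m, ids, labels)
        assert sorted(out) == sorted(ids) and len(out) == 9

    def test_fewer_than_nine_rejected_with_count(self):
        labels = {"r1": "PR", "r2": "PR", "n1": "PD", "n2": "PD"}
        m = _make_matrix(np.ones((4, 4)), labels)
        with pytest.raises(ValueError, match="4"):
            rank_representatives(m, [p.peak_id for p in m.peaks], labels)

    def test_matches_sequential_criteria_oracle(self):
        labels = ({f"r{i}": "PR" for i in range(6)}
                  | {f"n{i}": "PD" for i in range(6)})
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 100, size=(20, 12))
        m = _make_matrix(values, labels)
        ids = [p.peak_id for p in m.peaks]
        out = rank_representatives(m, ids, labels)

        # independent oracle: recompute the three criteria exhaustively
        resp = np.arange(6)
        nonresp = np.arange(6, 12)
        stats = {}
        for i, pid in enumerate(ids):
            v = values[i]
            scaled = v / v.max()
            stats[pid] = (
                v[resp].mean(),
                v[resp].var(ddof=1),
                scaled[resp].mean() - scaled[nonresp].mean(),
            )
        pool = list(ids)
        pick_mean = sorted(pool, key=lambda p: -stats[p][0])[:3]
        pool = [p for p in pool if p not in pick_mean]
        pick_var = sorted(pool, key=lambda p: stats[p][1])[:3]
        pool = [p for p in pool if p not in pick_var]
        pick_dist = sorted(pool, key=lambda p: -stats[p][2])[:3]
        assert out == pick_mean + pick_var + pick_dist

    def test_no_peak_chosen_twice(self, discovery_result):
        targets = discovery_result["targets"]
        assert len(targets) == len(set(targets)) == 9
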