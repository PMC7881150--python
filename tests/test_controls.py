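"""Control-peak discovery: consensus, annotation filtering, CV, top-k."""

import math

import numpy as np
import pandas as pd
import pytest

from atacscore.controls import (coefficient_of_variation, consensus_peaks,
                                filter_by_annotation, select_controls)
from atacscore.intervals import GenomicInterval
from atacscore.tracks import AreaMatrix


def _intervals(rng, n, span=5000, wmax=100):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        out.append(GenomicInterval("chr1", s, s + int(rng.integers(1, wmax))))
    return out


class TestConsensus:
    def test_identical_sets_return_first(self):
        s = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 50, 80)]
        assert consensus_peaks([s, list(s), list(s)]) == s

    def test_disjoint_sets_empty(self):
        a = [GenomicInterval("chr1", 0, 10)]
        b = [GenomicInterval("chr1", 100, 110)]
        assert consensus_peaks([a, b]) == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks([])

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        sets = [_intervals(rng, 60) for _ in range(3)]
        expected = [
            p for p in sets[0]
            if all(any(p.overlaps(q) for q in other) for other in sets[1:])
        ]
        assert consensus_peaks(sets) == expected


class TestAnnotationFilter:
    dh = [GenomicInterval("chr1", 100, 400)]
    tss = [GenomicInterval("chr1", 150, 160)]

    def test_contained_and_on_tss_kept(self):
        peak = GenomicInterval("chr1", 120, 300)
        assert filter_by_annotation([peak], self.dh, self.tss) == [peak]

    def test_partial_dh_overlap_dropped(self):
        peak = GenomicInterval("chr1", 50, 300)  # sticks out of the DH peak
        assert filter_by_annotation([peak], self.dh, self.tss) == []

    def test_contained_but_off_tss_dropped(self):
        peak = GenomicInterval("chr1", 200, 300)
        assert filter_by_annotation([peak], self.dh, self.tss) == []

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        peaks = _intervals(rng, 80)
        dh = _intervals(rng, 25, wmax=300)
        tss = _intervals(rng, 25, wmax=30)
        expected = [
            p for p in peaks
            if any(d.contains(p) for d in dh) and any(p.overlaps(t) for t in tss)
        ]
        assert filter_by_annotation(peaks, dh, tss) == expected


class TestCV:
    def test_constant_values_zero(self):
        assert coefficient_of_variation([1, 1, 1]) == 0.0

    def test_two_point_value(self):
        assert coefficient_of_variation([2, 4]) == pytest.approx(
            math.sqrt(2) / 3, rel=1e-12
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 10, size=12)
        cv = coefficient_of_variation(vals)
        assert coefficient_of_variation(7.3 * vals) == pytest.approx(cv, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([0.0, 0.0])


def _matrix_from_areas(peaks, areas):
    frame = pd.DataFrame(
        areas, index=[p.peak_id for p in peaks],
        columns=[f"s{i}" for i in range(areas.shape[1])],
    )
    return AreaMatrix(peaks, frame)


class TestSelectControls:
    def _planted_matrix(self, seed=0, n_peaks=300, n_low_cv=30, n_samples=8):
        """Matrix where a known subset has near-constant areas."""
        rng = np.random.default_rng(seed)
        peaks = [
            GenomicInterval("chr1", 1000 * i, 1000 * i + int(rng.integers(200, 499)))
            for i in range(n_peaks)
        ]
        areas = rng.uniform(10, 5000, size=(n_peaks, 1)) * rng.uniform(
            0.3, 1.7, size=(n_peaks, n_samples)
        )
        low = rng.choice(n_peaks, size=n_low_cv, replace=False)
        base = rng.uniform(100, 9000, size=n_low_cv)
        areas[low] = base[:, None] * (1 + rng.normal(0, 0.02, size=(n_low_cv, n_samples)))
        return peaks, np.abs(areas), set(low)

    def test_zero_cv_narrow_peak_retained(self):
        peaks = [GenomicInterval("chr1", 0, 300), GenomicInterval("chr1", 500, 900)]
        areas = np.array([[5.0, 5.0, 5.0], [1.0, 9.0, 2.0]])
        cs = select_controls(_matrix_from_areas(peaks, areas), k=1)
        assert cs.peaks == [peaks[0]]
        assert cs.cv[0] == 0.0

    def test_width_500_excluded_strictly(self):
        peaks = [GenomicInterval("chr1", 0, 500)]
        areas = np.array([[5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="0 peaks"):
            select_controls(_matrix_from_areas(peaks, areas), k=1)

    def test_top_k_matches_sort_oracle(self):
        peaks, areas, low = self._planted_matrix()
        m = _matrix_from_areas(peaks, areas)
        cs = select_controls(m, k=20)
        # oracle: filter then sort by mean desc, coordinate tie-break
        survivors = []
        for i, p in enumerate(peaks):
            vals = areas[i]
            cv = vals.std(ddof=1) / vals.mean()
            if cv < 0.3 and p.width < 500:
                survivors.append((p, vals.mean()))
        survivors.sort(key=lambda r: (-r[1], r[0].chrom, r[0].start))
        assert cs.peaks == [p for p, _ in survivors[:20]]
        assert all(c < 0.3 for c in cs.cv)

    def test_control_sets_are_nested(self):
        peaks, areas, _ = self._planted_matrix(seed=5)
        m = _matrix_from_areas(peaks, areas)
        top = {k: select_controls(m, k=k).peaks for k in (5, 20, 50)}
        assert set(p.peak_id for p in top[5]) <= set(p.peak_id for p in top[20])
        assert set(p.peak_id for p in top[20]) <= set(p.peak_id for p in top[50])

    def test_invariant_to_sample_order_and_global_scaling(self):
        peaks, areas, _ = self._planted_matrix(seed=7)
        m = _matrix_from_areas(peaks, areas)
        cs = select_controls(m, k=10)
        shuffled = _matrix_from_areas(peaks, areas[:, ::-1])
        assert select_controls(shuffled, k=10).peaks == cs.peaks
        scaled = _matrix_from_areas(peaks, areas * 4.0)
        assert select_controls(scaled, k=10).peaks == cs.peaks

    def test_normalized_matrix_rejected(self):
        peaks = [GenomicInterval("chr1", 0, 300)]
        m = _matrix_from_areas(peaks, np.array([[1.0, 1.0]]))
        m.normalized = True
        with pytest.raises(ValueError, match="raw"):
            select_controls(m, k=1)
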