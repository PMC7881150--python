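# Methods

## Coordinate and quantification conventions

All coordinates are 0-based half-open (BED/bedGraph convention);
1-based inputs are not supported, and chromosome names match by exact
string equality. The peak-area formula is written with an inclusive
upper bound; it is realized over the half-open interval [start, end), so
an area covers exactly `width` bases. The alternative (including the end
base) would differ by one base per peak; the half-open choice keeps
areas, widths and average heights mutually consistent with BED
coordinates. Areas are real-valued, since coverage tracks may carry
normalized read counts. Blacklist exclusion removes an overlapping peak
whole — never truncates it. The Tn5 correction shifts plus-strand reads
+4 bp and minus-strand reads −5 bp; a shift past the chromosome start is
clamped to 0 with a warning (the source procedure does not address
chromosome-start reads).

## Normalization model

Per sample, h is the mean over the m control peaks of the average height
kᵢ = Aᵢ/widthᵢ. The declared reference cohort (discovery) fixes
S_a = mean(h); every sample — fitted or new — gets F = S_a / h. Validation
samples never contribute to S_a: factors for new samples are the
cross-cohort F₁₂ computed against the frozen reference. Exactly two
cohort roles are supported. h = 0 is an error, not an infinite factor: a
sample with no control signal should fail QC, not silently dominate.

Numerical choice: factors are stored as exact rationals
(`fractions.Fraction` of the float S_a and h). In IEEE doubles,
`(S/h)*h == S` fails for roughly 10% of value pairs; with rational
factors the defining identity F·h = S_a holds exactly by construction,
and the factor is rounded to a float only once, when it multiplies an
area. Depth invariance (scaling a sample's track by c leaves its
normalized areas unchanged) then holds to ~1e-15 relative, bounded in
tests at 1e-9.

CV for control selection uses the sample SD (n−1) — the conventional
estimator at cohort sizes of a few dozen — and is computed on **raw**
areas: control discovery precedes normalization, so sequencing-depth
variation is part of the variability a control must tolerate. The
filters are strict inequalities as printed (CV < 0.3, width < 500 bp).
"Matched 100%" with a DNase-hypersensitive peak is read as full
containment of the candidate within the DH peak (the strictest
reproducible reading); TSS/5′-UTR location as ≥ 1 bp overlap. Mean-area
ranking ties break by genomic coordinate for determinism.

## Differential selection

Selection groups are responders R = {CR, PR} vs non-responders
NR = {PD}; SD samples are excluded from selection and re-enter at
evaluation. Criterion (i) — per-peak mean normalized area above the
grand mean over all peaks — is computed over the samples that enter
selection, keeping both criteria on the same population (the alternative
"all cohort samples" reading is one flag away). Criterion (ii) is the
two-sided Mann–Whitney U test at α = 0.05: exact null distribution when
both groups have ≤ 8 observations and no ties, otherwise the normal
approximation with tie and continuity corrections (scipy). No
multiple-testing correction is applied by default, matching the
procedure this mirrors; a Benjamini–Hochberg option exists (`fdr=`) but
is off.

Peak identity across the three control-set normalizations is the genomic
interval; the candidate list is fixed before normalization, so the
three-set intersection is well defined. The nine representatives are
chosen 3+3+3 **sequentially without replacement** (highest responder
mean, lowest responder variance, largest relative distance) — the
without-replacement reading guarantees nine distinct targets. The
variance criterion operates on normalized areas (not max-scaled values);
relative distance divides each sample's value by the per-peak maximum
before differencing group means, so it lies in [−1, 1] for non-negative
areas.

## Cutoffs, panel and score

"Minimize the Euclidean distance" is implemented as the
closest-to-corner rule: candidate thresholds are midpoints between
adjacent sorted unique scores plus sentinels below the minimum and above
the maximum; the winner minimizes √((1−sens)² + (1−spec)²). Ties break
by higher accuracy, then higher Youden index, then lower threshold.
"Above threshold" is strict, so a sample exactly at the threshold
predicts non-responder. When all scores coincide the cutoff is
degenerate: the threshold above the common value is returned with a
warning (everything predicts non-responder).

Per-target thresholds are fit on the selection grouping (R vs PD);
accuracy — and hence the 9…1 rank weights — and the combined
weighted-score cutoff are computed on the evaluation grouping
(R vs PD+SD), the grouping on which the combined score is reported.
Accuracy ties rank by higher AUROC, then genomic coordinate. The panel
size (9) is a named constant; the score bound generalizes to k(k+1)/2.
AUROC is computed by direct pair counting with ties weighted 1/2
(identical to the trapezoidal ROC area); sklearn's implementation serves
as an independent cross-check in the tests. Applying a panel to a new
cohort uses the frozen thresholds, weights and combined cutoff — never
refits.

## Survival

Kaplan–Meier product-limit estimation and the two-group log-rank test
are delegated to lifelines; tests carry independent hand-tabulated
oracles. The median is the first event time with S(t) ≤ 0.5, "not
reached" (∞) when the curve never gets there. Event/censor ties at the
same time process events first. PFS is in months.

## QC metrics

FRiP counts a read once if it overlaps ≥ 1 peak by ≥ 1 bp. The TSS
enrichment score aggregates a ±2000 bp profile over all TSSs, reversing
the per-TSS profile for minus-strand TSSs ("strand correction"),
normalizes by the mean count over both outermost 101-bp boundary
segments (offsets ±1900–2000, the two flanks averaged together), smooths
with a centered 51-bp moving average truncated at the window edges, and
takes the maximum within ±50 bp of the TSS. Reads enter the profile at
their 5′ cut site by default; `anchor="span"` counts every covered base
instead, since the field uses both conventions. A zero boundary mean is
an error (undefined ratio), not a zero score.

## Synthetic cohorts: what they model, and what they do not

The generator lays out non-overlapping control candidates (60),
differential candidates (500) and a few blacklist decoys on a 10-Mb
synthetic chromosome. Peak base heights are Gamma(1.5, 8) — non-negative
and right-skewed, like real coverage. Null candidate heights multiply
the base by unit-mean lognormal noise (σ = 0.5), exchangeable between
response groups. Planted peaks model consistently hyper-open chromatin
in responders: responder heights are 2.5× the base with low dispersion
(lognormal σ = 0.1), non-responders stay null-like, and planted bases
are drawn from the upper half of the height distribution. This encodes
the structure the selection and 3+3+3 ranking assume of a genuinely
predictive peak — high openness, consistently elevated in responders —
and makes the generator's own contract hold (every planted peak
significant at the default configuration). An effect multiplier of
exactly 1.0 disables planting entirely, giving the fully exchangeable
null used for calibration checks. Control candidates carry tight normal
noise (CV 0.05), so their raw-area CV stays below 0.3 even after the
uniform 0.8–1.2× per-sample depth factor that scales each whole track.

Default cohort compositions are 2 CR + 8 PR + 6 SD + 16 PD (discovery,
n = 32) and 3 CR + 15 PR + 10 SD + 24 PD (validation, n = 52). PFS is
exponential with mean 12 months for latently openness-high patients (all
responders plus a 15% minority of non-responders — the survival split is
informative but deliberately imperfect) and 3 months otherwise, censored
at 24 months. The three reference subset peak sets are ±20 bp jittered
copies of the control candidates; DH annotations pad them by 50 bp and
each carries a TSS at its midpoint, so consensus and annotation
filtering are non-trivial but complete by construction.

What the generator does **not** model: fragment-level Tn5 sequence bias,
mono-/di-nucleosome fragment periodicity, correlated peaks
(co-regulation), batch effects beyond a scalar depth factor, real human
genome coordinates, or label noise in RECIST calls. Passing the planted
recovery tests therefore shows the pipeline's machinery is correct and
depth-proof under its own assumptions — not that the nine-target panel
would reach any particular accuracy on real patient cohorts.

## Problem sizes and runtime

The test suite and the acceptance script run the full pipeline on the
default 32 + 52-sample cohorts with 500 candidate peaks and 20,000 reads
per sample for QC; a complete discovery + validation + null-calibration
pass takes well under a minute on one CPU. These sizes were chosen so
the end-to-end statistical behaviour (selection power, null calibration
within 3 SE of α over 500 peaks) is measurable while the whole analysis
stays desk-scale.

## Known limitations

* Exactly two cohort roles (reference/validation); more cohorts are
  rejected rather than generalized.
* The per-target cutoff grid is midpoint-based; on heavily tied data the
  combined score's discrete 0–45 range can make several thresholds
  equivalent (resolved deterministically by the tie-break chain).
* Median PFS is undefined ("not reached") when the KM curve stays above
  0.5; downstream JSON reports `null` for that group.
* The consensus operation keeps coordinates from the first peak set;
  merging or re-centering consensus peaks is out of scope.
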