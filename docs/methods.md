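# Methods

## The sliding-window-area detector

A T-wave boundary separates the wave from a (locally) isoelectric segment.
The SWA statistic exploits this: at candidate sample `t`, subtract the local
average amplitude `s̄_t` (mean over `[t−p, t+p]`, `p = 0.016 s`) and sum the
residual over a fixed window — forward `[t, t+w]` with `w = 0.12 s` for the
onset, backward `[t−w, t]` with `w = 0.128 s` for the offset. When `t` sits
on the isoelectric side of the boundary, the baseline estimate is clean and
the window captures the wave's mass; the area is maximal at the boundary.
The implementation evaluates all candidates with cumulative sums (O(n) per
record and window direction); a direct double-loop summation serves as the
test oracle, with agreement required to 1e−9 relative tolerance.

Three numerical choices deserve note:

* **Absolute vs signed area.** `|area|` is the default, making inverted and
  biphasic waves detectable without polarity logic. The flip side: `|area|`
  is largest not at the boundary but at the *wave peak*, where the
  `(w+1)·s̄_t` baseline term dominates (for a Gaussian wave of width σ and
  amplitude A, the peak-anchored area is ≈ `(w+1)·A` against `≈ 1.25·σ·A`
  at the boundary, so the peak wins whenever `σ ≲ 0.1 s` — i.e. for every
  physiologic T wave). **The search window must therefore exclude the peak
  region**; quantitatively, its inner edge must stay ≳ 0.5 σ away from the
  wave center. This is not a defect but the actual mechanism by which the
  RR-dependent boundaries carry information: they position the candidate
  range between the QRS end and the T peak (onset), or between the T peak
  and the next P wave (offset). A signed-area variant remains available
  (`use_abs_area: false`); it needs no peak exclusion for upright waves but
  fails on inverted ones.
* **Tie-breaking.** On an exactly linear wave flank the discrete area
  profile is constant (the window sum's increment cancels the baseline term
  exactly), so ties are real, and floating-point noise must not break them.
  Ties within a 1e−9 relative band resolve to the earliest candidate for the
  forward direction and the latest for the backward direction — the exact
  mirror that the time-reversal symmetry `Ae(t; s) = Ao(N−1−t; reverse(s))`
  implies. On such a flank the winning candidate is the first whose
  smoothing window clears the corner, i.e. within `p` samples of it; on
  smooth (Gaussian) waves the maximum is strict and lands within 2 samples
  of the 2 %-of-peak boundary.
* **Candidate clipping.** Candidates are restricted so the full sliding
  window fits inside the record; a window with fewer than 3 usable
  candidates yields a missing detection with a recorded skip reason.

## Search boundaries

Traditional windows are two-branch piecewise-linear functions of the
current RR interval (branch split at 0.88 s) with fixed coefficients. As
printed, the onset pair evaluates with its "left" bound to the right of its
"right" bound for every RR, so both expressions are evaluated and
order-normalized to `[min, max]`.

Improved windows have three branches (default breakpoints 0.76/1.13 s for
onsets, 0.72/1.1 s for offsets), fixed per-branch intercepts
(0.02/0.16, 0.04/0.24, 0.04/0.4 s for onsets; 0.18/0.3, 0.18/0.4,
0.18/0.48 s for offsets) and six dimensionless slopes. The published
best slopes ship as defaults (onset: ald 0.4, alu 0.2, ard 0.4, aru 0.4,
amd 0.3, amu 0.0; offset: ald 0.2, alu 0.1, ard 0.2, aru 0.0, amd 0.0,
amu 0.1). Degenerate windows — the published long-branch onset optimum has
zero width at RR ≥ 1.2 s — are widened to a configurable minimum span
(0.08 s) by extending the upper bound, and flagged. This minimum also
applies to the short-branch offset optimum (raw span 0.12 − 0.1·RR s).
A final guard keeps `left < right` after sample rounding.

RR intervals are per-beat *preceding* intervals (`R_i − R_{i−1}`), so
delineation of a beat never needs the following beat. Gaps outside
[0.3, 2.0] s — which arise when only a subset of beats is annotated — and
the first beat are replaced by the record's median plausible interval and
flagged `adjusted`.

## Calibration

`fit_cluster_model` runs k-means (k = 3, 10 restarts, fixed seed, inputs
sorted so the fit is order-invariant) on annotated `(RR, RT)` pairs, orders
clusters by RR centroid, and reads each breakpoint as the midpoint of the
gap between adjacent clusters' RR extents (centroid midpoint if they
overlap). Per-branch RT ranges are cluster extrema with a configurable
margin. `grid_search_cv` then scores every slope combination (the full
published grid is 4³·5³ = 8000 per kind; ranges are configurable) by
delineating validation records under record-level seeded 5-fold CV and
pooling TP/FP/FN within each fold (micro-average, 100 ms tolerance). The
objective is the mean fold F1; ties break toward the smaller mean absolute
error, then toward earlier grid order. The mean-|error| tie-break matters:
on clean corpora many window combinations reach F1 = 1 at the 100 ms
tolerance, and the tie-break is what selects boundary-exact windows over
peak-adjacent ones. Folding is by record, not beat, to prevent leakage
between training and validation beats of one record.

## The synthetic generator

Each beat is a sum of Gaussian components (P, Q, R, S, T), so T-boundary
truth has a closed form: the 2 %-of-peak crossing at
`center ± σ·sqrt(2·ln 50)` (threshold configurable); biphasic T waves are
two opposite-sign Gaussians with the truth spanning the full complex,
located on the sample grid. Noise (white, per channel) and sinusoidal
baseline wander are added after the truth is fixed; two channels differ by
an amplitude scale. The same seed reproduces records bit-identically.

What it emulates, and the choices behind the defaults:

* **RR mixture.** Cycle lengths come from a three-branch truncated-Gaussian
  mixture (centers 0.62/0.91/1.35 s, sds 0.035/0.026/0.02, ±2.5 sd). The
  gap midpoints sit at ≈ 0.78/1.14 s, so clustering the resulting (RR, RT)
  pairs recovers the three-branch onset structure; a variant with centers
  0.58/0.86/1.34 s produces the offset-style gaps at ≈ 0.72/1.1 s.
* **RT rule.** By default the T-wave center is *per-branch affine* in RR
  (slopes 0.1/0.2/0.1, intercepts 0.195/0.21/0.29 s): RT lengthens with RR
  within each branch and steps up between branches — the clustered,
  branch-banded structure the calibration stage presumes, with every
  generated pair inside the three-branch onset (0.05–0.25/0.35/0.45 s) and
  offset (0.2–0.45/0.6/0.8 s) bands. A smooth `a + b·sqrt(RR)` mode exists,
  but a square-root rule cannot be kept simultaneously inside the onset
  corridor (window upper edge between onset and peak − 0.5 σ) and the
  offset corridor across all three branches once slopes are quantized to
  the grid's 0.1 step, so the affine rule is the default.
* **T width** σ = 0.028 s places the boundary-to-peak distance
  (2.80 σ ≈ 78 ms) in the regime where the windowed-area maximum coincides
  with the 2 % crossing for both window widths (verified over a σ scan);
  the clean-signal detection error is then ≤ 2 samples for monophasic waves
  and ≤ 60 ms for biphasic complexes.
* **Beat ordering.** RR values are sorted ascending (a decelerating
  rhythm): with `RR_{i+1} ≥ RR_i`, every T wave provably clears the next
  beat's P wave (PR shortens with RR as `0.06 + 0.12·RR`) for all three
  branches, for any draw. The first beat of a record carries **no T wave**
  and is unannotated: the detector assigns it the record-median RR (the
  preceding-interval convention), which cannot be made consistent with an
  arbitrary following cycle. This mirrors sparsely annotated clinical
  records, and the evaluation protocol ignores unannotated beats.

What it does **not** emulate: ectopy and rhythm disturbances, pacing
artifacts, electrode-motion noise, ST-segment deviation, annotation
subjectivity (truth here is a geometric convention, not a cardiologist's
judgment), and T waves merged into the following P at very short cycles.
Perfect scores on clean synthetic corpora therefore demonstrate the
correctness of the machinery — windows positioned by the calibrated rules
contain the boundary and the area maximum sits on it — not clinical-grade
accuracy; on real databases the method's published F1 is ≈ 70 % (onsets)
and ≈ 94 % (offsets).

## Filtering

Denoising is a 0.05–45 Hz zero-phase band-pass (4th-order Butterworth per
edge). The two edges are applied as separate cascades: a single SOS
band-pass spanning both is numerically ill-conditioned at a normalized low
edge of ~4·10⁻⁴, and step-matched filtfilt initial conditions excite the
~20 s high-pass pole into order-one baseline drift. The high-pass runs as
zero-state forward/backward passes on the demeaned signal; the low-pass
uses standard `sosfiltfilt`. Passband gain is within 5 % of unity at 10 Hz
and the squared-magnitude response matches the analytic design within 5 %.

## Evaluation protocol

Matching is beat-anchored by default (the detection for beat *i* may only
match beat *i*'s annotation), which is what a per-beat detector implies;
greedy nearest-difference matching is available when beat correspondence is
absent. Unannotated beats are excluded, so `TP + FN` equals the number of
annotated fiducials and Se = P+ = F1 — the signature seen in published SWA
benchmark tables. `P+` is implemented as `TP/(TP+FP)` (the standard
definition of positive precision). Undefined 0/0 ratios report 0 with a
warning. Error SD uses the n−1 denominator. The CLCE curve counts beats
with `|error| ≤ τ` over a tolerance grid; beats with no detection never
count.

## Problem sizes

The shipped experiments use 10-record × 20-beat corpora (200 beats; 190
annotated) for calibration and clean-signal checks, the full 8000-point
grid in `scripts/acceptance.py` (a reduced 144-point superset of the
winning region in the test suite), and 10 seeds × 3 records per noise level
(0, 0.02, 0.05, 0.1 mV) for the robustness sweep. These sizes give stable
breakpoint recovery (±0.02 s across seeds) while keeping a full pipeline
run under a minute on one CPU.

## Known limitations

* The published best onset parameters place the mid-branch search window at
  [0.4·RR+0.04, 0.4·RR+0.24] s after R — largely beyond the onset band the
  same paper's clustering reports (RT_on < 0.35 s). On data whose RT
  structure matches those bands, the shipped onset windows detect late
  (≈ 87 ms mean error on the synthetic default corpus); recalibration on
  the data at hand is the intended workflow.
* `|area|` maximization requires peak-excluding windows (above); with
  windows that straddle the peak the detector returns the peak, which the
  100 ms tolerance may still accept.
* WFDB support covers single-file format-16/212 records and MIT-format
  annotations — enough for the QT and European ST-T layouts — not the full
  format zoo.
* Annotation-to-beat association assumes each T boundary belongs to the
  nearest preceding R peak; rhythms where that fails (e.g. interpolated
  ectopy) would need explicit beat typing.
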