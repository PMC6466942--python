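"""The sliding-window-area (SWA) T-wave delineator.

A fixed-width window slides across an RR-dependent search range.  At each
candidate sample ``t`` the baseline-corrected waveform area is

    onset  (forward):   Ao(t) = sum_{j=t}^{t+w}  (s_j - sbar_t)
    offset (backward):  Ae(t) = sum_{j=t-w}^{t}  (s_j - sbar_t)

with ``sbar_t`` the local average amplitude over ``[t-p, t+p]``.  The T-wave
onset/offset is the candidate maximizing ``|area|`` (absolute by default, so
inverted and biphasic T waves are handled; signed area is available as a
configuration flag).  Ties go to the earliest candidate.

Two families of search boundaries are provided: the traditional two-branch
piecewise-linear windows of the original SWA literature, and the improved
three-branch windows whose RR breakpoints come from k-means clustering of
annotated (RR, RT) pairs and whose slopes are calibrated by grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import MISSING, ECGRecord, FiducialSet
from .preprocess import RRSeries

__all__ = [
    "SWAConfig",
    "SearchWindow",
    "BoundaryParams",
    "AreaProfile",
    "DetectionResult",
    "paper_onset_params",
    "paper_offset_params",
    "local_baseline",
    "sliding_area",
    "area_series",
    "area_profile",
    "traditional_onset_window",
    "traditional_offset_window",
    "improved_window",
    "improved_bounds_arrays",
    "detect_t_onset",
    "detect_t_offset",
    "delineate_record",
]

BRANCHES = ("short", "mid", "long")

#: Minimum number of usable candidates before a beat degrades to missing.
MIN_CANDIDATES = 3


@dataclass(frozen=True)
class SWAConfig:
    """Sliding-window parameters (seconds).

    ``w_on``/``w_off`` are the forward/backward window widths, ``p`` the
    smoothing half-width of the local baseline, ``min_span`` the floor on a
    search window's width (degenerate windows are widened to it).
    """

    w_on: float = 0.12
    w_off: float = 0.128
    p: float = 0.016
    use_abs_area: bool = True
    min_span: float = 0.08

    def __post_init__(self) -> None:
        for name in ("w_on", "w_off", "p", "min_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def w_samples(self, kind: str, fs: float) -> int:
        w = self.w_on if kind == "onset" else self.w_off
        return max(1, round(w * fs))

    def p_samples(self, fs: float) -> int:
        return max(1, round(self.p * fs))

    def min_span_samples(self, fs: float) -> int:
        return max(1, round(self.min_span * fs))


@dataclass(frozen=True)
class SearchWindow:
    """Candidate range ``[left, right]`` (inclusive sample indices)."""

    left: int
    right: int
    branch: str
    degenerate_fixed: bool = False

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError(f"window left {self.left} must precede right {self.right}")


@dataclass(frozen=True)
class BoundaryParams:
    """Three-branch piecewise-affine search boundaries for one fiducial kind.

    For a beat with R peak ``R`` and current RR interval ``rr`` (s), the
    branch is selected by ``rr`` against ``breakpoints = (bp1, bp2)`` and the
    window is::

        lower = R + lower_slope * rr + lower_intercept
        upper = R + upper_slope * rr + upper_intercept

    Slopes are the six dimensionless grid-searched parameters
    (ald/alu short branch, ard/aru mid, amd/amu long); the intercepts and
    breakpoints are fixed constants of the method.
    """

    kind: str
    breakpoints: tuple[float, float]
    ald: float
    alu: float
    ard: float
    aru: float
    amd: float
    amu: float
    lower_intercepts: tuple[float, float, float]
    upper_intercepts: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("onset", "offset"):
            raise ValueError(f"kind must be 'onset' or 'offset', got {self.kind!r}")
        if not self.breakpoints[0] < self.breakpoints[1]:
            raise ValueError("breakpoints must be strictly increasing")
        if any(v < 0 for v in self.lower_intercepts + self.upper_intercepts):
            raise ValueError("intercepts must be non-negative")

    @property
    def lower_slopes(self) -> tuple[float, float, float]:
        return (self.ald, self.ard, self.amd)

    @property
    def upper_slopes(self) -> tuple[float, float, float]:
        return (self.alu, self.aru, self.amu)

    def branch_index(self, rr: float) -> int:
        bp1, bp2 = self.breakpoints
        return 0 if rr < bp1 else (1 if rr < bp2 else 2)

    def slope_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("ald", "alu", "ard", "aru", "amd", "amu")}

    def with_slopes(self, **slopes: float) -> "BoundaryParams":
        return replace(self, **slopes)


ONSET_BREAKPOINTS = (0.76, 1.13)
OFFSET_BREAKPOINTS = (0.72, 1.1)
ONSET_LOWER_INTERCEPTS = (0.02, 0.04, 0.04)
ONSET_UPPER_INTERCEPTS = (0.16, 0.24, 0.4)
OFFSET_LOWER_INTERCEPTS = (0.18, 0.18, 0.18)
OFFSET_UPPER_INTERCEPTS = (0.3, 0.4, 0.48)


def paper_onset_params() -> BoundaryParams:
    """The published grid-search optimum for T-wave onsets."""
    return BoundaryParams("onset", ONSET_BREAKPOINTS,
                          ald=0.4, alu=0.2, ard=0.4, aru=0.4, amd=0.3, amu=0.0,
                          lower_intercepts=ONSET_LOWER_INTERCEPTS,
                          upper_intercepts=ONSET_UPPER_INTERCEPTS)


def paper_offset_params() -> BoundaryParams:
    """The published grid-search optimum for T-wave offsets."""
    return BoundaryParams("offset", OFFSET_BREAKPOINTS,
                          ald=0.2, alu=0.1, ard=0.2, aru=0.0, amd=0.0, amu=0.1,
                          lower_intercepts=OFFSET_LOWER_INTERCEPTS,
                          upper_intercepts=OFFSET_UPPER_INTERCEPTS)


# ---------------------------------------------------------------------------
# Areas


def local_baseline(signal: np.ndarray, k: int, p: int) -> float:
    """Local average amplitude: mean of ``signal`` over ``[k-p, k+p]``.

    The window is clipped at the record edges (the mean is over the samples
    actually available).
    """
    lo = max(k - p, 0)
    hi = min(k + p, len(signal) - 1)
    return float(np.mean(signal[lo : hi + 1]))


def sliding_area(signal: np.ndarray, t: int, w: int, p: int, direction: str) -> float:
    """Baseline-corrected window area at candidate ``t``.

    ``direction='forward'`` sums over ``[t, t+w]`` (onset detection),
    ``'backward'`` over ``[t-w, t]`` (offset detection).  The baseline is
    evaluated once per candidate, at ``k = t``.
    """
    n = len(signal)
    if direction == "forward":
        if t < 0 or t + w > n - 1:
            raise ValueError(f"forward window [{t}, {t + w}] outside signal of length {n}")
        seg = signal[t : t + w + 1]
    elif direction == "backward":
        if t - w < 0 or t > n - 1:
            raise ValueError(f"backward window [{t - w}, {t}] outside signal of length {n}")
        seg = signal[t - w : t + 1]
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    return float(np.sum(seg) - (w + 1) * local_baseline(signal, t, p))


def area_series(signal: np.ndarray, w: int, p: int, direction: str) -> np.ndarray:
    """Vectorized sliding area at every candidate sample.

    Returns an array aligned with ``signal``; entries whose window does not
    fit inside the record are NaN.  Cumulative sums make this O(n); the
    result equals the direct summation of :func:`sliding_area` exactly (up to
    floating-point accumulation).
    """
    s = np.asarray(signal, dtype=float)
    n = len(s)
    c = np.concatenate([[0.0], np.cumsum(s)])
    idx = np.arange(n)
    lo = np.maximum(idx - p, 0)
    hi = np.minimum(idx + p, n - 1)
    baseline = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    out = np.full(n, np.nan)
    if direction == "forward":
        valid = idx <= n - 1 - w
        t = idx[valid]
        out[valid] = c[t + w + 1] - c[t] - (w + 1) * baseline[valid]
    elif direction == "backward":
        valid = idx >= w
        t = idx[valid]
        out[valid] = c[t + 1] - c[t - w] - (w + 1) * baseline[valid]
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    return out


@dataclass
class AreaProfile:
    """Window areas over a candidate range, with the detected argmax."""

    candidates: np.ndarray
    area: np.ndarray
    argmax: int  # sample index of the winning candidate

    def __post_init__(self) -> None:
        if len(self.candidates) != len(self.area):
            raise ValueError("candidates and area must be aligned")


def area_profile(signal: np.ndarray, window: SearchWindow, w: int, p: int,
                 direction: str, use_abs_area: bool = True,
                 precomputed: np.ndarray | None = None) -> AreaProfile | None:
    """Evaluate the area over a search window and locate its maximum.

    Candidates are clipped so the full sliding window stays inside the
    record; fewer than ``MIN_CANDIDATES`` usable candidates yields ``None``
    (the beat degrades to missing).
    """
    n = len(signal) if precomputed is None else len(precomputed)
    if direction == "forward":
        left = max(window.left, 0)
        right = min(window.right, n - 1 - w)
    else:
        left = max(window.left, w)
        right = min(window.right, n - 1)
    if right - left + 1 < MIN_CANDIDATES:
        return None
    series = precomputed if precomputed is not None else area_series(signal, w, p, direction)
    cand = np.arange(left, right + 1)
    area = series[cand]
    score = np.abs(area) if use_abs_area else area
    best = int(cand[argmax_tied(score, direction)])
    return AreaProfile(candidates=cand, area=area, argmax=best)


def argmax_tied(score: np.ndarray, direction: str) -> int:
    """Argmax with direction-consistent, float-tolerant tie-breaking.

    Ties (within a small relative tolerance, so exactly tied plateaus are
    not broken by summation noise) resolve to the earliest candidate for the
    forward (onset) direction and to the latest for the backward (offset)
    direction — the exact mirror the time-reversal symmetry of the two area
    definitions implies.
    """
    m = float(np.max(score))
    tied = score >= m - 1e-9 * max(1.0, abs(m))
    if direction == "forward":
        return int(np.argmax(tied))
    return int(len(score) - 1 - np.argmax(tied[::-1]))


# ---------------------------------------------------------------------------
# Search windows


def _to_window(lower_s: float, upper_s: float, r_peak: int, fs: float, branch: str,
               min_span_s: float | None = None) -> SearchWindow:
    lo, hi = sorted((lower_s, upper_s))  # order-normalize
    degenerate = False
    if min_span_s is not None and hi - lo < min_span_s:
        hi = lo + min_span_s
        degenerate = True
    left = r_peak + round(lo * fs)
    right = r_peak + round(hi * fs)
    if right <= left:  # rounding can collapse a near-degenerate window
        right = left + 1
        degenerate = True
    return SearchWindow(left=left, right=right, branch=branch,
                        degenerate_fixed=degenerate)


def traditional_onset_window(rr: float, r_peak: int, fs: float) -> SearchWindow:
    """Two-branch onset search range of the traditional SWA method.

    The two printed boundary expressions are evaluated and order-normalized
    to ``[min, max]`` (as printed they are reversed for every rr).
    """
    if rr <= 0:
        raise ValueError("rr must be positive")
    if rr < 0.88:
        a, b = 0.5 * rr + 0.08, 0.15 * rr + 0.12
        branch = "short"
    else:
        a, b = 0.5 * rr + 0.1, 0.32
        branch = "long"
    return _to_window(a, b, r_peak, fs, branch)


def traditional_offset_window(rr: float, r_peak: int, fs: float) -> SearchWindow:
    """Two-branch offset search range of the traditional SWA method."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    if rr < 0.88:
        a, b = 0.15 * rr + 0.148, 0.7 * rr - 0.036
        branch = "short"
    else:
        a, b = 0.28, 0.2 * rr + 0.404
        branch = "long"
    return _to_window(a, b, r_peak, fs, branch)


def improved_window(rr: float, r_peak: int, fs: float, params: BoundaryParams,
                    cfg: SWAConfig | None = None) -> SearchWindow:
    """Three-branch search range from calibrated boundary parameters.

    Degenerate windows (span below ``cfg.min_span``, which the published
    long-branch onset optimum produces) are widened by extending the upper
    bound, and flagged.
    """
    if rr <= 0:
        raise ValueError("rr must be positive")
    cfg = cfg or SWAConfig()
    b = params.branch_index(rr)
    lower = params.lower_slopes[b] * rr + params.lower_intercepts[b]
    upper = params.upper_slopes[b] * rr + params.upper_intercepts[b]
    return _to_window(lower, upper, r_peak, fs, BRANCHES[b], min_span_s=cfg.min_span)


def improved_bounds_arrays(rr: np.ndarray, r_peaks: np.ndarray, fs: float,
                           params: BoundaryParams,
                           cfg: SWAConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`improved_window` bounds for a whole record.

    Returns inclusive (left, right) sample-index arrays aligned to beats.
    Used by the grid search, where windows are rebuilt thousands of times.
    """
    cfg = cfg or SWAConfig()
    rr = np.asarray(rr, dtype=float)
    bp1, bp2 = params.breakpoints
    b = np.where(rr < bp1, 0, np.where(rr < bp2, 1, 2))
    lo_s = np.take(params.lower_slopes, b) * rr + np.take(params.lower_intercepts, b)
    hi_s = np.take(params.upper_slopes, b) * rr + np.take(params.upper_intercepts, b)
    lo, hi = np.minimum(lo_s, hi_s), np.maximum(lo_s, hi_s)
    hi = np.where(hi - lo < cfg.min_span, lo + cfg.min_span, hi)
    left = np.asarray(r_peaks) + np.round(lo * fs).astype(np.int64)
    right = np.asarray(r_peaks) + np.round(hi * fs).astype(np.int64)
    return left, right


# ---------------------------------------------------------------------------
# Detection


def detect_t_onset(signal: np.ndarray, window: SearchWindow, cfg: SWAConfig,
                   fs: float, precomputed: np.ndarray | None = None) -> int:
    """Forward-area argmax inside the window; ``MISSING`` if unusable."""
    prof = area_profile(signal, window, cfg.w_samples("onset", fs),
                        cfg.p_samples(fs), "forward", cfg.use_abs_area,
                        precomputed=precomputed)
    return MISSING if prof is None else prof.argmax


def detect_t_offset(signal: np.ndarray, window: SearchWindow, cfg: SWAConfig,
                    fs: float, precomputed: np.ndarray | None = None) -> int:
    """Backward-area argmax inside the window; ``MISSING`` if unusable."""
    prof = area_profile(signal, window, cfg.w_samples("offset", fs),
                        cfg.p_samples(fs), "backward", cfg.use_abs_area,
                        precomputed=precomputed)
    return MISSING if prof is None else prof.argmax


@dataclass
class DetectionResult:
    """Per-beat delineation output for one channel of one record."""

    r_peaks: np.ndarray
    t_onsets: np.ndarray
    t_offsets: np.ndarray
    onset_windows: list[SearchWindow | None]
    offset_windows: list[SearchWindow | None]
    skip_reasons: dict[int, str] = field(default_factory=dict)
    channel: int = 0
    method: str = "improved"
    record_id: str = ""

    def to_fiducials(self) -> FiducialSet:
        return FiducialSet(self.r_peaks, self.t_onsets, self.t_offsets,
                           channel=self.channel, record_id=self.record_id)


def delineate_record(record: ECGRecord, r_peaks: np.ndarray, rrs: RRSeries,
                     method: str = "improved",
                     onset_params: BoundaryParams | None = None,
                     offset_params: BoundaryParams | None = None,
                     cfg: SWAConfig | None = None,
                     channel: int = 0) -> DetectionResult:
    """Delineate every beat of one channel.

    ``method='traditional'`` uses the fixed two-branch windows;
    ``'improved'`` the three-branch windows of ``onset_params`` /
    ``offset_params`` (the published optima when omitted).  Beats whose
    window falls outside the record degrade to missing with a recorded skip
    reason; the caller is expected to have band-pass filtered ``record``.
    """
    if method not in ("traditional", "improved"):
        raise ValueError(f"method must be 'traditional' or 'improved', got {method!r}")
    cfg = cfg or SWAConfig()
    if method == "improved":
        onset_params = onset_params or paper_onset_params()
        offset_params = offset_params or paper_offset_params()
    sig = record.channel(channel)
    fs = record.fs
    fwd = area_series(sig, cfg.w_samples("onset", fs), cfg.p_samples(fs), "forward")
    bwd = area_series(sig, cfg.w_samples("offset", fs), cfg.p_samples(fs), "backward")

    r = np.asarray(r_peaks, dtype=np.int64)
    n = len(r)
    t_on = np.full(n, MISSING, dtype=np.int64)
    t_off = np.full(n, MISSING, dtype=np.int64)
    on_windows: list[SearchWindow | None] = []
    off_windows: list[SearchWindow | None] = []
    skips: dict[int, str] = {}
    for i in range(n):
        rr = float(rrs.rr[i])
        if method == "traditional":
            won = traditional_onset_window(rr, int(r[i]), fs)
            woff = traditional_offset_window(rr, int(r[i]), fs)
        else:
            won = improved_window(rr, int(r[i]), fs, onset_params, cfg)
            woff = improved_window(rr, int(r[i]), fs, offset_params, cfg)
        on_windows.append(won)
        off_windows.append(woff)
        t_on[i] = detect_t_onset(sig, won, cfg, fs, precomputed=fwd)
        t_off[i] = detect_t_offset(sig, woff, cfg, fs, precomputed=bwd)
        if t_on[i] == MISSING or t_off[i] == MISSING:
            skips[i] = "window_out_of_range"
    return DetectionResult(r, t_on, t_off, on_windows, off_windows, skips,
                           channel=channel, method=method,
                           record_id=record.record_id)
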