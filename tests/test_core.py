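"""The SWA detector core: areas vs brute-force oracles, windows, detection."""

import numpy as np
import pytest

from swadelin.signal_io import MISSING, ECGRecord
from swadelin.preprocess import RRSeries
from swadelin.core import (
    SWAConfig,
    SearchWindow,
    area_profile,
    area_series,
    delineate_record,
    detect_t_onset,
    detect_t_offset,
    improved_bounds_arrays,
    improved_window,
    local_baseline,
    paper_offset_params,
    paper_onset_params,
    sliding_area,
    traditional_offset_window,
    traditional_onset_window,
)

FS = 250.0
CFG = SWAConfig()


# -- brute-force oracles ----------------------------------------------------

def baseline_oracle(signal, k, p):
    """Direct loop-sum local mean over the clipped window [k-p, k+p]."""
    total, count = 0.0, 0
    for j in range(k - p, k + p + 1):
        if 0 <= j < len(signal):
            total += signal[j]
            count += 1
    return total / count


def area_oracle(signal, t, w, p, direction):
    """Double-loop summation of the window area."""
    base = baseline_oracle(signal, t, p)
    lo, hi = (t, t + w) if direction == "forward" else (t - w, t)
    total = 0.0
    for j in range(lo, hi + 1):
        total += signal[j] - base
    return total


class TestLocalBaseline:
    def test_constant(self):
        assert local_baseline(np.full(100, 3.7), 50, 4) == pytest.approx(3.7)

    def test_ramp_interior(self):
        sig = np.arange(100, dtype=float)
        assert local_baseline(sig, 42, 4) == pytest.approx(42.0)

    def test_matches_oracle_including_edges(self):
        rng = np.random.default_rng(11)
        sig = rng.normal(size=200)
        for k in [0, 1, 3, 100, 196, 199]:
            assert local_baseline(sig, k, 4) == pytest.approx(
                baseline_oracle(sig, k, 4), rel=1e-12)


class TestSlidingArea:
    def test_constant_signal_is_zero(self):
        sig = np.full(300, 0.25)
        for t, d in [(50, "forward"), (250, "backward")]:
            assert sliding_area(sig, t, 30, 4, d) == pytest.approx(0.0, abs=1e-12)

    def test_step_patch_matches_count(self):
        # ones on [t+5, t+w] over a flat zero baseline region
        w, t = 30, 100
        sig = np.zeros(300)
        sig[t + 5 : t + w + 1] = 1.0
        assert sliding_area(sig, t, w, 4, "forward") == pytest.approx(w - 4)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            sig = rng.normal(size=500)
            for t in rng.integers(40, 420, size=8):
                for d in ("forward", "backward"):
                    got = sliding_area(sig, int(t), 32, 4, d)
                    assert got == pytest.approx(
                        area_oracle(sig, int(t), 32, 4, d), rel=1e-9, abs=1e-9)

    def test_series_equals_scalar_everywhere(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(size=400)
        for d, rng_t in (("forward", range(0, 400 - 30)), ("backward", range(30, 400))):
            series = area_series(sig, 30, 4, d)
            for t in list(rng_t)[:: 37]:
                assert series[t] == pytest.approx(sliding_area(sig, t, 30, 4, d),
                                                  rel=1e-9, abs=1e-9)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        sig = rng.normal(size=300)
        rev = sig[::-1].copy()
        n = len(sig)
        for t in (50, 120, 200):
            fwd = sliding_area(rev, t, 30, 4, "forward")
            bwd = sliding_area(sig, n - 1 - t, 30, 4, "backward")
            assert fwd == pytest.approx(bwd, rel=1e-9, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sliding_area(np.zeros(100), 90, 30, 4, "forward")


class TestTraditionalWindows:
    @pytest.mark.parametrize("rr, lo, hi", [
        (0.8, 0.24, 0.48),    # short branch, order-normalized
        (1.0, 0.32, 0.60),
        (0.88, 0.32, 0.54),   # boundary rr uses the >= branch
    ])
    def test_onset_substitution(self, rr, lo, hi):
        win = traditional_onset_window(rr, 0, FS)
        assert win.left == round(lo * FS)
        assert win.right == round(hi * FS)

    def test_onset_branch_at_breakpoint(self):
        assert traditional_onset_window(0.88, 0, FS).branch == "long"
        assert traditional_onset_window(0.879, 0, FS).branch == "short"

    @pytest.mark.parametrize("rr, lo, hi", [
        (0.8, 0.268, 0.524),
        (1.0, 0.28, 0.604),
        (0.88, 0.28, 0.58),
    ])
    def test_offset_substitution(self, rr, lo, hi):
        win = traditional_offset_window(rr, 0, FS)
        assert win.left == round(lo * FS)
        assert win.right == round(hi * FS)

    def test_r_peak_offsets_window(self):
        base = traditional_onset_window(0.8, 0, FS)
        moved = traditional_onset_window(0.8, 1000, FS)
        assert (moved.left, moved.right) == (base.left + 1000, base.right + 1000)


class TestImprovedWindows:
    def test_published_onset_mid_branch(self):
        win = improved_window(0.8, 0, FS, paper_onset_params(), CFG)
        assert (win.left, win.right) == (round(0.36 * FS), round(0.56 * FS))
        assert win.branch == "mid" and not win.degenerate_fixed

    def test_degenerate_long_branch_widened(self):
        # published long-branch onset optimum collapses to zero width
        win = improved_window(1.2, 0, FS, paper_onset_params(), CFG)
        assert win.degenerate_fixed
        assert (win.left, win.right) == (round(0.40 * FS), round(0.48 * FS))

    def test_published_offset_short_branch(self):
        # raw substitution [0.30, 0.36] s; span below min_span, so widened
        win = improved_window(0.6, 0, FS, paper_offset_params(), CFG)
        assert win.left == round(0.30 * FS)
        assert win.branch == "short"
        assert win.degenerate_fixed
        assert win.right == win.left + round(CFG.min_span * FS)

    def test_branch_selection_at_breakpoints(self):
        p = paper_onset_params()
        assert improved_window(0.759, 0, FS, p, CFG).branch == "short"
        assert improved_window(0.76, 0, FS, p, CFG).branch == "mid"
        assert improved_window(1.13, 0, FS, p, CFG).branch == "long"

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(6)
        rr = rng.uniform(0.4, 1.6, size=50)
        r = np.arange(50) * 300
        for params in (paper_onset_params(), paper_offset_params()):
            left, right = improved_bounds_arrays(rr, r, FS, params, CFG)
            for i in range(50):
                win = improved_window(float(rr[i]), int(r[i]), FS, params, CFG)
                assert (left[i], right[i]) == (win.left, win.right)

    def test_left_always_precedes_right(self):
        for rr in np.linspace(0.3, 2.0, 171):
            for fn in (traditional_onset_window, traditional_offset_window):
                w = fn(float(rr), 0, FS)
                assert w.left < w.right
            for params in (paper_onset_params(), paper_offset_params()):
                w = improved_window(float(rr), 0, FS, params, CFG)
                assert w.left < w.right

    def test_piecewise_affine_within_branch(self):
        # within a branch the bounds are affine in rr: three collinear points
        p = paper_offset_params()
        rrs = (0.80, 0.90, 1.00)
        lows = [p.ard * rr + p.lower_intercepts[1] for rr in rrs]
        wins = [improved_window(rr, 0, FS, p, CFG) for rr in rrs]
        for w, lo in zip(wins, lows):
            assert w.left == round(lo * FS)


def triangle_beat(onset=500, peak=560, end=640, amp=0.3, n=1200):
    sig = np.zeros(n)
    sig[onset : peak + 1] = np.linspace(0, amp, peak - onset + 1)
    sig[peak : end + 1] = np.linspace(amp, 0, end - peak + 1)
    return sig


def brute_force_argmax(sig, win, w, p, direction, n):
    """|area| maximum over the window by direct double-loop sums; ties go
    earliest for the forward direction and latest for the backward one."""
    lo = max(win.left, 0 if direction == "forward" else w)
    hi = min(win.right, n - 1 - w if direction == "forward" else n - 1)
    areas = [abs(area_oracle(sig, t, w, p, direction)) for t in range(lo, hi + 1)]
    m = max(areas)
    tied = [i for i, a in enumerate(areas) if a >= m - 1e-9 * max(1.0, m)]
    return lo + (tied[0] if direction == "forward" else tied[-1])


class TestDetection:
    def test_triangle_onset_matches_brute_force(self):
        # on an exactly linear rise the discrete area profile is flat, so the
        # argmax pins to the first candidate whose baseline window clears the
        # corner: within p (4 samples) of the onset, and equal to the oracle
        sig = triangle_beat()
        win = SearchWindow(430, 540, "mid")
        det = detect_t_onset(sig, win, CFG, FS)
        assert det == brute_force_argmax(sig, win, 30, 4, "forward", len(sig))
        assert abs(det - 500) <= CFG.p_samples(FS) + 1

    def test_triangle_offset_matches_brute_force(self):
        sig = triangle_beat()
        win = SearchWindow(600, 700, "mid")
        det = detect_t_offset(sig, win, CFG, FS)
        assert det == brute_force_argmax(sig, win, 32, 4, "backward", len(sig))
        assert abs(det - 640) <= CFG.p_samples(FS) + 1

    def test_gaussian_wave_boundary_exact(self):
        # smooth monophasic wave: strict area maximum within 2 samples of the
        # 2%-of-peak crossing, for either polarity
        t = np.arange(1500) / FS
        for amp in (0.3, -0.3):
            sig = amp * np.exp(-0.5 * ((t - 3.0) / 0.028) ** 2)
            half = 0.028 * np.sqrt(2 * np.log(50))
            on, off = round((3.0 - half) * FS), round((3.0 + half) * FS)
            det_on = detect_t_onset(sig, SearchWindow(on - 40, on + 10, "mid"), CFG, FS)
            det_off = detect_t_offset(sig, SearchWindow(off - 10, off + 40, "mid"), CFG, FS)
            assert abs(det_on - on) <= 2
            assert abs(det_off - off) <= 2

    def test_inverted_wave_same_indices(self):
        sig = triangle_beat()
        win = SearchWindow(430, 540, "mid")
        assert detect_t_onset(-sig, win, CFG, FS) == detect_t_onset(sig, win, CFG, FS)

    def test_signed_area_still_right_for_upright(self):
        cfg = SWAConfig(use_abs_area=False)
        sig = triangle_beat()
        win = SearchWindow(430, 540, "mid")
        pos = detect_t_onset(sig, win, cfg, FS)
        assert abs(pos - 500) <= CFG.p_samples(FS) + 1

    def test_all_zero_ties_to_earliest(self):
        win = SearchWindow(100, 200, "mid")
        assert detect_t_onset(np.zeros(1000), win, CFG, FS) == 100

    def test_scale_offset_invariance(self):
        rng = np.random.default_rng(8)
        sig = triangle_beat() + 0.01 * rng.normal(size=1200)
        win = SearchWindow(430, 540, "mid")
        base = detect_t_onset(sig, win, CFG, FS)
        for a, b in [(3.0, 0.5), (-2.0, 1.0), (0.1, -4.0)]:
            assert detect_t_onset(a * sig + b, win, CFG, FS) == base

    def test_unusable_window_missing(self):
        win = SearchWindow(980, 1100, "long")  # forward window cannot fit
        assert detect_t_onset(np.zeros(1000), win, CFG, FS) == MISSING

    def test_area_profile_candidates_clipped(self):
        sig = np.zeros(500)
        prof = area_profile(sig, SearchWindow(400, 490, "long"), 30, 4, "forward")
        assert prof.candidates[-1] == 500 - 1 - 30
        assert len(prof.candidates) == len(prof.area)


class TestDelineateRecord:
    @pytest.fixture
    def ten_beat(self):
        import swadelin as sw
        sr = sw.generate(sw.SynthSpec(n_beats=10, seed=42))
        rr = RRSeries(sr.rr, np.zeros(len(sr.rr), dtype=bool) | [True] + [False] * 9)
        return sr, rr

    def test_all_beats_delineated_inside_windows(self, ten_beat):
        sr, rr = ten_beat
        res = delineate_record(sr.record, sr.truth.r_peaks, rr, "improved")
        assert np.all(res.t_onsets != MISSING) and np.all(res.t_offsets != MISSING)
        for i in range(10):
            assert res.onset_windows[i].left <= res.t_onsets[i] <= res.onset_windows[i].right
            assert res.offset_windows[i].left <= res.t_offsets[i] <= res.offset_windows[i].right

    def test_window_beyond_record_skipped(self, ten_beat):
        sr, rr = ten_beat
        short = ECGRecord(sr.record.signal[:, : int(sr.truth.r_peaks[-1]) + 10],
                          sr.record.fs, record_id="cut")
        res = delineate_record(short, sr.truth.r_peaks, rr, "improved")
        assert res.t_offsets[-1] == MISSING
        assert res.skip_reasons[9] == "window_out_of_range"

    def test_methods_differ_only_where_windows_differ(self, ten_beat):
        sr, rr = ten_beat
        trad = delineate_record(sr.record, sr.truth.r_peaks, rr, "traditional")
        impr = delineate_record(sr.record, sr.truth.r_peaks, rr, "improved")
        for i in range(10):
            if (trad.onset_windows[i].left, trad.onset_windows[i].right) == (
                    impr.onset_windows[i].left, impr.onset_windows[i].right):
                assert trad.t_onsets[i] == impr.t_onsets[i]
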