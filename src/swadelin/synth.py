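"""Seeded synthetic ECG records with exact ground-truth T-wave fiducials.

Each beat is a sum of Gaussian components (P, Q, R, S, T), so the T-wave
boundaries have a closed form: for a monophasic T of center ``c`` and width
``sigma``, the onset/offset are where the noiseless T component crosses 2%
of its peak, i.e. ``c -/+ sigma * sqrt(2 ln 50)``.  Biphasic T waves are two
opposite-sign Gaussians and the truth spans the full complex (located
numerically on the component).  Noise and baseline wander are added after
the truth is fixed.

The generator emulates the statistical structure the delineator assumes:
RR intervals drawn from a three-branch mixture (so (RR, RT) pairs form the
clusters the calibration stage recovers), RT intervals lengthening with RR
(Bazett-like, ``RT center = a + b*sqrt(RR)``), and positive / negative /
biphasic T morphologies.  RR values are sorted ascending within a record —
heart rate drifts rather than jumps — which also keeps short-cycle beats
from colliding with the following P wave.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .signal_io import (
    MISSING,
    ECGRecord,
    FiducialSet,
    read_detections,
    read_wfdb_record,
    write_detections,
    write_wfdb_record,
)
from .preprocess import RRSeries
from .calibration import AnnotatedRecord

__all__ = ["SynthSpec", "SynthRecord", "generate", "generate_corpus",
           "load_corpus", "to_annotated"]

#: Half-duration of a Gaussian wave at the 2%-of-peak crossing, in sigmas.
CROSS_2PCT = float(np.sqrt(2.0 * np.log(50.0)))

MORPHOLOGIES = ("positive", "negative", "biphasic")


@dataclass
class SynthSpec:
    """Generator parameters; defaults emulate a 250 Hz two-channel recording.

    RR mixture: one Gaussian branch per (short, mid, long) cycle-length
    cluster, truncated at ``rr_clip_sd`` standard deviations.  T placement
    (``rt_mode='branch_affine'``, the default): the T-wave center sits
    ``rt_slopes[b]*rr + rt_intercepts[b]`` seconds after the R peak, where
    ``b`` is the beat's RR branch — RT lengthens with RR within each branch
    and steps up between branches, the clustered structure the three-branch
    calibration bands describe.  ``rt_mode='sqrt'`` gives a smooth Bazett-like
    ``rt_sqrt[0] + rt_sqrt[1]*sqrt(rr)`` alternative.  P timing shortens with
    rr (``PR = pr_intercept + pr_slope*rr``), as real PR intervals do.
    Amplitudes in mV, times in seconds.
    """

    n_beats: int = 60
    fs: float = 250.0
    record_id: str = "synth"
    seed: int = 0
    # RR mixture (s)
    rr_centers: tuple[float, ...] = (0.62, 0.91, 1.35)
    rr_sds: tuple[float, ...] = (0.035, 0.026, 0.02)
    rr_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    rr_clip_sd: float = 2.5
    sort_rr: bool = True
    # T wave
    morphology: str = "positive"  # positive | negative | biphasic | mixed
    rt_mode: str = "branch_affine"  # or "sqrt"
    rt_slopes: tuple[float, ...] = (0.1, 0.2, 0.1)
    rt_intercepts: tuple[float, ...] = (0.195, 0.21, 0.29)
    rt_sqrt: tuple[float, float] = (0.12, 0.18)
    t_amp: float = 0.30
    t_sigma: float = 0.028
    biphasic_sep: float = 0.04
    biphasic_sigma: float = 0.020
    biphasic_amps: tuple[float, float] = (0.20, -0.15)
    # other waves
    p_amp: float = 0.10
    p_sigma: float = 0.018
    pr_intercept: float = 0.06
    pr_slope: float = 0.12
    q_amp: float = -0.08
    q_sigma: float = 0.010
    q_offset: float = -0.035
    r_amp: float = 1.0
    r_sigma: float = 0.012
    s_amp: float = -0.15
    s_sigma: float = 0.013
    s_offset: float = 0.04
    # degradations (added after truth is fixed)
    noise_sd: float = 0.0
    wander_amp: float = 0.0
    wander_hz: float = 0.33
    # misc
    truth_threshold: float = 0.02
    n_channels: int = 2
    channel_scale: tuple[float, ...] = (1.0, 0.85)
    lead_in: float = 0.5
    lead_out: float = 1.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_beats < 1:
            raise ValueError("fs must be positive and n_beats >= 1")
        if self.morphology not in MORPHOLOGIES + ("mixed",):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.rt_mode not in ("branch_affine", "sqrt"):
            raise ValueError(f"unknown rt_mode {self.rt_mode!r}")
        if self.rt_mode == "branch_affine" and (
                len(self.rt_slopes) != len(self.rr_centers)
                or len(self.rt_intercepts) != len(self.rr_centers)):
            raise ValueError("rt_slopes/rt_intercepts must match rr_centers")
        if len(self.rr_centers) != len(self.rr_sds) or \
                len(self.rr_centers) != len(self.rr_weights):
            raise ValueError("rr mixture tuples must have equal length")
        for name in ("t_sigma", "biphasic_sigma", "p_sigma", "q_sigma",
                     "r_sigma", "s_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SynthRecord:
    """A generated record with analytically known fiducials."""

    record: ECGRecord
    truth: FiducialSet
    rr: np.ndarray  # the rr used to shape each beat (s)
    branches: np.ndarray  # RR-mixture branch index per beat
    morphologies: list[str]
    spec: SynthSpec


def _rt_center(spec: SynthSpec, rr: float, branch: int) -> float:
    """Seconds from R peak to T-wave center."""
    if spec.rt_mode == "sqrt":
        return spec.rt_sqrt[0] + spec.rt_sqrt[1] * float(np.sqrt(rr))
    return spec.rt_slopes[branch] * rr + spec.rt_intercepts[branch]


def _gauss(t: np.ndarray, amp: float, center: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _t_component(spec: SynthSpec, morph: str, c_abs: float, t: np.ndarray) -> np.ndarray:
    if morph == "positive":
        return _gauss(t, spec.t_amp, c_abs, spec.t_sigma)
    if morph == "negative":
        return _gauss(t, -spec.t_amp, c_abs, spec.t_sigma)
    a1, a2 = spec.biphasic_amps
    return (_gauss(t, a1, c_abs - spec.biphasic_sep, spec.biphasic_sigma)
            + _gauss(t, a2, c_abs + spec.biphasic_sep, spec.biphasic_sigma))


def _t_truth(spec: SynthSpec, morph: str, c_abs: float, fs: float) -> tuple[int, int]:
    """Sample indices where the noiseless T component crosses the threshold."""
    if morph in ("positive", "negative"):
        half = spec.t_sigma * np.sqrt(-2.0 * np.log(spec.truth_threshold))
        return round((c_abs - half) * fs), round((c_abs + half) * fs)
    # biphasic: scan the component on the sample grid
    span = spec.biphasic_sep + 6 * spec.biphasic_sigma
    j0, j1 = round((c_abs - span) * fs), round((c_abs + span) * fs)
    tt = np.arange(j0, j1 + 1) / fs
    comp = np.abs(_t_component(spec, morph, c_abs, tt))
    above = np.flatnonzero(comp >= spec.truth_threshold * comp.max())
    return j0 + int(above[0]), j0 + int(above[-1])


def generate(spec: SynthSpec) -> SynthRecord:
    """Generate one record deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = spec.n_beats

    # preceding RR interval per beat; the first beat takes the median so the
    # shaping rr matches what rr_intervals() will reconstruct from the peaks
    weights = np.asarray(spec.rr_weights, dtype=float)
    weights = weights / weights.sum()
    if n > 1:
        branch = rng.choice(len(weights), size=n - 1, p=weights)
        raw = rng.normal(np.take(spec.rr_centers, branch), np.take(spec.rr_sds, branch))
        lo = np.take(spec.rr_centers, branch) - spec.rr_clip_sd * np.take(spec.rr_sds, branch)
        hi = np.take(spec.rr_centers, branch) + spec.rr_clip_sd * np.take(spec.rr_sds, branch)
        intervals = np.clip(raw, lo, hi)
        if spec.sort_rr:
            # heart rate drifts rather than jumps; an ascending (decelerating)
            # sequence guarantees each T wave clears the following P wave
            order = np.argsort(intervals)
            intervals, branch = intervals[order], branch[order]
        med = float(np.median(intervals))
        rr = np.concatenate([[med], intervals])
        first_branch = int(np.argmin(np.abs(np.asarray(spec.rr_centers) - med)))
        branches = np.concatenate([[first_branch], branch]).astype(int)
    else:
        rr = np.array([float(np.median(spec.rr_centers))])
        branches = np.array([int(len(weights) // 2)])

    r_peaks = np.empty(n, dtype=np.int64)
    r_peaks[0] = round(spec.lead_in * fs)
    for i in range(1, n):
        r_peaks[i] = r_peaks[i - 1] + round(rr[i] * fs)
    n_samples = int(r_peaks[-1] + round(spec.lead_out * fs))

    # The first beat has no preceding interval: the detector will assign it
    # the record's median RR, which need not match the short cycle that
    # follows it, so it carries no T wave and stays unannotated.
    if spec.morphology == "mixed":
        morphs = ["none"] + [MORPHOLOGIES[(i - 1) % 3] for i in range(1, n)]
    else:
        morphs = ["none"] + [spec.morphology] * (n - 1)

    t_axis = np.arange(n_samples) / fs
    clean = np.zeros(n_samples)
    t_on = np.empty(n, dtype=np.int64)
    t_off = np.empty(n, dtype=np.int64)

    def add(amp: float, center: float, sigma: float) -> None:
        j0 = max(0, round((center - 6 * sigma) * fs))
        j1 = min(n_samples, round((center + 6 * sigma) * fs) + 1)
        clean[j0:j1] += _gauss(t_axis[j0:j1], amp, center, sigma)

    for i in range(n):
        r_s = r_peaks[i] / fs
        p_center = r_s - (spec.pr_intercept + spec.pr_slope * rr[i])
        add(spec.p_amp, p_center, spec.p_sigma)
        add(spec.q_amp, r_s + spec.q_offset, spec.q_sigma)
        add(spec.r_amp, r_s, spec.r_sigma)
        add(spec.s_amp, r_s + spec.s_offset, spec.s_sigma)
        morph = morphs[i]
        if morph == "none":
            t_on[i] = t_off[i] = MISSING
            continue
        c_abs = r_s + _rt_center(spec, float(rr[i]), int(branches[i]))
        if morph in ("positive", "negative"):
            add(spec.t_amp if morph == "positive" else -spec.t_amp, c_abs, spec.t_sigma)
        else:
            a1, a2 = spec.biphasic_amps
            add(a1, c_abs - spec.biphasic_sep, spec.biphasic_sigma)
            add(a2, c_abs + spec.biphasic_sep, spec.biphasic_sigma)
        t_on[i], t_off[i] = _t_truth(spec, morph, c_abs, fs)
        # ordering invariant: P < QRS < T_on < T_end, inside this beat
        if not (p_center < r_s + spec.q_offset < r_s
                < r_s + spec.s_offset < t_on[i] / fs < t_off[i] / fs):
            raise ValueError(f"beat {i}: wave ordering broken "
                             f"(rr={rr[i]:.3f} s, morphology={morph})")
        if i + 1 < n and t_off[i] >= r_peaks[i] + round(rr[i + 1] * fs):
            raise ValueError(f"beat {i}: T offset reaches the next beat "
                             f"(rr={rr[i + 1]:.3f} s)")

    scales = np.asarray(spec.channel_scale[: spec.n_channels], dtype=float)
    if len(scales) < spec.n_channels:
        raise ValueError("channel_scale must cover n_channels")
    signal = np.outer(scales, clean)
    if spec.wander_amp > 0:
        for ch in range(spec.n_channels):
            phase = rng.uniform(0, 2 * np.pi)
            signal[ch] += spec.wander_amp * np.sin(
                2 * np.pi * spec.wander_hz * t_axis + phase)
    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=signal.shape)

    record = ECGRecord(signal=signal, fs=fs,
                       channel_names=[f"ch{c}" for c in range(spec.n_channels)],
                       record_id=spec.record_id)
    truth = FiducialSet(r_peaks, t_on, t_off, channel=0, record_id=spec.record_id)
    return SynthRecord(record=record, truth=truth, rr=rr, branches=branches,
                       morphologies=morphs, spec=spec)


def to_annotated(sr: SynthRecord, channel: int = 0,
                 record: ECGRecord | None = None) -> AnnotatedRecord:
    """Bundle a synthetic record for calibration/evaluation.

    The RR series uses the generator's own intervals (what ``rr_intervals``
    reconstructs, up to sample rounding); ``record`` may substitute e.g. a
    filtered copy of the signal.
    """
    fids = dataclasses.replace(sr.truth, channel=channel)
    rr = RRSeries(sr.rr, np.r_[True, np.zeros(len(sr.rr) - 1, dtype=bool)])
    return AnnotatedRecord(record=record or sr.record, fiducials=fids,
                           rr=rr, record_id=sr.record.record_id)


def generate_corpus(specs: list[SynthSpec], out_dir: str | Path) -> list[Path]:
    """Write records (WFDB pairs), truth CSVs, and a manifest; returns headers.

    Regenerating from the manifest reproduces the files byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    headers = []
    manifest = []
    for i, spec in enumerate(specs):
        if spec.record_id == "synth":
            spec = dataclasses.replace(spec, record_id=f"synth{i:03d}")
        sr = generate(spec)
        headers.append(write_wfdb_record(sr.record, out))
        write_detections(sr.truth, spec.fs, out / f"{spec.record_id}_truth.csv")
        manifest.append(dataclasses.asdict(spec))
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return headers


def load_corpus(corpus_dir: str | Path) -> list[tuple[ECGRecord, FiducialSet]]:
    """Read back a generated corpus (record + truth per entry)."""
    out = []
    corpus_dir = Path(corpus_dir)
    for hea in sorted(corpus_dir.glob("*.hea")):
        record = read_wfdb_record(hea)
        truth_csv = corpus_dir / f"{hea.stem}_truth.csv"
        if not truth_csv.exists():
            raise FileNotFoundError(f"missing truth file {truth_csv}")
        fids = next(iter(read_detections(truth_csv, record.fs).values()))
        out.append((record, fids))
    return out
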