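"""Scoring detections against annotations.

A detection matches an annotation when they differ by at most the tolerance
(100 ms by default).  With the per-beat protocol — one detection attempted
per annotated beat — matching is beat-anchored: the detection for beat *i*
may only match beat *i*'s annotation, so ``TP + FN`` equals the number of
annotated beats and ``TP + FP`` the number of detections (which is why
benchmark tables show Se == P+ == F1).  A greedy nearest-difference matcher
is available when beat correspondence does not exist.

Metrics: Se = TP/(TP+FN), P+ = TP/(TP+FP), F1 = 2TP/(2TP+FN+FP); signed
errors (detected - annotated, ms) summarize as sample mean +/- SD; the
cumulative line chart of error (CLCE) counts beats within each tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .signal_io import MISSING, FiducialSet

__all__ = [
    "EvalReport",
    "match_detections",
    "match_beat_anchored",
    "match_greedy",
    "compute_metrics",
    "clce_curve",
    "evaluate_record_set",
    "report_markdown",
]


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    se: float
    p_plus: float
    f1: float
    errors_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    error_mean_ms: float = float("nan")
    error_sd_ms: float = float("nan")


def match_beat_anchored(annotated: np.ndarray, detected: np.ndarray, fs: float,
                        tol_ms: float = 100.0) -> tuple[int, int, int, np.ndarray]:
    """Match per-beat aligned index arrays (``MISSING`` = absent).

    Beat *i*'s detection may only match beat *i*'s annotation; a pair farther
    apart than ``tol_ms`` counts one FN and one FP.  Returns
    ``(tp, fp, fn, signed errors in ms)``.
    """
    annotated = np.asarray(annotated, dtype=np.int64)
    detected = np.asarray(detected, dtype=np.int64)
    if annotated.shape != detected.shape:
        raise ValueError("beat-anchored matching needs aligned arrays")
    has_a = annotated != MISSING
    has_d = detected != MISSING
    diff_ms = (detected - annotated) * 1000.0 / fs
    hit = has_a & has_d & (np.abs(diff_ms) <= tol_ms)
    tp = int(hit.sum())
    fn = int((has_a & ~hit).sum())
    fp = int((has_d & ~hit).sum())
    return tp, fp, fn, diff_ms[hit]


def match_greedy(annotated: np.ndarray, detected: np.ndarray, fs: float,
                 tol_ms: float = 100.0) -> tuple[int, int, int, np.ndarray]:
    """One-to-one greedy matching by ascending absolute time difference."""
    ann = np.asarray([a for a in annotated if a != MISSING], dtype=np.int64)
    det = np.asarray([d for d in detected if d != MISSING], dtype=np.int64)
    pairs = sorted(
        ((abs(int(d) - int(a)), i, j) for i, a in enumerate(ann) for j, d in enumerate(det)),
        key=lambda x: (x[0], x[1], x[2]))
    tol_samples = tol_ms * fs / 1000.0
    used_a: set[int] = set()
    used_d: set[int] = set()
    errors = []
    for dist, i, j in pairs:
        if dist > tol_samples:
            break
        if i in used_a or j in used_d:
            continue
        used_a.add(i)
        used_d.add(j)
        errors.append((int(det[j]) - int(ann[i])) * 1000.0 / fs)
    tp = len(errors)
    return tp, len(det) - tp, len(ann) - tp, np.asarray(errors)


def match_detections(annotated: np.ndarray, detected: np.ndarray, fs: float,
                     tol_ms: float = 100.0, method: str = "beat"):
    """Dispatch to beat-anchored (default) or greedy matching."""
    if method == "beat":
        return match_beat_anchored(annotated, detected, fs, tol_ms)
    if method == "greedy":
        return match_greedy(annotated, detected, fs, tol_ms)
    raise ValueError(f"unknown matching method {method!r}")


def compute_metrics(tp: int, fp: int, fn: int, errors_ms: np.ndarray) -> EvalReport:
    """Se/P+/F1 and signed-error statistics from match counts.

    Undefined 0/0 ratios return 0 with a warning.  The error SD is the
    sample standard deviation (n-1 denominator).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    errors_ms = np.asarray(errors_ms, dtype=float)
    if tp != len(errors_ms):
        raise ValueError(f"tp={tp} but {len(errors_ms)} matched errors supplied")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (0/0); reporting 0")
            return 0.0
        return num / den

    se = ratio(tp, tp + fn, "Se")
    p_plus = ratio(tp, tp + fp, "P+")
    f1 = ratio(2 * tp, 2 * tp + fn + fp, "F1")
    mean = float(np.mean(errors_ms)) if tp else float("nan")
    sd = float(np.std(errors_ms, ddof=1)) if tp > 1 else float("nan")
    return EvalReport(tp, fp, fn, se, p_plus, f1, errors_ms, mean, sd)


def clce_curve(errors_ms: np.ndarray, tol_grid_ms: np.ndarray) -> np.ndarray:
    """Cumulative count of beats with ``|error| <= tol`` per tolerance.

    NaN entries (beats with no detection) never count at any tolerance.
    """
    tol = np.asarray(tol_grid_ms, dtype=float)
    if np.any(np.diff(tol) <= 0):
        raise ValueError("tolerance grid must be strictly increasing")
    e = np.abs(np.asarray(errors_ms, dtype=float))
    e = e[~np.isnan(e)]
    return np.array([int(np.sum(e <= t)) for t in tol])


def evaluate_record_set(
    annotated: Mapping[tuple[str, int], FiducialSet],
    detected: Mapping[tuple[str, int], FiducialSet],
    fs: float,
    tol_ms: float = 100.0,
) -> pd.DataFrame:
    """Pooled per-(channel, kind) metrics over a record set.

    Both mappings are keyed by ``(record_id, channel)``.  Counts are pooled
    (micro-averaged) across records.  Keys present in only one mapping are
    excluded with a warning.  Beats without an annotation are ignored, per
    the annotated-beat protocol.
    """
    keys = sorted(set(annotated) & set(detected))
    only = sorted(set(annotated) ^ set(detected))
    if only:
        warnings.warn(f"records present in only one set were excluded: {only}")
    if not keys:
        warnings.warn("no overlapping records to evaluate")
        return pd.DataFrame(columns=["channel", "kind", "tp", "fp", "fn",
                                     "se", "p_plus", "f1",
                                     "error_mean_ms", "error_sd_ms"])
    rows = []
    channels = sorted({ch for _, ch in keys})
    for ch in channels:
        for kind in ("onset", "offset"):
            tp = fp = fn = 0
            errors = []
            for rid, kch in keys:
                if kch != ch:
                    continue
                ann, det = annotated[(rid, kch)], detected[(rid, kch)]
                a = ann.boundary(kind)
                d = det.boundary(kind)
                if len(a) == len(d) and np.array_equal(ann.r_peaks, det.r_peaks):
                    mask = a != MISSING
                    t, p_, f, e = match_beat_anchored(a[mask], d[mask], fs, tol_ms)
                else:
                    warnings.warn(f"{rid}: beat sets differ; greedy matching used")
                    t, p_, f, e = match_greedy(a, d, fs, tol_ms)
                tp, fp, fn = tp + t, fp + p_, fn + f
                errors.append(e)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = compute_metrics(tp, fp, fn, np.concatenate(errors) if errors else [])
            rows.append({"channel": ch, "kind": kind, "tp": rep.tp, "fp": rep.fp,
                         "fn": rep.fn, "se": rep.se, "p_plus": rep.p_plus,
                         "f1": rep.f1, "error_mean_ms": rep.error_mean_ms,
                         "error_sd_ms": rep.error_sd_ms})
    return pd.DataFrame(rows)


def report_markdown(table: pd.DataFrame) -> str:
    """Benchmark-style markdown layout: per channel x kind, Se/P+/F1 in %."""
    lines = ["| Detection | Channel | Se (%) | P+ (%) | F1 (%) | Error mean ± SD (ms) |",
             "|---|---|---|---|---|---|"]
    for _, r in table.iterrows():
        err = (f"{r.error_mean_ms:.2f} ± {r.error_sd_ms:.2f}"
               if np.isfinite(r.error_mean_ms) and np.isfinite(r.error_sd_ms) else "—")
        lines.append(f"| {r['kind'].capitalize()} | {int(r['channel'])} "
                     f"| {100 * r.se:.2f} | {100 * r.p_plus:.2f} "
                     f"| {100 * r.f1:.2f} | {err} |")
    return "\n".join(lines)
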