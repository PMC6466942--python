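"""Shared fixtures: synthetic corpora and a calibration run reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import swadelin as sw
from swadelin.calibration import AnnotatedRecord

#: Reduced slope grid used by tests for speed; a superset of the combinations
#: the default synthetic geometry needs, sharing the published step of 0.1.
REDUCED_GRID_RANGES = {
    "ald": (0.1, 0.2, 0.1),
    "alu": (0.1, 0.2, 0.1),
    "ard": (0.1, 0.3, 0.1),
    "aru": (0.0, 0.1, 0.1),
    "amd": (0.0, 0.2, 0.1),
    "amu": (0.0, 0.1, 0.1),
}


def make_corpus(n_records=10, n_beats=20, morphology="positive", seed0=100,
                noise_sd=0.0, **kw):
    """Generate records and bundle them (band-pass filtered) for calibration."""
    srs, recs = [], []
    for i in range(n_records):
        sr = sw.generate(sw.SynthSpec(n_beats=n_beats, morphology=morphology,
                                      noise_sd=noise_sd, seed=seed0 + i,
                                      record_id=f"r{i}", **kw))
        filt = sw.bandpass_filter(sr.record)
        rr = sw.rr_intervals(sr.truth.r_peaks, sr.record.fs)
        srs.append(sr)
        recs.append(AnnotatedRecord(record=filt, fiducials=sr.truth, rr=rr))
    return srs, recs


@pytest.fixture(scope="session")
def clean_corpus():
    """10 noiseless monophasic records, 200 beats total."""
    return make_corpus()


@pytest.fixture(scope="session")
def calibrated(clean_corpus):
    """Boundary parameters calibrated on the clean corpus (reduced grid)."""
    _, recs = clean_corpus
    results = {}
    for kind in ("onset", "offset"):
        grid = sw.build_param_grid(kind, ranges=REDUCED_GRID_RANGES)
        results[kind] = sw.grid_search_cv(recs, grid, kind, folds=5, seed=0)
    return results


def corpus_f1(srs, recs, onset_params, offset_params, method="improved",
              kinds=("onset", "offset")):
    """Pooled F1 (and per-kind counts) of delineation against truth."""
    tp = fp = fn = 0
    for sr, rec in zip(srs, recs):
        res = sw.delineate_record(rec.record, sr.truth.r_peaks, rec.rr, method,
                                  onset_params, offset_params)
        for kind in kinds:
            det = res.t_onsets if kind == "onset" else res.t_offsets
            truth = sr.truth.boundary(kind)
            mask = truth != sw.MISSING  # score only annotated beats
            t, p, f, _ = sw.match_detections(truth[mask], det[mask], sr.record.fs)
            tp, fp, fn = tp + t, fp + p, fn + f
    return 2 * tp / (2 * tp + fp + fn), (tp, fp, fn)
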