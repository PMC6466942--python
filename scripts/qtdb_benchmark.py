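#!/usr/bin/env python
"""Benchmark against a local copy of the PhysioNet QT database.

Usage:
    python scripts/qtdb_benchmark.py /path/to/qtdb [--annotator q1c]
                                     [--channel 0] [--method improved]

Expects the usual QT layout (<record>.hea/.dat plus <record>.<annotator>
manual annotation files with '(' t ')' wave boundaries).  For every record
with T annotations: band-pass filter, rebuild per-beat RR with the
adjustment policy, delineate with the chosen method, and pool Se/P+/F1 and
signed errors per channel and fiducial kind into a benchmark-style table.

This script only formats results for qualitative comparison; it downloads
nothing and is not exercised by the test suite.
"""

from __future__ import annotations

import argparse
import warnings
from pathlib import Path

import numpy as np

import swadelin as sw
from swadelin.evaluation import evaluate_record_set, report_markdown


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("qtdb_dir", type=Path)
    ap.add_argument("--annotator", default="q1c",
                    help="manual annotation extension (q1c or q2c)")
    ap.add_argument("--method", choices=["traditional", "improved"],
                    default="improved")
    ap.add_argument("--channel", type=int, default=0)
    ap.add_argument("--tol-ms", type=float, default=100.0)
    ap.add_argument("--params", type=Path, default=None,
                    help="boundary-parameter YAML (shipped defaults if omitted)")
    args = ap.parse_args()

    onset_p, offset_p, cfg = sw.load_config(args.params)
    annotated, detected = {}, {}
    fs = 250.0
    for ann_path in sorted(args.qtdb_dir.glob(f"*.{args.annotator}")):
        base = ann_path.with_suffix("")
        try:
            record = sw.read_wfdb_record(base)
        except (FileNotFoundError, ValueError) as exc:
            warnings.warn(f"{base.name}: skipped ({exc})")
            continue
        fs = record.fs
        fids = sw.read_fiducials(ann_path, channel=args.channel)
        if fids.n_beats == 0:
            continue
        filtered = sw.bandpass_filter(record)
        rr = sw.rr_intervals(fids.r_peaks, record.fs)
        res = sw.delineate_record(filtered, fids.r_peaks, rr, args.method,
                                  onset_params=onset_p, offset_params=offset_p,
                                  cfg=cfg, channel=args.channel)
        key = (record.record_id, args.channel)
        annotated[key] = fids
        detected[key] = res.to_fiducials()
        n_on = int(np.sum(fids.t_onsets != sw.MISSING))
        n_off = int(np.sum(fids.t_offsets != sw.MISSING))
        print(f"{record.record_id}: {fids.n_beats} beats "
              f"({n_on} onsets, {n_off} offsets annotated)")

    if not annotated:
        raise SystemExit(f"no *.{args.annotator} records found in {args.qtdb_dir}")
    table = evaluate_record_set(annotated, detected, fs, tol_ms=args.tol_ms)
    print()
    print(report_markdown(table))


if __name__ == "__main__":
    main()
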