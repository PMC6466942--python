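"""Reading and writing ECG records and fiducial annotations.

Records are exchanged in the PhysioNet WFDB layout (a text ``.hea`` header
next to a binary ``.dat`` signal file); beat and wave annotations in the
MIT binary annotation format or as plain CSV detection tables.  Only the
subset of WFDB needed for single-file, format-16/212 records is supported.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ECGRecord",
    "FiducialSet",
    "AnnotationLoadReport",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_wfdb_annotations",
    "read_fiducials",
    "fiducials_from_stream",
    "write_detections",
    "read_detections",
    "DEFAULT_SYMBOL_MAP",
]

#: Sentinel for a fiducial that is not annotated / not detected.
MISSING = -1


@dataclass
class ECGRecord:
    """A sampled multichannel ECG in physical units (mV).

    ``signal`` has shape ``(n_channels, n_samples)``; sample index ``j`` of a
    channel addresses the amplitude at time ``j / fs`` seconds.  Indexing is
    0-based everywhere; times in seconds convert to samples by ``round(t*fs)``.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"record {self.record_id!r}: signal contains NaN/Inf")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length does not match signal")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int) -> np.ndarray:
        """One channel as a 1-D view."""
        if not 0 <= index < self.n_channels:
            raise ValueError(
                f"record {self.record_id!r} has {self.n_channels} channels "
                f"({', '.join(self.channel_names)}); channel {index} not present"
            )
        return self.signal[index]


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices for one channel.

    ``r_peaks`` is strictly increasing.  ``t_onsets``/``t_offsets`` are
    aligned to ``r_peaks``; ``MISSING`` (-1) marks a beat without that
    boundary.  Within a beat, ``r_peak < t_onset < t_offset`` whenever both
    boundaries are present.
    """

    r_peaks: np.ndarray
    t_onsets: np.ndarray | None = None
    t_offsets: np.ndarray | None = None
    channel: int = 0
    record_id: str = ""

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        n = len(self.r_peaks)
        if n and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        for name in ("t_onsets", "t_offsets"):
            v = getattr(self, name)
            v = np.full(n, MISSING, dtype=np.int64) if v is None else np.asarray(v, dtype=np.int64)
            if len(v) != n:
                raise ValueError(f"{name} must have one entry per beat")
            setattr(self, name, v)
        both = (self.t_onsets != MISSING) & (self.t_offsets != MISSING)
        if np.any(self.t_onsets[both] >= self.t_offsets[both]):
            # kept as a warning: raw detector output may disorder the pair
            warnings.warn("FiducialSet contains beats with t_onset >= t_offset")

    @property
    def n_beats(self) -> int:
        return len(self.r_peaks)

    def boundary(self, kind: str) -> np.ndarray:
        if kind == "onset":
            return self.t_onsets
        if kind == "offset":
            return self.t_offsets
        raise ValueError(f"kind must be 'onset' or 'offset', got {kind!r}")


# ---------------------------------------------------------------------------
# WFDB records


def _parse_gain_field(tok: str) -> tuple[float, float | None, str]:
    """Parse a header gain token ``gain(baseline)/units``."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = None
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(tok) if tok else 0.0
    if gain == 0.0:
        gain = 200.0  # WFDB default for an unspecified gain
    return gain, baseline, units


def read_wfdb_record(path: str | os.PathLike, channels: Sequence[int | str] | None = None) -> ECGRecord:
    """Read a WFDB record (``.hea`` + single ``.dat``, format 16 or 212).

    ``path`` may include or omit the ``.hea`` extension.  ``channels``
    optionally selects a subset by index or signal description.
    """
    base = Path(path)
    if base.suffix == ".hea":
        base = base.with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError(f"{hea}: header declares {n_sig} signals, found {len(sig_lines)} lines")
    fnames, fmts, gains, baselines, names = [], [], [], [], []
    for i, ln in enumerate(sig_lines):
        toks = ln.split()
        fnames.append(toks[0])
        fmt = toks[1]
        for sep in "x:+":
            fmt = fmt.split(sep)[0]
        fmts.append(int(fmt))
        gain, baseline, _units = _parse_gain_field(toks[2] if len(toks) > 2 else "")
        adc_zero = float(toks[4]) if len(toks) > 4 else 0.0
        gains.append(gain)
        baselines.append(baseline if baseline is not None else adc_zero)
        # description is everything after the fixed numeric fields, if present
        names.append(" ".join(toks[8:]) if len(toks) > 8 else f"sig{i}")
    if len(set(fnames)) != 1:
        raise ValueError(f"{hea}: multi-file records are not supported")
    if len(set(fmts)) != 1:
        raise ValueError(f"{hea}: mixed signal formats are not supported")
    fmt = fmts[0]

    dat = base.parent / fnames[0]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype=np.uint8)
    if fmt == 16:
        adc = raw.view("<i2").astype(np.int64)
        adc = adc[: (len(adc) // n_sig) * n_sig].reshape(-1, n_sig)
    elif fmt == 212:
        # 12-bit packed: 3 bytes carry 2 samples
        raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int64)
        s0 = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
        s1 = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
        pairs = np.column_stack([s0, s1]).ravel()
        pairs = np.where(pairs > 2047, pairs - 4096, pairs)
        adc = pairs[: (len(pairs) // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        raise ValueError(f"{hea}: unsupported WFDB signal format {fmt}")
    if n_samples:
        adc = adc[:n_samples]
    phys = (adc - np.asarray(baselines)) / np.asarray(gains)
    signal = phys.T
    if not np.all(np.isfinite(signal)):
        raise ValueError(f"{dat}: corrupt signal data (non-finite samples)")

    if channels is not None:
        idx = []
        for c in channels:
            if isinstance(c, str):
                if c not in names:
                    raise ValueError(
                        f"channel {c!r} not in record {record_id!r}; available: {names}")
                idx.append(names.index(c))
            else:
                if not 0 <= c < n_sig:
                    raise ValueError(
                        f"channel {c} not in record {record_id!r} "
                        f"({n_sig} channels: {names})")
                idx.append(int(c))
        signal = signal[idx]
        names = [names[i] for i in idx]
    return ECGRecord(signal=signal, fs=fs, channel_names=names, record_id=record_id)


def write_wfdb_record(record: ECGRecord, out_dir: str | os.PathLike,
                      gain: float = 2000.0) -> Path:
    """Write ``record`` as a format-16 WFDB pair; returns the header path.

    Amplitudes are quantized to ``1/gain`` mV steps (default 0.5 uV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rid = record.record_id or "record"
    adc = np.round(record.signal * gain)
    if np.any(np.abs(adc) > 32767):
        raise ValueError(f"record {rid!r}: amplitudes exceed int16 range at gain {gain}")
    adc = adc.astype("<i2")
    dat = out / f"{rid}.dat"
    adc.T.reshape(-1).tofile(dat)
    fs_txt = f"{record.fs:g}"
    lines = [f"{rid} {record.n_channels} {fs_txt} {record.n_samples}"]
    for name in record.channel_names:
        lines.append(f"{rid}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {name}")
    hea = out / f"{rid}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


# ---------------------------------------------------------------------------
# Annotations

# MIT annotation code -> mnemonic symbol (subset used by beat + wave files)
_ANN_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "(", 37: ")", 38: "r",
}

#: Beat symbols treated as R-peak markers.
DEFAULT_BEAT_SYMBOLS = frozenset("NLRaVFJASEj/Qen?")

DEFAULT_SYMBOL_MAP: dict = {
    "t_peak": "t",
    "onset": "(",
    "offset": ")",
    "beat": DEFAULT_BEAT_SYMBOLS,
}


@dataclass
class AnnotationLoadReport:
    """Bookkeeping for boundaries that could not be attached to a beat."""

    n_waves: int = 0
    n_unmatched: int = 0
    n_rejected: int = 0
    n_duplicate: int = 0


def read_wfdb_annotations(path: str | os.PathLike) -> list[tuple[int, str]]:
    """Decode an MIT-format binary annotation file to (sample, symbol) pairs.

    Pseudo-annotations (SKIP/NUM/SUB/CHN/AUX) are consumed but not emitted.
    """
    data = np.fromfile(path, dtype="<u2").astype(np.int64)
    out: list[tuple[int, str]] = []
    sample = 0
    i = 0
    while i < len(data):
        word = int(data[i])
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:  # end of file
            break
        if code == 59:  # SKIP: 4-byte interval follows, high word first
            if interval == 0:
                if i + 2 >= len(data):
                    raise ValueError(f"{path}: truncated SKIP annotation")
                delta = (int(data[i + 1]) << 16) | int(data[i + 2])
                if delta >= 1 << 31:
                    delta -= 1 << 32
                sample += delta
                i += 3
                continue
            i += 1
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modify the previous entry
            i += 1
            continue
        if code == 63:  # AUX: interval = byte count, padded to even
            i += 1 + (interval + 1) // 2
            continue
        sample += interval
        out.append((sample, _ANN_SYMBOLS.get(code, "?")))
        i += 1
    return out


def fiducials_from_stream(
    stream: Iterable[tuple[int, str]],
    symbol_map: Mapping | None = None,
    r_peaks: Sequence[int] | None = None,
    record_id: str = "",
    channel: int = 0,
    return_report: bool = False,
):
    """Build a :class:`FiducialSet` from an ordered (sample, symbol) stream.

    QT-database dialect: each annotated wave appears as ``'(' peak ')'``.  An
    opening parenthesis attaches to the wave symbol that follows it; a closing
    parenthesis attaches to the preceding wave if that wave was opened with
    ``'('``, otherwise it is taken as a bare T-wave offset.  Every T boundary
    is then associated with the nearest preceding R peak; boundaries with no
    preceding beat, duplicates for one beat, and pairs violating
    ``onset < offset`` are skipped with a warning and counted in the report.
    """
    smap = dict(DEFAULT_SYMBOL_MAP)
    if symbol_map:
        smap.update(symbol_map)
    beat_syms = set(smap["beat"])
    t_sym, open_sym, close_sym = smap["t_peak"], smap["onset"], smap["offset"]

    stream = sorted(stream, key=lambda sv: sv[0])
    peaks: list[int] = [] if r_peaks is None else list(r_peaks)
    # (symbol, onset, peak, offset) for each delimited wave
    waves: list[list] = []
    pending_open: int | None = None
    for sample, sym in stream:
        if sym == open_sym:
            pending_open = sample
        elif sym == close_sym:
            if waves and waves[-1][1] is not None and waves[-1][3] is None:
                waves[-1][3] = sample
            else:  # bare offset: QT files may annotate the T end alone
                waves.append([t_sym, None, None, sample])
        elif sym in beat_syms or sym == t_sym:
            if sym in beat_syms and r_peaks is None:
                peaks.append(sample)
            waves.append([sym, pending_open, sample, None])
            pending_open = None

    report = AnnotationLoadReport()
    r = np.asarray(sorted(set(peaks)), dtype=np.int64)
    n = len(r)
    t_on = np.full(n, MISSING, dtype=np.int64)
    t_off = np.full(n, MISSING, dtype=np.int64)
    for sym, on, peak, off in waves:
        if sym != t_sym:
            continue
        report.n_waves += 1
        anchor = next(v for v in (on, peak, off) if v is not None)
        beat = int(np.searchsorted(r, anchor, side="left")) - 1
        if beat < 0:
            warnings.warn(f"T boundary at sample {anchor} precedes every R peak; skipped")
            report.n_unmatched += 1
            continue
        if on is not None and off is not None and on >= off:
            warnings.warn(f"beat {beat}: T onset {on} >= offset {off}; rejected")
            report.n_rejected += 1
            continue
        if on is not None and on <= r[beat]:
            warnings.warn(f"beat {beat}: T onset {on} not after R peak {r[beat]}; rejected")
            report.n_rejected += 1
            continue
        if (on is not None and t_on[beat] != MISSING) or (
                off is not None and t_off[beat] != MISSING):
            warnings.warn(f"beat {beat}: duplicate T annotation; keeping the first")
            report.n_duplicate += 1
            continue
        if on is not None:
            t_on[beat] = on
        if off is not None:
            t_off[beat] = off
    # a beat may have accumulated a disordered pair from separate waves
    bad = (t_on != MISSING) & (t_off != MISSING) & (t_on >= t_off)
    for beat in np.flatnonzero(bad):
        warnings.warn(f"beat {beat}: T onset {t_on[beat]} >= offset "
                      f"{t_off[beat]}; both rejected")
        report.n_rejected += 1
        t_on[beat] = t_off[beat] = MISSING
    fids = FiducialSet(r, t_on, t_off, channel=channel, record_id=record_id)
    return (fids, report) if return_report else fids


def read_fiducials(
    path: str | os.PathLike,
    symbol_map: Mapping | None = None,
    r_peaks: Sequence[int] | None = None,
    record_id: str = "",
    channel: int = 0,
    return_report: bool = False,
):
    """Read an MIT annotation file and associate T boundaries with beats."""
    stream = read_wfdb_annotations(path)
    rid = record_id or Path(path).stem
    return fiducials_from_stream(stream, symbol_map, r_peaks=r_peaks,
                                 record_id=rid, channel=channel,
                                 return_report=return_report)


# ---------------------------------------------------------------------------
# Detection tables (CSV)

_CSV_COLUMNS = ["record_id", "channel", "r_peak_s", "t_onset_s", "t_offset_s"]


def write_detections(fiducials: FiducialSet, fs: float, path: str | os.PathLike) -> None:
    """Write one CSV row per beat, times in seconds to 6 decimals.

    Missing boundaries become empty cells, never zero.
    """
    def col(v: np.ndarray) -> np.ndarray:
        out = v / fs
        return np.where(v == MISSING, np.nan, out)

    df = pd.DataFrame({
        "record_id": fiducials.record_id,
        "channel": fiducials.channel,
        "r_peak_s": fiducials.r_peaks / fs,
        "t_onset_s": col(fiducials.t_onsets),
        "t_offset_s": col(fiducials.t_offsets),
    }, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_detections(path: str | os.PathLike, fs: float) -> dict[tuple[str, int], FiducialSet]:
    """Inverse of :func:`write_detections`; keyed by (record_id, channel)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[tuple[str, int], FiducialSet] = {}
    for (rid, ch), grp in df.groupby(["record_id", "channel"], sort=False):
        def to_idx(col: pd.Series) -> np.ndarray:
            v = np.round(col.to_numpy(dtype=float) * fs)
            return np.where(np.isnan(v), MISSING, v).astype(np.int64)

        out[(str(rid), int(ch))] = FiducialSet(
            r_peaks=np.round(grp["r_peak_s"].to_numpy(dtype=float) * fs).astype(np.int64),
            t_onsets=to_idx(grp["t_onset_s"]),
            t_offsets=to_idx(grp["t_offset_s"]),
            channel=int(ch),
            record_id=str(rid),
        )
    return out
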