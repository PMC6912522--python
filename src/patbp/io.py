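"""Stable, line-oriented text formats for waveform records and beat tables.

A waveform record is stored as a CSV of ``t, ecg, ppg, abp`` samples plus a
JSON sidecar carrying the sampling rate, subject id and metadata.  Per-beat
feature tables are plain CSV with a fixed, documented column order.  Both
carry a versioned header line so fixtures diff cleanly, and both round-trip
bit-exactly (floats are written with shortest round-trip repr).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RECORD_FORMAT = "patbp-record"
BEAT_FORMAT = "patbp-beats"
TRUTH_FORMAT = "patbp-truth"
FORMAT_VERSION = 1

CHANNELS = ("ecg", "ppg", "abp")

#: canonical ordering of the nine temporal features
FEATURE_NAMES = (
    "pat_abp",
    "pat_ppg_1",
    "pat_ppg_2",
    "pat_ppg_3",
    "pat_ppg_4",
    "ptt_1",
    "ptt_2",
    "ptt_3",
    "ptt_4",
)

#: canonical ordering of the four reference blood-pressure values
BP_NAMES = ("sbp", "dbp", "mbp", "pp")

_REASON_RE = re.compile(
    r"^($|artifact$|cond[1-6]$|no_extremum_(abp|ppg)$|nonpositive_slope$"
    r"|range_(abp_valley|abp_peak|ppg_valley|ppg_peak|ppg_maxderiv|ppg_it)$)"
)


def is_valid_reason(token: str) -> bool:
    """True iff *token* is a recognized beat-rejection reason ('' = valid)."""
    return bool(_REASON_RE.match(token))


class RecordParseError(ValueError):
    """A record or table file is malformed; the message names the field."""


@dataclass
class WaveformRecord:
    """One subject's synchronized ECG/PPG/ABP samples.

    ECG and PPG are in arbitrary units, ABP in mmHg.  ``t0`` is the absolute
    start time in seconds; all sample times are ``t0 + i / fs``.
    """

    subject_id: str
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = {ch: len(getattr(self, ch)) for ch in CHANNELS}
        if len(set(n.values())) != 1:
            raise ValueError(f"channel lengths differ: {n}")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def copy(self) -> "WaveformRecord":
        return WaveformRecord(
            subject_id=self.subject_id,
            fs=self.fs,
            ecg=self.ecg.copy(),
            ppg=self.ppg.copy(),
            abp=self.abp.copy(),
            t0=self.t0,
            metadata=dict(self.metadata),
        )


@dataclass
class BeatFeatures:
    """Per-cardiac-cycle BP values, temporal features and validity flag.

    Fiducial times are seconds relative to ``t0``; temporal features are in
    milliseconds.  ``pat_ppg``/``ptt`` index mapping: 1 = PPG valley, 2 = PPG
    peak, 3 = maximum derivative, 4 = intersecting-tangent point.
    """

    beat_index: int
    r_time: float
    abp_peak: float = math.nan
    abp_valley: float = math.nan
    ppg_valley: float = math.nan
    ppg_peak: float = math.nan
    ppg_maxderiv: float = math.nan
    ppg_it: float = math.nan
    sbp: float = math.nan
    dbp: float = math.nan
    mbp: float = math.nan
    pp: float = math.nan
    pat_abp: float = math.nan
    pat_ppg: tuple = (math.nan,) * 4
    ptt: tuple = (math.nan,) * 4
    valid: bool = False
    reject_reason: str = ""

    def __post_init__(self) -> None:
        self.pat_ppg = tuple(float(v) for v in self.pat_ppg)
        self.ptt = tuple(float(v) for v in self.ptt)
        if len(self.pat_ppg) != 4 or len(self.ptt) != 4:
            raise ValueError("pat_ppg and ptt must each hold 4 values")
        if not is_valid_reason(self.reject_reason):
            raise ValueError(f"unknown reject_reason {self.reject_reason!r}")


BEAT_COLUMNS = (
    ["beat_index", "r_time"]
    + ["abp_peak", "abp_valley", "ppg_valley", "ppg_peak", "ppg_maxderiv", "ppg_it"]
    + list(BP_NAMES)
    + list(FEATURE_NAMES)
    + ["valid", "reject_reason"]
)


def _header_line(fmt: str) -> str:
    return f"# {fmt} v{FORMAT_VERSION}"


def _check_header(path: Path, fmt: str) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first != _header_line(fmt):
        raise RecordParseError(
            f"{path}: expected header {_header_line(fmt)!r}, found {first!r}"
        )


def _record_paths(path_stem) -> tuple[Path, Path]:
    stem = Path(path_stem)
    return stem.with_suffix(".csv"), stem.with_suffix(".json")


def write_record(record: WaveformRecord, path_stem) -> tuple[Path, Path]:
    """Write *record* as ``<stem>.csv`` + ``<stem>.json``; returns both paths."""
    csv_path, json_path = _record_paths(path_stem)
    sidecar = {
        "format": RECORD_FORMAT,
        "version": FORMAT_VERSION,
        "subject_id": record.subject_id,
        "fs": record.fs,
        "t0": record.t0,
        "n_samples": record.n_samples,
        "metadata": record.metadata,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    df = pd.DataFrame(
        {"t": record.times, "ecg": record.ecg, "ppg": record.ppg, "abp": record.abp}
    )
    with open(csv_path, "w") as fh:
        fh.write(_header_line(RECORD_FORMAT) + "\n")
        df.to_csv(fh, index=False)
    return csv_path, json_path


def read_record(path_stem) -> WaveformRecord:
    csv_path, json_path = _record_paths(path_stem)
    if not json_path.exists():
        raise RecordParseError(f"sidecar {json_path} absent")
    try:
        sidecar = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise RecordParseError(f"{json_path}: invalid JSON ({exc})") from exc
    for key in ("format", "version", "subject_id", "fs", "t0", "metadata"):
        if key not in sidecar:
            raise RecordParseError(f"{json_path}: field {key!r} absent")
    if sidecar["format"] != RECORD_FORMAT:
        raise RecordParseError(f"{json_path}: format {sidecar['format']!r} unknown")
    _check_header(csv_path, RECORD_FORMAT)
    df = pd.read_csv(csv_path, comment="#", float_precision="round_trip")
    for ch in CHANNELS:
        if ch not in df.columns:
            raise RecordParseError(f"{csv_path}: channel {ch} absent")
    return WaveformRecord(
        subject_id=str(sidecar["subject_id"]),
        fs=float(sidecar["fs"]),
        t0=float(sidecar["t0"]),
        ecg=df["ecg"].to_numpy(),
        ppg=df["ppg"].to_numpy(),
        abp=df["abp"].to_numpy(),
        metadata=dict(sidecar["metadata"]),
    )


def beats_to_frame(beats: Sequence[BeatFeatures]) -> pd.DataFrame:
    rows = []
    for b in beats:
        row = {
            "beat_index": b.beat_index,
            "r_time": b.r_time,
            "abp_peak": b.abp_peak,
            "abp_valley": b.abp_valley,
            "ppg_valley": b.ppg_valley,
            "ppg_peak": b.ppg_peak,
            "ppg_maxderiv": b.ppg_maxderiv,
            "ppg_it": b.ppg_it,
            "sbp": b.sbp,
            "dbp": b.dbp,
            "mbp": b.mbp,
            "pp": b.pp,
            "pat_abp": b.pat_abp,
            "valid": int(b.valid),
            "reject_reason": b.reject_reason,
        }
        for k in range(4):
            row[f"pat_ppg_{k + 1}"] = b.pat_ppg[k]
            row[f"ptt_{k + 1}"] = b.ptt[k]
        rows.append(row)
    return pd.DataFrame(rows, columns=BEAT_COLUMNS)


def frame_to_beats(df: pd.DataFrame) -> list[BeatFeatures]:
    beats = []
    for _, row in df.iterrows():
        reason = row["reject_reason"]
        reason = "" if (isinstance(reason, float) and math.isnan(reason)) else str(reason)
        if not is_valid_reason(reason):
            raise RecordParseError(f"unknown reject_reason token {reason!r}")
        beats.append(
            BeatFeatures(
                beat_index=int(row["beat_index"]),
                r_time=float(row["r_time"]),
                abp_peak=float(row["abp_peak"]),
                abp_valley=float(row["abp_valley"]),
                ppg_valley=float(row["ppg_valley"]),
                ppg_peak=float(row["ppg_peak"]),
                ppg_maxderiv=float(row["ppg_maxderiv"]),
                ppg_it=float(row["ppg_it"]),
                sbp=float(row["sbp"]),
                dbp=float(row["dbp"]),
                mbp=float(row["mbp"]),
                pp=float(row["pp"]),
                pat_abp=float(row["pat_abp"]),
                pat_ppg=tuple(float(row[f"pat_ppg_{k + 1}"]) for k in range(4)),
                ptt=tuple(float(row[f"ptt_{k + 1}"]) for k in range(4)),
                valid=bool(int(row["valid"])),
                reject_reason=reason,
            )
        )
    return beats


def write_beat_table(beats: Sequence[BeatFeatures], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line(BEAT_FORMAT) + "\n")
        beats_to_frame(beats).to_csv(fh, index=False)
    return path


def read_beat_table(path) -> list[BeatFeatures]:
    path = Path(path)
    _check_header(path, BEAT_FORMAT)
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(f"{path}: columns absent: {missing}")
    df["reject_reason"] = df["reject_reason"].astype(str).replace("nan", "")
    return frame_to_beats(df)


def write_ground_truth(frame: pd.DataFrame, path) -> Path:
    """Write a per-beat ground-truth table (one row per beat) with header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line(TRUTH_FORMAT) + "\n")
        frame.to_csv(fh, index=False)
    return path


def read_ground_truth(path) -> pd.DataFrame:
    path = Path(path)
    _check_header(path, TRUTH_FORMAT)
    return pd.read_csv(path, comment="#", float_precision="round_trip")
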