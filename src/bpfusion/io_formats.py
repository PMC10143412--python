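"""Record I/O and the core data model shared by all pipeline stages.

Waveform input comes either from WFDB-style header+signal pairs (the
layout used by the MIMIC-III waveform database) or from plain CSV
exports with ``ecg``/``ppg``(/``abp``) columns.  Feature tables are
round-tripped as RFC-4180 CSV with a fixed, documented column order.

Conventions (used everywhere in this package):

* all sample indices are 0-based; the time of index ``i`` is ``i / fs``
  seconds;
* gender is encoded numerically, male=1 / female=0 by default
  (override via :data:`GENDER_ENCODING`);
* a missing weight is carried as NaN, never as 0.
"""

from __future__ import annotations

import math
import re
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENDER_ENCODING",
    "SubjectInfo",
    "SignalRecord",
    "FormatError",
    "ChannelNotFoundError",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_csv_record",
    "write_csv_record",
    "write_feature_table",
    "read_feature_table",
]

#: numeric gender codes; overridable by assignment before reading metadata
GENDER_ENCODING: dict[str, int] = {"male": 1, "female": 0}

# case-insensitive channel aliases; MIMIC-III naming varies
ECG_ALIASES = {"ii", "ecg", "i", "iii", "mlii"}
PPG_ALIASES = {"pleth", "ppg"}
ABP_ALIASES = {"abp", "art", "bp"}


class FormatError(ValueError):
    """A record or table does not conform to the expected file format."""


class ChannelNotFoundError(FormatError):
    """A required channel is absent from a waveform record."""


@dataclass(frozen=True)
class SubjectInfo:
    """Per-subject metadata: id, encoded gender, age (years), weight (kg)."""

    subject_id: str
    gender: int
    age: int
    weight: float = math.nan

    def __post_init__(self) -> None:
        if self.gender not in set(GENDER_ENCODING.values()):
            raise ValueError(f"gender code {self.gender!r} not in {GENDER_ENCODING}")
        if not (self.age >= 0 and math.isfinite(self.age)):
            raise ValueError(f"age must be a finite non-negative number, got {self.age!r}")
        if not math.isnan(self.weight) and not (self.weight > 0 and math.isfinite(self.weight)):
            raise ValueError(f"weight must be positive and finite (or NaN), got {self.weight!r}")


@dataclass
class SignalRecord:
    """One synchronized ECG+PPG (+optional ABP) recording.

    ``ecg`` and ``ppg`` are equal-length sample sequences at sampling
    rate ``fs`` (Hz, nominal 125); ``abp`` when present is in mmHg and
    the same length.  ``sbp_ref``/``dbp_ref`` are optional reference
    pressures in mmHg.
    """

    ecg: np.ndarray
    ppg: np.ndarray
    fs: float
    subject: SubjectInfo
    abp: np.ndarray | None = None
    sbp_ref: float | None = None
    dbp_ref: float | None = None

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.ecg.ndim != 1 or self.ppg.ndim != 1:
            raise ValueError("ecg and ppg must be 1-D sample sequences")
        if len(self.ecg) != len(self.ppg):
            raise ValueError(
                f"ecg and ppg must be synchronous: {len(self.ecg)} vs {len(self.ppg)} samples"
            )
        if self.abp is not None:
            self.abp = np.asarray(self.abp, dtype=float)
            if len(self.abp) != len(self.ecg):
                raise ValueError("abp must have the same length as ecg/ppg")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.sbp_ref is not None and self.dbp_ref is not None:
            if not self.sbp_ref > self.dbp_ref:
                raise ValueError(
                    f"sbp_ref ({self.sbp_ref}) must exceed dbp_ref ({self.dbp_ref})"
                )

    def __len__(self) -> int:
        return len(self.ecg)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self.ecg) / self.fs

    def with_signals(self, *, ecg: np.ndarray | None = None,
                     ppg: np.ndarray | None = None) -> "SignalRecord":
        """Copy of the record with one or both channels replaced."""
        return replace(
            self,
            ecg=self.ecg if ecg is None else ecg,
            ppg=self.ppg if ppg is None else ppg,
        )


# ---------------------------------------------------------------------------
# WFDB header + signal reading (minimal, formats 16 / 80 / 212)
# ---------------------------------------------------------------------------

def _classify_channel(name: str) -> str | None:
    low = name.strip().lower()
    if low in ECG_ALIASES:
        return "ecg"
    if low in PPG_ALIASES:
        return "ppg"
    if low in ABP_ALIASES:
        return "abp"
    return None


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    adc_zero: int
    description: str


def _parse_header(header_path: Path) -> tuple[int, float, int, list[_SignalSpec]]:
    lines = [
        ln.strip() for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty WFDB header: {header_path}")
    rec = lines[0].split()
    if len(rec) < 2:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    n_sig = int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    specs: list[_SignalSpec] = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"malformed WFDB signal line: {ln!r}")
        fmt = int(re.match(r"\d+", parts[1]).group())  # strip xN / :N / +N suffixes
        gain, baseline, units = 200.0, 0, "adu"
        if len(parts) > 2:
            m = re.match(r"(-?[\d.]+)(?:\((-?\d+)\))?(?:/(\S+))?$", parts[2])
            if m:
                gain = float(m.group(1)) or 200.0
                baseline = int(m.group(2)) if m.group(2) else 0
                units = m.group(3) or "adu"
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if len(parts) > 2 and not (m and m.group(2)):
            baseline = adc_zero
        # description = everything past the fixed fields, else the filename
        desc = " ".join(parts[8:]) if len(parts) > 8 else parts[0]
        specs.append(_SignalSpec(parts[0], fmt, gain, baseline, units, adc_zero, desc))
    return n_sig, fs, n_samp, specs


def _read_dat(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """Return raw ADC values as an (n_samples, n_sig) int array."""
    raw = path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
    elif fmt == 80:
        data = np.frombuffer(raw, dtype=np.uint8).astype(np.int16) - 128
    elif fmt == 212:
        # 12-bit two's-complement pairs packed into 3 bytes
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (len(b) // 3)].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        data = np.empty(2 * len(b), dtype=np.int32)
        data[0::2] = np.where(first > 2047, first - 4096, first)
        data[1::2] = np.where(second > 2047, second - 4096, second)
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt}")
    n = (len(data) // n_sig) * n_sig
    return data[:n].reshape(-1, n_sig)


def read_wfdb_record(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    subject: SubjectInfo | None = None,
) -> SignalRecord:
    """Read a WFDB header+signal pair into a :class:`SignalRecord`.

    Parameters
    ----------
    path
        Path to the record, with or without the ``.hea`` extension.
    channel_map
        Optional mapping ``{"ecg": name, "ppg": name, "abp": name}``
        overriding the built-in case-insensitive aliases
        (II/ECG, PLETH/PPG, ABP/ART).
    subject
        Caller-supplied metadata (WFDB waveform headers carry none).

    Samples are converted to physical units via ``(adc - baseline) / gain``.
    Channels not selected by the map are ignored; the sampling rate is
    taken verbatim from the header (never resampled).
    """
    path = Path(path)
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    n_sig, fs, _, specs = _parse_header(header)

    roles: dict[str, int] = {}
    if channel_map:
        lower_map = {role: name.lower() for role, name in channel_map.items()}
        for i, s in enumerate(specs):
            for role, name in lower_map.items():
                if s.description.lower() == name:
                    roles[role] = i
    else:
        for i, s in enumerate(specs):
            role = _classify_channel(s.description)
            if role is not None and role not in roles:
                roles[role] = i

    available = [s.description for s in specs]
    for required in ("ecg", "ppg"):
        if required not in roles:
            raise ChannelNotFoundError(
                f"channel for {required!r} not found in {header.name}; "
                f"available channels: {available}"
            )

    files = {s.file_name for s in specs}
    if len(files) != 1:
        raise FormatError("multi-file WFDB records are not supported")
    fmt = specs[0].fmt
    data = _read_dat(header.with_name(files.pop()), fmt, n_sig)

    def physical(idx: int) -> np.ndarray:
        s = specs[idx]
        return (data[:, idx].astype(float) - s.baseline) / s.gain

    if subject is None:
        subject = SubjectInfo(subject_id=header.stem, gender=GENDER_ENCODING["male"], age=0)
    return SignalRecord(
        ecg=physical(roles["ecg"]),
        ppg=physical(roles["ppg"]),
        abp=physical(roles["abp"]) if "abp" in roles else None,
        fs=fs,
        subject=subject,
    )


def write_wfdb_record(record: SignalRecord, path: str | Path, gain: float = 200.0) -> None:
    """Write a record as a WFDB header + format-16 signal file (test/export aid)."""
    path = Path(path)
    channels = [("II", record.ecg), ("PLETH", record.ppg)]
    if record.abp is not None:
        channels.append(("ABP", record.abp))
    n = len(record.ecg)
    fs_str = f"{record.fs:g}"
    lines = [f"{path.stem} {len(channels)} {fs_str} {n}"]
    cols = []
    for name, sig in channels:
        adc = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
        cols.append(adc)
        lines.append(f"{path.stem}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0])} 0 0 {name}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    interleaved = np.column_stack(cols).reshape(-1)
    path.with_suffix(".dat").write_bytes(struct.pack(f"<{len(interleaved)}h", *interleaved))


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------

def read_csv_record(
    path: str | Path,
    fs: float | None = None,
    subject: SubjectInfo | None = None,
    max_gap_s: float = 1.0,
) -> SignalRecord:
    """Read a CSV waveform export with ``ecg``, ``ppg`` and optional ``abp`` columns.

    ``fs`` may be supplied by the caller or embedded as a header comment
    line ``# fs=125``.  A NaN run longer than ``max_gap_s`` seconds in any
    channel is rejected with a gap report naming the run's row span.
    """
    path = Path(path)
    if fs is None:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                m = re.search(r"fs\s*=\s*([\d.]+)", line)
                if m:
                    fs = float(m.group(1))
        if fs is None:
            raise FormatError(f"{path.name}: fs not supplied and no '# fs=' header comment")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("ecg", "ppg"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    for col in ("ecg", "ppg", "abp"):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path.name}: non-numeric value in column {col!r} at row {int(bad.idxmax())}"
            )
        gaps = _nan_runs(vals.to_numpy())
        for start, stop in gaps:
            if (stop - start) / fs > max_gap_s:
                raise FormatError(
                    f"{path.name}: NaN gap of {(stop - start) / fs:.2f} s in {col!r} "
                    f"(rows {start}-{stop - 1}) exceeds {max_gap_s} s"
                )
        df[col] = vals
    if subject is None:
        subject = SubjectInfo(subject_id=path.stem, gender=GENDER_ENCODING["male"], age=0)
    return SignalRecord(
        ecg=df["ecg"].to_numpy(float),
        ppg=df["ppg"].to_numpy(float),
        abp=df["abp"].to_numpy(float) if "abp" in df.columns else None,
        fs=fs,
        subject=subject,
    )


def _nan_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of consecutive NaNs."""
    isnan = np.isnan(x)
    if not isnan.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], isnan, [False])).astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def write_csv_record(record: SignalRecord, path: str | Path) -> None:
    """Write a record to CSV with an ``# fs=`` header comment."""
    path = Path(path)
    cols = {"ecg": record.ecg, "ppg": record.ppg}
    if record.abp is not None:
        cols["abp"] = record.abp
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _table_columns() -> list[str]:
    from .features import FEATURE_NAMES
    return ["subject_id", *FEATURE_NAMES, "sbp_ref", "dbp_ref", "n_beats_used"]


def write_feature_table(vectors: Sequence, path: str | Path) -> None:
    """Write feature vectors as CSV in the fixed documented column order.

    Missing values (e.g. an absent dicrotic-wave timing or weight) are
    serialized as empty cells.
    """
    rows = [v.as_row() for v in vectors]
    pd.DataFrame(rows, columns=_table_columns()).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_feature_table(path: str | Path):
    """Read a feature-table CSV back into a list of FeatureVector.

    The schema is name-keyed: column order does not matter, but an
    unknown column raises a schema error.
    """
    from .features import FeatureVector

    df = pd.read_csv(path, float_precision="round_trip")
    expected = set(_table_columns())
    unknown = set(df.columns) - expected
    if unknown:
        raise FormatError(f"unknown feature-table column(s): {sorted(unknown)}")
    missing = expected - set(df.columns)
    if missing:
        raise FormatError(f"feature table missing column(s): {sorted(missing)}")
    return [FeatureVector.from_row(row) for _, row in df.iterrows()]
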