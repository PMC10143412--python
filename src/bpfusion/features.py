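"""Per-beat feature computation and per-record aggregation.

Twenty-five named features are produced per record: three individual
features (Gender, Age, Weight) and twenty-two waveform features derived
from the paired ECG/PPG landmarks:

* pulse arrival times PATp / PATf / PATd (R peak to PPG peak / valley /
  maximum-slope point, seconds);
* timing: HR = 60*fs/RR (bpm), PP (peak-to-peak interval), AT / DT
  (ascending / descending branch times), PPT (first peak to dicrotic
  peak or inflection; may be missing per beat);
* intensity: PIRp = PI_peak/PI_valley, PIRmd = PI_maxslope/PI_valley,
  and the per-cycle mean / SD / max / min of the PPG intensity;
* the K value, K = (P_m - PI_v) / (PI_p - PI_v), with P_m the mean
  intensity over the cardiac cycle (discrete mean of the samples);
* morphology: ascending/descending slopes AS / DS, branch sums SA / SD,
  branch averages AA / AD, and the sum ratio SR = SA/SD.

Intensities are computed on a positively offset copy of the filtered
PPG: after mean subtraction the valley value can be non-positive, which
would break the PIR ratios and K; the record minimum is therefore mapped
to a floor of 0.25x the record's peak-to-peak range.  A range-
proportional floor keeps every intensity ratio invariant to amplitude
scaling, and K is affine-invariant by construction.

Each waveform feature of the record is the mean over beats that carry
it (beats lacking a dicrotic landmark simply do not contribute to PPT);
the median is available via ``aggregator="median"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fiducials import BeatFiducials, FiducialSet, delineate_record, extract_bp_labels
from .io_formats import SignalRecord, SubjectInfo

__all__ = [
    "FEATURE_NAMES",
    "WAVEFORM_FEATURES",
    "INDIVIDUAL_FEATURES",
    "FeatureVector",
    "compute_pat",
    "compute_hr",
    "compute_time_features",
    "compute_intensity_features",
    "compute_k",
    "compute_morphology",
    "beat_feature_rows",
    "aggregate_record",
    "extract_features",
]

INDIVIDUAL_FEATURES = ("Gender", "Age", "Weight")
WAVEFORM_FEATURES = (
    "PATp", "PATf", "PATd", "HR", "PP", "PPT",
    "PIRp", "PIRmd", "PIavg", "PIsd", "PImax", "PImin",
    "SA", "AA", "SD", "AD", "SR", "K", "AT", "DT", "AS", "DS",
)
#: the fixed 25-feature surface, in table order
FEATURE_NAMES = INDIVIDUAL_FEATURES + WAVEFORM_FEATURES

#: intensity floor as a fraction of the record's peak-to-peak PPG range
INTENSITY_FLOOR_FRAC = 0.25


@dataclass
class FeatureVector:
    """The 25 named features for one record, plus labels and provenance."""

    subject_id: str
    values: dict[str, float]
    sbp_ref: float = math.nan
    dbp_ref: float = math.nan
    n_beats_used: int = 0

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(
                f"feature vector must carry exactly the 25 named features; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update({k: self.values[k] for k in FEATURE_NAMES})
        row.update(sbp_ref=self.sbp_ref, dbp_ref=self.dbp_ref,
                   n_beats_used=self.n_beats_used)
        return row

    @classmethod
    def from_row(cls, row) -> "FeatureVector":
        return cls(
            subject_id=str(row["subject_id"]),
            values={k: float(row[k]) for k in FEATURE_NAMES},
            sbp_ref=float(row["sbp_ref"]),
            dbp_ref=float(row["dbp_ref"]),
            n_beats_used=int(row["n_beats_used"]),
        )


# ---------------------------------------------------------------------------
# Per-beat primitives
# ---------------------------------------------------------------------------

def compute_pat(beat: BeatFiducials, fs: float) -> tuple[float, float, float]:
    """(PATp, PATf, PATd) in seconds: R peak to PPG peak/valley/max-slope."""
    return (
        (beat.ppg_peak - beat.r_peak) / fs,
        (beat.ppg_valley - beat.r_peak) / fs,
        (beat.ppg_max_slope - beat.r_peak) / fs,
    )


def compute_hr(r_peaks: np.ndarray, fs: float) -> np.ndarray:
    """Per-beat heart rate HR_i = 60*fs / (r_{i+1} - r_i), beats/min."""
    r_peaks = np.asarray(r_peaks, dtype=float)
    if len(r_peaks) < 2:
        raise ValueError("need at least 2 R peaks for a heart rate")
    return 60.0 * fs / np.diff(r_peaks)


def compute_time_features(beats: FiducialSet) -> list[dict[str, float]]:
    """PP, AT, DT, PPT per beat (seconds); trailing beats lack PP/DT."""
    fs = beats.fs
    rows = []
    for i, b in enumerate(beats.beats):
        nxt = beats.beats[i + 1] if i + 1 < len(beats.beats) else None
        rows.append({
            "PP": (nxt.ppg_peak - b.ppg_peak) / fs if nxt else math.nan,
            "AT": (b.ppg_peak - b.ppg_valley) / fs,
            "DT": (nxt.ppg_valley - b.ppg_peak) / fs if nxt else math.nan,
            "PPT": (b.ppg_second_peak - b.ppg_peak) / fs
                   if b.ppg_second_peak is not None else math.nan,
        })
    return rows


def intensity_signal(ppg: np.ndarray, floor_frac: float = INTENSITY_FLOOR_FRAC) -> np.ndarray:
    """Strictly positive intensity version of the (filtered) PPG."""
    ppg = np.asarray(ppg, dtype=float)
    rng = float(np.max(ppg) - np.min(ppg))
    if rng <= 0:
        raise ValueError("constant PPG has no intensity structure")
    return ppg - np.min(ppg) + floor_frac * rng


def compute_intensity_features(
    pi: np.ndarray, beat: BeatFiducials, next_valley: int
) -> dict[str, float]:
    """PIRp, PIRmd, PIavg, PIsd, PImax, PImin over the cycle [valley, next_valley).

    ``pi`` is the strictly positive intensity signal; the SD uses the
    population (1/n) convention.
    """
    seg = pi[beat.ppg_valley:next_valley]
    if len(seg) == 0:
        raise ValueError("empty cardiac cycle")
    pi_v = pi[beat.ppg_valley]
    if pi_v <= 0:
        raise ValueError("non-positive valley intensity; beat rejected")
    return {
        "PIRp": pi[beat.ppg_peak] / pi_v,
        "PIRmd": pi[beat.ppg_max_slope] / pi_v,
        "PIavg": float(np.mean(seg)),
        "PIsd": float(np.std(seg)),
        "PImax": float(np.max(seg)),
        "PImin": float(np.min(seg)),
    }


def compute_k(pi: np.ndarray, beat: BeatFiducials, next_valley: int) -> float:
    """K = (P_m - PI_v) / (PI_p - PI_v); P_m is the cycle's mean intensity."""
    seg = pi[beat.ppg_valley:next_valley]
    pi_v, pi_p = pi[beat.ppg_valley], pi[beat.ppg_peak]
    if not pi_p > pi_v:
        raise ValueError("degenerate cycle: peak intensity does not exceed valley")
    p_m = float(np.mean(seg))
    return (p_m - pi_v) / (pi_p - pi_v)


def compute_morphology(
    pi: np.ndarray, beat: BeatFiducials, next_valley: int, fs: float
) -> dict[str, float]:
    """AS, DS, SA, AA, SD, AD, SR from the ascending/descending branches.

    Slopes are positive magnitudes (rise or fall per second); branch
    sums/averages use plain sample sums over the closed branches.
    """
    v, p = beat.ppg_valley, beat.ppg_peak
    at = (p - v) / fs
    dt = (next_valley - p) / fs
    if not (at > 0 and dt > 0):
        raise ValueError("branch times must be positive")
    asc = pi[v:p + 1]
    desc = pi[p:next_valley + 1]
    sa, sd = float(np.sum(asc)), float(np.sum(desc))
    return {
        "AS": (pi[p] - pi[v]) / at,
        "DS": (pi[p] - pi[next_valley]) / dt,
        "SA": sa,
        "AA": sa / len(asc),
        "SD": sd,
        "AD": sd / len(desc),
        "SR": sa / sd if sd != 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# Record-level assembly
# ---------------------------------------------------------------------------

def beat_feature_rows(ppg: np.ndarray, fiducials: FiducialSet) -> list[dict[str, float]]:
    """One row of the 22 waveform features per paired beat (NaN = missing)."""
    fs = fiducials.fs
    pi = intensity_signal(ppg)
    r_peaks = np.asarray([b.r_peak for b in fiducials.beats])
    hr = compute_hr(r_peaks, fs)
    time_rows = compute_time_features(fiducials)
    rows = []
    for i, b in enumerate(fiducials.beats):
        nxt = fiducials.beats[i + 1] if i + 1 < len(fiducials.beats) else None
        row = dict.fromkeys(WAVEFORM_FEATURES, math.nan)
        row["PATp"], row["PATf"], row["PATd"] = compute_pat(b, fs)
        row["HR"] = float(hr[i]) if i < len(hr) else math.nan
        row.update({k: time_rows[i][k] for k in ("PP", "AT", "DT", "PPT")})
        if nxt is not None:
            next_valley = nxt.ppg_valley
            try:
                row.update(compute_intensity_features(pi, b, next_valley))
                row["K"] = compute_k(pi, b, next_valley)
                row.update(compute_morphology(pi, b, next_valley, fs))
            except ValueError:
                pass  # degenerate cycle: beat contributes timing features only
        rows.append(row)
    return rows


def aggregate_record(
    rows: list[dict[str, float]],
    subject: SubjectInfo,
    sbp_ref: float = math.nan,
    dbp_ref: float = math.nan,
    aggregator: str = "mean",
) -> FeatureVector:
    """Reduce per-beat rows to one :class:`FeatureVector`.

    Each waveform feature is the mean (or median) over the beats that
    carry it; a feature missing in every beat stays NaN (flagged, never
    zero-filled).  Fewer than 2 valid beats rejects the record.
    """
    if len(rows) < 2:
        raise ValueError(f"record rejected: only {len(rows)} valid beat(s)")
    reduce = np.nanmedian if aggregator == "median" else np.nanmean
    values: dict[str, float] = {
        "Gender": float(subject.gender),
        "Age": float(subject.age),
        "Weight": float(subject.weight),
    }
    for name in WAVEFORM_FEATURES:
        col = np.asarray([r[name] for r in rows], dtype=float)
        values[name] = float(reduce(col)) if not np.all(np.isnan(col)) else math.nan
    return FeatureVector(
        subject_id=subject.subject_id,
        values=values,
        sbp_ref=sbp_ref,
        dbp_ref=dbp_ref,
        n_beats_used=len(rows),
    )


def extract_features(
    record: SignalRecord,
    fiducials: FiducialSet | None = None,
    aggregator: str = "mean",
) -> FeatureVector:
    """Full per-record extraction: landmarks -> beat rows -> aggregate.

    Labels come from ``record.sbp_ref``/``dbp_ref`` when set, else from
    the ABP channel when present.
    """
    if fiducials is None:
        fiducials = delineate_record(record)
    rows = beat_feature_rows(record.ppg, fiducials)
    sbp, dbp = record.sbp_ref, record.dbp_ref
    if (sbp is None or dbp is None) and record.abp is not None:
        sbp, dbp = extract_bp_labels(record.abp, record.fs)
    return aggregate_record(
        rows, record.subject,
        sbp_ref=math.nan if sbp is None else sbp,
        dbp_ref=math.nan if dbp is None else dbp,
        aggregator=aggregator,
    )
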