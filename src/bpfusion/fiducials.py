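"""Beat landmark detection on ECG, PPG and ABP channels.

Per beat the pipeline needs four landmarks: the ECG R peak, and on the
PPG pulse its valley (onset/foot), maximum-slope point on the systolic
upstroke, and systolic peak; plus the dicrotic second peak or descending
inflection when the pulse contour shows one.  R peaks come from the
Pan-Tompkins detector; PPG peaks from a double-threshold scheme (an
adaptive amplitude threshold plus a minimum peak separation); valleys
and slopes from first-difference zero crossings and argmax.

The valley is located by searching backward in time from each peak over
0.4 peak intervals for the first-difference zero crossing from negative
to positive nearest the peak (the pulse foot precedes the peak).

Beats are paired across channels by matching each R peak to the first
PPG valley within 0.6 s; pulse-arrival times outside the physiological
[0.05, 0.6] s band are rejected and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .io_formats import SignalRecord

__all__ = [
    "BeatFiducials",
    "FiducialSet",
    "InsufficientBeatsError",
    "detect_r_peaks",
    "detect_ppg_peaks",
    "detect_valley",
    "detect_max_slope",
    "detect_second_peak",
    "pair_beats",
    "extract_bp_labels",
    "delineate_record",
]

#: pairing window (s) between an R peak and its PPG valley
PAIRING_WINDOW_S = 0.6
#: physiological plausibility band for pulse arrival time (s)
PAT_RANGE_S = (0.05, 0.6)


class InsufficientBeatsError(ValueError):
    """Fewer beats than the operation needs were detected."""


@dataclass(frozen=True)
class BeatFiducials:
    """Landmark sample indices for one paired beat (0-based)."""

    r_peak: int
    ppg_valley: int
    ppg_max_slope: int
    ppg_peak: int
    ppg_second_peak: int | None = None
    next_r_peak: int | None = None

    def __post_init__(self) -> None:
        if not (self.r_peak <= self.ppg_valley < self.ppg_max_slope < self.ppg_peak):
            raise ValueError(
                f"fiducial ordering violated: R={self.r_peak}, valley={self.ppg_valley}, "
                f"max_slope={self.ppg_max_slope}, peak={self.ppg_peak}"
            )
        if self.ppg_second_peak is not None and not self.ppg_second_peak > self.ppg_peak:
            raise ValueError("second peak must follow the systolic peak")


@dataclass
class FiducialSet:
    """Ordered paired beats for one record plus the rejection count."""

    beats: list[BeatFiducials]
    fs: float
    n_rejected: int = 0

    def __post_init__(self) -> None:
        rs = [b.r_peak for b in self.beats]
        if sorted(set(rs)) != rs:
            raise ValueError("beats must be sorted by r_peak with no duplicates")

    def __len__(self) -> int:
        return len(self.beats)


# ---------------------------------------------------------------------------
# ECG: Pan-Tompkins
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins R-peak detection on a pre-filtered ECG.

    Stages: five-point derivative, squaring, 150 ms moving-window
    integration, adaptive dual thresholds with a 200 ms refractory
    period and search-back, then refinement of each decision to the
    local ECG maximum (upright R assumed, as in lead II).
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz for R detection, got {fs}")
    if len(ecg) < int(fs):
        raise InsufficientBeatsError("record too short for R detection")

    kern = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    deriv = np.convolve(ecg, kern, mode="same")
    squared = deriv ** 2
    w = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(w) / w, mode="same")

    refractory = int(round(0.200 * fs))
    candidates, _ = sps.find_peaks(mwi, distance=refractory)
    if len(candidates) == 0:
        raise InsufficientBeatsError("insufficient beats: no integrated peaks found")

    head = mwi[: int(2 * fs)]
    spki = float(np.max(head)) / 3.0
    npki = float(np.mean(head)) / 2.0
    accepted: list[int] = []
    rr_hist: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < len(candidates):
        p = candidates[i]
        if mwi[p] > threshold1():
            accepted.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(accepted) >= 2:
                rr_hist.append(accepted[-1] - accepted[-2])
                rr_hist = rr_hist[-8:]
        else:
            # search-back: a long gap since the last beat re-examines the
            # strongest skipped candidate at half threshold
            rr_avg = np.mean(rr_hist) if rr_hist else fs
            if accepted and p - accepted[-1] > 1.66 * rr_avg:
                gap = [c for c in candidates if accepted[-1] < c <= p]
                if gap:
                    best = max(gap, key=lambda c: mwi[c])
                    if mwi[best] > threshold1() / 2:
                        accepted.append(int(best))
                        accepted.sort()
                        spki = 0.25 * mwi[best] + 0.75 * spki
            npki = 0.125 * mwi[p] + 0.875 * npki
        i += 1

    # refine each decision to the local ECG maximum; the integrated peak
    # sits within half an integration window (+25 ms slack) of R
    half = w // 2 + int(round(0.025 * fs))
    refined: list[int] = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(int(lo + np.argmax(ecg[lo:hi])))
    refined = sorted(set(refined))
    # enforce the refractory on refined indices, larger R survives
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if ecg[p] > ecg[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    if len(out) < 2:
        raise InsufficientBeatsError(f"insufficient beats: {len(out)} R peak(s) detected")
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# PPG: double-threshold peak detection
# ---------------------------------------------------------------------------

def detect_ppg_peaks(
    ppg: np.ndarray,
    fs: float,
    theta_amp: float = 0.5,
    min_separation_s: float = 0.4,
    window_s: float = 5.0,
) -> np.ndarray:
    """Double-threshold systolic peak detection.

    A candidate is a local maximum exceeding an adaptive amplitude
    threshold (``theta_amp`` of the rolling ``window_s`` max-min range
    above the rolling minimum); among candidates closer than
    ``min_separation_s`` the larger survives.  Flat input yields an
    empty list.
    """
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) == 0:
        return np.asarray([], dtype=int)
    w = max(3, int(round(window_s * fs)) | 1)
    rmax = maximum_filter1d(ppg, w, mode="nearest")
    rmin = minimum_filter1d(ppg, w, mode="nearest")
    rng = rmax - rmin
    if np.max(rng) <= 1e-12 * max(1.0, np.max(np.abs(ppg))):
        return np.asarray([], dtype=int)
    thresh = rmin + theta_amp * rng

    cand, _ = sps.find_peaks(ppg)
    cand = cand[ppg[cand] >= thresh[cand]]
    if len(cand) == 0:
        return np.asarray([], dtype=int)

    sep = int(round(min_separation_s * fs))
    # greedy by amplitude: the larger of two close candidates survives
    order = cand[np.argsort(-ppg[cand], kind="stable")]
    kept: list[int] = []
    for p in order:
        if all(abs(p - q) >= sep for q in kept):
            kept.append(int(p))
    return np.asarray(sorted(kept), dtype=int)


def _local_peak_interval(peaks: np.ndarray, i: int, fs: float) -> int:
    """Local peak-to-peak interval (samples) around peak ``i``."""
    if len(peaks) < 2:
        return int(round(fs))  # fall back to a 1-s nominal beat
    if i == 0:
        return int(peaks[1] - peaks[0])
    return int(peaks[i] - peaks[i - 1])


def detect_valley(ppg: np.ndarray, fs: float, peak: int, peak_interval: int) -> int:
    """Pulse-onset (foot) detection for the beat ending at ``peak``.

    Searches backward in time from the peak over a window of
    0.4 x ``peak_interval`` samples for the first-difference zero
    crossing from negative to positive nearest the peak; if the window
    holds no sign change, its minimum-value index is returned.
    """
    ppg = np.asarray(ppg, dtype=float)
    window = max(1, int(round(0.4 * peak_interval)))
    start = peak - window
    if start < 0:
        raise ValueError("valley search window extends before the record start")
    d = np.diff(ppg)
    # d[j] = ppg[j+1] - ppg[j]; a valley at v has d[v-1] <= 0 < d[v]
    for v in range(peak - 1, start, -1):
        if d[v] > 0 and d[v - 1] <= 0:
            return v
    return int(start + np.argmin(ppg[start:peak + 1]))


def detect_max_slope(ppg: np.ndarray, valley: int, peak: int) -> int:
    """Maximum-slope point on the systolic upstroke.

    Argmax of the first difference over [valley, peak); the earliest
    index wins on ties.
    """
    if not valley < peak:
        raise ValueError(f"invalid beat: valley ({valley}) must precede peak ({peak})")
    d = np.diff(np.asarray(ppg, dtype=float)[valley:peak + 1])
    return int(valley + np.argmax(d))


def detect_second_peak(
    ppg: np.ndarray, fs: float, peak: int, next_valley: int
) -> int | None:
    """Dicrotic second peak or descending-branch inflection, if any.

    On the descending branch [peak, next_valley]: the largest interior
    local maximum (dicrotic peak) if one exists; otherwise the first
    zero crossing of the second difference from negative to positive
    after the peak (inflection); otherwise None.
    """
    ppg = np.asarray(ppg, dtype=float)
    if next_valley - peak < 3:
        return None
    branch = ppg[peak:next_valley + 1]
    maxima, _ = sps.find_peaks(branch)
    if len(maxima):
        best = maxima[np.argmax(branch[maxima])]
        return int(peak + best)
    # second difference at i: ppg[i-1] - 2 ppg[i] + ppg[i+1]
    for i in range(max(peak + 1, 2), next_valley):
        sd = ppg[i - 1] - 2 * ppg[i] + ppg[i + 1]
        sd_prev = ppg[i - 2] - 2 * ppg[i - 1] + ppg[i]
        if sd_prev < 0 and sd >= 0:
            return int(i)
    return None


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_beats(
    r_peaks: np.ndarray,
    ppg_peaks: np.ndarray,
    ppg_valleys: np.ndarray,
    fs: float,
    ppg: np.ndarray | None = None,
) -> FiducialSet:
    """Pair each R peak with its PPG pulse into a :class:`FiducialSet`.

    ``ppg_valleys`` is parallel to ``ppg_peaks`` (one onset per pulse).
    An R peak is matched with the earliest valley in
    (r, r + 0.6 s]; beats with a second R before the matched valley, a
    pulse-arrival time outside [0.05, 0.6] s, or a violated landmark
    ordering are rejected and counted.  ``ppg`` (the waveform) is needed
    to place the maximum-slope and dicrotic landmarks.
    """
    if ppg is None:
        raise ValueError("pair_beats needs the ppg waveform to locate the max-slope point")
    r_peaks = np.asarray(r_peaks, dtype=int)
    ppg_peaks = np.asarray(ppg_peaks, dtype=int)
    ppg_valleys = np.asarray(ppg_valleys, dtype=int)
    if len(ppg_peaks) != len(ppg_valleys):
        raise ValueError("ppg_peaks and ppg_valleys must be parallel lists")

    window = int(round(PAIRING_WINDOW_S * fs))
    lo_pat, hi_pat = (int(round(PAT_RANGE_S[0] * fs)), int(round(PAT_RANGE_S[1] * fs)))
    beats: list[BeatFiducials] = []
    n_rejected = 0
    for k, r in enumerate(r_peaks):
        next_r = int(r_peaks[k + 1]) if k + 1 < len(r_peaks) else None
        in_win = np.flatnonzero((ppg_valleys > r) & (ppg_valleys <= r + window))
        if len(in_win) == 0:
            n_rejected += 1
            continue
        j = int(in_win[0])
        v, p = int(ppg_valleys[j]), int(ppg_peaks[j])
        if next_r is not None and next_r < v:
            n_rejected += 1
            continue
        pat = v - r
        if not (lo_pat <= pat <= hi_pat):
            n_rejected += 1
            continue
        try:
            ms = detect_max_slope(ppg, v, p)
            if not v < ms < p:
                # degenerate upstroke (slope maximal at an endpoint)
                ms = min(max(v + 1, ms), p - 1)
            next_v = int(ppg_valleys[j + 1]) if j + 1 < len(ppg_valleys) else len(ppg) - 1
            sp = detect_second_peak(ppg, fs, p, next_v)
            beats.append(BeatFiducials(int(r), v, int(ms), p, sp, next_r))
        except ValueError:
            n_rejected += 1
    if len(beats) < 2:
        raise InsufficientBeatsError(
            f"insufficient paired beats: {len(beats)} paired, {n_rejected} rejected"
        )
    return FiducialSet(beats=beats, fs=fs, n_rejected=n_rejected)


def delineate_record(record: SignalRecord) -> FiducialSet:
    """Full landmark detection for a preprocessed record."""
    r_peaks = detect_r_peaks(record.ecg, record.fs)
    peaks = detect_ppg_peaks(record.ppg, record.fs)
    valleys, kept_peaks = [], []
    for i, p in enumerate(peaks):
        interval = _local_peak_interval(peaks, i, record.fs)
        try:
            valleys.append(detect_valley(record.ppg, record.fs, int(p), interval))
            kept_peaks.append(int(p))
        except ValueError:
            continue
    return pair_beats(r_peaks, np.asarray(kept_peaks), np.asarray(valleys),
                      record.fs, ppg=record.ppg)


# ---------------------------------------------------------------------------
# ABP labels
# ---------------------------------------------------------------------------

def extract_bp_labels(
    abp: np.ndarray, fs: float, stat: str = "mean", min_duration_s: float = 10.0
) -> tuple[float, float]:
    """Reference SBP/DBP from an arterial-pressure segment.

    Per-beat systolic peaks and diastolic valleys are located with the
    same double-threshold scheme used for PPG; SBP and DBP are the
    ``stat`` (mean, or median via config) of the per-beat peak and
    valley pressures.  A pulse pressure below 10 mmHg is rejected as
    implausible.
    """
    abp = np.asarray(abp, dtype=float)
    if len(abp) / fs < min_duration_s:
        raise ValueError(f"ABP segment shorter than {min_duration_s} s")
    peaks = detect_ppg_peaks(abp, fs)
    if len(peaks) < 2:
        raise ValueError("unusable ABP: no pulsatile activity detected")
    valleys = []
    for i, p in enumerate(peaks):
        interval = _local_peak_interval(peaks, i, fs)
        try:
            valleys.append(detect_valley(abp, fs, int(p), interval))
        except ValueError:
            continue
    if len(valleys) < 2:
        raise ValueError("unusable ABP: valleys not detectable")
    reduce = np.median if stat == "median" else np.mean
    sbp = float(reduce(abp[peaks]))
    dbp = float(reduce(abp[np.asarray(valleys)]))
    if sbp - dbp < 10:
        raise ValueError(
            f"unusable ABP: pulse pressure {sbp - dbp:.1f} mmHg is implausibly low"
        )
    return sbp, dbp
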