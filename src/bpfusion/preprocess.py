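"""Denoising of ECG and PPG channels.

ECG: mean removal, then a 4th-order zero-phase Butterworth low-pass at
35 Hz (high-frequency noise incl. mains), then a 2nd-order zero-phase
high-pass at 0.9 Hz (baseline wander).  PPG: mean removal and a
zero-phase low-pass at 10 Hz, followed by cubic-spline baseline removal
anchored at the pulse onsets.

All filters are applied forward-backward (``filtfilt``) so landmarks
are not phase-shifted; the stated order is the one-pass design order,
so the effective attenuation is doubled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io_formats import SignalRecord

__all__ = [
    "FilterSpec",
    "DEFAULT_CONFIG",
    "filter_ecg",
    "filter_ppg_lowpass",
    "remove_baseline_spline",
    "preprocess_record",
]

logger = logging.getLogger(__name__)

#: overridable cut-offs and orders for the denoising chain
DEFAULT_CONFIG = {
    "ecg.lowpass_hz": 35.0,
    "ecg.highpass_hz": 0.9,
    "ecg.lowpass_order": 4,
    "ecg.highpass_order": 2,
    "ppg.lowpass_hz": 10.0,
    "ppg.lowpass_order": 4,
}


@dataclass(frozen=True)
class FilterSpec:
    """One zero-phase Butterworth stage."""

    kind: str  # {"lowpass", "highpass"}
    order: int
    cutoff_hz: float
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not 1 <= self.order <= 8:
            raise ValueError(f"order must be in 1..8, got {self.order}")
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")

    def apply(self, x: np.ndarray, fs: float) -> np.ndarray:
        if not self.cutoff_hz < fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is not below Nyquist ({fs / 2} Hz)"
            )
        sos = sps.butter(self.order, self.cutoff_hz, btype=self.kind, fs=fs, output="sos")
        # odd-symmetric extension of 3x the section length removes startup transients
        padlen = min(len(x) - 1, 3 * 6 * len(sos))
        if len(x) <= 3 * (2 * self.order + 1):
            raise ValueError(
                f"record too short ({len(x)} samples) for zero-phase order-{self.order} filtering"
            )
        if self.zero_phase:
            return sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)
        return sps.sosfilt(sos, x)


def filter_ecg(record: SignalRecord, config: dict | None = None) -> SignalRecord:
    """Return a copy of ``record`` with the ECG channel denoised.

    Pipeline: subtract mean -> 4th-order zero-phase low-pass (35 Hz)
    -> 2nd-order zero-phase high-pass (0.9 Hz).  Output length equals
    input length and the output mean is ~0.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if not record.fs > 2 * cfg["ecg.lowpass_hz"]:
        raise ValueError(
            f"fs={record.fs} Hz too low for a {cfg['ecg.lowpass_hz']} Hz low-pass"
        )
    x = record.ecg - np.mean(record.ecg)
    x = FilterSpec("lowpass", int(cfg["ecg.lowpass_order"]), cfg["ecg.lowpass_hz"]).apply(x, record.fs)
    x = FilterSpec("highpass", int(cfg["ecg.highpass_order"]), cfg["ecg.highpass_hz"]).apply(x, record.fs)
    return record.with_signals(ecg=x)


def filter_ppg_lowpass(record: SignalRecord, config: dict | None = None) -> SignalRecord:
    """Return a copy of ``record`` with PPG mean-subtracted and low-passed at 10 Hz."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if not record.fs > 2 * cfg["ppg.lowpass_hz"]:
        raise ValueError(
            f"fs={record.fs} Hz too low for a {cfg['ppg.lowpass_hz']} Hz low-pass"
        )
    x = record.ppg - np.mean(record.ppg)
    x = FilterSpec("lowpass", int(cfg["ppg.lowpass_order"]), cfg["ppg.lowpass_hz"]).apply(x, record.fs)
    return record.with_signals(ppg=x)


def remove_baseline_spline(ppg: np.ndarray, anchors: np.ndarray, fs: float) -> np.ndarray:
    """Subtract a natural cubic spline through (anchor, value) pairs.

    The anchors are typically the detected pulse-onset (valley) indices,
    which track the slowly varying baseline by construction.  The spline
    is evaluated at every sample (linear extrapolation outside the
    anchor span) and subtracted, so the output is ~0 at each anchor.

    With fewer than 4 anchors a natural cubic spline is underdetermined;
    a linear trend through the anchors is subtracted instead, with a
    logged warning.
    """
    ppg = np.asarray(ppg, dtype=float)
    anchors = np.asarray(anchors, dtype=int)
    if np.any(np.diff(anchors) <= 0):
        raise ValueError("anchor indices must be strictly increasing")
    t = np.arange(len(ppg))
    if len(anchors) < 4:
        logger.warning(
            "only %d baseline anchors; falling back to linear-trend removal", len(anchors)
        )
        if len(anchors) >= 2:
            coef = np.polyfit(anchors, ppg[anchors], 1)
            baseline = np.polyval(coef, t)
        else:
            baseline = np.full_like(ppg, ppg[anchors[0]] if len(anchors) else np.mean(ppg))
        return ppg - baseline
    spline = CubicSpline(anchors, ppg[anchors], bc_type="natural", extrapolate=False)
    baseline = spline(t)
    # linear extrapolation beyond the anchor span
    lo, hi = anchors[0], anchors[-1]
    if lo > 0:
        slope = spline(lo, 1)
        baseline[:lo] = ppg[lo] + slope * (t[:lo] - lo)
    if hi < len(ppg) - 1:
        slope = spline(hi, 1)
        baseline[hi + 1:] = ppg[hi] + slope * (t[hi + 1:] - hi)
    return ppg - baseline


def preprocess_record(record: SignalRecord, config: dict | None = None) -> SignalRecord:
    """Full denoising chain for one record.

    ECG is filtered as in :func:`filter_ecg`.  PPG is low-passed, a
    first coarse valley pass supplies spline anchors at the pulse
    onsets, and the spline baseline is subtracted.
    """
    from .fiducials import detect_ppg_peaks, detect_valley, _local_peak_interval

    rec = filter_ecg(record, config)
    rec = filter_ppg_lowpass(rec, config)
    peaks = detect_ppg_peaks(rec.ppg, rec.fs)
    if len(peaks) >= 2:
        anchors = []
        for i, p in enumerate(peaks):
            interval = _local_peak_interval(peaks, i, rec.fs)
            try:
                anchors.append(detect_valley(rec.ppg, rec.fs, p, interval))
            except ValueError:
                continue
        anchors = np.unique(anchors)
        if len(anchors) >= 2:
            rec = rec.with_signals(ppg=remove_baseline_spline(rec.ppg, anchors, rec.fs))
    return rec
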