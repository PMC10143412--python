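"""Synthetic paired ECG+PPG(+ABP) records and cohorts with known truth.

Every pipeline stage is testable without external data:

* :func:`generate_record` builds one 30-s, 125-Hz record.  The ECG is a
  per-beat sum of three Gaussian waves (P, QRS, T) at jittered beat
  times; the PPG pulse is a raised-cosine systolic upstroke starting
  exactly at the pulse onset (each R time plus the true pulse-arrival
  time), an exponential diastolic decay, and a scaled, delayed dicrotic
  Gaussian — the raised-cosine ascent leaves a sharp, well-defined foot
  at the onset, so the foot-PAT of the waveform matches the configured
  ``pat_s``.  Both channels then receive sinusoidal baseline drift and
  white noise.  The returned truth lists every landmark to sample
  precision, measured on the clean (drift- and noise-free) waveforms.
* :func:`generate_cohort` draws a multi-subject cohort whose SBP/DBP
  labels follow a known generating function
  ``SBP = b0 + b1/PAT + b2*HR + b3*Age + subject_offset + eps``
  (DBP analogous) — shorter transit means higher pressure, and the
  inverse-PAT term gives the relation a nonlinearity a forest can
  exploit.
* :func:`generate_feature_cohort` draws the same latent cohort but
  emits the 25-feature table directly from the latent truth (plus
  optional pure-noise distractor columns), skipping waveform synthesis;
  it backs the multi-seed selection and calibration experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import FEATURE_NAMES, FeatureVector
from .io_formats import SignalRecord, SubjectInfo

__all__ = [
    "GeneratorConfig",
    "CohortConfig",
    "RecordTruth",
    "generate_record",
    "generate_cohort",
    "generate_feature_cohort",
    "feature_frame_to_vectors",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """One-record generator settings (times in s, rates in Hz/bpm)."""

    fs: float = 125.0
    duration_s: float = 30.0
    hr_bpm: float = 75.0
    hr_jitter_bpm: float = 2.0
    pat_s: float = 0.25
    pat_jitter_s: float = 0.005
    # PPG pulse shape
    rise_s: float = 0.20            # onset -> systolic apex (systolic width)
    decay_tau_s: float = 0.18       # diastolic exponential decay constant
    dicrotic_frac: float = 0.25     # dicrotic amplitude / systolic amplitude
    dicrotic_delay_s: float = 0.25  # systolic apex -> dicrotic apex
    dicrotic_width_s: float = 0.07
    # ECG wave shape (amplitude, Gaussian width, offset from R)
    p_amp: float = 0.15
    p_width_s: float = 0.03
    p_offset_s: float = -0.18
    qrs_amp: float = 1.0
    qrs_width_s: float = 0.018
    t_amp: float = 0.30
    t_width_s: float = 0.07
    t_offset_s: float = 0.28
    # disturbances
    drift_freq_hz: float = 0.30
    ecg_drift_amp: float = 0.20
    ppg_drift_amp: float = 0.30
    ecg_noise_sd: float = 0.02
    ppg_noise_sd: float = 0.01
    ecg_snr_db: float | None = None  # overrides ecg_noise_sd when set
    ppg_snr_db: float | None = None
    # optional ABP channel
    include_abp: bool = False
    sbp_mmhg: float = 120.0
    dbp_mmhg: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30 < self.hr_bpm < 200:
            raise ValueError(f"hr_bpm must be in (30, 200), got {self.hr_bpm}")
        if not 0.05 < self.pat_s < 0.6:
            raise ValueError(f"pat_s must be in (0.05, 0.6), got {self.pat_s}")
        for name in ("hr_jitter_bpm", "pat_jitter_s", "ecg_noise_sd", "ppg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.include_abp and not self.sbp_mmhg > self.dbp_mmhg:
            raise ValueError("sbp_mmhg must exceed dbp_mmhg")


@dataclass
class RecordTruth:
    """Per-beat ground-truth landmarks (sample indices) and latents."""

    fs: float
    beat_times_s: np.ndarray
    r_idx: np.ndarray
    valley_idx: np.ndarray
    max_slope_idx: np.ndarray
    peak_idx: np.ndarray
    second_peak_idx: list[int | None]
    pat_s: np.ndarray   # (valley - R)/fs per beat
    hr_bpm: np.ndarray  # per-beat, from consecutive R intervals

    def __len__(self) -> int:
        return len(self.r_idx)


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _pulse(tau: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """One PPG pulse as a function of time since onset.

    Zero before the onset; raised-cosine ascent to the systolic apex at
    ``rise_s``; exponential diastolic decay after; plus the dicrotic
    Gaussian.  The foot (value 0, slope 0) sits exactly at tau = 0.
    """
    rise = cfg.rise_s
    sys_wave = np.where(
        tau < 0, 0.0,
        np.where(
            tau <= rise,
            0.5 * (1.0 - np.cos(np.pi * np.clip(tau, 0, rise) / rise)),
            np.exp(-np.clip(tau - rise, 0, None) / cfg.decay_tau_s),
        ),
    )
    dic = cfg.dicrotic_frac * _gauss(tau, rise + cfg.dicrotic_delay_s, cfg.dicrotic_width_s)
    return sys_wave + np.where(tau < 0, 0.0, dic)


def generate_record(
    config: GeneratorConfig | None = None,
    subject: SubjectInfo | None = None,
) -> tuple[SignalRecord, RecordTruth]:
    """Build one synthetic record plus its ground truth."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration_s))
    t = np.arange(n) / cfg.fs

    # jittered beat schedule with lead-in/out margins so every pulse fits
    beat_times: list[float] = []
    tb = 0.35
    while tb < cfg.duration_s - 0.9:
        beat_times.append(tb)
        hr_i = np.clip(cfg.hr_bpm + rng.normal(0, cfg.hr_jitter_bpm), 31, 199)
        tb += 60.0 / hr_i
    beats = np.asarray(beat_times)
    pats = np.clip(cfg.pat_s + rng.normal(0, cfg.pat_jitter_s, len(beats)), 0.06, 0.58)

    ecg = np.zeros(n)
    ppg = np.zeros(n)
    for tb_i, pat_i in zip(beats, pats):
        ecg += cfg.p_amp * _gauss(t, tb_i + cfg.p_offset_s, cfg.p_width_s)
        ecg += cfg.qrs_amp * _gauss(t, tb_i, cfg.qrs_width_s)
        ecg += cfg.t_amp * _gauss(t, tb_i + cfg.t_offset_s, cfg.t_width_s)
        ppg += _pulse(t - (tb_i + pat_i), cfg)

    truth = _truth_from_clean(ecg, ppg, beats, pats, cfg)

    def _noise_sd(clean: np.ndarray, sd: float, snr_db: float | None) -> float:
        if snr_db is None:
            return sd
        rms = float(np.sqrt(np.mean((clean - np.mean(clean)) ** 2)))
        return rms * 10.0 ** (-snr_db / 20.0)

    drift = np.sin(2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi))
    ecg_out = ecg + cfg.ecg_drift_amp * drift \
        + rng.normal(0, _noise_sd(ecg, cfg.ecg_noise_sd, cfg.ecg_snr_db), n)
    drift2 = np.sin(2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi))
    ppg_out = ppg + cfg.ppg_drift_amp * drift2 \
        + rng.normal(0, _noise_sd(ppg, cfg.ppg_noise_sd, cfg.ppg_snr_db), n)

    abp = None
    if cfg.include_abp:
        rngp = np.ptp(ppg)
        abp = cfg.dbp_mmhg + (cfg.sbp_mmhg - cfg.dbp_mmhg) * (ppg - np.min(ppg)) / rngp

    if subject is None:
        subject = SubjectInfo(subject_id=f"synthetic-{cfg.seed}", gender=1, age=30, weight=70.0)
    record = SignalRecord(
        ecg=ecg_out, ppg=ppg_out, abp=abp, fs=cfg.fs, subject=subject,
        sbp_ref=cfg.sbp_mmhg if cfg.include_abp else None,
        dbp_ref=cfg.dbp_mmhg if cfg.include_abp else None,
    )
    return record, truth


def _truth_from_clean(
    ecg: np.ndarray, ppg: np.ndarray, beats: np.ndarray, pats: np.ndarray,
    cfg: GeneratorConfig
) -> RecordTruth:
    """Locate every landmark numerically on the clean waveforms."""
    fs, n = cfg.fs, len(ecg)
    half = int(round(0.06 * fs))
    r_idx = []
    for tb in beats:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        r_idx.append(lo + int(np.argmax(ecg[lo:hi])))
    r_idx = np.asarray(r_idx, dtype=int)

    peak_idx = []
    for tb, pat_i in zip(beats, pats):
        apex = tb + pat_i + cfg.rise_s
        lo = max(0, int(round((apex - 0.08) * fs)))
        hi = min(n, int(round((apex + 0.08) * fs)))
        peak_idx.append(lo + int(np.argmax(ppg[lo:hi])))
    peak_idx = np.asarray(peak_idx, dtype=int)

    valley_idx = []
    for k, p in enumerate(peak_idx):
        lo = peak_idx[k - 1] if k > 0 else max(0, p - int(round(0.6 * fs)))
        w = ppg[lo:p + 1]
        # last index attaining the minimum: on a flat lead-in the foot is
        # the final zero sample before the upstroke
        mn = np.min(w)
        valley_idx.append(lo + int(np.flatnonzero(w <= mn + 1e-12)[-1]))
    valley_idx = np.asarray(valley_idx, dtype=int)

    max_slope_idx = []
    for v, p in zip(valley_idx, peak_idx):
        d = np.diff(ppg[v:p + 1])
        max_slope_idx.append(v + int(np.argmax(d)))
    max_slope_idx = np.asarray(max_slope_idx, dtype=int)

    second_peak_idx: list[int | None] = []
    for k, p in enumerate(peak_idx):
        nv = valley_idx[k + 1] if k + 1 < len(valley_idx) else min(n - 1, p + int(0.45 * fs))
        branch = ppg[p:nv + 1]
        maxima, _ = sps.find_peaks(branch)
        second_peak_idx.append(int(p + maxima[np.argmax(branch[maxima])]) if len(maxima) else None)

    rr = np.diff(r_idx)
    hr = 60.0 * fs / rr if len(rr) else np.asarray([])
    return RecordTruth(
        fs=fs,
        beat_times_s=beats,
        r_idx=r_idx,
        valley_idx=valley_idx,
        max_slope_idx=max_slope_idx,
        peak_idx=peak_idx,
        second_peak_idx=second_peak_idx,
        pat_s=(valley_idx - r_idx) / fs,
        hr_bpm=hr,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Multi-subject cohort with a known BP-generating function.

    ``sbp_coef``/``dbp_coef`` are (b0, b1, b2, b3) in
    ``BP = b0 + b1/PAT + b2*HR + b3*Age + subject_offset + eps`` with
    PAT in s, HR in bpm, Age in years, BP in mmHg.
    """

    n_subjects: int = 15
    records_per_subject: int = 6
    fs: float = 125.0
    duration_s: float = 30.0
    age_range: tuple[int, int] = (20, 40)
    weight_mean: float = 65.0
    weight_sd: float = 12.0
    male_prob: float = 0.5
    pat_mean_s: float = 0.25
    pat_between_sd: float = 0.04
    pat_within_sd: float = 0.01
    hr_mean_bpm: float = 75.0
    hr_between_sd: float = 10.0
    hr_within_sd: float = 3.0
    sbp_coef: tuple[float, float, float, float] = (40.0, 15.0, 0.2, 0.5)
    dbp_coef: tuple[float, float, float, float] = (20.0, 9.0, 0.1, 0.3)
    subject_offset_sd: float = 5.0
    eps_sd: float = 3.0
    include_abp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.records_per_subject < 1:
            raise ValueError("cohort must contain at least one subject and record")
        for name in ("pat_between_sd", "pat_within_sd", "hr_between_sd",
                     "hr_within_sd", "subject_offset_sd", "eps_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _draw_latents(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject- and record-level latent truth for one cohort."""
    rows = []
    for s in range(cfg.n_subjects):
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        weight = float(np.clip(rng.normal(cfg.weight_mean, cfg.weight_sd), 40, 130))
        gender = int(rng.random() < cfg.male_prob)
        pat_subj = float(np.clip(rng.normal(cfg.pat_mean_s, cfg.pat_between_sd), 0.12, 0.45))
        hr_subj = float(np.clip(rng.normal(cfg.hr_mean_bpm, cfg.hr_between_sd), 45, 160))
        off_s = float(rng.normal(0, cfg.subject_offset_sd))
        off_d = float(rng.normal(0, cfg.subject_offset_sd))
        for r in range(cfg.records_per_subject):
            pat = float(np.clip(rng.normal(pat_subj, cfg.pat_within_sd), 0.08, 0.55))
            hr = float(np.clip(rng.normal(hr_subj, cfg.hr_within_sd), 40, 180))
            b = cfg.sbp_coef
            sbp = b[0] + b[1] / pat + b[2] * hr + b[3] * age + off_s + rng.normal(0, cfg.eps_sd)
            b = cfg.dbp_coef
            dbp = b[0] + b[1] / pat + b[2] * hr + b[3] * age + off_d + rng.normal(0, cfg.eps_sd)
            dbp = min(dbp, sbp - 20.0)  # keep the pulse pressure physiological
            rows.append(dict(
                subject_id=f"S{s:03d}", record_id=f"S{s:03d}R{r}",
                age=age, weight=weight, gender=gender,
                pat_true_s=pat, hr_true_bpm=hr,
                sbp_offset=off_s, dbp_offset=off_d,
                sbp=float(sbp), dbp=float(dbp),
            ))
    return pd.DataFrame(rows)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SignalRecord], pd.DataFrame]:
    """Signal-level cohort: one synthesized record per latent row."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    latents = _draw_latents(cfg, rng)
    records = []
    for _, row in latents.iterrows():
        rec_cfg = GeneratorConfig(
            fs=cfg.fs, duration_s=cfg.duration_s,
            hr_bpm=row.hr_true_bpm, pat_s=row.pat_true_s,
            include_abp=cfg.include_abp,
            sbp_mmhg=row.sbp, dbp_mmhg=row.dbp,
            seed=int(rng.integers(2 ** 31)),
        )
        subject = SubjectInfo(subject_id=row.subject_id, gender=int(row.gender),
                              age=int(row.age), weight=row.weight)
        record, _ = generate_record(rec_cfg, subject=subject)
        record.sbp_ref = row.sbp
        record.dbp_ref = row.dbp
        records.append(record)
    assert all(r.sbp_ref > r.dbp_ref for r in records)
    return records, latents


def generate_feature_cohort(
    config: CohortConfig | None = None,
    n_noise_features: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level cohort drawn directly from the latent truth.

    Emits one row of the 25 named features per record, with realistic
    measurement noise on the informative entries (landmark timing noise
    of about half a sample at 125 Hz) and feature values unrelated to
    the BP targets for the purely morphological entries; optional
    ``noise_00..`` columns are iid standard normal distractors.

    Returns ``(table, latents)``; the table carries ``subject_id``,
    the features, any noise columns, and ``sbp_ref``/``dbp_ref``.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    lat = _draw_latents(cfg, rng)
    n = len(lat)
    rise = 0.20
    pat = lat.pat_true_s.to_numpy()
    hr = lat.hr_true_bpm.to_numpy()
    tnoise = lambda sd: rng.normal(0, sd, n)

    cols: dict = {"subject_id": lat.subject_id}
    cols["Gender"] = lat.gender.astype(float)
    cols["Age"] = lat.age.astype(float)
    cols["Weight"] = lat.weight
    cols["PATf"] = pat + tnoise(0.004)
    cols["PATd"] = pat + 0.45 * rise + tnoise(0.004)
    cols["PATp"] = pat + rise + tnoise(0.004)
    cols["HR"] = hr + tnoise(0.5)
    cols["PP"] = 60.0 / hr + tnoise(0.01)
    cols["AT"] = rise + tnoise(0.008)
    cols["DT"] = 60.0 / hr - rise + tnoise(0.015)
    # morphology/intensity entries: plausible scales, independent of BP
    cols["PPT"] = 0.25 + tnoise(0.02)
    cols["PIRp"] = 5.0 + tnoise(0.4)
    cols["PIRmd"] = 3.0 + tnoise(0.3)
    cols["PIavg"] = 0.6 + tnoise(0.05)
    cols["PIsd"] = 0.3 + tnoise(0.03)
    cols["PImax"] = 1.25 + tnoise(0.05)
    cols["PImin"] = 0.25 + tnoise(0.02)
    cols["SA"] = 18.0 + tnoise(2.0)
    cols["AA"] = 0.7 + tnoise(0.05)
    cols["SD"] = 30.0 + tnoise(3.0)
    cols["AD"] = 0.55 + tnoise(0.05)
    cols["SR"] = 0.6 + tnoise(0.05)
    cols["K"] = 0.35 + tnoise(0.03)
    cols["AS"] = 5.0 + tnoise(0.4)
    cols["DS"] = 2.5 + tnoise(0.25)
    for j in range(n_noise_features):
        cols[f"noise_{j:02d}"] = rng.normal(0, 1, n)
    cols["sbp_ref"] = lat.sbp
    cols["dbp_ref"] = lat.dbp
    return pd.DataFrame(cols), lat


def feature_frame_to_vectors(table: pd.DataFrame) -> list[FeatureVector]:
    """Convert a feature-cohort table (no noise columns) to FeatureVectors."""
    vectors = []
    for _, row in table.iterrows():
        vectors.append(FeatureVector(
            subject_id=str(row["subject_id"]),
            values={k: float(row[k]) for k in FEATURE_NAMES},
            sbp_ref=float(row["sbp_ref"]),
            dbp_ref=float(row["dbp_ref"]),
            n_beats_used=2,
        ))
    return vectors
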