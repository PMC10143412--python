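"""Blood-pressure specific evaluation: MAE/STD, BHS grading, Bland-Altman.

MAE is the mean absolute error over records.  STD is the standard
deviation of the signed errors ``e_i = estimated_i - reference_i``
about their mean (population 1/N convention) — the universal BP-
validation convention, so "MAE +/- STD" pairs describe the error
distribution.  A literal variant that takes the SD of the reference
pressures about their own mean is available behind
``std_mode="reference"`` for audit.

BHS grading assigns A/B/C by the cumulative percentages of absolute
errors within 5/10/15 mmHg (A: 60/85/95, B: 50/75/90, C: 40/65/85, all
thresholds inclusive); anything below C is graded D.

Bland-Altman agreement reports the mean difference and the
mean +/- 1.96 SD limits of agreement of the differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "EvalReport",
    "compute_errors",
    "bhs_grade",
    "bland_altman",
    "BHS_THRESHOLDS",
]

#: (grade, pct<=5, pct<=10, pct<=15); all three must hold (>=)
BHS_THRESHOLDS = (
    ("A", 60.0, 85.0, 95.0),
    ("B", 50.0, 75.0, 90.0),
    ("C", 40.0, 65.0, 85.0),
)


@dataclass
class EvalReport:
    """Error metrics, cumulative proportions, BHS grade, Bland-Altman."""

    target_name: str
    n: int
    mae: float
    std_err: float
    pct_le_5: float
    pct_le_10: float
    pct_le_15: float
    bhs_grade: str
    ba_mean_diff: float
    ba_lower: float
    ba_upper: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def bhs_grade(pct_le_5: float, pct_le_10: float, pct_le_15: float) -> str:
    """Highest BHS grade whose 5/10/15-mmHg thresholds are all met."""
    for grade, t5, t10, t15 in BHS_THRESHOLDS:
        if pct_le_5 >= t5 and pct_le_10 >= t10 and pct_le_15 >= t15:
            return grade
    return "D"


def bland_altman(
    reference: np.ndarray, estimated: np.ndarray
) -> tuple[float, float, float]:
    """(mean difference, lower, upper) limits of agreement in mmHg.

    Differences are estimated - reference; limits are
    mean +/- 1.96 SD (population convention).
    """
    reference = np.asarray(reference, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if reference.shape != estimated.shape or reference.size < 2:
        raise ValueError("reference and estimated must be equal-length, n >= 2")
    d = estimated - reference
    mean_diff = float(np.mean(d))
    spread = 1.96 * float(np.std(d))
    return mean_diff, mean_diff - spread, mean_diff + spread


def compute_errors(
    reference,
    estimated,
    target_name: str = "BP",
    std_mode: str = "error",
) -> EvalReport:
    """Full evaluation report for one target.

    ``std_mode="error"`` (default) reports the SD of the signed errors;
    ``std_mode="reference"`` reports the literal SD of the reference
    pressures about their mean (audit only).
    """
    reference = np.asarray(reference, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if reference.shape != estimated.shape:
        raise ValueError(
            f"length mismatch: {reference.shape} reference vs {estimated.shape} estimated"
        )
    n = reference.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    err = estimated - reference
    abs_err = np.abs(err)
    mae = float(np.mean(abs_err))
    if std_mode == "error":
        std = float(np.std(err))
    elif std_mode == "reference":
        std = float(np.std(reference))
    else:
        raise ValueError(f"unknown std_mode {std_mode!r}")
    pct5 = float(100.0 * np.mean(abs_err <= 5.0))
    pct10 = float(100.0 * np.mean(abs_err <= 10.0))
    pct15 = float(100.0 * np.mean(abs_err <= 15.0))
    mean_diff, lower, upper = bland_altman(reference, estimated)
    return EvalReport(
        target_name=target_name,
        n=int(n),
        mae=mae,
        std_err=std,
        pct_le_5=pct5,
        pct_le_10=pct10,
        pct_le_15=pct15,
        bhs_grade=bhs_grade(pct5, pct10, pct15),
        ba_mean_diff=mean_diff,
        ba_lower=lower,
        ba_upper=upper,
    )
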