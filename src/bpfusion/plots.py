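"""Diagnostic plots: Bland-Altman agreement and the group-MI trajectory."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import bland_altman
from .gcmi_selection import SelectionResult

__all__ = ["bland_altman_plot", "mi_trajectory_plot"]


def bland_altman_plot(reference, estimated, path: str | Path, target_name: str = "BP") -> None:
    """Scatter of difference vs mean with the mean +/- 1.96 SD limits."""
    reference = np.asarray(reference, float)
    estimated = np.asarray(estimated, float)
    mean_diff, lower, upper = bland_altman(reference, estimated)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((reference + estimated) / 2, estimated - reference, s=12, alpha=0.6)
    ax.axhline(mean_diff, ls="--", color="k", label=f"mean {mean_diff:+.2f}")
    for y in (lower, upper):
        ax.axhline(y, color="k", lw=1)
    ax.set_xlabel(f"mean of reference and estimated {target_name} (mmHg)")
    ax.set_ylabel("estimated - reference (mmHg)")
    ax.set_title(f"Bland-Altman, {target_name} [{lower:.1f}, {upper:.1f}] mmHg")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mi_trajectory_plot(result: SelectionResult, path: str | Path) -> None:
    """Group MI (bits) against the number of remaining features."""
    n0 = len(result.selected) + len(result.elimination_order)
    sizes = list(range(n0, n0 - len(result.mi_trajectory), -1))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sizes, result.mi_trajectory, "o-")
    ax.axvline(len(result.selected), ls=":", color="k",
               label=f"kept {len(result.selected)}")
    ax.invert_xaxis()
    ax.set_xlabel("features remaining")
    ax.set_ylabel("group GCMI (bits)")
    ax.set_title(f"Backward elimination, {result.target_name}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
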