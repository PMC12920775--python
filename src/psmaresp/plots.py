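"""Optional Kaplan-Meier plotting helpers (matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .survival_stats import SurvivalSample, km_estimate


def plot_km_groups(
    groups: Mapping[str, SurvivalSample],
    title: str,
    path: str | Path,
) -> None:
    """Step-plot one KM curve per labelled group and save to ``path``."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, sample in groups.items():
        est = km_estimate(sample)
        ax.step(
            [0.0, *est.times], [1.0, *est.survival], where="post",
            label=f"{label} (n={est.n}, median {est.median_label})",
        )
    ax.set_xlabel("Months from follow-up scan")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
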