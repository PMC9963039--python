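"""Optional figures for a finished run (risk scatter, per-participant RMSE)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def risk_scatter(workdays: pd.DataFrame, condition: str = "trunkforce", ax=None):
    """Estimated vs lab-based daily risk with a unity line, coloured by participant."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for pid, group in workdays.groupby("participant_id"):
        ax.scatter(
            group["risk_lab"] * 100,
            group[f"risk_{condition}"] * 100,
            s=4,
            alpha=0.4,
            label=f"P{int(pid) + 1}",
        )
    ax.plot([0, 100], [0, 100], "k-", lw=1)
    ax.set_xlabel("Lab-based LBD risk (%)")
    ax.set_ylabel(f"{condition} LBD risk (%)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.legend(fontsize=6, ncol=2)
    return ax


def rmse_lines(summary: dict, ax=None):
    """Per-participant RMSE for trunk vs trunk+force, joined by lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    per = summary["per_participant"]
    for pid, entry in per.items():
        ax.plot(
            [0, 1],
            [entry["rmse_trunk"], entry["rmse_trunkforce"]],
            marker="o",
            label=f"P{int(pid) + 1}",
        )
    ax.set_xticks([0, 1], ["Trunk", "Trunk+Force"])
    ax.set_ylabel("RMSE of LBD risk (percentage points)")
    ax.legend(fontsize=6, ncol=2)
    return ax
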