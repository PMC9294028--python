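"""Descriptive figures: biomarker-vs-age scatter plots and visit trajectories.

Age plots pool both arms (they describe cohort-level change with age, not
treatment effects); a least-squares trend line is overlaid where at least
two distinct ages exist.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .synthetic import BIOMARKER_COLUMNS

__all__ = ["plot_biomarkers_vs_age", "plot_trajectories"]


def _age_at_visit(table: pd.DataFrame) -> pd.Series:
    return table["age_baseline"] + table["week"] * 7.0 / 365.25


def plot_biomarkers_vs_age(table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """One scatter per biomarker, age on the abscissa, arms pooled."""
    if table is None or len(table) == 0:
        warnings.warn("empty cohort table: no age plots produced", stacklevel=2)
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    age = _age_at_visit(table)
    paths: list[Path] = []
    for col in BIOMARKER_COLUMNS:
        if col not in table.columns:
            continue
        y = table[col].to_numpy(float)
        keep = np.isfinite(y) & np.isfinite(age.to_numpy(float))
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(age[keep], y[keep], s=8, alpha=0.5, color="0.25")
        if keep.sum() >= 2 and np.ptp(age[keep].to_numpy()) > 0:
            b, a = np.polyfit(age[keep], y[keep], 1)
            xs = np.linspace(age[keep].min(), age[keep].max(), 50)
            ax.plot(xs, a + b * xs, color="crimson", lw=1.2)
        ax.set_xlabel("age at visit (years)")
        ax.set_ylabel(col)
        fig.tight_layout()
        p = out_dir / f"age_{col}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_trajectories(table: pd.DataFrame, out_dir: str | Path, endpoint: str = "mvi_percent") -> Path | None:
    """Per-subject endpoint trajectories over visit weeks, coloured by arm."""
    if table is None or len(table) == 0 or endpoint not in table.columns:
        warnings.warn("no trajectory plot: empty table or missing endpoint", stacklevel=2)
        return None
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"treatment": "tab:blue", "placebo": "tab:red"}
    for (sid, arm), sub in table.groupby(["subject_id", "arm"]):
        sub = sub.sort_values("week")
        ax.plot(sub["week"], sub[endpoint], color=colors.get(arm, "0.5"), alpha=0.35, lw=0.8)
    for arm, c in colors.items():
        ax.plot([], [], color=c, label=arm)
    ax.set_xlabel("week")
    ax.set_ylabel(endpoint)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    p = out_dir / f"trajectories_{endpoint}.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    return p
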