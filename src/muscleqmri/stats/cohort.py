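"""CohortTable bookkeeping: change-from-baseline derivation and visit rules.

The cohort table is long format, one row per subject x visit, with the eight
biomarker columns, functional outcomes, arm/stratum/age, and (optionally) a
``visit_type`` column.  Baseline is the week-0 (last pre-dose) row.
Unscheduled and early-termination readings are excluded before any change
from baseline is derived, and each post-baseline change is attributed to the
dose received at the previous visit.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

__all__ = ["derive_cfb"]


def derive_cfb(
    table: pd.DataFrame,
    endpoints: Sequence[str],
    mode: str = "both",
) -> pd.DataFrame:
    """Add cfb_/pcfb_ columns per endpoint and dose-attribution bookkeeping.

    ``cfb = x_t - x_0`` and ``pcfb = 100 (x_t - x_0) / x_0`` against the
    subject's week-0 baseline.  Rows whose ``visit_type`` is not
    ``"scheduled"`` are dropped.  A zero baseline leaves pcfb missing with a
    warning.  Baseline rows carry cfb = pcfb = 0.
    """
    if mode not in {"absolute", "percent", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    df = table.copy()
    if "visit_type" in df.columns:
        df = df[df["visit_type"] == "scheduled"].copy()
    if "week" not in df.columns or "subject_id" not in df.columns:
        raise ValueError("cohort table requires 'subject_id' and 'week' columns")

    df = df.sort_values(["subject_id", "week"], kind="stable").reset_index(drop=True)
    base = df[df["week"] == 0].set_index("subject_id")
    grp = df.groupby("subject_id")

    # attribution: change at each visit belongs to the dose given at the previous visit
    df["dose_attribution_week"] = grp["week"].shift(1)
    if "arm" in df.columns:
        df["dose_attributed"] = grp["arm"].shift(1)

    for ep in endpoints:
        if ep not in df.columns:
            raise ValueError(f"endpoint column {ep!r} not in table")
        b = df["subject_id"].map(base[ep]) if ep in base.columns else float("nan")
        if mode in {"absolute", "both"}:
            df[f"cfb_{ep}"] = df[ep] - b
        if mode in {"percent", "both"}:
            zero = b == 0
            if zero.any():
                warnings.warn(
                    f"{int(zero.sum())} rows have a zero baseline for {ep!r}; pcfb left missing",
                    stacklevel=2,
                )
            df[f"pcfb_{ep}"] = (100.0 * (df[ep] - b) / b).where(~zero)
    return df
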