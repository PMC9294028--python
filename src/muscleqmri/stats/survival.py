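"""Cox analyses of time to loss of ambulation.

Two model forms, both including baseline age as a covariate and using Efron
tie handling:

* :class:`MedianSplitCox` — compares subjects above vs below the median
  baseline value of an MRI parameter.  "Below" means strictly less than the
  median; ties at the median join the upper group.  The binary covariate is
  oriented so that a hazard ratio above 1 means the *less favourable*
  baseline group loses ambulation sooner.
* :class:`TimeVaryingCox` — counting-process Cox fit with the MRI parameter
  carried forward between visits as a step function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter

__all__ = ["SurvivalResults", "MedianSplitCox", "TimeVaryingCox", "build_time_varying_table"]


class NoEventsError(ValueError):
    """Cox fit impossible: no loss-of-ambulation events observed."""


@dataclass
class SurvivalResults:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    n_subjects: int
    model_type: str  # {"median_split", "time_varying"}
    covariates: tuple[str, ...]

    def summary(self) -> str:
        return (
            f"Cox ({self.model_type}, covariates: {', '.join(self.covariates)}): "
            f"HR {self.hazard_ratio:.2f} (95% CI {self.ci_low:.2f}, {self.ci_high:.2f}), "
            f"P = {self.p_value:.4f}, events {self.n_events}/{self.n_subjects}"
        )


class MedianSplitCox:
    """Time to loss of ambulation by median baseline split of one MRI parameter."""

    def __init__(
        self,
        baseline_values: np.ndarray,
        age: np.ndarray,
        time: np.ndarray,
        event: np.ndarray,
        higher_is_better: bool = True,
    ) -> None:
        v = np.asarray(baseline_values, dtype=np.float64)
        self.age = np.asarray(age, dtype=np.float64)
        self.time = np.asarray(time, dtype=np.float64)
        self.event = np.asarray(event).astype(bool)
        if not (len(v) == len(self.age) == len(self.time) == len(self.event)):
            raise ValueError("all per-subject arrays must share a length")
        if len(v) < 4:
            raise ValueError("need at least 4 subjects")
        if self.event.sum() < 1:
            raise NoEventsError("no ambulation-loss events: Cox model cannot be fitted")
        median = float(np.median(v))
        below = v < median  # strict; ties at the median go to the upper group
        self.unfavourable = below if higher_is_better else ~below
        self.median = median

    def fit(self) -> SurvivalResults:
        df = pd.DataFrame(
            {
                "duration": self.time,
                "event": self.event.astype(int),
                "unfavourable": self.unfavourable.astype(float),
                "age": self.age,
            }
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="duration", event_col="event", fit_options={"precision": 1e-9})
        s = cph.summary.loc["unfavourable"]
        return SurvivalResults(
            hazard_ratio=float(np.exp(s["coef"])),
            ci_low=float(np.exp(s["coef lower 95%"])),
            ci_high=float(np.exp(s["coef upper 95%"])),
            p_value=float(s["p"]),
            n_events=int(self.event.sum()),
            n_subjects=len(df),
            model_type="median_split",
            covariates=("unfavourable", "age"),
        )


def build_time_varying_table(
    table: pd.DataFrame,
    endpoint: str,
    subject_col: str = "subject_id",
    week_col: str = "week",
    event_day_col: str = "ambulation_event_day",
    event_col: str = "ambulation_event",
    age_col: str = "age_baseline",
) -> pd.DataFrame:
    """Expand a cohort table into counting-process intervals for one endpoint.

    The endpoint value observed at each visit is carried forward until the
    next visit; the final interval ends at the event/censoring day, with the
    event flag set only there.  Visits after the event/censoring day are
    dropped.
    """
    rows = []
    for sid, sub in table.sort_values([subject_col, week_col]).groupby(subject_col, sort=False):
        sub = sub.dropna(subset=[endpoint])
        if sub.empty:
            continue
        days = sub[week_col].to_numpy(float) * 7.0
        vals = sub[endpoint].to_numpy(float)
        end_day = float(sub[event_day_col].iloc[0])
        event = bool(sub[event_col].iloc[0])
        age = float(sub[age_col].iloc[0])
        keep = days < end_day
        days, vals = days[keep], vals[keep]
        if len(days) == 0:
            continue
        stops = np.append(days[1:], end_day)
        for j in range(len(days)):
            if stops[j] <= days[j]:
                continue
            rows.append(
                {
                    subject_col: sid,
                    "start": days[j],
                    "stop": float(stops[j]),
                    endpoint: vals[j],
                    "age": age,
                    "event": int(event and j == len(days) - 1),
                }
            )
    return pd.DataFrame(rows)


class TimeVaryingCox:
    """Counting-process Cox model with one MRI parameter as a step covariate."""

    def __init__(
        self,
        long_table: pd.DataFrame,
        covariate: str,
        subject_col: str = "subject_id",
        age_col: str = "age",
    ) -> None:
        req = {subject_col, "start", "stop", covariate, age_col, "event"}
        missing = req - set(long_table.columns)
        if missing:
            raise ValueError(f"long table missing columns: {sorted(missing)}")
        df = long_table.sort_values([subject_col, "start"]).reset_index(drop=True)
        for sid, sub in df.groupby(subject_col, sort=False):
            starts = sub["start"].to_numpy(float)
            stops = sub["stop"].to_numpy(float)
            if np.any(stops <= starts):
                raise ValueError(f"subject {sid}: interval with stop <= start")
            if np.any(np.abs(starts[1:] - stops[:-1]) > 1e-9):
                raise ValueError(f"subject {sid}: intervals must partition follow-up (gap/overlap)")
            ev = sub["event"].to_numpy()
            if ev[:-1].any():
                raise ValueError(f"subject {sid}: event allowed only in the final interval")
        if df["event"].sum() < 1:
            raise NoEventsError("no ambulation-loss events: Cox model cannot be fitted")
        self.df = df
        self.covariate = covariate
        self.subject_col = subject_col
        self.age_col = age_col

    def fit(self) -> SurvivalResults:
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            self.df[[self.subject_col, "start", "stop", self.covariate, self.age_col, "event"]],
            id_col=self.subject_col,
            start_col="start",
            stop_col="stop",
            event_col="event",
            fit_options={"precision": 1e-9},
        )
        s = ctv.summary.loc[self.covariate]
        return SurvivalResults(
            hazard_ratio=float(np.exp(s["coef"])),
            ci_low=float(np.exp(s["coef lower 95%"])),
            ci_high=float(np.exp(s["coef upper 95%"])),
            p_value=float(s["p"]),
            n_events=int(self.df["event"].sum()),
            n_subjects=int(self.df[self.subject_col].nunique()),
            model_type="time_varying",
            covariates=(self.covariate, self.age_col),
        )
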