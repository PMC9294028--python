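"""Mixed model for repeated measures (MMRM) treatment contrasts by visit.

Fixed effects: stratification factor, baseline value of the endpoint,
treatment, time (visit week, categorical), and treatment-by-time interaction;
participants enter as the repeated-measures unit.  The default covariance is
unstructured across visits — the standard MMRM choice, fitted here by
iterated feasible GLS with a pooled (pairwise-complete) within-subject
covariance estimate — with a ``"random_intercept"`` (compound symmetry)
option via statsmodels MixedLM.  Degrees of freedom for contrasts use a
between-within approximation (subjects minus between-subject parameters).
P values are nominal; no multiplicity adjustment is applied anywhere.

Progression in this disease is heterogeneous across boys (subject-specific
slopes), which makes a compound-symmetry covariance anticonservative for
late-visit contrasts; the unstructured default reflects that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = ["MMRM", "MMRMResults"]


@dataclass
class MMRMResults:
    """Per-visit adjusted means, treatment difference, CI and nominal p-value."""

    by_week: pd.DataFrame  # indexed by week
    endpoint: str
    covariance: str
    df_contrast: float
    converged: bool

    def summary(self) -> str:
        lines = [
            f"MMRM: {self.endpoint}   (covariance: {self.covariance}, "
            f"contrast df: {self.df_contrast:.0f})",
            f"{'week':>5} {'n_trt':>6} {'n_pbo':>6} {'adj mean trt (95% CI)':>28} "
            f"{'adj mean pbo (95% CI)':>28} {'difference (95% CI)':>28} {'P':>8}",
        ]
        for week, r in self.by_week.iterrows():
            lines.append(
                f"{week:>5} {int(r.n_treatment):>6} {int(r.n_placebo):>6} "
                f"{r.mean_treatment:>10.2f} ({r.mean_treatment_lo:.2f}, {r.mean_treatment_hi:.2f}) "
                f"{r.mean_placebo:>10.2f} ({r.mean_placebo_lo:.2f}, {r.mean_placebo_hi:.2f}) "
                f"{r.difference:>10.2f} ({r.difference_lo:.2f}, {r.difference_hi:.2f}) "
                f"{r.p_value:>8.4f}"
            )
        return "\n".join(lines)


class MMRM:
    """Model object for one endpoint's repeated-measures treatment analysis.

    Parameters
    ----------
    table
        Long-format cohort table (one row per subject x visit) already
        carrying the derived endpoint column (a cfb/pcfb column).
    endpoint
        Response column name.
    baseline
        Column with the subject's baseline (week-0) value of the underlying
        biomarker, entered as a fixed covariate.
    covariance
        ``"random_intercept"`` (default, compound symmetry) or
        ``"unstructured"`` (per-visit random effects).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        endpoint: str,
        baseline: str,
        weeks: tuple[int, ...] | None = None,
        arm_col: str = "arm",
        stratum_col: str = "stratum",
        subject_col: str = "subject_id",
        covariance: str = "unstructured",
    ) -> None:
        if covariance not in {"random_intercept", "unstructured"}:
            raise ValueError(f"unknown covariance structure {covariance!r}")
        df = table.copy()
        df = df[df["week"] > 0]
        if weeks is not None:
            df = df[df["week"].isin(weeks)]
        cols = [endpoint, baseline, arm_col, stratum_col, subject_col, "week"]
        df = df.dropna(subset=[c for c in cols if c in df.columns])
        if df.empty:
            raise ValueError("no usable post-baseline rows")

        # report visits only where both arms contribute data
        ok_weeks = []
        for w, sub in df.groupby("week"):
            arms = set(sub[arm_col].unique())
            if {"treatment", "placebo"} <= arms:
                ok_weeks.append(w)
            else:
                warnings.warn(f"week {w} omitted: only one arm has data", stacklevel=2)
        df = df[df["week"].isin(ok_weeks)]
        if df["week"].nunique() < 2:
            raise ValueError("MMRM requires at least 2 post-baseline visits with both arms")

        self.table = df.reset_index(drop=True)
        self.endpoint = endpoint
        self.baseline = baseline
        self.arm_col, self.stratum_col, self.subject_col = arm_col, stratum_col, subject_col
        self.covariance = covariance
        self.weeks = sorted(df["week"].unique())

    # -- design ------------------------------------------------------------
    def _design(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        df = self.table
        treated = (df[self.arm_col] == "treatment").to_numpy(float)
        strata = sorted(df[self.stratum_col].astype(str).unique())
        base = df[self.baseline].to_numpy(float)
        base_c = base - base.mean()
        sd = base_c.std()
        if sd > 0:  # standardized for conditioning; contrasts are unaffected
            base_c = base_c / sd

        cols: list[np.ndarray] = [np.ones(len(df))]
        names = ["intercept"]
        for s in strata[1:]:
            cols.append((df[self.stratum_col].astype(str) == s).to_numpy(float))
            names.append(f"stratum[{s}]")
        cols.append(base_c)
        names.append("baseline")
        for w in self.weeks[1:]:
            cols.append((df["week"] == w).to_numpy(float))
            names.append(f"week[{w}]")
        cols.append(treated)
        names.append("treated")
        for w in self.weeks[1:]:
            cols.append(treated * (df["week"] == w).to_numpy(float))
            names.append(f"treated:week[{w}]")
        self._strata = strata
        self._strata_props = [
            float((df[self.stratum_col].astype(str) == s).mean()) for s in strata
        ]
        return np.column_stack(cols), names, df[self.endpoint].to_numpy(float)

    @staticmethod
    def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
        """Greedily drop columns that are (numerically) linear in earlier ones."""
        keep = [0]
        for j in range(1, X.shape[1]):
            A = X[:, keep]
            coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
            resid = X[:, j] - A @ coef
            if np.linalg.norm(resid) > 1e-8 * max(np.linalg.norm(X[:, j]), 1.0):
                keep.append(j)
        return X[:, keep], [names[j] for j in keep]

    def _fit_gls_unstructured(
        self, X: np.ndarray, y: np.ndarray, n_iter: int = 3
    ) -> tuple[np.ndarray, np.ndarray, bool]:
        """Iterated feasible GLS with a pooled unstructured visit covariance.

        The m x m within-subject covariance is estimated from residual
        cross-products over subjects with both visits available (pairwise
        complete); each subject's GLS block uses the submatrix matching its
        available visits.
        """
        df = self.table
        week_idx = {w: j for j, w in enumerate(self.weeks)}
        widx = df["week"].map(week_idx).to_numpy()
        sids, sinv = np.unique(df[self.subject_col].to_numpy(), return_inverse=True)
        n_sub, m, k = len(sids), len(self.weeks), X.shape[1]

        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        cov = np.eye(k)
        for _ in range(n_iter):
            resid = y - X @ beta
            R = np.full((n_sub, m), np.nan)
            R[sinv, widx] = resid
            have = ~np.isnan(R)
            R0 = np.where(have, R, 0.0)
            counts = have.astype(float).T @ have.astype(float)
            sigma = (R0.T @ R0) / np.maximum(counts, 1.0)
            # guard against non-PD pairwise estimates
            ev = np.linalg.eigvalsh(sigma)
            if ev.min() <= 1e-10 * max(ev.max(), 1e-30):
                sigma = sigma + (1e-8 + abs(min(ev.min(), 0.0))) * np.eye(m)
            A = np.zeros((k, k))
            b = np.zeros(k)
            inv_cache: dict[tuple, np.ndarray] = {}
            for s in range(n_sub):
                rows = np.flatnonzero(sinv == s)
                jj = widx[rows]
                key = tuple(jj)
                Sinv = inv_cache.get(key)
                if Sinv is None:
                    Sinv = np.linalg.inv(sigma[np.ix_(jj, jj)])
                    inv_cache[key] = Sinv
                Xi = X[rows]
                A += Xi.T @ Sinv @ Xi
                b += Xi.T @ Sinv @ y[rows]
            cov = np.linalg.inv(A)
            beta = cov @ b
        return beta, cov, True

    def fit(self, reml: bool = True) -> MMRMResults:
        X, names, y = self._design()
        X, names = self._drop_collinear(X, names)
        if "treated" not in names:
            raise ValueError("treatment effect not estimable: design is singular in 'treated'")
        df = self.table
        k = X.shape[1]
        covariance_label = self.covariance
        if self.covariance == "unstructured":
            beta, cov, converged = self._fit_gls_unstructured(X, y)
        else:
            groups = df[self.subject_col].to_numpy()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = MixedLM(y, X, groups=groups, exog_re=np.ones((len(df), 1)))
                    res = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"])
                beta = np.asarray(res.fe_params)
                cov = np.asarray(res.cov_params())[:k, :k]
                converged = bool(res.converged)
            except np.linalg.LinAlgError:
                # degenerate tiny samples: profiled covariance collapses; fall
                # back to independent errors so the contrast is still reported
                warnings.warn(
                    "mixed-model covariance degenerate; independent-errors fallback", stacklevel=2
                )
                import statsmodels.api as sm

                ols = sm.OLS(y, X).fit()
                beta = np.asarray(ols.params)
                cov = np.asarray(ols.cov_params())
                converged = True
                covariance_label = f"{self.covariance} (fallback: independent errors)"
        idx = {nm: i for i, nm in enumerate(names)}

        n_subjects = df[self.subject_col].nunique()
        between = [nm for nm in names if nm == "intercept" or nm == "baseline" or nm == "treated" or nm.startswith("stratum[")]
        df_c = max(float(n_subjects - len(between)), 1.0)
        tcrit = sps.t.ppf(0.975, df_c)

        rows = []
        for w in self.weeks:
            c = np.zeros(k)
            c[idx["treated"]] = 1.0
            if w != self.weeks[0] and f"treated:week[{w}]" in idx:
                c[idx[f"treated:week[{w}]"]] = 1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            tstat = est / se if se > 0 else np.inf
            p = 2.0 * sps.t.sf(abs(tstat), df_c)

            means = {}
            for arm, a in (("treatment", 1.0), ("placebo", 0.0)):
                L = np.zeros(k)
                L[idx["intercept"]] = 1.0
                for s, prop in zip(self._strata[1:], self._strata_props[1:]):
                    if f"stratum[{s}]" in idx:
                        L[idx[f"stratum[{s}]"]] = prop
                if w != self.weeks[0] and f"week[{w}]" in idx:
                    L[idx[f"week[{w}]"]] = 1.0
                L[idx["treated"]] = a
                if a and w != self.weeks[0] and f"treated:week[{w}]" in idx:
                    L[idx[f"treated:week[{w}]"]] = 1.0
                m = float(L @ beta)
                mse = float(np.sqrt(L @ cov @ L))
                means[arm] = (m, m - tcrit * mse, m + tcrit * mse)

            sub = df[df["week"] == w]
            rows.append(
                {
                    "week": int(w),
                    "n_treatment": int((sub[self.arm_col] == "treatment").sum()),
                    "n_placebo": int((sub[self.arm_col] == "placebo").sum()),
                    "mean_treatment": means["treatment"][0],
                    "mean_treatment_lo": means["treatment"][1],
                    "mean_treatment_hi": means["treatment"][2],
                    "mean_placebo": means["placebo"][0],
                    "mean_placebo_lo": means["placebo"][1],
                    "mean_placebo_hi": means["placebo"][2],
                    "difference": est,
                    "se": se,
                    "difference_lo": est - tcrit * se,
                    "difference_hi": est + tcrit * se,
                    "p_value": float(p),
                }
            )
        by_week = pd.DataFrame(rows).set_index("week")
        return MMRMResults(by_week, self.endpoint, covariance_label, df_c, converged)
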