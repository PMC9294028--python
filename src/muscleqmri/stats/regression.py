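"""Simple linear regression of week-49 MRI change on week-97 function change.

Arms are pooled and only complete cases (subjects with both measurements)
enter the fit, mirroring the trial's exploratory correlative analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RegressionResult", "regress_mri_on_function"]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    stderr: float
    n: int


def regress_mri_on_function(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of functional change (y) on MRI change (x), complete cases only."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete (MRI, function) pairs")
    if np.ptp(x) == 0:
        raise ZeroDivisionError("zero variance in the MRI predictor: slope undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=int(len(x)),
    )
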