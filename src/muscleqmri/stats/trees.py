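"""Single-cutpoint regression trees linking week-49 MRI change to week-97 function.

``find_cutpoint`` exhaustively scans midpoints between consecutive sorted
distinct predictor values and picks the split minimizing the pooled
within-subgroup sum of squared deviations of the outcome; ties break toward
the smaller cutpoint.  Whether a split is informative is judged by a seeded
permutation test on the SSE reduction.  ``bivariate_tree`` reproduces the
two-biomarker structure: split on muscle volume first, then split only the
low-volume branch on the quality endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CutpointResult", "BivariateTreeResult", "NoSplitError", "find_cutpoint", "bivariate_tree"]


class NoSplitError(ValueError):
    """All predictor values identical: no cutpoint exists."""


@dataclass
class CutpointResult:
    cutpoint: float
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    sse: float  # pooled within-subgroup SSE at the chosen split
    sse_total: float  # SSE with no split
    informative: bool
    p_permutation: float


@dataclass
class BivariateTreeResult:
    """First split on x1; the low-x1 branch is split again on x2."""

    split_x1: CutpointResult
    split_x2: CutpointResult | None
    mean_high_x1: float  # terminal region: x1 > c1 (unsplit)
    mean_low_x1_low_x2: float
    mean_low_x1_high_x2: float


def _split_scan(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Best (cutpoint, SSE, n_low) by exhaustive scan; ties -> smaller cutpoint.

    Vectorized via prefix sums over the sorted order.  Inputs are sorted by
    (x, y) beforehand so the result is invariant to record order.
    """
    n = len(x)
    cs = np.cumsum(y)
    cs2 = np.cumsum(y * y)
    total, total2 = cs[-1], cs2[-1]
    # candidate boundaries after position i (0-based), only between distinct x
    boundary = np.flatnonzero(np.diff(x) > 0)
    nl = boundary + 1.0
    nr = n - nl
    sse_l = cs2[boundary] - cs[boundary] ** 2 / nl
    sse_r = (total2 - cs2[boundary]) - (total - cs[boundary]) ** 2 / nr
    sse = sse_l + sse_r
    best = int(np.argmin(sse))  # argmin returns the first minimum: smaller cutpoint
    b = boundary[best]
    cut = 0.5 * (x[b] + x[b + 1])
    return float(cut), float(sse[best]), int(b + 1)


def find_cutpoint(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> CutpointResult:
    """Optimal single cutpoint on x minimizing within-subgroup SSE of y.

    The ``informative`` flag compares the achieved SSE reduction with its
    permutation-null distribution (y shuffled against x, seeded); a constant
    outcome or a reduction compatible with noise is flagged uninformative.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 2 or np.unique(x).size < 2:
        raise NoSplitError("need at least 2 distinct predictor values")

    order = np.lexsort((y, x))  # order-invariant canonical form
    xs, ys = x[order], y[order]
    cut, sse, n_low = _split_scan(xs, ys)
    sse_total = float(np.sum((ys - ys.mean()) ** 2))
    reduction = sse_total - sse

    if sse_total <= 1e-12:
        p = 1.0
    else:
        rng = np.random.default_rng(seed)
        hits = 1
        for _ in range(n_permutations):
            _, sse_p, _ = _split_scan(xs, rng.permutation(ys))
            if sse_total - sse_p >= reduction - 1e-12:
                hits += 1
        p = hits / (n_permutations + 1)

    return CutpointResult(
        cutpoint=cut,
        n_low=n_low,
        n_high=len(xs) - n_low,
        mean_low=float(ys[:n_low].mean()),
        mean_high=float(ys[n_low:].mean()),
        sse=sse,
        sse_total=sse_total,
        informative=bool(p <= alpha),
        p_permutation=float(p),
    )


def bivariate_tree(
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> BivariateTreeResult:
    """Two-level tree: split on x1, then split the low-x1 subgroup on x2.

    The high-x1 region stays unsplit; terminal region means of y are
    reported.  Errors from the primary split propagate; a second split on an
    uninformative x2 is reported with ``informative=False``.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(y)
    x1, x2, y = x1[keep], x2[keep], y[keep]
    if len(y) < 4:
        raise ValueError("need at least 4 complete (x1, x2, y) triples")
    order = np.lexsort((y, x2, x1))  # canonical order: record-order invariant
    x1, x2, y = x1[order], x2[order], y[order]

    s1 = find_cutpoint(x1, y, n_permutations=n_permutations, alpha=alpha, seed=seed)
    low = x1 <= s1.cutpoint
    high_mean = float(y[~low].mean())

    s2: CutpointResult | None = None
    mean_ll = mean_lh = float(y[low].mean())
    try:
        s2 = find_cutpoint(
            x2[low], y[low], n_permutations=n_permutations, alpha=alpha, seed=seed + 1
        )
        mean_ll = s2.mean_low
        mean_lh = s2.mean_high
    except NoSplitError:
        pass  # degenerate x2 in the low branch: branch left unsplit
    return BivariateTreeResult(s1, s2, high_mean, mean_ll, mean_lh)
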