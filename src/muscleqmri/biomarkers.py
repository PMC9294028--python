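"""Per-visit imaging endpoints.

Eight endpoint scalars per subject-visit: muscle volume, inter/intramuscular
fat volume, muscle volume index (MVI), mean T2 of the muscle bundle and of
lean muscle, percent non-elevated voxels (T2 strictly below 55 ms), and mean
Dixon fat fraction of the bundle and of lean muscle — plus copper-sulfate
belt-phantom QC on the T2 map.

T2 is fitted per voxel to a mono-exponential decay ``S(TE) = S0 exp(-TE/T2)``
by nonlinear least squares, always excluding the first echo (stimulated-echo
mitigation).  The solver is a vectorized Levenberg-Marquardt iteration over
all voxels simultaneously (two parameters per voxel, closed-form 2x2 normal
equations), initialized by a signal-weighted log-linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, ImageVolume, MultiEchoSeries, Tissue, TissueLabelMap

__all__ = [
    "T2Map",
    "FatFractionMap",
    "VisitBiomarkers",
    "PhantomQCReport",
    "compute_volumes",
    "compute_mvi",
    "fit_t2_map",
    "percent_non_elevated",
    "fat_fraction_map",
    "roi_mean",
    "qc_phantom_t2",
    "extract_visit_biomarkers",
]

T2_BOUNDS_MS = (1.0, 1000.0)
DEFAULT_T2_THRESHOLD_MS = 55.0


@dataclass
class T2Map:
    t2_ms: np.ndarray
    s0: np.ndarray
    fit_ok: np.ndarray
    threshold_ms: float = DEFAULT_T2_THRESHOLD_MS


@dataclass
class FatFractionMap:
    ff: np.ndarray  # fraction in [0, 1] where valid
    valid: np.ndarray  # False where water + fat signal is zero


@dataclass
class PhantomQCReport:
    status: str  # {"pass", "fail", "error"}
    median_t2_ms: float
    expected_range_ms: tuple[float, float]
    n_voxels: int

    @property
    def passed(self) -> bool:
        return self.status == "pass"


@dataclass
class VisitBiomarkers:
    """The eight endpoint scalars for one subject-visit."""

    muscle_volume_mm3: float
    intermuscular_fat_volume_mm3: float
    mvi_percent: float
    t2_bundle_ms: float
    t2_lean_ms: float
    pct_non_elevated: float
    ff_bundle_percent: float
    ff_lean_percent: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_volumes(labels: TissueLabelMap, spacing: tuple[float, float, float] | None = None):
    """Tissue volumes in mm^3: (lean muscle, inter/intramuscular fat, subcutaneous fat)."""
    spacing = spacing or labels.spacing
    vv = float(np.prod(spacing))
    return (
        labels.count(Tissue.LEAN_MUSCLE) * vv,
        labels.count(Tissue.INTERMUSCULAR_FAT) * vv,
        labels.count(Tissue.SUBCUTANEOUS_FAT) * vv,
    )


def compute_mvi(muscle_volume: float, intermuscular_fat_volume: float) -> float:
    """Muscle volume index: 100 x muscle / (muscle + inter/intramuscular fat)."""
    if muscle_volume < 0 or intermuscular_fat_volume < 0:
        raise ValueError("volumes must be non-negative")
    total = muscle_volume + intermuscular_fat_volume
    if total == 0:
        raise ZeroDivisionError("MVI undefined: muscle and fat volumes are both zero")
    return 100.0 * muscle_volume / total


def _loglinear_init(te: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signal-weighted log-linear fit of log S = log S0 - TE/T2 per voxel."""
    yy = np.clip(y, 1e-12, None)
    w = y.clip(min=0.0) ** 2  # weights ~ S^2 compensate the log transform
    wsum = w.sum(axis=1)
    bad = wsum <= 0
    w[bad] = 1.0
    wsum = w.sum(axis=1)
    ly = np.log(yy)
    tbar = (w * te).sum(axis=1) / wsum
    lbar = (w * ly).sum(axis=1) / wsum
    cov = (w * (te - tbar[:, None]) * (ly - lbar[:, None])).sum(axis=1)
    var = (w * (te - tbar[:, None]) ** 2).sum(axis=1)
    slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), -1.0 / 50.0)
    r2 = np.clip(-slope, 1.0 / T2_BOUNDS_MS[1], 1.0 / T2_BOUNDS_MS[0])
    s0 = np.exp(lbar + r2 * tbar)
    return s0, r2


def fit_t2_map(series: MultiEchoSeries, mask: np.ndarray | None = None) -> T2Map:
    """Per-voxel mono-exponential T2 fit, excluding the initial echo.

    Least squares on echoes 2..n via damped Gauss-Newton in ``(S0, R2=1/T2)``,
    vectorized across voxels.  ``fit_ok`` is False where the signal is
    non-positive at every kept echo, where the fitted T2 leaves (1, 1000) ms,
    or where S0 is non-positive.
    """
    te_all = np.asarray(series.echo_times_ms)
    if len(te_all) - 1 < 3:
        raise ConfigurationError("need >= 3 echoes after excluding the first")
    te = te_all[1:]
    data = series.data[..., 1:]
    shape = series.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ConfigurationError("mask shape must match the series")

    y = data[mask].astype(np.float64)  # (n_voxels, n_echoes)
    n = y.shape[0]
    t2 = np.full(shape, np.nan)
    s0map = np.full(shape, np.nan)
    okmap = np.zeros(shape, dtype=bool)
    if n == 0:
        return T2Map(t2, s0map, okmap)

    usable = (y > 0).any(axis=1)
    s0, r2 = _loglinear_init(te, y)

    def cost(s0v, r2v):
        resid = s0v[:, None] * np.exp(-r2v[:, None] * te[None, :]) - y
        return (resid**2).sum(axis=1)

    lam = np.full(n, 1e-3)
    c = cost(s0, r2)
    for _ in range(50):
        e = np.exp(-r2[:, None] * te[None, :])
        resid = s0[:, None] * e - y
        j0 = e  # d resid / d S0
        j1 = -s0[:, None] * te[None, :] * e  # d resid / d R2
        a00 = (j0 * j0).sum(axis=1) * (1.0 + lam)
        a11 = (j1 * j1).sum(axis=1) * (1.0 + lam)
        a01 = (j0 * j1).sum(axis=1)
        g0 = (j0 * resid).sum(axis=1)
        g1 = (j1 * resid).sum(axis=1)
        det = a00 * a11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1.0, det)
        ds0 = -(a11 * g0 - a01 * g1) / det
        dr2 = -(a00 * g1 - a01 * g0) / det
        s0_new = s0 + ds0
        r2_new = np.clip(r2 + dr2, 1.0 / T2_BOUNDS_MS[1] / 10.0, 1.0 / T2_BOUNDS_MS[0] * 10.0)
        c_new = cost(s0_new, r2_new)
        better = c_new < c
        s0 = np.where(better, s0_new, s0)
        r2 = np.where(better, r2_new, r2)
        c = np.where(better, c_new, c)
        lam = np.where(better, lam * 0.5, lam * 4.0)
        if not better.any():
            break

    t2v = 1.0 / r2
    ok = usable & (s0 > 0) & (t2v > T2_BOUNDS_MS[0]) & (t2v < T2_BOUNDS_MS[1]) & np.isfinite(t2v)
    t2[mask] = t2v
    s0map[mask] = s0
    okmap[mask] = ok
    return T2Map(t2, s0map, okmap)


def percent_non_elevated(t2map: T2Map, mask: np.ndarray | None = None) -> float:
    """Percent of valid-fit voxels in the mask with T2 strictly below the threshold."""
    valid = t2map.fit_ok if mask is None else (np.asarray(mask, dtype=bool) & t2map.fit_ok)
    n = int(valid.sum())
    if n == 0:
        warnings.warn("no valid-fit voxels in mask; percent non-elevated undefined", stacklevel=2)
        return float("nan")
    return 100.0 * float((t2map.t2_ms[valid] < t2map.threshold_ms).sum()) / n


def fat_fraction_map(water: ImageVolume, fat: ImageVolume) -> FatFractionMap:
    """Dixon fat fraction: fat / (water + fat), invalid where the denominator is zero."""
    w = np.asarray(water.data, dtype=np.float64)
    f = np.asarray(fat.data, dtype=np.float64)
    if w.shape != f.shape:
        raise ConfigurationError("water and fat volumes must share a shape")
    if (w < 0).any() or (f < 0).any():
        raise ValueError("Dixon magnitude signals must be non-negative")
    denom = w + f
    valid = denom > 0
    ff = np.zeros_like(denom)
    ff[valid] = f[valid] / denom[valid]
    return FatFractionMap(ff, valid)


def roi_mean(
    values: np.ndarray,
    labels: TissueLabelMap,
    roi: str,
    valid: np.ndarray | None = None,
) -> float:
    """Mean of a per-voxel map over an ROI: ``muscle_bundle`` or ``lean_muscle``.

    The muscle bundle is the union of lean muscle and inter/intramuscular
    fat.  Voxels flagged invalid are excluded; an empty ROI yields NaN with
    a warning rather than an exception.
    """
    if roi == "muscle_bundle":
        m = labels.bundle_mask
    elif roi == "lean_muscle":
        m = labels.mask(Tissue.LEAN_MUSCLE)
    else:
        raise ValueError(f"unknown ROI {roi!r}")
    if valid is not None:
        m = m & np.asarray(valid, dtype=bool)
    if not m.any():
        warnings.warn(f"ROI {roi!r} is empty after validity masking", stacklevel=2)
        return float("nan")
    return float(np.asarray(values)[m].mean())


def qc_phantom_t2(
    t2map: T2Map, phantom_region: np.ndarray, expected_range: tuple[float, float] = (80.0, 100.0)
) -> PhantomQCReport:
    """Belt-phantom QC: pass iff the median phantom T2 falls in the expected range."""
    region = np.asarray(phantom_region, dtype=bool) & t2map.fit_ok
    n = int(region.sum())
    if n == 0:
        return PhantomQCReport("error", float("nan"), tuple(expected_range), 0)
    med = float(np.median(t2map.t2_ms[region]))
    status = "pass" if expected_range[0] <= med <= expected_range[1] else "fail"
    return PhantomQCReport(status, med, tuple(expected_range), n)


def extract_visit_biomarkers(
    labels: TissueLabelMap,
    t2map: T2Map,
    ffmap: FatFractionMap,
    t2_slice_window: tuple[int, int] | None = None,
) -> VisitBiomarkers:
    """Assemble the eight endpoints from label, T2 and fat-fraction maps.

    Volumes and Dixon fat-fraction summaries use the full stack (whole-thigh
    acquisitions); T2 summaries may be restricted to a proximal sub-stack
    ``[start, stop)`` of slices, mirroring the shorter coverage of the T2
    mapping acquisition.
    """
    mv, imf, _ = compute_volumes(labels)
    mvi = compute_mvi(mv, imf) if (mv + imf) > 0 else float("nan")

    window = np.zeros(labels.shape, dtype=bool)
    if t2_slice_window is None:
        window[:] = True
    else:
        window[..., t2_slice_window[0] : t2_slice_window[1]] = True

    sub = TissueLabelMap(np.where(window, labels.data, Tissue.BACKGROUND), labels.spacing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t2_bundle = roi_mean(t2map.t2_ms, sub, "muscle_bundle", valid=t2map.fit_ok)
        t2_lean = roi_mean(t2map.t2_ms, sub, "lean_muscle", valid=t2map.fit_ok)
        pct = percent_non_elevated(t2map, sub.bundle_mask)
        ff_bundle = 100.0 * roi_mean(ffmap.ff, labels, "muscle_bundle", valid=ffmap.valid)
        ff_lean = 100.0 * roi_mean(ffmap.ff, labels, "lean_muscle", valid=ffmap.valid)
    return VisitBiomarkers(mv, imf, mvi, t2_bundle, t2_lean, pct, ff_bundle, ff_lean)
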