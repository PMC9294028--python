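"""Automated thigh tissue segmentation.

Two-stage design on the proton-density volume, slice by slice:

1. fuzzy c-means (k=3) over in-thigh intensities plus geometric rules —
   the outermost connected bright component is the subcutaneous fat ring,
   the darkest compact central component is bone; the remaining
   cross-section is the muscle bundle, whose boundary is refined by a
   morphological smoothing step (the "active contour" stage);
2. two-class fuzzy clustering of bundle voxels into lean muscle
   (lower PD intensity) and inter/intramuscular fat (higher PD intensity).

Class-to-tissue assignment uses centroid ordering and geometry rather than
fixed intensity thresholds, so the segmenter is invariant to affine
intensity scaling of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import DegenerateInputError, ImageVolume, Tissue, TissueLabelMap
from .synthetic import derive_seed

__all__ = [
    "SegmentationConfig",
    "FuzzyClusterResult",
    "normalize_volume",
    "fuzzy_cmeans",
    "refine_bundle_boundary",
    "segment_thigh",
]


@dataclass
class SegmentationConfig:
    n_classes_stage1: int = 3
    fuzzifier_m: float = 2.0
    convergence_tol: float = 1e-5
    max_iterations: int = 200
    contour_smoothing_radius: int = 2  # structuring-element radius, voxels
    max_area_change_frac: float = 0.10  # boundary refinement sanity bound
    min_component_voxels: int = 4  # smaller components merge into surroundings
    background_threshold: float = 0.08  # on the normalized volume
    min_centroid_gap: float = 0.15  # stage-2 lean/fat separability (normalized units)

    def __post_init__(self) -> None:
        if self.fuzzifier_m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence tolerance must be positive")


@dataclass
class FuzzyClusterResult:
    centroids: np.ndarray  # ascending intensity order
    memberships: np.ndarray  # (n_samples, k), rows sum to 1
    iterations_run: int
    converged: bool
    objective: float


def normalize_volume(volume: ImageVolume) -> ImageVolume:
    """Map intensities to [0, 1] by robust p1-p99 percentile scaling."""
    x = np.asarray(volume.data, dtype=np.float64)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise DegenerateInputError("volume must be non-empty with finite values")
    p1, p99 = np.percentile(x, [1.0, 99.0])
    if p99 - p1 <= 1e-12:
        raise DegenerateInputError("constant-intensity volume cannot be normalized")
    return ImageVolume(np.clip((x - p1) / (p99 - p1), 0.0, 1.0), volume.spacing)


def fuzzy_cmeans(
    values: np.ndarray, k: int, config: SegmentationConfig | None = None, seed: int = 0
) -> FuzzyClusterResult:
    """Standard fuzzy c-means on a 1-D intensity sample.

    Alternating updates: memberships ``u_ij = 1 / sum_l (d_ij/d_lj)^(2/(m-1))``
    then weighted centroid means ``v_i = sum_j u_ij^m x_j / sum_j u_ij^m``.
    Centroids are initialized evenly spaced over the sample range at
    positions ``(2i+1)/(2k)`` (deterministic, and robust when cluster sizes
    are highly unequal); iteration stops when the
    largest centroid shift drops below the convergence tolerance.  The final
    centroids are returned in ascending order with memberships re-ordered to
    match.  ``seed`` is accepted for interface stability but the procedure
    is deterministic.
    """
    config = config or SegmentationConfig()
    x = np.asarray(values, dtype=np.float64).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.size < k:
        raise DegenerateInputError(f"need at least k={k} samples")
    uniq = np.unique(x)
    if uniq.size < k:
        raise DegenerateInputError(f"need at least k={k} distinct values")

    lo, hi = float(x.min()), float(x.max())
    v = lo + (hi - lo) * (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    m = config.fuzzifier_m
    power = 2.0 / (m - 1.0)

    u = np.empty((x.size, k))
    it = 0
    converged = False
    for it in range(1, config.max_iterations + 1):
        d = np.abs(x[:, None] - v[None, :])
        zero = d < 1e-15
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-power)
            u = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        um = u**m
        v_new = um.T @ x / um.sum(axis=0)
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        if shift < config.convergence_tol:
            converged = True
            break

    order = np.argsort(v)
    v, u = v[order], u[:, order]
    d = np.abs(x[:, None] - v[None, :])
    objective = float(np.sum((u**m) * d**2))
    return FuzzyClusterResult(v, u, it, converged, objective)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def refine_bundle_boundary(mask: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Smooth a per-slice binary region to a single simply connected component.

    Morphological closing then opening with a disk, retaining the largest
    connected component and filling holes — a morphological-snake-style
    boundary regularization.  Warns if a slice is empty (passed through) or
    if the refined area departs from the input by more than the configured
    fraction.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    single = mask.ndim == 2
    stack = mask[..., None] if single else mask
    out = np.zeros_like(stack)
    selem = morphology.disk(config.contour_smoothing_radius)
    for z in range(stack.shape[2]):
        sl = stack[..., z]
        if not sl.any():
            warnings.warn(f"empty bundle mask on slice {z}; passed through", stacklevel=2)
            continue
        r = ndimage.binary_closing(sl, structure=selem)
        r = ndimage.binary_opening(r, structure=selem)
        if not r.any():  # opening removed everything (tiny region); keep input
            r = sl
        r = _largest_component(r)
        r = ndimage.binary_fill_holes(r)
        change = abs(int(r.sum()) - int(sl.sum())) / max(int(sl.sum()), 1)
        if change > config.max_area_change_frac:
            warnings.warn(f"bundle refinement changed slice {z} area by {change:.1%}", stacklevel=2)
        out[..., z] = r
    return out[..., 0] if single else out


def _classify_slice(
    sl: np.ndarray, config: SegmentationConfig, seed: int
) -> np.ndarray:
    """Stage-1 + stage-2 labelling of a single normalized PD slice."""
    nx, ny = sl.shape
    labels = np.zeros((nx, ny), dtype=np.int16)

    fg = ndimage.binary_closing(sl > config.background_threshold, structure=morphology.disk(1))
    lab, n = ndimage.label(fg)
    if n == 0:
        return labels
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    thigh_id = 1 + int(np.argmax(sizes))
    thigh = ndimage.binary_fill_holes(lab == thigh_id)
    for comp in range(1, n + 1):
        if comp != thigh_id and sizes[comp - 1] >= config.min_component_voxels:
            labels[lab == comp] = Tissue.PHANTOM

    vals = sl[thigh]
    try:
        fcm = fuzzy_cmeans(vals, config.n_classes_stage1, config, seed=seed)
    except DegenerateInputError:
        labels[thigh] = Tissue.LEAN_MUSCLE
        return labels
    # hard assignment by maximum membership; ties go to the lower-intensity class
    cls = np.argmax(fcm.memberships, axis=1)
    class_map = np.full((nx, ny), -1, dtype=np.int8)
    class_map[thigh] = cls  # 0 dark, 1 mid, 2 bright

    bright = class_map == 2
    shell = thigh & ~ndimage.binary_erosion(thigh, iterations=2)
    blab, bn = ndimage.label(bright)
    ring_ids = np.unique(blab[bright & shell])
    ring_ids = ring_ids[ring_ids > 0]
    subcut = np.isin(blab, ring_ids) if ring_ids.size else np.zeros_like(bright)

    if not subcut.any():
        warnings.warn("no closed subcutaneous fat ring found; intensity-only fallback", stacklevel=3)
        bundle = thigh.copy()
    else:
        bundle = thigh & ~subcut
        bundle = refine_bundle_boundary(bundle, config)

    # bone: darkest-class compact component closest to the bundle centroid
    dark = (class_map == 0) & bundle
    bone = np.zeros_like(dark)
    dlab, dn = ndimage.label(dark)
    if dn and bundle.any():
        cyx = np.array(ndimage.center_of_mass(bundle))
        best, best_dist = 0, np.inf
        for comp in range(1, dn + 1):
            size = int((dlab == comp).sum())
            if size < config.min_component_voxels:
                continue
            c = np.array(ndimage.center_of_mass(dlab == comp))
            dist = float(np.hypot(*(c - cyx)))
            if dist < best_dist:
                best, best_dist = comp, dist
        if best:
            bone = ndimage.binary_fill_holes(dlab == best)

    tissue_bundle = bundle & ~bone
    labels[subcut] = Tissue.SUBCUTANEOUS_FAT
    labels[bone & bundle] = Tissue.BONE
    labels[thigh & ~bundle & ~subcut] = Tissue.SUBCUTANEOUS_FAT  # residual rim voxels
    labels[tissue_bundle] = Tissue.LEAN_MUSCLE

    # stage 2: lean vs inter/intramuscular fat within the bundle
    bvals = sl[tissue_bundle]
    if bvals.size >= 2:
        try:
            fcm2 = fuzzy_cmeans(bvals, 2, config, seed=derive_seed(seed, 2))
            gap = float(fcm2.centroids[1] - fcm2.centroids[0])
            if gap >= config.min_centroid_gap:
                hard = np.argmax(fcm2.memberships, axis=1)  # argmax tie -> lower class
                fat = np.zeros_like(tissue_bundle)
                fat[tissue_bundle] = hard == 1
                fat = morphology.remove_small_objects(fat, max_size=config.min_component_voxels - 1)
                lean_holes = tissue_bundle & ~fat
                small_lean = lean_holes & ~morphology.remove_small_objects(
                    lean_holes, max_size=config.min_component_voxels - 1
                )
                # tiny lean islands fully inside fat merge into fat
                fat |= small_lean & ndimage.binary_dilation(fat)
                labels[fat] = Tissue.INTERMUSCULAR_FAT
        except DegenerateInputError:
            pass  # homogeneous bundle: all lean
    return labels


def segment_thigh(
    pd_volume: ImageVolume, config: SegmentationConfig | None = None, seed: int = 0
) -> TissueLabelMap:
    """Segment a normalized proton-density volume into the tissue palette.

    Operates per slice (matching slice-wise acquisition) with a light 3-D
    consistency pass: bone is constrained to its largest 3-D connected
    component, stray bone voxels reverting to lean muscle.
    """
    config = config or SegmentationConfig()
    x = np.asarray(pd_volume.data, dtype=np.float64)
    if x.min() < -0.01 or x.max() > 1.01:
        raise ValueError("segment_thigh expects a normalized volume (see normalize_volume)")
    if np.ptp(x) <= 1e-12:
        raise DegenerateInputError("degenerate constant volume")

    labels = np.zeros(x.shape, dtype=np.int16)
    for z in range(x.shape[2]):
        labels[..., z] = _classify_slice(x[..., z], config, seed=derive_seed(seed, 1, z))

    bone = labels == Tissue.BONE
    if bone.any():
        keep = _largest_component(bone)
        labels[bone & ~keep] = Tissue.LEAN_MUSCLE
    return TissueLabelMap(labels, pd_volume.spacing)
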