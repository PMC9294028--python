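"""Synthetic DMD thigh-MRI trial generator.

Emulates a two-arm imaging trial in ambulatory boys with Duchenne muscular
dystrophy: each subject carries a latent *infiltration* trajectory (the
fraction of the thigh muscle bundle replaced by inter/intramuscular fat),
which drives

* rendered imaging volumes per visit (proton-density stack, multi-echo
  spin-echo series, Dixon water/fat pair) with known ground-truth labels,
* timed-function (4-stair-climb) and NSAA outcomes, and
* loss-of-ambulation event times from a proportional-hazards model.

The treatment arm progresses at a configurable multiple of the placebo rate,
so a protective effect (multiplier < 1) exists by construction and every
downstream estimator can be checked against generator truth.

All randomness flows from ``numpy.random.SeedSequence`` keys derived from a
single root seed (see :func:`derive_seed`), so identical configuration and
seed reproduce byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter

from .core import ConfigurationError, ImageVolume, MultiEchoSeries, Tissue, TissueLabelMap

__all__ = [
    "CohortConfig",
    "PhantomSpec",
    "OutcomeConfig",
    "TabularMeasurementConfig",
    "SubjectState",
    "VisitImaging",
    "FunctionalOutcomes",
    "derive_seed",
    "simulate_cohort",
    "render_visit",
    "simulate_outcomes",
    "simulate_biomarker_table",
    "BIOMARKER_COLUMNS",
]

#: Canonical biomarker column names, matching the eight per-visit endpoints.
BIOMARKER_COLUMNS = (
    "muscle_volume_mm3",
    "intermuscular_fat_volume_mm3",
    "mvi_percent",
    "t2_bundle_ms",
    "t2_lean_ms",
    "pct_non_elevated",
    "ff_bundle_percent",
    "ff_lean_percent",
)

DEFAULT_VISIT_WEEKS = (0, 17, 33, 49, 97)


def derive_seed(root: int, *key: int) -> int:
    """Derive a subsidiary 31-bit seed from a root seed and an integer key path.

    Uses :class:`numpy.random.SeedSequence` hashing so subject- and
    visit-level streams are independent yet fully reproducible.
    """
    return int(np.random.SeedSequence((int(root), *map(int, key))).generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Trial-generation parameters.

    The disease model is a subject-specific linear growth of the latent
    infiltration fraction: ``f_v = clip(f0 + r_i * week_v, 0, 1)`` with
    ``r_i = rate * arm_multiplier * exp(b_i)`` and
    ``b_i ~ N(-sd^2/2, sd^2)`` (mean-one lognormal), so the arm means obey
    ``E[f_v - f0] = rate * multiplier * week_v`` exactly.  Baseline
    infiltration follows a logistic curve in age (disease burden accrues
    fastest around 8-10 years).
    """

    arm_ratio: float = 2.0  # treatment : placebo, trial randomised 2:1
    age_range: tuple[float, float] = (6.0, 12.0)
    visit_weeks: tuple[int, ...] = DEFAULT_VISIT_WEEKS
    infiltration_rate_per_week: float = 0.004
    treatment_rate_multiplier: float = 0.5
    rate_sd_log: float = 0.4  # between-subject lognormal sd of the rate
    baseline_max: float = 0.60  # logistic plateau of baseline infiltration
    baseline_age_mid: float = 9.5  # years at half-plateau
    baseline_age_scale: float = 1.8  # logistic width, years
    baseline_sd: float = 0.05  # additive subject noise on baseline
    baseline_clip: tuple[float, float] = (0.02, 0.95)
    stratum_edges: tuple[float, ...] = (8.0, 11.0)  # age-band stratification

    def validate(self) -> None:
        if self.infiltration_rate_per_week <= 0:
            raise ConfigurationError("infiltration rate must be positive")
        if self.treatment_rate_multiplier <= 0:
            raise ConfigurationError("treatment rate multiplier must be positive")
        if self.rate_sd_log < 0 or self.baseline_sd < 0:
            raise ConfigurationError("variances must be non-negative")
        if self.arm_ratio <= 0:
            raise ConfigurationError("arm ratio must be positive")
        weeks = tuple(self.visit_weeks)
        if len(weeks) < 2 or weeks[0] != 0 or any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigurationError("visit weeks must start at 0 and strictly increase")
        if not (0 < self.baseline_max < 1):
            raise ConfigurationError("baseline plateau must lie in (0, 1)")


@dataclass
class PhantomSpec:
    """Geometry and signal model of the rendered thigh phantom.

    Slice thickness is fixed at 5 mm (axial stack, 0 mm gap).  Tissue T2
    defaults keep lean muscle (40 ms) below the 55 ms elevation threshold and
    fat (150 ms) well above it; the copper-sulfate belt phantom sits at 90 ms.
    """

    slice_count: int = 12
    in_plane_shape: tuple[int, int] = (96, 96)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    tissue_T2: Mapping[str, float] = field(
        default_factory=lambda: {"lean_muscle": 40.0, "fat": 150.0, "bone": 5.0, "phantom": 90.0}
    )
    tissue_PD_intensity: Mapping[str, float] = field(
        default_factory=lambda: {
            "background": 0.0,
            "bone": 0.12,
            "lean_muscle": 0.45,
            "fat": 1.0,
            "phantom": 0.70,
        }
    )
    noise_sigma: float = 0.02  # Rician sigma, same arbitrary units as PD S0
    echo_times: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0)
    stim_echo_bias: float = 0.08  # fractional inflation of the first echo only
    lean_t2_slope: float = 0.5  # lean T2 grows by this fraction per unit infiltration
    ff_lean_base: float = 0.10  # lean-muscle fat fraction at zero infiltration
    ff_lean_slope: float = 0.25  # lean FF increase per unit infiltration
    ff_fat: float = 0.90
    ff_bone: float = 0.15
    blob_smoothing_sigma: float = 2.5  # in-plane voxels; spatial coherence of infiltration

    def validate(self) -> None:
        if self.voxel_spacing[2] != 5.0:
            raise ConfigurationError("slice thickness must be 5 mm (axial stack, 0 mm gap)")
        if any(t2 <= 0 for t2 in self.tissue_T2.values()):
            raise ConfigurationError("tissue T2 values must be positive")
        te = tuple(self.echo_times)
        if len(te) < 4 or any(b <= a for a, b in zip(te, te[1:])):
            raise ConfigurationError("need >= 4 strictly increasing echo times")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")
        if min(self.in_plane_shape) < 24 or self.slice_count < 1:
            raise ConfigurationError("volume too small to contain the thigh geometry")


@dataclass
class OutcomeConfig:
    """Latent link from infiltration to function and ambulation loss.

    4SC time is lognormal with log-mean linear in infiltration; NSAA is a
    truncated, rounded Gaussian declining with infiltration.  Loss of
    ambulation follows a proportional-hazards model whose log-hazard is
    linear in the *current* (carried-forward) infiltration plus baseline age.
    """

    log4sc_base_mean: float = math.log(5.0)  # log-seconds at zero infiltration
    log4sc_base_sd: float = 0.25
    beta_4sc: float = 2.5  # log-seconds per unit infiltration
    noise_4sc_sd: float = 0.08
    nsaa_base_mean: float = 32.0
    nsaa_age_slope: float = -1.0  # points per year of baseline age above 6
    nsaa_base_sd: float = 2.0
    beta_nsaa: float = 25.0  # points lost per unit infiltration
    noise_nsaa_sd: float = 1.0
    baseline_hazard_per_day: float = 4.5e-5
    log_hr_per_infiltration: float = math.log(2.0) / 0.25  # HR 2 per +0.25 infiltration
    log_hr_per_year: float = 0.10  # age covariate on the log-hazard
    study_end_day: int = 97 * 7

    def validate(self) -> None:
        if min(self.log4sc_base_sd, self.noise_4sc_sd, self.nsaa_base_sd, self.noise_nsaa_sd) < 0:
            raise ConfigurationError("outcome noise SDs must be non-negative")
        if self.baseline_hazard_per_day <= 0:
            raise ConfigurationError("baseline hazard must be positive")
        if self.study_end_day <= 0:
            raise ConfigurationError("study length must be positive")


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class SubjectState:
    """Latent disease state of one virtual participant."""

    subject_id: str
    arm: str  # {"treatment", "placebo"}
    age_baseline: float
    stratum: str
    infiltration: np.ndarray  # one fraction per visit, non-decreasing pre-noise
    visit_weeks: tuple[int, ...]

    def __post_init__(self) -> None:
        self.infiltration = np.asarray(self.infiltration, dtype=np.float64)
        if np.any(self.infiltration < 0) or np.any(self.infiltration > 1):
            raise ConfigurationError("infiltration fractions must lie in [0, 1]")
        if len(self.infiltration) != len(self.visit_weeks):
            raise ConfigurationError("one infiltration value per visit required")


@dataclass
class VisitImaging:
    """All acquisitions of one subject-visit plus generator ground truth."""

    pd_volume: ImageVolume
    multi_echo: MultiEchoSeries
    dixon_water: ImageVolume
    dixon_fat: ImageVolume
    truth_labels: TissueLabelMap
    truth_fat_fraction: np.ndarray


@dataclass
class FunctionalOutcomes:
    """Per-visit functional scores and the ambulation event for one subject."""

    fourSC_seconds: np.ndarray
    nsaa_total: np.ndarray
    ambulation_event_day: float  # event or censoring day
    ambulation_event: bool  # True if the event was observed


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _stratum_label(age: float, edges: Sequence[float], lo: float, hi: float) -> str:
    bounds = [lo, *edges, hi]
    idx = int(np.digitize(age, edges))
    return f"{bounds[idx]:g}-{bounds[idx + 1]:g}"


def simulate_cohort(n_subjects: int, config: CohortConfig | None = None, seed: int = 0) -> list[SubjectState]:
    """Draw a virtual trial cohort of latent disease trajectories.

    Deterministic given ``(config, seed)``.  Arm assignment respects
    ``config.arm_ratio``; infiltration grows linearly per week at a
    subject-specific rate, slowed multiplicatively in the treatment arm.
    """
    config = config or CohortConfig()
    config.validate()
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0)))
    n_treat = int(round(n_subjects * config.arm_ratio / (1.0 + config.arm_ratio)))
    n_treat = min(max(n_treat, 1), n_subjects - 1)
    arms = np.array(["placebo"] * n_subjects, dtype=object)
    arms[rng.permutation(n_subjects)[:n_treat]] = "treatment"

    ages = rng.uniform(*config.age_range, size=n_subjects)
    weeks = np.asarray(config.visit_weeks, dtype=np.float64)
    lo, hi = config.baseline_clip

    subjects: list[SubjectState] = []
    for i in range(n_subjects):
        f0 = config.baseline_max / (1.0 + math.exp(-(ages[i] - config.baseline_age_mid) / config.baseline_age_scale))
        f0 += rng.normal(0.0, config.baseline_sd) if config.baseline_sd > 0 else 0.0
        f0 = float(np.clip(f0, lo, hi))
        mult = config.treatment_rate_multiplier if arms[i] == "treatment" else 1.0
        sd = config.rate_sd_log
        b = rng.normal(-0.5 * sd * sd, sd) if sd > 0 else 0.0
        rate_i = config.infiltration_rate_per_week * mult * math.exp(b)
        traj = np.clip(f0 + rate_i * weeks, 0.0, 1.0)
        subjects.append(
            SubjectState(
                subject_id=f"S{i + 1:04d}",
                arm=str(arms[i]),
                age_baseline=float(ages[i]),
                stratum=_stratum_label(ages[i], config.stratum_edges, config.age_range[0], config.age_range[1]),
                infiltration=traj,
                visit_weeks=tuple(int(w) for w in config.visit_weeks),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |signal + complex Gaussian|."""
    if sigma <= 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def _thigh_geometry(spec: PhantomSpec, geo_rng: np.random.Generator) -> dict:
    """Per-subject slice geometry: concentric ellipses with mild jitter."""
    nx, ny = spec.in_plane_shape
    nz = spec.slice_count
    a0 = 0.33 * nx * (1.0 + 0.04 * geo_rng.uniform(-1, 1))
    b0 = 0.31 * ny * (1.0 + 0.04 * geo_rng.uniform(-1, 1))
    if min(a0, b0) < 5.0:
        raise ConfigurationError("in-plane shape too small to contain the thigh geometry")
    centers = np.stack(
        [
            nx / 2.0 + geo_rng.uniform(-0.015 * nx, 0.015 * nx, nz),
            ny / 2.0 + geo_rng.uniform(-0.015 * ny, 0.015 * ny, nz),
        ],
        axis=1,
    )
    jitter = 1.0 + geo_rng.uniform(-0.02, 0.02, nz)
    return {"a": a0, "b": b0, "centers": centers, "jitter": jitter, "rho_bundle": 0.80, "rho_bone": 0.16}


def _base_labels(spec: PhantomSpec, geom: dict) -> np.ndarray:
    """Render the infiltration-free label volume (bundle all lean)."""
    nx, ny = spec.in_plane_shape
    nz = spec.slice_count
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    # belt phantom in the image corner, well clear of the thigh ellipse
    px, py = 0.12 * nx, 0.12 * ny
    pr = max(1.8, 0.05 * nx)
    phantom = (xi - px) ** 2 + (yi - py) ** 2 <= pr**2

    for z in range(nz):
        cx, cy = geom["centers"][z]
        a = geom["a"] * geom["jitter"][z]
        b = geom["b"] * geom["jitter"][z]
        rho = np.sqrt(((xi - cx) / a) ** 2 + ((yi - cy) / b) ** 2)
        sl = np.zeros((nx, ny), dtype=np.int16)
        sl[rho <= 1.0] = Tissue.SUBCUTANEOUS_FAT
        sl[rho <= geom["rho_bundle"]] = Tissue.LEAN_MUSCLE
        sl[rho <= geom["rho_bone"]] = Tissue.BONE
        sl[phantom & (sl == Tissue.BACKGROUND)] = Tissue.PHANTOM
        labels[..., z] = sl
    return labels


def render_visit(
    subject: SubjectState,
    visit_index: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    t2_scale: float = 1.0,
) -> VisitImaging:
    """Render all acquisitions for one subject-visit with ground truth.

    The thigh is concentric ellipses per slice (subcutaneous fat ring,
    muscle bundle behind a one-voxel fascia margin, central bone) plus a
    copper-sulfate belt phantom at the image edge.  A fraction equal to the
    subject's infiltration at this visit of *all* bundle voxels is converted
    to inter/intramuscular fat by thresholding a fixed, spatially smoothed
    per-subject noise field, so infiltrated regions are coherent blobs that
    grow monotonically across visits.

    ``seed`` should be subject-level: geometry and the infiltration field
    depend only on it (stable across visits) while acquisition noise also
    keys on ``visit_index``.  ``t2_scale`` multiplies every tissue T2 —
    a deliberate miscalibration hook for phantom-belt QC testing.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    if not 0 <= visit_index < len(subject.visit_weeks):
        raise ConfigurationError(f"visit_index {visit_index} out of range")

    geo_rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x6E0)))
    noise_rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA0 + int(visit_index))))

    geom = _thigh_geometry(spec, geo_rng)
    labels = _base_labels(spec, geom)

    # spatially correlated infiltration: pick the top-k voxels of a fixed
    # smoothed field among the bundle interior (one-voxel fascia margin keeps
    # blobs disconnected from the subcutaneous ring)
    field3 = geo_rng.normal(size=labels.shape)
    sig = spec.blob_smoothing_sigma
    field3 = gaussian_filter(field3, sigma=(sig, sig, max(0.5, sig / 3.0)))
    bundle = labels == Tissue.LEAN_MUSCLE
    eligible = np.zeros_like(bundle)
    for z in range(labels.shape[2]):
        eligible[..., z] = binary_erosion(bundle[..., z], iterations=1)
    f = float(subject.infiltration[visit_index])
    n_bundle = int(bundle.sum())
    k = int(round(f * n_bundle))
    k = min(k, int(eligible.sum()))
    if k > 0:
        vals = np.where(eligible, field3, -np.inf)
        flat = np.argpartition(vals.ravel(), -k)[-k:]
        mask = np.zeros(labels.size, dtype=bool)
        mask[flat] = True
        labels[mask.reshape(labels.shape)] = Tissue.INTERMUSCULAR_FAT

    # per-voxel tissue parameters
    pd_i = spec.tissue_PD_intensity
    s0 = np.zeros(labels.shape)
    t2 = np.full(labels.shape, np.inf)
    ff = np.zeros(labels.shape)
    lean_t2 = spec.tissue_T2["lean_muscle"] * (1.0 + spec.lean_t2_slope * f)
    ff_lean = float(np.clip(spec.ff_lean_base + spec.ff_lean_slope * f, 0.0, 1.0))
    for tissue, s0v, t2v, ffv in (
        (Tissue.BONE, pd_i["bone"], spec.tissue_T2["bone"], spec.ff_bone),
        (Tissue.SUBCUTANEOUS_FAT, pd_i["fat"], spec.tissue_T2["fat"], spec.ff_fat),
        (Tissue.LEAN_MUSCLE, pd_i["lean_muscle"], lean_t2, ff_lean),
        (Tissue.INTERMUSCULAR_FAT, pd_i["fat"], spec.tissue_T2["fat"], spec.ff_fat),
        (Tissue.PHANTOM, pd_i["phantom"], spec.tissue_T2["phantom"], 0.02),
    ):
        m = labels == tissue
        s0[m], t2[m], ff[m] = s0v, t2v, ffv
    t2 = t2 * float(t2_scale)

    pd_vol = ImageVolume(_rician(s0, spec.noise_sigma, noise_rng), spec.voxel_spacing)

    te = np.asarray(spec.echo_times)
    with np.errstate(divide="ignore"):
        decay = np.exp(-te[None, None, None, :] / t2[..., None])
    echoes = s0[..., None] * decay
    echoes[..., 0] *= 1.0 + spec.stim_echo_bias  # stimulated-echo contamination
    echoes = _rician(echoes, spec.noise_sigma, noise_rng)
    series = MultiEchoSeries(tuple(spec.echo_times), echoes, spec.voxel_spacing)

    water = ImageVolume(_rician(s0 * (1.0 - ff), spec.noise_sigma, noise_rng), spec.voxel_spacing)
    fat = ImageVolume(_rician(s0 * ff, spec.noise_sigma, noise_rng), spec.voxel_spacing)

    return VisitImaging(
        pd_volume=pd_vol,
        multi_echo=series,
        dixon_water=water,
        dixon_fat=fat,
        truth_labels=TissueLabelMap(labels, spec.voxel_spacing),
        truth_fat_fraction=ff,
    )


# ---------------------------------------------------------------------------
# functional outcomes and ambulation events
# ---------------------------------------------------------------------------


def simulate_outcomes(
    subject: SubjectState, config: OutcomeConfig | None = None, seed: int = 0
) -> FunctionalOutcomes:
    """Draw 4SC / NSAA trajectories and a loss-of-ambulation time.

    4SC worsens (log-linearly) and NSAA declines with the subject's current
    infiltration; the ambulation hazard is piecewise-constant between visits
    with log-hazard linear in carried-forward infiltration plus baseline age.
    """
    config = config or OutcomeConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x0F)))
    f = subject.infiltration

    base_log = config.log4sc_base_mean + (
        rng.normal(0.0, config.log4sc_base_sd) if config.log4sc_base_sd > 0 else 0.0
    )
    eps = rng.normal(0.0, config.noise_4sc_sd, len(f)) if config.noise_4sc_sd > 0 else np.zeros(len(f))
    four_sc = np.exp(base_log + config.beta_4sc * f + eps)

    nsaa_base = (
        config.nsaa_base_mean
        + config.nsaa_age_slope * (subject.age_baseline - 6.0)
        + (rng.normal(0.0, config.nsaa_base_sd) if config.nsaa_base_sd > 0 else 0.0)
    )
    eps_n = rng.normal(0.0, config.noise_nsaa_sd, len(f)) if config.noise_nsaa_sd > 0 else np.zeros(len(f))
    nsaa = np.clip(np.round(nsaa_base - config.beta_nsaa * f + eps_n), 0, 34).astype(int)

    # piecewise-exponential event time: hazard constant between visits,
    # infiltration carried forward from the most recent visit
    days = np.asarray(subject.visit_weeks, dtype=float) * 7.0
    edges = np.append(days, float(config.study_end_day))
    u = rng.exponential(1.0)
    cum = 0.0
    event_day = float(config.study_end_day)
    event = False
    for j in range(len(days)):
        if edges[j + 1] <= edges[j]:
            continue
        lam = config.baseline_hazard_per_day * math.exp(
            config.log_hr_per_infiltration * f[j] + config.log_hr_per_year * subject.age_baseline
        )
        seg = lam * (edges[j + 1] - edges[j])
        if cum + seg >= u:
            event_day = edges[j] + (u - cum) / lam
            event = True
            break
        cum += seg
    return FunctionalOutcomes(four_sc, nsaa, float(event_day), event)


# ---------------------------------------------------------------------------
# fast tabular path (no image rendering)
# ---------------------------------------------------------------------------


@dataclass
class TabularMeasurementConfig:
    """Measurement model mapping latent infiltration to the eight endpoints.

    Used by the tabular simulation path (statistical calibration work where
    rendering and segmenting images would only add voxel-level noise around
    the same latent truth).  Bundle volume is subject-specific; endpoint
    noise SDs are small relative to the trajectories they measure.
    """

    bundle_volume_base_mm3: float = 1.55e6
    bundle_volume_age_slope: float = 0.03  # relative per year from age 9
    bundle_volume_sd_log: float = 0.10
    volume_noise_sd_log: float = 0.01
    t2_lean_base_ms: float = 40.0
    t2_lean_slope: float = 0.5
    t2_fat_ms: float = 150.0
    t2_noise_sd_ms: float = 0.5
    pct_noise_sd: float = 1.0
    ff_lean_base: float = 0.10
    ff_lean_slope: float = 0.25
    ff_fat: float = 0.90
    ff_noise_sd_percent: float = 0.5


def simulate_biomarker_table(
    subjects: Sequence[SubjectState],
    outcome_config: OutcomeConfig | None = None,
    measurement: TabularMeasurementConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a long-format subject x visit cohort table directly from latent state.

    Bypasses rendering/segmentation: biomarkers are computed from the same
    latent infiltration the renderer uses, plus measurement noise.  Columns
    follow the CohortTable schema consumed by the statistics layer.
    """
    outcome_config = outcome_config or OutcomeConfig()
    measurement = measurement or TabularMeasurementConfig()
    m = measurement
    rows = []
    for i, s in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xB10, i)))
        out = simulate_outcomes(s, outcome_config, seed=derive_seed(seed, 0x0D, i))
        vb = m.bundle_volume_base_mm3 * (1.0 + m.bundle_volume_age_slope * (s.age_baseline - 9.0))
        if m.bundle_volume_sd_log > 0:
            vb *= math.exp(rng.normal(-0.5 * m.bundle_volume_sd_log**2, m.bundle_volume_sd_log))
        for v, week in enumerate(s.visit_weeks):
            f = float(s.infiltration[v])
            e = rng.normal(0.0, 1.0, 8)
            mv = vb * (1.0 - f) * math.exp(m.volume_noise_sd_log * e[0])
            imf = vb * f * math.exp(m.volume_noise_sd_log * e[1])
            t2_lean_true = m.t2_lean_base_ms * (1.0 + m.t2_lean_slope * f)
            ff_lean_frac = m.ff_lean_base + m.ff_lean_slope * f
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "arm": s.arm,
                    "stratum": s.stratum,
                    "age_baseline": s.age_baseline,
                    "week": int(week),
                    "visit_type": "scheduled",
                    "muscle_volume_mm3": mv,
                    "intermuscular_fat_volume_mm3": imf,
                    "mvi_percent": 100.0 * mv / (mv + imf),
                    "t2_bundle_ms": (1 - f) * t2_lean_true + f * m.t2_fat_ms + m.t2_noise_sd_ms * e[2],
                    "t2_lean_ms": t2_lean_true + m.t2_noise_sd_ms * e[3],
                    "pct_non_elevated": float(np.clip(100.0 * (1.0 - f) + m.pct_noise_sd * e[4], 0, 100)),
                    "ff_bundle_percent": 100.0 * ((1 - f) * ff_lean_frac + f * m.ff_fat)
                    + m.ff_noise_sd_percent * e[5],
                    "ff_lean_percent": 100.0 * ff_lean_frac + m.ff_noise_sd_percent * e[6],
                    "fourSC_seconds": float(out.fourSC_seconds[v]),
                    "nsaa_total": int(out.nsaa_total[v]),
                    "ambulation_event_day": out.ambulation_event_day,
                    "ambulation_event": int(out.ambulation_event),
                }
            )
    return pd.DataFrame(rows)
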