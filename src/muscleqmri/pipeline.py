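"""End-to-end trial-in-a-box: generate -> segment -> extract -> analyze -> report.

``run_pipeline`` executes the full chain on a synthetic cohort and writes a
reproducible output tree::

    <out>/config.yaml          configuration echo
    <out>/images/<subject>/week_<w>/*.nii.gz     (optional)
    <out>/tables/*.csv         cohort table, CFB table, per-analysis results
    <out>/plots/*.png          trajectories and biomarker-vs-age scatters
    <out>/report.txt           human-readable statistics report
    <out>/run_manifest.json    per-scan QC, stage status, checksums, seed

Scans whose belt-phantom T2 falls outside the expected range are marked
non-evaluable and excluded from the statistics input; the manifest records
the reason and the overall evaluable fraction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import extract_visit_biomarkers, fat_fraction_map, fit_t2_map, qc_phantom_t2
from .core import Tissue
from .plotting import plot_biomarkers_vs_age, plot_trajectories
from .segmentation import SegmentationConfig, normalize_volume, segment_thigh
from .stats import (
    MMRM,
    MedianSplitCox,
    TimeVaryingCox,
    bivariate_tree,
    build_time_varying_table,
    derive_cfb,
    find_cutpoint,
    regress_mri_on_function,
)
from .synthetic import (
    BIOMARKER_COLUMNS,
    CohortConfig,
    OutcomeConfig,
    PhantomSpec,
    derive_seed,
    render_visit,
    simulate_cohort,
    simulate_outcomes,
)

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline", "ENDPOINT_SCALE", "HIGHER_IS_BETTER"]

#: Analysis scale per endpoint: volumes and MVI are analysed as percent
#: change from baseline, T2 / percent-non-elevated / fat-fraction as
#: absolute change from baseline.
ENDPOINT_SCALE = {
    "muscle_volume_mm3": "percent",
    "intermuscular_fat_volume_mm3": "percent",
    "mvi_percent": "percent",
    "t2_bundle_ms": "absolute",
    "t2_lean_ms": "absolute",
    "pct_non_elevated": "absolute",
    "ff_bundle_percent": "absolute",
    "ff_lean_percent": "absolute",
}

#: Favourable direction per endpoint (orients the median-split Cox covariate).
HIGHER_IS_BETTER = {
    "muscle_volume_mm3": True,
    "intermuscular_fat_volume_mm3": False,
    "mvi_percent": True,
    "t2_bundle_ms": False,
    "t2_lean_ms": False,
    "pct_non_elevated": True,
    "ff_bundle_percent": False,
    "ff_lean_percent": False,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records the details."""


@dataclass
class RunConfig:
    n_subjects: int = 12
    seed: int = 0
    output_dir: str = "muscleqmri_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    outcomes: OutcomeConfig = field(default_factory=OutcomeConfig)
    t2_threshold_ms: float = 55.0
    t2_proximal_fraction: float = 0.4  # leading slice fraction used for T2 summaries
    qc_expected_t2_range: tuple[float, float] = (80.0, 100.0)
    qc_fault_scans: tuple[tuple[str, int], ...] = ()  # (subject_id, week) with miscalibrated T2
    qc_fault_t2_scale: float = 1.3
    mmrm_weeks: tuple[int, ...] = (17, 33, 49)
    write_images: bool = True
    make_plots: bool = True
    run_survival: bool = True
    run_regressions: bool = True

    def t2_slice_window(self) -> tuple[int, int]:
        nz = self.phantom.slice_count
        return (0, max(1, round(self.t2_proximal_fraction * nz)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(dataclasses.asdict(self)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("cohort", CohortConfig),
            ("phantom", PhantomSpec),
            ("segmentation", SegmentationConfig),
            ("outcomes", OutcomeConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = _coerce_dataclass(sub, kwargs[key])
        if "qc_fault_scans" in kwargs:
            kwargs["qc_fault_scans"] = tuple((str(s), int(w)) for s, w in kwargs["qc_fault_scans"])
        for key in ("qc_expected_t2_range", "mmrm_weeks"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _coerce_dataclass(cls, raw: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        val = raw[f.name]
        if isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict[str, str] = field(default_factory=dict)
    scans: list[dict] = field(default_factory=list)
    warnings_log: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    evaluable_fraction: float = float("nan")

    def write(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["evaluable_fraction"] = (
            None if math.isnan(self.evaluable_fraction) else self.evaluable_fraction
        )
        Path(path).write_text(json.dumps(_plain(payload), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cfb_column(endpoint: str) -> str:
    return ("pcfb_" if ENDPOINT_SCALE[endpoint] == "percent" else "cfb_") + endpoint


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, returning (and writing) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    manifest = RunManifest(config=_plain(dataclasses.asdict(config)), seed=config.seed, version=__version__)
    manifest_path = out / "run_manifest.json"
    emitted: list[Path] = []
    report_lines: list[str] = []

    def emit(path: Path) -> None:
        emitted.append(path)

    try:
        config.to_yaml(out / "config.yaml")
        emit(out / "config.yaml")

        # ----- stage 1: cohort ------------------------------------------------
        subjects = simulate_cohort(config.n_subjects, config.cohort, seed=derive_seed(config.seed, 1))
        manifest.stages["simulate_cohort"] = "ok"

        # ----- stage 2: imaging + biomarkers ---------------------------------
        faults = {(s, int(w)) for s, w in config.qc_fault_scans}
        rows: list[dict] = []
        n_eval = 0
        window = config.t2_slice_window()
        for i, subj in enumerate(subjects):
            render_seed = derive_seed(config.seed, 2, i)
            outcome = simulate_outcomes(subj, config.outcomes, seed=derive_seed(config.seed, 0x0D, i))
            for v, week in enumerate(subj.visit_weeks):
                t2_scale = config.qc_fault_t2_scale if (subj.subject_id, week) in faults else 1.0
                imaging = render_visit(subj, v, config.phantom, seed=render_seed, t2_scale=t2_scale)
                if config.write_images:
                    vis_dir = out / "images" / subj.subject_id / f"week_{week:03d}"
                    vis_dir.mkdir(parents=True, exist_ok=True)
                    for name, vol in (
                        ("pd", imaging.pd_volume),
                        ("dixon_water", imaging.dixon_water),
                        ("dixon_fat", imaging.dixon_fat),
                        ("truth_labels", imaging.truth_labels),
                        ("multi_echo", imaging.multi_echo),
                    ):
                        emit(vol.to_nifti(vis_dir / f"{name}.nii.gz"))

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    seg = segment_thigh(
                        normalize_volume(imaging.pd_volume),
                        config.segmentation,
                        seed=derive_seed(config.seed, 3, i, v),
                    )
                    t2map = fit_t2_map(imaging.multi_echo, seg.data != Tissue.BACKGROUND)
                    t2map.threshold_ms = config.t2_threshold_ms
                    qc = qc_phantom_t2(t2map, seg.data == Tissue.PHANTOM, config.qc_expected_t2_range)
                    ffmap = fat_fraction_map(imaging.dixon_water, imaging.dixon_fat)
                    bm = extract_visit_biomarkers(seg, t2map, ffmap, t2_slice_window=window)

                evaluable = qc.passed
                n_eval += evaluable
                manifest.scans.append(
                    {
                        "subject_id": subj.subject_id,
                        "week": int(week),
                        "qc_status": qc.status,
                        "phantom_t2_ms": None if math.isnan(qc.median_t2_ms) else round(qc.median_t2_ms, 2),
                        "evaluable": bool(evaluable),
                        "reason": None if evaluable else f"phantom QC {qc.status}",
                    }
                )
                if not evaluable:
                    continue
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "arm": subj.arm,
                        "stratum": subj.stratum,
                        "age_baseline": subj.age_baseline,
                        "week": int(week),
                        "visit_type": "scheduled",
                        **bm.as_dict(),
                        "fourSC_seconds": float(outcome.fourSC_seconds[v]),
                        "nsaa_total": int(outcome.nsaa_total[v]),
                        "ambulation_event_day": outcome.ambulation_event_day,
                        "ambulation_event": int(outcome.ambulation_event),
                    }
                )
        table = pd.DataFrame(rows)
        table.to_csv(out / "tables" / "cohort.csv", index=False)
        emit(out / "tables" / "cohort.csv")
        manifest.evaluable_fraction = n_eval / max(len(manifest.scans), 1)
        manifest.stages["imaging_biomarkers"] = "ok"

        # ----- stage 3: change from baseline ----------------------------------
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfb = derive_cfb(table, list(BIOMARKER_COLUMNS) + ["fourSC_seconds", "nsaa_total"], mode="both")
        baselines = table[table.week == 0].set_index("subject_id")
        for ep in BIOMARKER_COLUMNS:
            cfb[f"bl_{ep}"] = cfb["subject_id"].map(baselines[ep])
        cfb.to_csv(out / "tables" / "cohort_cfb.csv", index=False)
        emit(out / "tables" / "cohort_cfb.csv")
        manifest.stages["derive_cfb"] = "ok"

        # ----- stage 4: statistics --------------------------------------------
        stats_ok = True

        mmrm_rows = []
        for ep in BIOMARKER_COLUMNS:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = MMRM(cfb, _cfb_column(ep), f"bl_{ep}", weeks=config.mmrm_weeks).fit()
                for week, r in res.by_week.iterrows():
                    mmrm_rows.append({"endpoint": ep, "scale": ENDPOINT_SCALE[ep], "week": week, **r.to_dict()})
                report_lines.append(res.summary())
            except Exception as exc:  # noqa: BLE001 - recorded, run continues
                stats_ok = False
                manifest.warnings_log.append(f"MMRM failed for {ep}: {exc}")
        if mmrm_rows:
            pd.DataFrame(mmrm_rows).to_csv(out / "tables" / "mmrm.csv", index=False)
            emit(out / "tables" / "mmrm.csv")
        manifest.stages["mmrm"] = "ok" if stats_ok else "partial"

        if config.run_regressions:
            wk49 = cfb[cfb.week == 49].set_index("subject_id")
            wk97 = cfb[cfb.week == 97].set_index("subject_id")
            reg_rows = []
            for func_ep, func_col in (("fourSC", "pcfb_fourSC_seconds"), ("nsaa", "cfb_nsaa_total")):
                for ep in BIOMARKER_COLUMNS:
                    xcol = _cfb_column(ep)
                    joined = wk49[[xcol]].join(wk97[[func_col]], how="inner").dropna()
                    if len(joined) < 4:
                        manifest.warnings_log.append(f"regression {ep} vs {func_ep}: too few pairs")
                        continue
                    try:
                        reg = regress_mri_on_function(joined[xcol].to_numpy(), joined[func_col].to_numpy())
                        cp = find_cutpoint(joined[xcol].to_numpy(), joined[func_col].to_numpy())
                        reg_rows.append(
                            {
                                "functional": func_ep,
                                "endpoint": ep,
                                "n": reg.n,
                                "slope": reg.slope,
                                "intercept": reg.intercept,
                                "r": reg.r,
                                "p_value": reg.p_value,
                                "cutpoint": cp.cutpoint,
                                "mean_low": cp.mean_low,
                                "mean_high": cp.mean_high,
                                "cut_informative": cp.informative,
                            }
                        )
                    except Exception as exc:  # noqa: BLE001
                        stats_ok = False
                        manifest.warnings_log.append(f"regression {ep} vs {func_ep} failed: {exc}")
            if reg_rows:
                pd.DataFrame(reg_rows).to_csv(out / "tables" / "regressions.csv", index=False)
                emit(out / "tables" / "regressions.csv")

            # bivariate trees: muscle volume + a lean-quality endpoint vs NSAA
            for quality in ("ff_lean_percent", "t2_lean_ms"):
                try:
                    joined = (
                        wk49[["pcfb_muscle_volume_mm3", f"cfb_{quality}"]]
                        .join(wk97[["cfb_nsaa_total"]], how="inner")
                        .dropna()
                    )
                    bt = bivariate_tree(
                        joined["pcfb_muscle_volume_mm3"].to_numpy(),
                        joined[f"cfb_{quality}"].to_numpy(),
                        joined["cfb_nsaa_total"].to_numpy(),
                    )
                    report_lines.append(
                        f"Bivariate tree (muscle volume %CFB + {quality} CFB -> NSAA CFB): "
                        f"volume cut {bt.split_x1.cutpoint:.2f}; high-volume mean {bt.mean_high_x1:.2f}; "
                        f"quality cut {bt.split_x2.cutpoint:.2f} "
                        f"(means {bt.mean_low_x1_low_x2:.2f} / {bt.mean_low_x1_high_x2:.2f})"
                        if bt.split_x2
                        else f"Bivariate tree: volume cut {bt.split_x1.cutpoint:.2f}; low branch unsplit"
                    )
                except Exception as exc:  # noqa: BLE001
                    manifest.warnings_log.append(f"bivariate tree ({quality}) failed: {exc}")
            manifest.stages["regressions"] = "ok"

        if config.run_survival:
            cox_rows = []
            base = table[table.week == 0].dropna(subset=["ambulation_event_day"])
            for ep in BIOMARKER_COLUMNS:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ms = MedianSplitCox(
                            base[ep].to_numpy(),
                            base["age_baseline"].to_numpy(),
                            base["ambulation_event_day"].to_numpy(),
                            base["ambulation_event"].to_numpy(),
                            higher_is_better=HIGHER_IS_BETTER[ep],
                        ).fit()
                    cox_rows.append({"endpoint": ep, "model": "median_split", "hr": ms.hazard_ratio,
                                     "ci_low": ms.ci_low, "ci_high": ms.ci_high, "p_value": ms.p_value,
                                     "n_events": ms.n_events})
                    report_lines.append(f"{ep}: {ms.summary()}")
                except Exception as exc:  # noqa: BLE001
                    manifest.warnings_log.append(f"median-split Cox failed for {ep}: {exc}")
                try:
                    long = build_time_varying_table(table, ep)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        tv = TimeVaryingCox(long, ep, age_col="age").fit()
                    cox_rows.append({"endpoint": ep, "model": "time_varying", "hr": tv.hazard_ratio,
                                     "ci_low": tv.ci_low, "ci_high": tv.ci_high, "p_value": tv.p_value,
                                     "n_events": tv.n_events})
                except Exception as exc:  # noqa: BLE001
                    manifest.warnings_log.append(f"time-varying Cox failed for {ep}: {exc}")
            if cox_rows:
                pd.DataFrame(cox_rows).to_csv(out / "tables" / "cox.csv", index=False)
                emit(out / "tables" / "cox.csv")
            manifest.stages["survival"] = "ok"

        manifest.stages["stats"] = "ok" if stats_ok else "partial"

        # ----- stage 5: plots --------------------------------------------------
        if config.make_plots:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for p in plot_biomarkers_vs_age(table, out / "plots"):
                    emit(p)
                traj = plot_trajectories(table, out / "plots")
            if traj:
                emit(traj)
            manifest.stages["plots"] = "ok"

        (out / "report.txt").write_text("\n\n".join(report_lines) + "\n")
        emit(out / "report.txt")
    except Exception as exc:
        manifest.stages["fatal"] = f"{type(exc).__name__}: {exc}"
        manifest.warnings_log.append(traceback.format_exc(limit=5))
        manifest.checksums = {str(p.relative_to(out)): _sha256(p) for p in emitted if p.exists()}
        manifest.write(manifest_path)
        raise PipelineError(str(exc)) from exc

    manifest.checksums = {str(p.relative_to(out)): _sha256(p) for p in emitted if p.exists()}
    manifest.write(manifest_path)
    return manifest
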