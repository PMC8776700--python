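"""End-to-end cohort analysis: drift -> gating -> dosimetry, with reports.

``run_pipeline`` orchestrates the full analysis for a configured cohort
(synthetic or read from trace CSVs) and writes:

* ``drift_summary.csv`` — per trace and direction, per-beam drift stats;
* ``residual_motion.csv`` — residual motion per trace, method, phase and
  direction;
* ``hi_table.csv`` — DVH metrics and HI per patient group, method and
  phase (beams of a group pooled by equal-weight PDF averaging), plus the
  unblurred reference plan;
* ``summary.json`` — machine-readable aggregate summary (byte-identical
  for identical config + seed);
* ``run.log`` — seed, library versions and per-stage progress.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .dosimetry import (AXIS_DIRECTIONS, DoseGrid, ReferencePlanParams,
                        average_pdfs, build_position_pdf, build_reference_dose,
                        compute_dvh, convolve_dose, pctv_for_window)
from .drift import drift_profile_for_trace, summarize_drift
from .gating import (METHODS, PHASES, GatingError, GatingWindowSpec,
                     compare_gating_methods, compute_gating_mask,
                     prepare_gating, residual_difference)
from .synthetic import (PopulationParams, generate_clinical_cohort,
                        generate_cohort, cohort_manifest)
from .trace import DIRECTIONS, RespiratoryTrace, read_trace_csv, write_trace_csv

logger = logging.getLogger("respigate")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_StrictModel):
    kind: Literal["clinical", "custom"] = "clinical"
    n_traces: int | None = None          # custom cohorts
    beams_per_patient: int | None = None  # clinical cohort cap
    amplitude_mean_mm: float | None = None
    amplitude_sd_mm: float | None = None
    period_mean_s: float | None = None
    period_sd_s: float | None = None
    duration_mean_s: float | None = None
    duration_sd_s: float | None = None
    duration_min_s: float | None = None
    duration_max_s: float | None = None
    amplitude_cv: float | None = None
    period_cv: float | None = None
    drift_cc_range_mm_per_s: tuple[float, float] | None = None
    drift_style: Literal["constant", "wandering"] | None = None
    noise_sd_mm: float | None = None
    sample_rate_hz: float | None = None


class PlanConfig(_StrictModel):
    ctv_diameter_mm: float = 23.0
    ptv_margin_mm: float = 5.0
    prescription_gy: float = 48.0
    isodose_coverage: float = 0.80
    penumbra_sigma_mm: float = 5.0


class GridConfig(_StrictModel):
    spacing_mm: float = 1.0
    shape: int = 81


class RunConfig(_StrictModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    seed: int = 0
    cohort: CohortConfig | None = CohortConfig()
    trace_files: list[str] = Field(default_factory=list)
    gating_direction: str = "cc"
    methods: list[str] = Field(default_factory=lambda: list(METHODS))
    phases: list[str] = Field(default_factory=lambda: list(PHASES))
    n_calibration_cycles: int = 3
    strict_amplitude_bounds: bool = False
    residual_metric: Literal["range", "sd"] = "range"
    aggregation: Literal["mean", "max"] = "mean"
    plan: PlanConfig = PlanConfig()
    grid: GridConfig = GridConfig()
    pdf_bin_width_mm: float = 1.0
    dosimetry: bool = True
    write_traces: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_population(cfg: CohortConfig) -> PopulationParams:
    base = PopulationParams()
    overrides = {k: v for k, v in cfg.model_dump().items()
                 if v is not None and k in PopulationParams.__dataclass_fields__}
    import dataclasses
    return dataclasses.replace(base, **overrides)


def load_traces(config: RunConfig) -> list[RespiratoryTrace]:
    """Materialize the cohort: trace files first, then synthetic traces."""
    traces: list[RespiratoryTrace] = []
    for path in config.trace_files:
        traces.append(read_trace_csv(path, meta={"trace_id": Path(path).stem}))
    if config.cohort is not None and not config.trace_files:
        if config.cohort.kind == "clinical":
            traces = generate_clinical_cohort(
                seed=config.seed,
                beams_per_patient=config.cohort.beams_per_patient)
        else:
            if config.cohort.n_traces is None:
                raise ValueError("custom cohort requires n_traces")
            traces = generate_cohort(config.cohort.n_traces,
                                     population=_build_population(config.cohort),
                                     seed=config.seed)
    if not traces:
        raise ValueError("no traces configured (set cohort or trace_files)")
    return traces


# -- analysis stages ------------------------------------------------------

def drift_table(traces: Sequence[RespiratoryTrace]) -> pd.DataFrame:
    """Per-trace, per-direction drift statistics (auto-refined detection)."""
    rows = []
    for tr in traces:
        for d in DIRECTIONS:
            profile = drift_profile_for_trace(tr, d, refine_half_width_s="auto")
            row = {"trace_id": tr.trace_id,
                   "patient": tr.meta.get("patient", ""),
                   "direction": d,
                   "n_cycle_pairs": int(profile.delta_mm_per_s.size)}
            if profile.empty:
                row.update(delta_mean_mm_per_s=np.nan, delta_max_mm_per_s=np.nan,
                           delta_p95_mm_per_s=np.nan)
            else:
                row.update(delta_mean_mm_per_s=profile.summary["mean"],
                           delta_max_mm_per_s=profile.summary["max"],
                           delta_p95_mm_per_s=profile.summary["p95"])
            rows.append(row)
    return pd.DataFrame(rows)


def residual_table(traces: Sequence[RespiratoryTrace], config: RunConfig
                   ) -> pd.DataFrame:
    """Residual-motion report rows: trace x method x phase x direction."""
    frames = []
    for tr in traces:
        try:
            table = compare_gating_methods(
                tr, gating_direction=config.gating_direction,
                n_calibration_cycles=config.n_calibration_cycles,
                strict_bounds=config.strict_amplitude_bounds,
                per_cycle_metric=config.residual_metric)
        except GatingError as exc:
            logger.warning("skipping trace %s in residual analysis: %s",
                           tr.trace_id, exc)
            continue
        frames.append(table)
    if not frames:
        raise RuntimeError("residual analysis failed for every trace")
    wide = pd.concat(frames, ignore_index=True)
    long = wide.melt(
        id_vars=["trace_id", "method", "phase", "residual_3d_mm"],
        value_vars=["ap_mm", "cc_mm", "lr_mm"],
        var_name="direction", value_name="mean_residual_mm")
    long["direction"] = long["direction"].str.replace("_mm", "", regex=False)
    return long[["trace_id", "method", "phase", "direction",
                 "mean_residual_mm", "residual_3d_mm"]]


def hi_table(traces: Sequence[RespiratoryTrace], config: RunConfig,
             reference: DoseGrid | None = None) -> pd.DataFrame:
    """DVH metrics per patient group, method and phase.

    Beams of one group are pooled by averaging their per-direction position
    PDFs with equal weight; one convolution per group x method x phase.
    The unblurred reference plan is reported as group ``reference``.
    """
    plan = ReferencePlanParams(**config.plan.model_dump())
    if reference is None:
        reference = build_reference_dose(plan, shape=(config.grid.shape,) * 3,
                                         spacing_mm=config.grid.spacing_mm)
    ref_dvh = compute_dvh(reference, ctv_diameter_mm=plan.ctv_diameter_mm)
    rows = [{"config": "reference", "method": "none", "phase": "none",
             "D2_gy": ref_dvh.metrics["D2"], "D98_gy": ref_dvh.metrics["D98"],
             "D50_gy": ref_dvh.metrics["D50"], "HI": ref_dvh.metrics["HI"],
             "P_CTV": 1.0}]
    groups: dict[str, list[RespiratoryTrace]] = {}
    for tr in traces:
        groups.setdefault(str(tr.meta.get("patient", tr.trace_id)), []).append(tr)
    for group_id in sorted(groups):
        contexts = []
        for tr in groups[group_id]:
            try:
                contexts.append(prepare_gating(
                    tr, config.gating_direction,
                    n_calibration_cycles=config.n_calibration_cycles))
            except GatingError as exc:
                logger.warning("skipping trace %s in dosimetry: %s",
                               tr.trace_id, exc)
        if not contexts:
            continue
        for method in config.methods:
            for phase in config.phases:
                window = GatingWindowSpec.default(method, phase)
                pdfs_by_dir: dict[str, list] = {d: [] for d in AXIS_DIRECTIONS}
                p_ctvs = []
                for ctx in contexts:
                    mask = compute_gating_mask(
                        ctx.assignment, window,
                        strict_bounds=config.strict_amplitude_bounds)
                    if not mask.on.any():
                        logger.warning("window %s/%s empty on trace %s",
                                       method, phase, ctx.trace.trace_id)
                        continue
                    cyc = ctx.assignment.cycle_index
                    for d in AXIS_DIRECTIONS:
                        pdfs_by_dir[d].append(build_position_pdf(
                            ctx.trace, mask, cyc, d, config.pdf_bin_width_mm,
                            config.n_calibration_cycles))
                    gx = ctx.trace.direction(config.gating_direction)
                    cal = mask.on & (cyc >= 0) & (cyc < config.n_calibration_cycles)
                    planned = float(gx[cal].mean() if cal.any() else gx[mask.on].mean())
                    pdf_g = pdfs_by_dir[config.gating_direction][-1]
                    p_ctvs.append(pctv_for_window(
                        ctx, window, mask, pdf_g, planned,
                        config.n_calibration_cycles))
                if not pdfs_by_dir[AXIS_DIRECTIONS[0]]:
                    continue
                pooled = {d: average_pdfs(pdfs_by_dir[d]) for d in AXIS_DIRECTIONS}
                blurred = convolve_dose(reference, pooled)
                dvh = compute_dvh(blurred, ctv_diameter_mm=plan.ctv_diameter_mm)
                rows.append({"config": group_id, "method": method, "phase": phase,
                             "D2_gy": dvh.metrics["D2"],
                             "D98_gy": dvh.metrics["D98"],
                             "D50_gy": dvh.metrics["D50"],
                             "HI": dvh.metrics["HI"],
                             "P_CTV": float(np.mean(p_ctvs))})
    return pd.DataFrame(rows)


def summarize(drift_df: pd.DataFrame, residual_df: pd.DataFrame,
              hi_df: pd.DataFrame | None, config: RunConfig,
              n_traces: int) -> dict:
    """Aggregate summary of all stages (deterministic for fixed config+seed)."""
    drift = {}
    for d in DIRECTIONS:
        sub = drift_df[(drift_df.direction == d)
                       & drift_df.delta_mean_mm_per_s.notna()]
        if len(sub):
            drift[d] = {
                "min_beam_mean_mm_per_s": round(float(sub.delta_mean_mm_per_s.min()), 6),
                "max_beam_mean_mm_per_s": round(float(sub.delta_mean_mm_per_s.max()), 6),
                "mean_beam_mean_mm_per_s": round(float(sub.delta_mean_mm_per_s.mean()), 6),
            }
    res3d = residual_df.drop_duplicates(["trace_id", "method", "phase"])
    res = {}
    diffs = {}
    for phase in config.phases:
        per_method = {}
        for method in config.methods:
            sel = res3d[(res3d.method == method) & (res3d.phase == phase)]
            per_method[method] = round(float(sel.residual_3d_mm.mean()), 6)
        res[phase] = per_method
        if "phase" in per_method and "amplitude" in per_method:
            diffs[phase] = round(per_method["phase"] - per_method["amplitude"], 6)
    summary = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_traces": n_traces,
        "baseline_drift_mm_per_s": drift,
        "residual_3d_mm": res,
        "residual_3d_phase_minus_amplitude_mm": diffs,
    }
    if hi_df is not None and len(hi_df):
        hi = {}
        for method in config.methods:
            hi[method] = {}
            for phase in config.phases:
                sel = hi_df[(hi_df.method == method) & (hi_df.phase == phase)]
                if len(sel):
                    hi[method][phase] = round(float(sel.HI.mean()), 6)
        ref = hi_df[hi_df.config == "reference"]
        summary["hi"] = hi
        if len(ref):
            summary["hi_reference"] = round(float(ref.HI.iloc[0]), 6)
    return summary


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages and write reports into ``out_dir``; returns the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        import scipy
        logger.info("respigate %s | numpy %s scipy %s pandas %s | seed %d",
                    __version__, np.__version__, scipy.__version__,
                    pd.__version__, config.seed)
        traces = load_traces(config)
        logger.info("cohort: %d traces", len(traces))
        if config.write_traces:
            tdir = out / "traces"
            tdir.mkdir(exist_ok=True)
            paths = [write_trace_csv(tr, tdir / f"{tr.trace_id}.csv")
                     for tr in traces]
            (out / "cohort_manifest.json").write_text(json.dumps(
                cohort_manifest(traces, [str(p) for p in paths]), indent=1))
        drift_df = drift_table(traces)
        drift_df.to_csv(out / "drift_summary.csv", index=False,
                        float_format="%.6g")
        logger.info("drift stage done")
        residual_df = residual_table(traces, config)
        residual_df.to_csv(out / "residual_motion.csv", index=False,
                           float_format="%.6g")
        logger.info("residual-motion stage done")
        hi_df = None
        if config.dosimetry:
            hi_df = hi_table(traces, config)
            hi_df.to_csv(out / "hi_table.csv", index=False, float_format="%.6g")
            logger.info("dosimetry stage done")
        summary = summarize(drift_df, residual_df, hi_df, config, len(traces))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")
        logger.info("summary written")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
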