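"""End-to-end orchestration: cohort -> metrics -> variability -> models.

A run executes the analysis stages in order:

1. obtain reads and dose maps (synthetic cohort or user manifest);
2. per-read geometric and dose metrics (volume, RECIST diameter, mean dose
   with/without PVC, D10, D90);
3. inter/intra Dice pairing and the Welch test of their means;
4. per-lesion summaries (mean, SD, CV% per metric);
5. variance decomposition and reliability per metric, globally and for
   size/boundary subgroups and named lesion exclusions;
6. power-law fits of CV versus volume (volume CV and PVC mean-dose CV);
7. optional propagation of the PVC-dose fit through a logistic TCP model.

Results come back as in-memory tables and are optionally written as CSV/JSON
with a run manifest (seed, package versions, configuration).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dosimetry import MIN_VALID_VOLUME_ML, compute_dose_metrics
from .io import load_reads
from .masks import ReadRecord
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort
from .tcp import TCPModel, delta_tcp_table, summarize_delta
from .uncertainty import fit_power_model, predict_cv, spearman_volume_cv
from .varcomp import reliability_coefficients, fit_variance_components, subgroup_analysis
from .variability import (
    compare_dice,
    cohort_cv_summary,
    dice_pairs,
    pairs_table,
    summarize_lesions,
)

logger = logging.getLogger("segdosim")

#: metrics analyzed by the variance decomposition, in reporting order
ANALYSIS_METRICS = ("volume_ml", "mean_gy", "mean_pvc_gy", "diameter_mm")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is "synthetic" (requires ``cohort``) or "real" (requires
    ``manifest_csv``). ``seed`` overrides the cohort seed so a single flag
    controls all randomness. ``exclude_lesions`` removes lesions up front
    (sensitivity re-runs); ``subgroups`` adds size/boundary subset fits.
    """

    mode: str = "synthetic"
    cohort: Optional[CohortConfig] = None
    manifest_csv: Optional[str] = None
    pvc: bool = True
    dvh_method: str = "linear"
    subgroups: bool = True
    exclude_lesions: list[str] = field(default_factory=list)
    tcp_model: Optional[TCPModel] = None
    out_dir: Optional[str] = None
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode == "synthetic":
            if self.cohort is None:
                self.cohort = CohortConfig()
            if self.seed is not None:
                self.cohort.seed = int(self.seed)
        elif self.mode == "real":
            if not self.manifest_csv:
                raise ValueError("real mode requires manifest_csv")
        else:
            raise ValueError("mode must be 'synthetic' or 'real'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = CohortConfig.from_dict(raw["cohort"])
        if "tcp_model" in raw and raw["tcp_model"] is not None:
            raw["tcp_model"] = TCPModel(**raw["tcp_model"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Bundle of all tables and fitted models produced by one run."""

    reads_metrics: pd.DataFrame
    dice_pairs: pd.DataFrame
    dice_test: dict
    lesion_summary: pd.DataFrame
    cv_summary: pd.DataFrame
    variance_table: pd.DataFrame
    power_fits: dict
    fig_volume_cv: pd.DataFrame
    tcp_deltas: Optional[pd.DataFrame]
    tcp_summary: Optional[dict]
    manifest: dict


def _stage(name: str):
    logger.info("stage: %s", name)


def _read_metrics_table(
    reads: list[ReadRecord],
    dose_maps,
    pvc: bool,
    dvh_method: str,
) -> pd.DataFrame:
    rows = []
    for r in reads:
        try:
            dm = dose_maps[r.lesion_id]
            apply_pvc_here = pvc and r.volume_ml >= MIN_VALID_VOLUME_ML
            met = compute_dose_metrics(dm, r.mask, pvc=apply_pvc_here, dvh_method=dvh_method)
            if pvc and not apply_pvc_here:
                logger.warning(
                    "read (%s, %s, round %s): volume %.2f mL below PVC validity; "
                    "PVC dose set to NaN",
                    r.lesion_id, r.reader_id, r.round, r.volume_ml,
                )
        except Exception as exc:
            raise type(exc)(
                f"dosimetry stage, read ({r.lesion_id}, {r.reader_id}, round {r.round}): {exc}"
            ) from exc
        rows.append(
            {
                "lesion_id": r.lesion_id,
                "reader_id": r.reader_id,
                "round": r.round,
                "volume_ml": r.volume_ml,
                "diameter_mm": r.diameter_mm,
                "mean_gy": met.mean_gy,
                "mean_pvc_gy": met.mean_pvc_gy,
                "d10_gy": met.d10_gy,
                "d90_gy": met.d90_gy,
                "rc": met.rc,
            }
        )
    return pd.DataFrame(rows)


def _variance_analyses(
    reads_metrics: pd.DataFrame,
    lesion_summary: pd.DataFrame,
    boundary_by_lesion: dict[str, str],
    subgroups: bool,
) -> pd.DataFrame:
    """Variance components + reliability per metric, with optional subsets."""
    size_by_lesion = {
        row.lesion_id: ("small" if row.volume_ml_mean <= 8.0 else "large")
        for row in lesion_summary.itertuples(index=False)
    }
    frames = []
    for metric in ANALYSIS_METRICS:
        obs = reads_metrics[["lesion_id", "reader_id", "round", metric]].rename(
            columns={metric: "value"}
        )
        n_before = len(obs)
        obs = obs.dropna(subset=["value"])
        if len(obs) < n_before:
            logger.warning("metric %s: dropped %d reads with missing values", metric, n_before - len(obs))
        ok = obs.groupby("lesion_id")["value"].transform("count") >= 2
        obs = obs[ok]
        subsets: dict[str, pd.Series] = {"all": pd.Series(True, index=obs.index)}
        if subgroups:
            size = obs["lesion_id"].map(size_by_lesion)
            subsets["small"] = size == "small"
            subsets["large"] = size == "large"
            if boundary_by_lesion:
                boundary = obs["lesion_id"].map(boundary_by_lesion)
                subsets["well"] = boundary == "well"
                subsets["poor"] = boundary == "poor"
        frames_metric = []
        for name, sel in subsets.items():
            try:
                tab = subgroup_analysis(obs, {name: sel})
            except ValueError as exc:
                logger.warning("metric %s subset %s skipped: %s", metric, name, exc)
                continue
            frames_metric.append(tab)
        tab = pd.concat(frames_metric, ignore_index=True)
        tab.insert(0, "metric", metric)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    _stage("load/generate reads")
    boundary_by_lesion: dict[str, str] = {}
    if config.mode == "synthetic":
        cohort: SyntheticCohort = generate_cohort(config.cohort)
        reads, dose_maps = cohort.reads, cohort.dose_maps
        boundary_by_lesion = {t.lesion_id: t.boundary_class for t in cohort.lesions}
    else:
        reads, dose_maps = load_reads(config.manifest_csv)

    if config.exclude_lesions:
        excl = set(config.exclude_lesions)
        reads = [r for r in reads if r.lesion_id not in excl]
        logger.info("excluded lesions: %s", sorted(excl))

    _stage("per-read dose metrics")
    reads_metrics = _read_metrics_table(reads, dose_maps, config.pvc, config.dvh_method)

    _stage("Dice pairing and inter/intra test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inter = dice_pairs(reads, "inter")
        intra = dice_pairs(reads, "intra")
    pairs = pairs_table(inter + intra)
    inter_vals = [p.dice for p in inter]
    intra_vals = [p.dice for p in intra]
    if len(inter_vals) >= 2 and len(intra_vals) >= 2:
        t, p = compare_dice(inter_vals, intra_vals)
    else:
        t, p = float("nan"), float("nan")
    dice_test = {
        "mean_inter": float(np.mean(inter_vals)) if inter_vals else float("nan"),
        "mean_intra": float(np.mean(intra_vals)) if intra_vals else float("nan"),
        "n_inter": len(inter_vals),
        "n_intra": len(intra_vals),
        "t": t,
        "p": p,
    }

    _stage("lesion summaries")
    metric_cols = ["volume_ml", "diameter_mm", "mean_gy", "d10_gy", "d90_gy"]
    lesion_summary = summarize_lesions(reads_metrics, metrics=metric_cols)
    if config.pvc:
        pvc_rows = reads_metrics.dropna(subset=["mean_pvc_gy"])
        ok = pvc_rows.groupby("lesion_id")["mean_pvc_gy"].transform("count") >= 2
        pvc_summary = summarize_lesions(pvc_rows[ok], metrics=["mean_pvc_gy"])
        lesion_summary = lesion_summary.merge(
            pvc_summary.drop(columns="n_reads"), on="lesion_id", how="left"
        )
    cv_summary = cohort_cv_summary(lesion_summary)

    _stage("variance components and reliability")
    variance_table = _variance_analyses(
        reads_metrics, lesion_summary, boundary_by_lesion, config.subgroups
    )

    _stage("CV-versus-volume power models")
    power_fits: dict = {}
    fig_rows = lesion_summary[["lesion_id", "volume_ml_mean", "volume_ml_cv_pct"]].copy()
    targets = {"volume": "volume_ml_cv_pct"}
    if config.pvc and "mean_pvc_gy_cv_pct" in lesion_summary:
        targets["mean_dose_pvc"] = "mean_pvc_gy_cv_pct"
        fig_rows["mean_pvc_gy_cv_pct"] = lesion_summary["mean_pvc_gy_cv_pct"]
    for name, col in targets.items():
        sub = lesion_summary[["volume_ml_mean", col]].dropna()
        sub = sub[sub[col] > 0]
        if len(sub) < 3:
            logger.warning("power fit %s skipped: fewer than 3 usable lesions", name)
            continue
        fit = fit_power_model(sub["volume_ml_mean"], sub[col])
        power_fits[name] = {
            "alpha": fit.alpha,
            "beta": fit.beta,
            "se_beta": fit.se_beta,
            "p_beta": fit.p_beta,
            "n": fit.n,
            "spearman_rho": spearman_volume_cv(sub["volume_ml_mean"], sub[col]),
            "_fit": fit,
        }

    _stage("TCP propagation")
    tcp_deltas = None
    tcp_summary = None
    if config.tcp_model is not None and "mean_dose_pvc" in power_fits:
        fit = power_fits["mean_dose_pvc"]["_fit"]
        lesions = lesion_summary.rename(
            columns={"volume_ml_mean": "volume_ml", "mean_pvc_gy_mean": "mean_dose_gy"}
        )[["lesion_id", "volume_ml", "mean_dose_gy"]].dropna()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tcp_deltas = delta_tcp_table(config.tcp_model, fit, lesions)
        tcp_deltas.insert(0, "lesion_id", lesions["lesion_id"].to_numpy())
        tcp_summary = summarize_delta(tcp_deltas["delta_tcp"].to_numpy())

    manifest = {
        "package": "segdosim",
        "version": __version__,
        "mode": config.mode,
        "seed": (config.cohort.seed if config.mode == "synthetic" else config.seed),
        "n_reads": len(reads),
        "n_lesions": int(reads_metrics["lesion_id"].nunique()),
        "pvc": config.pvc,
        "dvh_method": config.dvh_method,
        "excluded_lesions": list(config.exclude_lesions),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }

    result = PipelineResult(
        reads_metrics=reads_metrics,
        dice_pairs=pairs,
        dice_test=dice_test,
        lesion_summary=lesion_summary,
        cv_summary=cv_summary,
        variance_table=variance_table,
        power_fits={k: {kk: vv for kk, vv in v.items() if kk != "_fit"} for k, v in power_fits.items()},
        fig_volume_cv=fig_rows,
        tcp_deltas=tcp_deltas,
        tcp_summary=tcp_summary,
        manifest=manifest,
    )
    if config.out_dir:
        write_results(result, config.out_dir)
    return result


def write_results(result: PipelineResult, out_dir) -> None:
    """Write all result tables as CSV (6 significant digits) and JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    result.reads_metrics.to_csv(out / "reads_metrics.csv", index=False, float_format=fmt)
    result.dice_pairs.to_csv(out / "dice_pairs.csv", index=False, float_format=fmt)
    result.lesion_summary.to_csv(out / "lesion_summary.csv", index=False, float_format=fmt)
    result.cv_summary.to_csv(out / "cv_summary.csv", index=False, float_format=fmt)
    result.variance_table.to_csv(out / "variance_components.csv", index=False, float_format=fmt)
    result.fig_volume_cv.to_csv(out / "cv_vs_volume.csv", index=False, float_format=fmt)
    with open(out / "dice_test.json", "w") as fh:
        json.dump(result.dice_test, fh, indent=2)
    with open(out / "power_fits.json", "w") as fh:
        json.dump(result.power_fits, fh, indent=2)
    if result.tcp_deltas is not None:
        result.tcp_deltas.to_csv(out / "tcp_deltas.csv", index=False, float_format=fmt)
        with open(out / "tcp_summary.json", "w") as fh:
            json.dump(result.tcp_summary, fh, indent=2)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
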