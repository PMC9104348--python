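"""End-to-end orchestration: simulate -> qc -> stats -> trajectories ->
panel -> ratios -> msi, from a single configuration.

A single global seed is expanded into fixed per-stage seeds so every stage
is reproducible in isolation; the run report records the configuration
verbatim, per-stage feature counts, panel membership, CV metrics, the
permutation p-value, the top ratios and the segmentation summary, in both
plain text and a machine-readable JSON bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import cohort_sim, feature_qc, msi, ratio_biomarkers, timecourse, univariate
from .chemometrics import NEG_LABEL, POS_LABEL, permutation_test, venetian_blind_cv
from .cohort_sim import SimConfig, generate_cohort, generate_msi_phantom
from .ga_select import GaConfig, ga_feature_select
from .io_tables import Group, sample_ids_by_group, study_sample_ids, write_feature_table


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    blank_factor: float = 5.0
    qc_presence: float = 0.5
    qc_rsd: float = 0.30
    drift_correct: bool = True
    alpha: float = 0.05
    onset_window: tuple[float, float] = (37.0, 61.0)
    n_orth: int = 2
    cv_folds: int = 10
    n_permutations: int = 1000
    ga: GaConfig = field(default_factory=GaConfig)
    ratio_top_k: int = 20
    ratio_boot: int = 2000
    msi_k: int = 3
    msi_grid: tuple[int, int] = (30, 30)
    msi_features: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed, fixed per-stage derivations
        self.sim.seed = self.seed
        self.ga.seed = self.seed + 1


def _stage_seed(config: RunConfig, offset: int) -> int:
    return (config.seed + offset) % (2**31 - 1)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages in order; returns (and writes) the report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": _serialize_config(config), "stages": {}}

    # --- simulate -------------------------------------------------------
    table, records, annotations, truth = generate_cohort(config.sim)
    write_feature_table(table, records, outdir / "matrix.tsv", outdir / "samples.tsv")
    cohort_sim.write_truth(truth, outdir / "truth.json")
    report["stages"]["simulate"] = {
        "n_features": table.n_features,
        "n_samples": table.n_samples,
    }

    # --- qc -------------------------------------------------------------
    study_ids = study_sample_ids(records)
    blank_ids = sample_ids_by_group(records, Group.BLANK)
    qc_ids = sample_ids_by_group(records, Group.QC)
    reports = []
    table, rep = feature_qc.blank_filter(table, study_ids, blank_ids, config.blank_factor)
    reports.append(rep)
    table, rep = feature_qc.qc_presence_filter(table, qc_ids, config.qc_presence)
    reports.append(rep)
    table, rep = feature_qc.qc_rsd_filter(table, qc_ids, config.qc_rsd)
    reports.append(rep)
    if config.drift_correct:
        table, rep = feature_qc.qc_drift_correct(table, records, qc_ids)
        reports.append(rep)
    feature_qc.write_qc_report(reports, outdir / "qc_report.tsv")
    report["stages"]["qc"] = {
        "surviving_features": table.n_features,
        "removed": {r.rule: r.n_removed for r in reports},
    }

    # --- stats ----------------------------------------------------------
    selected, results = univariate.select_significant(table, records, alpha=config.alpha)
    onset_selected, _ = univariate.select_significant(
        table, records, alpha=config.alpha, pct_window=config.onset_window
    )
    report["stages"]["stats"] = {
        "significant_all": len(selected),
        "significant_onset_window": len(onset_selected),
    }
    with open(outdir / "stats.tsv", "w") as fh:
        fh.write("feature_id\tt\tdf\tp\tq\n")
        for r in results:
            fh.write(f"{r.feature_id}\t{r.t:.6g}\t{r.df:.6g}\t{r.p:.6g}\t{r.q:.6g}\n")

    if not selected:
        report["stages"]["skipped"] = "no significant features; panel/ratio stages skipped"
        _write_report(report, outdir)
        return report

    # --- trajectories ---------------------------------------------------
    traj = timecourse.TrajectoryTable()
    classes = sorted({a.lipid_class for a in annotations if a.lipid_class not in (None, "noise")})
    for cls in classes:
        pts = timecourse.class_trajectory(table, annotations, records, cls, selected)
        traj.add(cls, pts)
    traj.to_frame().to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    report["stages"]["trajectories"] = {"classes": len(classes)}

    # --- panel (GA + oPLS-DA on the onset window) -----------------------
    study = [r for r in records if r.group in (Group.TKO, Group.CTRL)]
    window = [
        r
        for r in study
        if r.pct_lifetime is not None
        and config.onset_window[0] <= r.pct_lifetime <= config.onset_window[1]
    ]
    window_ids = [r.sample_id for r in window]
    pool = onset_selected if len(onset_selected) >= 2 else selected
    sub = table.subset_features(pool, "panel_pool").subset_samples(window_ids, "onset_window")
    X = np.nan_to_num(sub.values.T, nan=0.0)
    y = np.array([POS_LABEL if r.group is Group.TKO else NEG_LABEL for r in window])
    order = np.argsort([r.injection_order for r in window])
    ga_res = ga_feature_select(X, y, config.ga, feature_ids=pool)
    panel_idx = [pool.index(f) for f in ga_res.selected]
    cv = venetian_blind_cv(
        X[:, panel_idx], y, n_orth=config.n_orth, n_folds=min(config.cv_folds, len(y)), order=order
    )
    _, perm_p, _ = permutation_test(
        X[:, panel_idx],
        y,
        n_orth=config.n_orth,
        n_perm=config.n_permutations,
        seed=_stage_seed(config, 2),
    )
    report["stages"]["panel"] = {
        "panel_size": len(ga_res.selected),
        "panel": ga_res.selected,
        "rmsecv": ga_res.best_rmsecv,
        "cv_sensitivity": cv.sensitivity,
        "cv_specificity": cv.specificity,
        "cv_accuracy": cv.accuracy,
        "permutation_p": perm_p,
        "separation_statistic": "between/within sum-of-squares of predictive scores",
    }

    # --- ratios ---------------------------------------------------------
    ratio_pool = pool[: min(len(pool), 46)]
    rsub = table.subset_features(ratio_pool, "ratio_pool").subset_samples(window_ids, "onset_window")
    ratios, pairs = ratio_biomarkers.all_pair_ratios(rsub.values, ratio_pool)
    top = ratio_biomarkers.rank_ratios(ratios, pairs, y, top_k=config.ratio_top_k)
    pair_index = {(b.numerator, b.denominator): pairs.index((b.numerator, b.denominator)) for b in top}
    evaluated = []
    for b in top[:5]:
        r = ratios[pair_index[(b.numerator, b.denominator)]]
        evaluated.append(
            ratio_biomarkers.cv_logistic_eval(
                r, y, biomarker=b, n_folds=min(config.cv_folds, len(y)),
                n_boot=config.ratio_boot, seed=_stage_seed(config, 3),
            )
        )
    with open(outdir / "ratios.tsv", "w") as fh:
        fh.write("ratio\tp\tauc\tauc_lo\tauc_hi\tsens\tsens_lo\tsens_hi\tspec\tspec_lo\tspec_hi\n")
        for b in evaluated:
            fh.write(
                f"{b.name}\t{b.p:.3g}\t{b.auc:.3f}\t{b.auc_ci[0]:.3f}\t{b.auc_ci[1]:.3f}\t"
                f"{b.sensitivity:.3f}\t{b.sensitivity_ci[0]:.3f}\t{b.sensitivity_ci[1]:.3f}\t"
                f"{b.specificity:.3f}\t{b.specificity_ci[0]:.3f}\t{b.specificity_ci[1]:.3f}\n"
            )
    report["stages"]["ratios"] = {
        "n_ratios": len(pairs),
        "top": [{"ratio": b.name, "p": b.p, "auc": b.auc} for b in evaluated],
    }

    # --- msi ------------------------------------------------------------
    phantom, msi_truth = generate_msi_phantom(
        width=config.msi_grid[0],
        height=config.msi_grid[1],
        n_features=config.msi_features,
        seed=_stage_seed(config, 4),
    )
    norm = msi.tic_normalize(phantom)
    refs = norm.mz_arrays[0]
    M, _ = msi.build_pixel_matrix(norm, refs, tol_da=0.001)
    seg = msi.bisecting_kmeans_segment(M, k=config.msi_k, seed=_stage_seed(config, 5))
    msi.write_raster(seg.as_raster(norm), outdir / "segmentation.tsv")
    msi.write_raster(msi_truth.region_labels, outdir / "msi_truth.tsv")
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(msi_truth.region_labels.ravel(), seg.labels)
    fc_ab, _ = msi.region_log2fc(M, seg.labels, 0, 1)
    report["stages"]["msi"] = {
        "n_pixels": norm.n_pixels,
        "k": config.msi_k,
        "adjusted_rand_vs_truth": float(ari),
        "median_abs_region_log2fc": float(np.nanmedian(np.abs(fc_ab))),
    }

    _write_report(report, outdir)
    return report


def _serialize_config(config: RunConfig) -> dict:
    def _clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    return _clean(config)


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    lines = ["run report", "=========="]
    for stage, info in report["stages"].items():
        lines.append(f"\n[{stage}]")
        if isinstance(info, dict):
            for k, v in info.items():
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"  {info}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
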