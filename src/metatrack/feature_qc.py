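"""QC-based feature curation: blank, presence and RSD filters, drift correction.

Untargeted LC-MS feature tables are curated with pooled-QC and blank
injections before any statistics:

* blank filter - a feature is background unless its mean study-sample
  abundance is at least ``factor`` (default 5) times its mean blank
  abundance (boundary kept; a zero blank mean keeps the feature);
* QC presence filter - kept iff detected (non-missing and > 0) in at least
  ``min_fraction`` (default 50%) of QC injections;
* QC RSD filter - kept iff the sample (n-1) relative standard deviation
  over QC injections is at most ``max_rsd`` (default 30%); features with
  fewer than 3 usable QC values are flagged indeterminate and kept;
* drift correction - a smooth curve (LOWESS on log abundance vs injection
  order, span 0.75; a least-squares line when fewer than 5 QCs) is fit to
  each feature's QC values, normalized to the median QC level, and every
  sample is divided by the interpolated curve value at its injection order.

Each rule is per-feature and independent, so the order of the three
filters does not change the surviving set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_tables import FeatureTable, SampleRecord


class QcError(ValueError):
    pass


@dataclass
class QcReport:
    """Per-feature QC metrics and pass/fail flags for one rule application."""

    rule: str
    metrics: pd.DataFrame  # indexed by feature_id
    removed: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def _mean_over(table: FeatureTable, sample_ids: Sequence[str]) -> np.ndarray:
    idx = table.sample_indices(sample_ids)
    with np.errstate(invalid="ignore"):
        return np.nanmean(table.values[:, idx], axis=1)


def blank_filter(
    table: FeatureTable,
    study_sample_ids: Sequence[str],
    blank_sample_ids: Sequence[str],
    factor: float = 5.0,
) -> tuple[FeatureTable, QcReport]:
    """Remove background features: kept iff mean study abundance >=
    factor x mean blank abundance (zero blank mean always keeps)."""
    if len(blank_sample_ids) == 0:
        raise QcError("no blank samples; skip the blank rule explicitly if intended")
    study_mean = _mean_over(table, study_sample_ids)
    blank_mean = np.nan_to_num(_mean_over(table, blank_sample_ids), nan=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(blank_mean > 0, study_mean / blank_mean, np.inf)
    keep = (blank_mean == 0) | (np.nan_to_num(study_mean) >= factor * blank_mean)
    metrics = pd.DataFrame(
        {
            "study_mean": study_mean,
            "blank_mean": blank_mean,
            "blank_ratio": ratio,
            "pass": keep,
        },
        index=table.feature_ids,
    )
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    out = table.subset_features(kept_ids, f"blank_filter:factor={factor}:removed={len(removed)}")
    return out, QcReport(rule="blank", metrics=metrics, removed=removed)


def qc_presence_filter(
    table: FeatureTable,
    qc_sample_ids: Sequence[str],
    min_fraction: float = 0.5,
) -> tuple[FeatureTable, QcReport]:
    """Kept iff present (non-missing, > 0) in >= min_fraction of QC injections."""
    if len(qc_sample_ids) < 2:
        raise QcError(f"need >=2 QC samples, got {len(qc_sample_ids)}")
    idx = table.sample_indices(qc_sample_ids)
    qc = table.values[:, idx]
    present = np.isfinite(qc) & (qc > 0)
    frac = present.mean(axis=1)
    keep = frac >= min_fraction
    metrics = pd.DataFrame(
        {"qc_presence_fraction": frac, "pass": keep}, index=table.feature_ids
    )
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    out = table.subset_features(
        kept_ids, f"qc_presence_filter:min={min_fraction}:removed={len(removed)}"
    )
    return out, QcReport(rule="qc_presence", metrics=metrics, removed=removed)


def qc_rsd_filter(
    table: FeatureTable,
    qc_sample_ids: Sequence[str],
    max_rsd: float = 0.30,
) -> tuple[FeatureTable, QcReport]:
    """Kept iff QC RSD (sample sd / mean) <= max_rsd.

    Features with < 3 usable QC values are indeterminate: kept and flagged.
    """
    if len(qc_sample_ids) < 3:
        raise QcError(f"need >=3 QC samples, got {len(qc_sample_ids)}")
    idx = table.sample_indices(qc_sample_ids)
    qc = table.values[:, idx]
    rsd = np.full(table.n_features, np.nan)
    indeterminate = np.zeros(table.n_features, dtype=bool)
    for i in range(table.n_features):
        v = qc[i][np.isfinite(qc[i])]
        if v.size < 3:
            indeterminate[i] = True
        elif v.mean() > 0:
            rsd[i] = v.std(ddof=1) / v.mean()
        else:
            indeterminate[i] = True
    keep = indeterminate | (rsd <= max_rsd)
    metrics = pd.DataFrame(
        {"qc_rsd": rsd, "indeterminate": indeterminate, "pass": keep},
        index=table.feature_ids,
    )
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    flagged = [f for f, m in zip(table.feature_ids, indeterminate) if m]
    out = table.subset_features(kept_ids, f"qc_rsd_filter:max={max_rsd}:removed={len(removed)}")
    return out, QcReport(rule="qc_rsd", metrics=metrics, removed=removed, flagged=flagged)


def qc_drift_correct(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    qc_sample_ids: Sequence[str],
    span: float = 0.75,
) -> tuple[FeatureTable, QcReport]:
    """Divide every sample by a QC-derived drift curve per feature.

    The curve is fit on log abundance vs injection order over QC points
    (LOWESS with the given span; ordinary least squares when < 5 QCs),
    interpolated linearly between QC injections and held at the nearest
    fitted value outside their range (such features are flagged as
    extrapolated). The per-feature median QC abundance is preserved
    exactly. Within an injection, only the feature's scale changes, so the
    rank order of samples per feature is untouched.
    """
    if len(qc_sample_ids) < 3:
        raise QcError(f"need >=3 QC samples spanning the run, got {len(qc_sample_ids)}")
    order_of = {r.sample_id: r.injection_order for r in records}
    missing = [s for s in table.sample_ids if order_of.get(s) is None]
    if missing:
        raise QcError(f"samples lack injection order: {missing[:5]}")
    all_orders = np.array([order_of[s] for s in table.sample_ids], dtype=float)
    qc_pos = table.sample_indices(qc_sample_ids)
    qc_orders = all_orders[qc_pos]
    sort = np.argsort(qc_orders)
    qc_orders_sorted = qc_orders[sort]

    span_lo, span_hi = qc_orders_sorted[0], qc_orders_sorted[-1]
    extrapolated = (all_orders < span_lo) | (all_orders > span_hi)

    corrected = table.values.copy()
    flagged = []
    eps = 1e-12
    for i in range(table.n_features):
        qv = table.values[i, qc_pos][sort]
        ok = np.isfinite(qv) & (qv > 0)
        if ok.sum() < 3:
            flagged.append(table.feature_ids[i])
            continue
        xo, lv = qc_orders_sorted[ok], np.log(qv[ok] + eps)
        if ok.sum() < 5:
            slope, icpt = np.polyfit(xo, lv, 1)
            fitted = slope * xo + icpt
        else:
            fitted = lowess(lv, xo, frac=span, return_sorted=False)
        curve = np.interp(all_orders, xo, fitted)  # nearest value beyond ends
        med = np.median(np.exp(lv))
        factor = np.exp(curve) / med
        corrected[i] = table.values[i] / factor
        # pin the QC median exactly
        qc_after = corrected[i, qc_pos]
        qc_after = qc_after[np.isfinite(qc_after) & (qc_after > 0)]
        if qc_after.size:
            med_after = np.median(qc_after)
            if med_after > 0:
                corrected[i] *= med / med_after

    metrics = pd.DataFrame(
        {
            "drift_corrected": [f not in flagged for f in table.feature_ids],
            "extrapolated_samples": int(extrapolated.sum()),
        },
        index=table.feature_ids,
    )
    out = table.with_values(corrected, f"qc_drift_correct:span={span}")
    return out, QcReport(rule="drift", metrics=metrics, flagged=flagged)


def write_qc_report(reports: Sequence[QcReport], path) -> None:
    frames = []
    for r in reports:
        m = r.metrics.copy()
        m.insert(0, "rule", r.rule)
        m.index.name = "feature_id"
        frames.append(m.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
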