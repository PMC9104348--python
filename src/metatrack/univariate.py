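"""Welch's t-test screening with Benjamini-Hochberg FDR control.

This is the gatekeeper of the pipeline: features passing q < alpha on the
TKO-vs-control comparison feed the trajectory, panel-selection and
ratio-screening stages. Tests are run on raw post-QC abundances with
missing values dropped per feature (no imputation), and longitudinal
samples are treated as independent observations; ``per_mouse='mean'``
collapses to one value per animal first for a conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import FeatureTable, Group, SampleRecord


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    feature_id: str
    t: float
    df: float
    p: float
    q: float = float("nan")


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t with Satterthwaite df and two-tailed p.

    Zero variance in both groups with equal means returns (0, df, 1) by
    convention; zero variance with unequal means is an error (the statistic
    is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise StatsError(f"need >=2 values per group, got {x.size} and {y.size}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise StatsError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    # Satterthwaite df, recomputed for the report
    sx, sy = vx / x.size, vy / y.size
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    alpha: float = 0.05,
    pct_window: tuple[float, float] | None = None,
    per_mouse: str | None = None,
) -> tuple[list[str], list[TestResult]]:
    """Welch + BH across all features on TKO vs CTRL study samples.

    ``pct_window=(lo, hi)`` restricts to samples with lo <= %lifetime <= hi
    (e.g. (37, 60) for the tumor-onset stage). Returns ids with q < alpha
    plus the full result list. Features with insufficient data are reported
    with NaN statistics and never selected.
    """
    recs = {r.sample_id: r for r in records}

    def _in_window(r: SampleRecord) -> bool:
        if r.group not in (Group.TKO, Group.CTRL):
            return False
        if pct_window is None:
            return True
        if r.pct_lifetime is None:
            return False
        return pct_window[0] <= r.pct_lifetime <= pct_window[1]

    tko_ids = [s for s in table.sample_ids if s in recs and recs[s].group is Group.TKO and _in_window(recs[s])]
    ctrl_ids = [s for s in table.sample_ids if s in recs and recs[s].group is Group.CTRL and _in_window(recs[s])]
    if len(tko_ids) < 2 or len(ctrl_ids) < 2:
        raise StatsError(
            f"need >=2 samples per group in window, got {len(tko_ids)} TKO / {len(ctrl_ids)} CTRL"
        )

    if per_mouse == "mean":
        xmat = _per_mouse_means(table, [recs[s] for s in tko_ids])
        ymat = _per_mouse_means(table, [recs[s] for s in ctrl_ids])
    else:
        xmat = table.values[:, table.sample_indices(tko_ids)]
        ymat = table.values[:, table.sample_indices(ctrl_ids)]

    results = []
    ps = []
    for i, fid in enumerate(table.feature_ids):
        try:
            t, df, p = welch_t(xmat[i], ymat[i])
        except StatsError:
            t, df, p = float("nan"), float("nan"), float("nan")
        results.append(TestResult(feature_id=fid, t=t, df=df, p=p))
        ps.append(p)

    ps = np.asarray(ps)
    ok = np.isfinite(ps)
    qs = np.full_like(ps, np.nan)
    if ok.any():
        qs[ok] = bh_adjust(ps[ok])
    for r, q in zip(results, qs):
        r.q = float(q)

    selected = [r.feature_id for r in results if np.isfinite(r.q) and r.q < alpha]
    return selected, results


def _per_mouse_means(table: FeatureTable, recs: Sequence[SampleRecord]) -> np.ndarray:
    mice: dict[str, list[int]] = {}
    for r in recs:
        mice.setdefault(r.mouse_id or r.sample_id, []).append(
            table.sample_ids.index(r.sample_id)
        )
    cols = [np.nanmean(table.values[:, idx], axis=1) for idx in mice.values()]
    return np.column_stack(cols)
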