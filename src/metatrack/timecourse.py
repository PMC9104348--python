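"""%lifetime alignment, stage bins, and fold-change trajectories.

Longitudinal cohorts with variable survival are aligned on *percent
lifetime*: a sample's age divided by the animal's total lifespan (for
controls, the age at the last blood collection), times 100. The axis is
divided into four disease-stage bins - premalignant (PRE), early stage I
(tumor onset, ET1), early stage II (ET2) and advanced (AT) - and per-bin
log2 fold changes TKO/control summarize each feature's (or lipid class's)
temporal trajectory.

The published integer bin labels (20-36, 37-60, 61-80, 81-100) are realized
as half-open real intervals [20,37), [37,61), [61,81), [81,100]; values
below 20 (possible for a long-lived control's earliest samples) map to PRE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_tables import FeatureAnnotation, FeatureTable, Group, SampleRecord, Stage


class TimecourseError(ValueError):
    pass


# half-open stage bins on %lifetime; AT closes at 100
DEFAULT_STAGE_BINS: dict[Stage, tuple[float, float]] = {
    Stage.PRE: (20.0, 37.0),
    Stage.ET1: (37.0, 61.0),
    Stage.ET2: (61.0, 81.0),
    Stage.AT: (81.0, 100.0),
}


def percent_lifetime(age_weeks: float, lifespan_weeks: float) -> float:
    """100 x age / lifespan; for controls the denominator is the age at the
    last blood collection. Scale-invariant in (age, lifespan)."""
    if lifespan_weeks <= 0:
        raise TimecourseError(f"non-positive lifespan: {lifespan_weeks}")
    if age_weeks <= 0:
        raise TimecourseError(f"non-positive age: {age_weeks}")
    if age_weeks > lifespan_weeks + 1e-9:
        raise TimecourseError(f"age {age_weeks} exceeds lifespan {lifespan_weeks}")
    return 100.0 * age_weeks / lifespan_weeks


def assign_stage(pct_lifetime: float, bins: dict[Stage, tuple[float, float]] | None = None) -> Stage:
    """Map a %lifetime value to its stage bin (exhaustive over [0, 100])."""
    if not (0.0 <= pct_lifetime <= 100.0):
        raise TimecourseError(f"%lifetime out of [0,100]: {pct_lifetime}")
    bins = bins or DEFAULT_STAGE_BINS
    if pct_lifetime < bins[Stage.PRE][0]:
        return Stage.PRE  # early samples of long-lived controls
    for stage, (lo, hi) in bins.items():
        if lo <= pct_lifetime < hi:
            return stage
    return Stage.AT  # pct == upper edge (100)


def derive_time_fields(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    """Fill pct_lifetime and stage on study samples, in place; returns records."""
    for r in records:
        if r.group in (Group.TKO, Group.CTRL):
            if r.age_weeks is None or r.lifespan_weeks is None:
                raise TimecourseError(f"sample {r.sample_id} lacks age/lifespan")
            r.pct_lifetime = percent_lifetime(r.age_weeks, r.lifespan_weeks)
            r.stage = assign_stage(r.pct_lifetime)
    return records


@dataclass
class TrajectoryPoint:
    """One bin of a log2 fold-change trajectory (TKO over control)."""

    bin_label: str
    bin_center: float
    log2fc: float
    se: float
    n_tko: int
    n_ctrl: int


def _bin_members(
    records: Sequence[SampleRecord],
    lo: float,
    hi: float,
    closed_right: bool,
) -> tuple[list[str], list[str]]:
    tko, ctrl = [], []
    for r in records:
        if r.group not in (Group.TKO, Group.CTRL) or r.pct_lifetime is None:
            continue
        p = r.pct_lifetime
        inside = (lo <= p < hi) or (closed_right and p == hi)
        if lo == 20.0 and p < 20.0:  # PRE absorbs <20
            inside = True
        if inside:
            (tko if r.group is Group.TKO else ctrl).append(r.sample_id)
    return tko, ctrl


def bin_log2_fold_change(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    feature_id: str,
    bin_range: tuple[float, float],
    closed_right: bool = False,
    bin_label: str | None = None,
) -> TrajectoryPoint | None:
    """log2(mean TKO / mean CTRL) of one feature within a %lifetime bin.

    The standard error is by the delta method,
    ``(1/ln 2) * sqrt(cv_tko^2/n_tko + cv_ctrl^2/n_ctrl)`` with cv the
    within-bin coefficient of variation. Returns None when either group is
    empty in the bin.
    """
    lo, hi = bin_range
    tko_ids, ctrl_ids = _bin_members(records, lo, hi, closed_right)
    if not tko_ids or not ctrl_ids:
        return None
    row = table.values[table.feature_index(feature_id)]
    x = row[table.sample_indices(tko_ids)]
    y = row[table.sample_indices(ctrl_ids)]
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return None
    my, mx = y.mean(), x.mean()
    if my == 0:
        raise TimecourseError(f"zero control mean for {feature_id} in bin {bin_range}")
    log2fc = float(np.log2(mx / my))
    cvx = x.std(ddof=1) / mx if x.size > 1 and mx != 0 else 0.0
    cvy = y.std(ddof=1) / my if y.size > 1 else 0.0
    se = float(np.sqrt(cvx**2 / x.size + cvy**2 / y.size) / np.log(2))
    return TrajectoryPoint(
        bin_label=bin_label or f"[{lo:g},{hi:g})",
        bin_center=(lo + hi) / 2.0,
        log2fc=log2fc,
        se=se,
        n_tko=int(x.size),
        n_ctrl=int(y.size),
    )


def stage_bin_ranges(
    bins: dict[Stage, tuple[float, float]] | None = None,
) -> list[tuple[str, tuple[float, float], bool]]:
    """(label, (lo, hi), closed_right) triples for the four stage bins."""
    bins = bins or DEFAULT_STAGE_BINS
    out = []
    stages = list(bins)
    for i, stage in enumerate(stages):
        out.append((stage.value, bins[stage], i == len(stages) - 1))
    return out


def fine_bin_ranges(width: float = 5.0, lo: float = 20.0, hi: float = 100.0) -> list[tuple[str, tuple[float, float], bool]]:
    """Fixed-width fine bins for the high-resolution trajectory view."""
    edges = np.arange(lo, hi, width)
    out = []
    for i, e in enumerate(edges):
        top = min(e + width, hi)
        out.append((f"{e:g}-{top:g}", (float(e), float(top)), i == len(edges) - 1))
    return out


def feature_trajectory(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    feature_id: str,
    bins: list[tuple[str, tuple[float, float], bool]] | None = None,
) -> list[TrajectoryPoint]:
    bins = bins or stage_bin_ranges()
    pts = []
    for label, rng, closed in bins:
        pt = bin_log2_fold_change(table, records, feature_id, rng, closed, label)
        if pt is not None:
            pts.append(pt)
    return pts


def class_trajectory(
    table: FeatureTable,
    annotations: Sequence[FeatureAnnotation],
    records: Sequence[SampleRecord],
    lipid_class: str,
    significant_ids: Sequence[str],
    bins: list[tuple[str, tuple[float, float], bool]] | None = None,
) -> list[TrajectoryPoint]:
    """Class-level trajectory: per sample, the class score is the mean
    abundance over the class's significant features; the score is then
    binned like a single feature."""
    sig = set(significant_ids)
    members = [
        a.feature_id
        for a in annotations
        if a.lipid_class == lipid_class and a.feature_id in sig and a.feature_id in table.feature_ids
    ]
    if not members:
        return []
    idx = [table.feature_index(f) for f in members]
    with warnings.catch_warnings():
        # samples with every class member missing yield a NaN score
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.nanmean(table.values[idx, :], axis=0)
    score_table = FeatureTable(
        feature_ids=[f"class:{lipid_class}"],
        sample_ids=list(table.sample_ids),
        values=score[None, :],
        provenance=table.provenance + [f"class_score:{lipid_class}:n={len(members)}"],
    )
    return feature_trajectory(score_table, records, f"class:{lipid_class}", bins)


@dataclass
class TrajectoryTable:
    """Long-format collection of trajectories, one row per (class, bin)."""

    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, points: Sequence[TrajectoryPoint]) -> None:
        for p in points:
            self.rows.append(
                {
                    "series": name,
                    "bin": p.bin_label,
                    "bin_center": p.bin_center,
                    "log2fc": p.log2fc,
                    "se": p.se,
                    "n_tko": p.n_tko,
                    "n_ctrl": p.n_ctrl,
                }
            )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)
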