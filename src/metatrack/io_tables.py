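"""Tabular data model and delimited-text I/O.

The package's core container is :class:`FeatureTable`, a features-by-samples
matrix of non-negative peak areas (NaN = missing) with an append-only
provenance log, accompanied by per-sample metadata (:class:`SampleRecord`)
and optional per-feature annotations (:class:`FeatureAnnotation`).

On disk everything is tab-separated text: the abundance matrix has features
as rows and samples as columns (the common metabolomics export orientation),
one header row, and missing values encoded as empty cells.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Group(str, enum.Enum):
    """Sample class: study groups plus instrument-control injections."""

    TKO = "TKO"
    CTRL = "CTRL"
    QC = "QC"
    BLANK = "BLANK"


class Stage(str, enum.Enum):
    """Disease-stage bins on the %lifetime axis."""

    PRE = "PRE"    # premalignant
    ET1 = "ET1"    # early stage I (tumor onset)
    ET2 = "ET2"    # early stage II
    AT = "AT"      # advanced / metastatic


STUDY_GROUPS = (Group.TKO, Group.CTRL)


class ValidationError(ValueError):
    """Raised when input tables violate the data-model contracts."""


@dataclass
class SampleRecord:
    """Metadata for one injection.

    ``age_weeks`` and ``lifespan_weeks`` are only meaningful for study
    samples (TKO/CTRL); for controls ``lifespan_weeks`` is the age at the
    last blood collection. ``pct_lifetime`` and ``stage`` are derived by
    :mod:`metatrack.timecourse`.
    """

    sample_id: str
    group: Group
    mouse_id: str | None = None
    age_weeks: float | None = None
    lifespan_weeks: float | None = None
    injection_order: int | None = None
    pct_lifetime: float | None = None
    stage: Stage | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.stage is not None:
            self.stage = Stage(self.stage)
        if self.group in STUDY_GROUPS:
            if (
                self.age_weeks is not None
                and self.lifespan_weeks is not None
                and self.age_weeks > self.lifespan_weeks + 1e-9
            ):
                raise ValidationError(
                    f"sample {self.sample_id}: age {self.age_weeks} exceeds "
                    f"lifespan {self.lifespan_weeks}"
                )


@dataclass
class FeatureAnnotation:
    """Per-feature identification record (Table-style column set)."""

    feature_id: str
    name: str = ""
    mz_experimental: float | None = None
    retention_time_min: float | None = None
    formula: str | None = None
    adduct: str | None = None
    lipid_class: str | None = None
    log2fc: float | None = None
    q_value: float | None = None
    confidence_level: int | None = None

    def __post_init__(self) -> None:
        if self.confidence_level is not None and self.confidence_level not in (1, 2, 3, 4):
            raise ValidationError(
                f"confidence level must be 1-4, got {self.confidence_level}"
            )
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(f"q-value out of [0,1]: {self.q_value}")


@dataclass
class FeatureTable:
    """Non-negative abundance matrix (features x samples, NaN = missing)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_features, n_samples), float, NaN allowed
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValidationError("negative abundance values are not allowed")

    # -- views ----------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id}") from None

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    # -- derived tables -------------------------------------------------
    def subset_features(self, keep: Sequence[str], note: str) -> "FeatureTable":
        idx = [self.feature_index(f) for f in keep]
        return FeatureTable(
            feature_ids=list(keep),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :].copy(),
            provenance=self.provenance + [note],
        )

    def subset_samples(self, keep: Sequence[str], note: str) -> "FeatureTable":
        idx = self.sample_indices(keep)
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            sample_ids=list(keep),
            values=self.values[:, idx].copy(),
            provenance=self.provenance + [note],
        )

    def with_values(self, values: np.ndarray, note: str) -> "FeatureTable":
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            provenance=self.provenance + [note],
        )


# ---------------------------------------------------------------------------
# group helpers

def sample_ids_by_group(records: Sequence[SampleRecord], group: Group) -> list[str]:
    return [r.sample_id for r in records if r.group is Group(group)]


def study_sample_ids(records: Sequence[SampleRecord]) -> list[str]:
    return [r.sample_id for r in records if r.group in STUDY_GROUPS]


# ---------------------------------------------------------------------------
# delimited-text I/O

_META_COLUMNS = [
    "sample_id",
    "mouse_id",
    "group",
    "age_weeks",
    "lifespan_weeks",
    "injection_order",
    "pct_lifetime",
    "stage",
]

_ANNOT_COLUMNS = [
    "feature_id",
    "name",
    "adduct",
    "mz_experimental",
    "formula",
    "retention_time_min",
    "mass_error_ppm",
    "lipid_class",
    "log2fc",
    "q_value",
    "confidence_level",
]


def write_feature_table(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    matrix_path,
    metadata_path,
) -> None:
    """Write the matrix and metadata as two TSV files (empty cell = NaN)."""
    if table.n_features == 0 or table.n_samples == 0:
        raise ValidationError("refusing to write an empty feature table")
    rec_ids = {r.sample_id for r in records}
    missing = [s for s in table.sample_ids if s not in rec_ids]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    df = table.to_frame()
    df.index.name = "feature_id"
    df.to_csv(matrix_path, sep="\t", na_rep="")

    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["group"] = r.group.value
        d["stage"] = r.stage.value if r.stage is not None else None
        rows.append(d)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def read_feature_table(matrix_path, metadata_path) -> tuple[FeatureTable, list[SampleRecord]]:
    """Read matrix + metadata TSVs, validating ids and non-negativity."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata file lacks a sample_id column")
    meta_ids = set(meta["sample_id"].astype(str))
    sample_ids = [str(c) for c in df.columns]
    orphans = sorted(set(sample_ids) - meta_ids)
    if orphans:
        raise ValidationError(f"samples missing from metadata: {orphans}")

    values = df.to_numpy(dtype=float)
    if np.any(values[np.isfinite(values)] < 0):
        bad = df.index[(df < 0).any(axis=1)].tolist()
        raise ValidationError(f"negative abundances for features: {bad}")

    records = []
    for _, row in meta.iterrows():
        def _f(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        order = _f("injection_order")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                mouse_id=None if _f("mouse_id") is None else str(_f("mouse_id")),
                group=Group(str(row["group"])),
                age_weeks=_f("age_weeks"),
                lifespan_weeks=_f("lifespan_weeks"),
                injection_order=None if order is None else int(order),
                pct_lifetime=_f("pct_lifetime"),
                stage=None if _f("stage") is None else Stage(str(_f("stage"))),
            )
        )
    orders = [r.injection_order for r in records if r.injection_order is not None]
    if len(orders) != len(set(orders)):
        raise ValidationError("injection_order values are not unique")

    table = FeatureTable(
        feature_ids=[str(i) for i in df.index],
        sample_ids=sample_ids,
        values=values,
        provenance=[f"read:{matrix_path}"],
    )
    return table, records


def write_annotations(annotations: Sequence[FeatureAnnotation], path) -> None:
    rows = [dataclasses.asdict(a) for a in annotations]
    for r in rows:
        r.setdefault("mass_error_ppm", None)
    pd.DataFrame(rows).reindex(columns=_ANNOT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[FeatureAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        def _f(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        conf = _f("confidence_level")
        out.append(
            FeatureAnnotation(
                feature_id=str(row["feature_id"]),
                name=str(_f("name") or ""),
                mz_experimental=_f("mz_experimental"),
                retention_time_min=_f("retention_time_min"),
                formula=None if _f("formula") is None else str(_f("formula")),
                adduct=None if _f("adduct") is None else str(_f("adduct")),
                lipid_class=None if _f("lipid_class") is None else str(_f("lipid_class")),
                log2fc=_f("log2fc"),
                q_value=_f("q_value"),
                confidence_level=None if conf is None else int(conf),
            )
        )
    return out
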