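"""Synthetic longitudinal serum cohorts and MSI phantoms with ground truth.

The generator emulates the structure of a two-arm longitudinal mouse study:
15 tumor-bearing (TKO) and 15 control animals bled every two weeks from 8
weeks of age, TKO lifespans drawn uniformly from 24-40 weeks, controls
followed to a fixed end point. Features are drawn log-normal per feature
(strictly positive, right-skewed peak areas); each non-noise feature
belongs to a lipid class whose planted temporal template (piecewise-linear
log2 fold change vs %lifetime) multiplies TKO abundances by
``2^(effect_scale * template(pct))``. Pooled-QC injections recur every
``qc_every_n_injections`` with dispersion ``qc_rsd_target``, blanks carry a
small fraction of the baseline, and a configurable fraction of entries is
missing completely at random. Everything is keyed off a single seed and is
byte-reproducible.

The MSI phantom partitions a pixel grid into contiguous regions (by default
a tumor ring around a healthy core plus a necrotic lobe) with
region-specific mean intensities per feature and Poisson-like noise, again
with full ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_tables import FeatureAnnotation, FeatureTable, Group, SampleRecord
from .msi import MSIDataset
from .timecourse import derive_time_fields


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# temporal templates

TEMPLATE_SHAPES = (
    "monotone_up",
    "monotone_down",
    "inverted_U",
    "wave_down_up_down",
    "late_spike_then_drop",
    "flat",
)


@dataclass(frozen=True)
class PlantedTemplate:
    """Piecewise-linear log2 fold-change template on the %lifetime axis.

    Anchors map %lifetime knots to planted log2 fold changes; between knots
    the template interpolates linearly, outside the knot range it holds the
    nearest anchor. By convention the anchor at 20 %lifetime is 0 (no
    premalignant effect unless explicitly configured).
    """

    shape: str
    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.shape not in TEMPLATE_SHAPES:
            raise ConfigError(f"unknown template shape {self.shape!r}")
        if not self.anchors:
            raise ConfigError("template needs at least one anchor")


def template_value(template: PlantedTemplate, pct_lifetime: float) -> float:
    """Evaluate a template at a %lifetime point (nearest anchor outside)."""
    knots = np.array([k for k, _ in template.anchors], dtype=float)
    vals = np.array([v for _, v in template.anchors], dtype=float)
    order = np.argsort(knots)
    return float(np.interp(pct_lifetime, knots[order], vals[order]))


# canonical shapes, normalized so the peak |log2FC| is 1 where meaningful;
# the late-spike shape carries the published 20a-OHP magnitudes (+0.99 at
# 37-80 %lifetime, -0.43 in the advanced stage) so effect_scale=1 plants them
DEFAULT_TEMPLATES: dict[str, PlantedTemplate] = {
    "monotone_up": PlantedTemplate("monotone_up", ((20.0, 0.0), (100.0, 1.0))),
    "monotone_down": PlantedTemplate("monotone_down", ((20.0, 0.0), (100.0, -1.0))),
    "inverted_U": PlantedTemplate(
        "inverted_U", ((20.0, 0.0), (50.0, 0.3), (80.0, 0.3), (100.0, -1.0))
    ),
    "wave_down_up_down": PlantedTemplate(
        "wave_down_up_down", ((20.0, 0.0), (45.0, -0.4), (70.0, 0.3), (100.0, -0.5))
    ),
    "late_spike_then_drop": PlantedTemplate(
        "late_spike_then_drop",
        ((20.0, 0.0), (37.0, 0.99), (80.0, 0.99), (85.0, -0.43), (100.0, -0.43)),
    ),
    "flat": PlantedTemplate("flat", ((20.0, 0.0), (100.0, 0.0))),
}

# class -> template shape, mirroring the reported per-class temporal trends:
# sphingomyelins fall while ceramides rise; glycerophospholipids and
# glycerolipids rise; lyso-species follow the inverted-U; ether lipids and
# short-chain FA fall; VLCFA rise; the steroid 20a-OHP spikes late then drops
DEFAULT_CLASS_TEMPLATES: dict[str, str] = {
    "SM": "monotone_down",
    "Cer": "monotone_up",
    "HexCer": "monotone_up",
    "PC": "monotone_up",
    "PE": "monotone_up",
    "PS": "monotone_up",
    "PI": "monotone_up",
    "TG": "monotone_up",
    "DG": "monotone_up",
    "LPC": "inverted_U",
    "LPE": "inverted_U",
    "PC O-": "monotone_down",
    "PE O-": "monotone_down",
    "PS O-": "monotone_down",
    "FA": "monotone_down",
    "VLCFA": "monotone_up",
    "sterol": "late_spike_then_drop",
    "polar": "wave_down_up_down",
    "Car": "flat",
}


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    n_tko: int = 15
    n_ctrl: int = 15
    sampling_interval_weeks: float = 2.0
    start_age_weeks: float = 8.0
    tko_lifespan_range_weeks: tuple[float, float] = (24.0, 40.0)
    ctrl_followup_weeks: float = 40.0
    n_features_per_class: Mapping[str, int] = field(
        default_factory=lambda: {c: 10 for c in DEFAULT_CLASS_TEMPLATES}
    )
    n_noise_features: int = 50
    effect_scale: float = 1.0
    qc_every_n_injections: int = 10
    qc_rsd_target: float = 0.15
    blank_level: float = 0.02
    noise_rsd: float = 0.20
    dropout_fraction: float = 0.02
    n_blanks: int = 3
    baseline_log10_range: tuple[float, float] = (4.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tko < 0 or self.n_ctrl < 0:
            raise ConfigError("mouse counts must be >= 0")
        lo, hi = self.tko_lifespan_range_weeks
        if not lo < hi:
            raise ConfigError("lifespan range must satisfy low < high")
        if not (0.0 < self.qc_rsd_target < 1.0):
            raise ConfigError("qc_rsd_target must be in (0, 1)")
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise ConfigError("dropout_fraction must be in [0, 1]")
        if self.effect_scale < 0:
            raise ConfigError("effect_scale must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    feature_class: dict[str, str] = field(default_factory=dict)
    feature_template: dict[str, PlantedTemplate] = field(default_factory=dict)
    feature_effect: dict[str, float] = field(default_factory=dict)
    mouse_lifespan: dict[str, float] = field(default_factory=dict)
    region_labels: np.ndarray | None = None  # MSI phantom pixel labels


# ---------------------------------------------------------------------------
# serum cohort generator

def _lognormal_sigma(rsd: float) -> float:
    """Log-sd giving a multiplicative noise RSD of ``rsd``."""
    return float(np.sqrt(np.log1p(rsd**2)))


def generate_cohort(
    config: SimConfig,
) -> tuple[FeatureTable, list[SampleRecord], list[FeatureAnnotation], SyntheticTruth]:
    """Simulate a longitudinal two-arm cohort with pooled QCs and blanks."""
    n_features = sum(config.n_features_per_class.values()) + config.n_noise_features
    if n_features == 0:
        raise ConfigError("no features configured")
    if config.n_tko + config.n_ctrl == 0:
        raise ConfigError("no mice configured")
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()

    # features: class membership, planted template, baseline abundance
    feature_ids: list[str] = []
    annotations: list[FeatureAnnotation] = []
    lo10, hi10 = config.baseline_log10_range
    baselines: list[float] = []
    templates: list[PlantedTemplate] = []
    flat = DEFAULT_TEMPLATES["flat"]
    for cls, count in config.n_features_per_class.items():
        shape = DEFAULT_CLASS_TEMPLATES.get(cls, "flat")
        tmpl = DEFAULT_TEMPLATES[shape]
        for j in range(count):
            fid = f"{cls.replace(' ', '')}_{j:03d}"
            feature_ids.append(fid)
            annotations.append(FeatureAnnotation(feature_id=fid, name=fid, lipid_class=cls))
            truth.feature_class[fid] = cls
            truth.feature_template[fid] = tmpl
            truth.feature_effect[fid] = config.effect_scale
            templates.append(tmpl)
            baselines.append(10.0 ** rng.uniform(lo10, hi10))
    for j in range(config.n_noise_features):
        fid = f"noise_{j:03d}"
        feature_ids.append(fid)
        annotations.append(FeatureAnnotation(feature_id=fid, name=fid, lipid_class="noise"))
        truth.feature_class[fid] = "noise"
        truth.feature_template[fid] = flat
        truth.feature_effect[fid] = 0.0
        templates.append(flat)
        baselines.append(10.0 ** rng.uniform(lo10, hi10))
    baselines_arr = np.array(baselines)

    # mice and their sampling schedules
    study: list[tuple[str, Group, float, float]] = []  # (mouse, group, age, lifespan)
    for m in range(config.n_tko):
        mouse = f"TKO{m + 1:02d}"
        lifespan = float(rng.uniform(*config.tko_lifespan_range_weeks))
        truth.mouse_lifespan[mouse] = lifespan
        ages = np.arange(config.start_age_weeks, lifespan + 1e-9, config.sampling_interval_weeks)
        study.extend((mouse, Group.TKO, float(a), lifespan) for a in ages)
    for m in range(config.n_ctrl):
        mouse = f"CTRL{m + 1:02d}"
        lifespan = float(config.ctrl_followup_weeks)
        truth.mouse_lifespan[mouse] = lifespan
        ages = np.arange(config.start_age_weeks, lifespan + 1e-9, config.sampling_interval_weeks)
        study.extend((mouse, Group.CTRL, float(a), lifespan) for a in ages)

    # injection sequence: randomized study order, QCs interleaved, blanks
    # at the start, middle and end of the run
    perm = rng.permutation(len(study))
    sequence: list[tuple[str, Group, float | None, float | None]] = []
    qc_count = 0
    sequence.append(("BLANK_1", Group.BLANK, None, None))
    for k, idx in enumerate(perm):
        if config.qc_every_n_injections and k % config.qc_every_n_injections == 0:
            qc_count += 1
            sequence.append((f"QC_{qc_count:03d}", Group.QC, None, None))
        mouse, grp, age, lifespan = study[idx]
        sid = f"{mouse}_w{age:04.1f}"
        sequence.append((sid, grp, age, lifespan))
    qc_count += 1
    sequence.append((f"QC_{qc_count:03d}", Group.QC, None, None))
    for b in range(2, config.n_blanks + 1):
        sequence.insert(len(sequence) // 2 if b == 2 else len(sequence), (f"BLANK_{b}", Group.BLANK, None, None))

    records: list[SampleRecord] = []
    mouse_of: dict[str, str] = {}
    for order, (sid, grp, age, lifespan) in enumerate(sequence, start=1):
        mouse = sid.split("_w")[0] if grp in (Group.TKO, Group.CTRL) else None
        if mouse:
            mouse_of[sid] = mouse
        records.append(
            SampleRecord(
                sample_id=sid,
                mouse_id=mouse,
                group=grp,
                age_weeks=age,
                lifespan_weeks=lifespan,
                injection_order=order,
            )
        )
    derive_time_fields(records)

    # abundance matrix
    sigma = _lognormal_sigma(config.noise_rsd)
    sigma_qc = _lognormal_sigma(config.qc_rsd_target)
    n_samples = len(records)
    values = np.empty((n_features, n_samples))
    pooled_mean = baselines_arr  # pooled QC approximates the study average
    for s, rec in enumerate(records):
        if rec.group is Group.BLANK:
            col = config.blank_level * baselines_arr * rng.lognormal(0.0, sigma, n_features)
        elif rec.group is Group.QC:
            col = pooled_mean * rng.lognormal(0.0, sigma_qc, n_features)
        else:
            col = baselines_arr * rng.lognormal(0.0, sigma, n_features)
            if rec.group is Group.TKO and config.effect_scale > 0:
                tvals = np.array(
                    [template_value(t, rec.pct_lifetime) for t in templates]
                )
                col = col * np.power(2.0, config.effect_scale * tvals)
        values[:, s] = col

    if config.dropout_fraction > 0:
        drop = rng.random(values.shape) < config.dropout_fraction
        values[drop] = np.nan

    table = FeatureTable(
        feature_ids=feature_ids,
        sample_ids=[r.sample_id for r in records],
        values=values,
        provenance=[f"simulated:seed={config.seed}"],
    )
    return table, records, annotations, truth


# ---------------------------------------------------------------------------
# MSI phantom

DEFAULT_REGIONS = ("HGSC", "necrotic", "healthy")


def generate_msi_phantom(
    width: int = 30,
    height: int = 30,
    n_features: int = 50,
    region_effects: Mapping[str, Sequence[float]] | None = None,
    region_contrast_log2sd: float = 1.5,
    noise_rsd: float = 0.15,
    tic_variation: float = 0.2,
    mz_range: tuple[float, float] = (150.0, 1200.0),
    seed: int = 0,
) -> tuple[MSIDataset, SyntheticTruth]:
    """Three-region tissue phantom with centroid spectra per pixel.

    The default geometry nests a healthy core inside a tumor (HGSC) ring
    with a necrotic lobe in one corner; ``region_effects`` can instead give
    explicit per-region intensity multipliers (region -> length-n_features
    vector), which also determines the region set. Per-pixel intensities
    are region mean x pixel TIC factor x multiplicative noise.
    """
    if width < 2 or height < 2:
        raise ConfigError("phantom grid must be at least 2x2")
    rng = np.random.default_rng(seed)

    if region_effects is not None:
        regions = list(region_effects)
        if len(regions) < 2:
            raise ConfigError("need >= 2 regions")
        effects = {r: np.asarray(v, dtype=float) for r, v in region_effects.items()}
        for r, v in effects.items():
            if v.shape != (n_features,):
                raise ConfigError(f"region {r}: expected {n_features} multipliers")
    else:
        regions = list(DEFAULT_REGIONS)
        # independent per-region mean profiles with log-normal contrast
        effects = {
            r: np.power(2.0, rng.normal(0.0, region_contrast_log2sd, n_features))
            for r in regions
        }

    # geometry: healthy disk at center, necrotic lobe lower-left, HGSC elsewhere
    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    r_core = min(width, height) / 4.5
    labels = np.zeros((height, width), dtype=int)  # 0 = first region
    region_index = {r: i for i, r in enumerate(regions)}
    if region_effects is None or set(regions) == set(DEFAULT_REGIONS):
        healthy = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_core**2
        lx, ly = width * 0.18, height * 0.8
        necrotic = ((xx - lx) ** 2 + (yy - ly) ** 2 <= (min(width, height) / 3.8) ** 2) & ~healthy
        labels[:] = region_index.get("HGSC", 0)
        labels[necrotic] = region_index.get("necrotic", 1 % len(regions))
        labels[healthy] = region_index.get("healthy", len(regions) - 1)
    else:
        # fallback: vertical bands, one per region
        band = np.clip((xx * len(regions)) // width, 0, len(regions) - 1)
        labels[:] = band

    mzs = np.sort(rng.uniform(mz_range[0], mz_range[1], n_features))
    base = 10.0 ** rng.uniform(2.0, 4.0, n_features)
    sigma = _lognormal_sigma(noise_rsd)

    coords = [(int(x), int(y)) for y in range(height) for x in range(width)]
    intensities = np.empty((len(coords), n_features))
    for k, (x, y) in enumerate(coords):
        region = regions[labels[y, x]]
        tic_factor = float(rng.lognormal(0.0, _lognormal_sigma(tic_variation)))
        mean = base * effects[region] * tic_factor
        intensities[k] = mean * rng.lognormal(0.0, sigma, n_features)

    dataset = MSIDataset(
        coordinates=coords,
        mz_arrays=[mzs.copy() for _ in coords],
        intensity_arrays=[intensities[k] for k in range(len(coords))],
        mz_range=mz_range,
        polarity="-",
    )
    truth = SyntheticTruth(region_labels=labels)
    truth.feature_class = {f"mz_{m:.4f}": regions[0] for m in mzs}  # mz registry
    return dataset, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize the planted truth as a plain-text sidecar."""
    import json

    payload = {
        "feature_class": truth.feature_class,
        "feature_template": {
            f: {"shape": t.shape, "anchors": list(map(list, t.anchors))}
            for f, t in truth.feature_template.items()
        },
        "feature_effect": truth.feature_effect,
        "mouse_lifespan": truth.mouse_lifespan,
        "region_labels": None
        if truth.region_labels is None
        else truth.region_labels.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
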