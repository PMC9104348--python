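"""Mass spectrometry imaging: data model, normalization, segmentation.

An :class:`MSIDataset` holds centroid spectra per pixel (ascending m/z and
non-negative intensity arrays, processed-mode layout). The analysis chain
is: TIC normalization (each pixel divided by its total ion current), ion
images extracted in a fixed +/-window around a target m/z (absolute Da,
default 0.001), a pixel x feature matrix built from a reference m/z list,
and divisive spatial segmentation by bisecting k-means: starting from one
cluster, the cluster with the largest within-cluster SSE is repeatedly
split by 2-means on L2-normalized rows (cosine geometry; Euclidean
available), recording the split tree. Region-vs-region log2 fold changes
per feature summarize the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

class MsiError(ValueError):
    pass


@dataclass
class MSIDataset:
    """Processed-mode MSI data: per-pixel centroid m/z + intensity arrays."""

    coordinates: list[tuple[int, int]]  # (x, y)
    mz_arrays: list[np.ndarray]
    intensity_arrays: list[np.ndarray]
    mz_range: tuple[float, float] = (150.0, 1200.0)
    polarity: str = "-"
    excluded_pixels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.coordinates) == 0:
            raise MsiError("empty pixel list")
        if len({c for c in self.coordinates}) != len(self.coordinates):
            raise MsiError("duplicate pixel coordinates")
        if not (len(self.coordinates) == len(self.mz_arrays) == len(self.intensity_arrays)):
            raise MsiError("per-pixel array counts do not match coordinates")
        for i, (mz, it) in enumerate(zip(self.mz_arrays, self.intensity_arrays)):
            mz = np.asarray(mz, dtype=float)
            it = np.asarray(it, dtype=float)
            if mz.shape != it.shape:
                raise MsiError(f"pixel {i}: m/z and intensity lengths differ")
            if mz.size > 1 and np.any(np.diff(mz) <= 0):
                raise MsiError(f"pixel {i}: m/z array not strictly ascending")
            if np.any(it < 0):
                raise MsiError(f"pixel {i}: negative intensity")
            self.mz_arrays[i] = mz
            self.intensity_arrays[i] = it

    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)

    def shape(self) -> tuple[int, int]:
        xs = [c[0] for c in self.coordinates]
        ys = [c[1] for c in self.coordinates]
        return max(ys) + 1, max(xs) + 1  # (height, width)


# ---------------------------------------------------------------------------
# imzML I/O (processed mode)

def write_imzml(dataset: MSIDataset, path) -> None:
    """Write the dataset as a processed-mode imzML/ibd pair."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), polarity="negative" if dataset.polarity == "-" else "positive") as w:
        for (x, y), mz, it in zip(dataset.coordinates, dataset.mz_arrays, dataset.intensity_arrays):
            # imzML coordinates are 1-based
            w.addSpectrum(mz, it, (x + 1, y + 1, 1))


def load_imzml(path) -> MSIDataset:
    """Read an imzML/ibd pair (continuous or processed mode)."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = []
    mzs = []
    its = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, it = parser.getspectrum(i)
        coords.append((int(x) - 1, int(y) - 1))
        mzs.append(np.asarray(mz, dtype=float))
        its.append(np.asarray(it, dtype=float))
    if not coords:
        raise MsiError(f"no pixels found in {path}")
    lo = min(float(m[0]) for m in mzs if m.size)
    hi = max(float(m[-1]) for m in mzs if m.size)
    return MSIDataset(coordinates=coords, mz_arrays=mzs, intensity_arrays=its, mz_range=(lo, hi))


# ---------------------------------------------------------------------------
# normalization and images

def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Divide each pixel's intensities by its total ion current.

    All-zero pixels cannot be normalized; they are kept with zero spectra
    and listed in ``excluded_pixels``.
    """
    new_int = []
    excluded = []
    for i, it in enumerate(dataset.intensity_arrays):
        tic = it.sum()
        if tic <= 0:
            excluded.append(i)
            new_int.append(it.copy())
        else:
            new_int.append(it / tic)
    return MSIDataset(
        coordinates=list(dataset.coordinates),
        mz_arrays=[m.copy() for m in dataset.mz_arrays],
        intensity_arrays=new_int,
        mz_range=dataset.mz_range,
        polarity=dataset.polarity,
        excluded_pixels=excluded,
    )


def ion_image(dataset: MSIDataset, target_mz: float, window_da: float = 0.001) -> np.ndarray:
    """Raster of summed intensity within [target - window, target + window].

    Pixels without peaks in the window are 0; the window is absolute Da.
    """
    if window_da <= 0:
        raise MsiError(f"window must be positive, got {window_da}")
    h, w = dataset.shape()
    img = np.zeros((h, w))
    lo, hi = target_mz - window_da, target_mz + window_da
    for (x, y), mz, it in zip(dataset.coordinates, dataset.mz_arrays, dataset.intensity_arrays):
        a, b = np.searchsorted(mz, lo, "left"), np.searchsorted(mz, hi, "right")
        if b > a:
            img[y, x] = it[a:b].sum()
    return img


def build_pixel_matrix(
    dataset: MSIDataset, reference_mzs: Sequence[float], tol_da: float = 0.001
) -> tuple[np.ndarray, list[int]]:
    """Pixel x feature matrix: column j is the ion image of reference j.

    Returns (matrix, zero_columns) where zero_columns flags references with
    no signal anywhere (e.g. outside the data range).
    """
    refs = list(reference_mzs)
    if not refs:
        raise MsiError("empty reference m/z list")
    n = dataset.n_pixels
    M = np.zeros((n, len(refs)))
    for j, target in enumerate(refs):
        lo, hi = target - tol_da, target + tol_da
        for i, (mz, it) in enumerate(zip(dataset.mz_arrays, dataset.intensity_arrays)):
            a, b = np.searchsorted(mz, lo, "left"), np.searchsorted(mz, hi, "right")
            if b > a:
                M[i, j] = it[a:b].sum()
    zero_cols = [j for j in range(len(refs)) if not M[:, j].any()]
    return M, zero_cols


# ---------------------------------------------------------------------------
# bisecting k-means segmentation

@dataclass
class SegmentationMap:
    """Cluster assignment per pixel plus the divisive split tree."""

    labels: np.ndarray  # length n_pixels, ids contiguous from 0
    split_tree: list[dict] = field(default_factory=list)

    def as_raster(self, dataset: MSIDataset) -> np.ndarray:
        h, w = dataset.shape()
        img = np.full((h, w), -1, dtype=int)
        for (x, y), lab in zip(dataset.coordinates, self.labels):
            img[y, x] = lab
        return img


def _cluster_sse(X: np.ndarray, idx: np.ndarray) -> float:
    sub = X[idx]
    return float(np.sum((sub - sub.mean(axis=0)) ** 2))


def bisecting_kmeans_segment(
    pixel_matrix: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int | None = None,
    metric: str = "cosine",
) -> SegmentationMap:
    """Divisive segmentation: repeatedly 2-means-split the cluster with the
    largest within-cluster SSE.

    With ``metric='cosine'`` rows are L2-normalized before each 2-means
    split (spherical geometry on TIC-normalized spectra); ``'euclidean'``
    splits raw rows. Deterministic under a fixed seed; each split records
    the within-cluster SSE before and after.
    """
    X = np.asarray(pixel_matrix, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise MsiError("k must be >= 1")
    if k > n:
        raise MsiError(f"k={k} exceeds number of pixels {n}")
    if metric not in ("cosine", "euclidean"):
        raise MsiError(f"unknown metric {metric!r}")

    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = np.where(norms > 0, X / np.where(norms == 0, 1.0, norms), 0.0) if metric == "cosine" else X

    labels = np.zeros(n, dtype=int)
    tree: list[dict] = []
    rng = np.random.default_rng(seed)
    next_id = 1
    while next_id < k:
        # pick the cluster with largest SSE that can still be split
        sses = {}
        for c in range(next_id):
            idx = np.flatnonzero(labels == c)
            if idx.size >= 2 and np.unique(Xn[idx], axis=0).shape[0] >= 2:
                sses[c] = _cluster_sse(Xn, idx)
        if not sses:
            break
        target = max(sses, key=sses.get)
        idx = np.flatnonzero(labels == target)
        km = KMeans(
            n_clusters=2,
            n_init=n_restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(Xn[idx])
        sub = km.labels_
        if np.unique(sub).size < 2:
            break
        labels[idx[sub == 1]] = next_id
        after = _cluster_sse(Xn, idx[sub == 0]) + _cluster_sse(Xn, idx[sub == 1])
        tree.append(
            {
                "split": target,
                "new_cluster": next_id,
                "sse_before": sses[target],
                "sse_after": after,
                "sizes": (int(np.sum(sub == 0)), int(np.sum(sub == 1))),
            }
        )
        next_id += 1
    return SegmentationMap(labels=labels, split_tree=tree)


def region_log2fc(
    pixel_matrix: np.ndarray,
    labels: Sequence[int],
    region_a: int,
    region_b: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature log2(mean intensity region_a / region_b).

    Returns (log2fc, flagged) where flagged marks features with a zero
    denominator (log2fc set to NaN there).
    """
    X = np.asarray(pixel_matrix, dtype=float)
    labels = np.asarray(labels)
    ia, ib = labels == region_a, labels == region_b
    if not ia.any() or not ib.any():
        raise MsiError(f"empty region: a={ia.sum()} pixels, b={ib.sum()} pixels")
    ma, mb = X[ia].mean(axis=0), X[ib].mean(axis=0)
    flagged = mb == 0
    out = np.full(X.shape[1], np.nan)
    ok = ~flagged & (ma > 0)
    out[ok] = np.log2(ma[ok] / mb[ok])
    out[~flagged & (ma == 0)] = -np.inf
    return out, flagged


def write_raster(raster: np.ndarray, path) -> None:
    """Plain-text raster (rows = y, tab-separated)."""
    np.savetxt(path, raster, fmt="%g", delimiter="\t")
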