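"""Chemometric transforms and supervised class-discrimination models.

Implements the multivariate toolchain used for two-class discrimination of
longitudinal metabolomics samples:

* autoscaling (column mean 0 / unit sample sd) and the generalized
  logarithm (g-log) variance-stabilizing transform;
* PCA (thin wrapper over scikit-learn, exposed for exploratory views);
* orthogonal PLS discriminant analysis (oPLS-DA): orthogonal-signal-
  correction components that capture class-uncorrelated variation are
  removed iteratively, then a single predictive PLS component is fit on
  the filtered matrix (Trygg-Wold style O-PLS);
* venetian-blind cross-validation: fold f holds every sample whose position
  in a fixed ordering (by convention the injection order) is congruent to
  f modulo the fold count;
* a label-permutation test on the between/within-class sum-of-squares
  ratio (B/W "group separation distance") of the predictive scores.

Class coding is TKO:+1, CTRL:-1 with decision threshold 0; an exact tie is
assigned CTRL so predictions are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA as _SkPCA


class ModelError(ValueError):
    pass


POS_LABEL = 1.0   # TKO
NEG_LABEL = -1.0  # CTRL


# ---------------------------------------------------------------------------
# transforms

def autoscale(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to unit sample sd.

    Zero-variance columns are set to 0 (scale recorded as 1) so they carry
    no weight downstream. Returns (scaled, means, scales).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ModelError("autoscale needs a 2-D matrix with >=2 rows")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, means, scales


def apply_scaling(matrix: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - means) / scales


def glog(matrix: np.ndarray, lam: float | None = None) -> np.ndarray:
    """Generalized logarithm log2((x + sqrt(x^2 + lambda)) / 2).

    Defaults lambda to the squared minimum positive value of the matrix;
    lambda = 0 reduces to plain log2.
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X[np.isfinite(X)] < 0):
        raise ModelError("g-log requires non-negative inputs")
    if lam is None:
        pos = X[np.isfinite(X) & (X > 0)]
        lam = float(pos.min()) ** 2 if pos.size else 1.0
    if lam < 0:
        raise ModelError("lambda must be non-negative")
    return np.log2((X + np.sqrt(X**2 + lam)) / 2.0)


def pca(matrix: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA scores, loadings and explained-variance fractions.

    Expects a centered (typically autoscaled) matrix; components beyond the
    matrix rank are truncated.
    """
    X = np.asarray(matrix, dtype=float)
    rank = min(X.shape)
    k = min(n_components, rank)
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.components_.T, model.explained_variance_ratio_


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) - the predictive engine under oPLS-DA and the GA fitness

def pls1_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> dict:
    """Single-y NIPALS PLS with deflation; returns weights/loadings.

    X should be scaled, y is centered internally (intercept stored).
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    intercept = y.mean()
    y = y - intercept
    n, p = X.shape
    k = min(n_components, p, max(n - 1, 1))
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros(k)
    for a in range(k):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            k = a
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-14:
            k = a
            break
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X -= np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], Q[a] = w, p_a, q_a
    return {"W": W[:, :k], "P": P[:, :k], "Q": Q[:k], "intercept": intercept, "n_components": k}


def pls1_coefficients(model: dict, n_components: int | None = None) -> np.ndarray:
    """Regression vector b with y_hat = intercept + X b."""
    k = model["n_components"] if n_components is None else min(n_components, model["n_components"])
    if k == 0:
        return np.zeros(model["W"].shape[0])
    W, P, Q = model["W"][:, :k], model["P"][:, :k], model["Q"][:k]
    return W @ np.linalg.solve(P.T @ W, Q)


def pls1_predict(model: dict, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    return model["intercept"] + np.asarray(X, dtype=float) @ pls1_coefficients(model, n_components)


# ---------------------------------------------------------------------------
# oPLS-DA

@dataclass
class OplsModel:
    """Fitted oPLS-DA model: orthogonal filter + one predictive component."""

    means: np.ndarray
    scales: np.ndarray
    w_orth: list[np.ndarray] = field(default_factory=list)
    p_orth: list[np.ndarray] = field(default_factory=list)
    t_orth: list[np.ndarray] = field(default_factory=list)
    w_pred: np.ndarray | None = None
    p_pred: np.ndarray | None = None
    q_pred: float = 0.0
    t_pred: np.ndarray | None = None
    intercept: float = 0.0
    n_orth: int = 0

    def filter_orthogonal(self, X: np.ndarray) -> np.ndarray:
        """Remove the stored y-orthogonal variation from (scaled) X."""
        Xf = np.asarray(X, dtype=float).copy()
        for w_o, p_o in zip(self.w_orth, self.p_orth):
            t_o = Xf @ w_o
            Xf -= np.outer(t_o, p_o)
        return Xf

    def predictive_scores(self, X_scaled: np.ndarray) -> np.ndarray:
        return self.filter_orthogonal(X_scaled) @ self.w_pred


def opls_da_fit(X: np.ndarray, y: Sequence[float], n_orth: int = 1, scale: bool = True) -> OplsModel:
    """Fit oPLS-DA on X with +/-1 class labels.

    ``scale=True`` autoscales internally and stores means/scales for reuse
    on new data; pass ``scale=False`` for pre-scaled input. With
    ``n_orth=0`` predictions coincide exactly with 1-component PLS-DA.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ModelError("both classes must be present")
    if n_orth < 0:
        raise ModelError("n_orth must be >= 0")
    if scale:
        Xs, means, scales = autoscale(X)
    else:
        Xs = np.asarray(X, dtype=float).copy()
        means = np.zeros(Xs.shape[1])
        scales = np.ones(Xs.shape[1])
    model = OplsModel(means=means, scales=scales, n_orth=0)
    yc = y - y.mean()
    model.intercept = float(y.mean())

    Xf = Xs.copy()
    for _ in range(n_orth):
        w = Xf.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w  # part of the loading orthogonal to y-predictive weight
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf -= np.outer(t_o, p_o)
        model.w_orth.append(w_o)
        model.p_orth.append(p_o)
        model.t_orth.append(t_o)
        model.n_orth += 1

    # single predictive PLS component on the filtered matrix
    w = Xf.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-14:
        raise ModelError("y carries no covariance with X")
    w /= nw
    t = Xf @ w
    tt = t @ t
    model.w_pred = w
    model.p_pred = Xf.T @ t / tt
    model.q_pred = float(yc @ t / tt)
    model.t_pred = t
    return model


def opls_da_predict(model: OplsModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted continuous y and class labels (+1 TKO / -1 CTRL).

    Exact ties at the 0 threshold are assigned CTRL.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.means.size:
        raise ModelError(
            f"feature mismatch: model has {model.means.size}, input has {X_new.shape[1]}"
        )
    Xs = apply_scaling(X_new, model.means, model.scales)
    t = model.predictive_scores(Xs)
    y_hat = model.intercept + model.q_pred * t
    classes = np.where(y_hat > 0, POS_LABEL, NEG_LABEL)
    return y_hat, classes


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CvReport:
    sensitivity: float
    specificity: float
    accuracy: float
    rmsecv: float
    n_folds: int
    y_true: np.ndarray
    y_pred: np.ndarray
    y_hat: np.ndarray
    sample_order: np.ndarray


def venetian_blind_folds(n_samples: int, n_folds: int) -> list[np.ndarray]:
    """Fold f = samples at positions congruent to f mod n_folds."""
    if n_folds < 2 or n_folds > n_samples:
        raise ModelError(f"n_folds must be in [2, n]; got {n_folds} for n={n_samples}")
    pos = np.arange(n_samples)
    return [pos[pos % n_folds == f] for f in range(n_folds)]


def venetian_blind_cv(
    X: np.ndarray,
    y: Sequence[float],
    n_orth: int = 1,
    n_folds: int = 10,
    order: Sequence[int] | None = None,
) -> CvReport:
    """Venetian-blind cross-validated oPLS-DA metrics.

    ``order`` fixes the sample ordering the blinds are cut from (use the
    injection order); defaults to the given row order. Scaling is refit
    inside each training fold to avoid leakage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    order = np.arange(n) if order is None else np.asarray(order, dtype=int)
    Xo, yo = X[order], y[order]
    folds = venetian_blind_folds(n, n_folds)
    y_hat = np.full(n, np.nan)
    y_pred = np.full(n, np.nan)
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        if np.unique(yo[train]).size < 2:
            raise ModelError(
                "a training split contains a single class; reorder samples or reduce folds"
            )
        model = opls_da_fit(Xo[train], yo[train], n_orth=n_orth, scale=True)
        yh, yp = opls_da_predict(model, Xo[f])
        y_hat[f] = yh
        y_pred[f] = yp
    tp = np.sum((yo == POS_LABEL) & (y_pred == POS_LABEL))
    fn = np.sum((yo == POS_LABEL) & (y_pred == NEG_LABEL))
    tn = np.sum((yo == NEG_LABEL) & (y_pred == NEG_LABEL))
    fp = np.sum((yo == NEG_LABEL) & (y_pred == POS_LABEL))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n
    rmsecv = float(np.sqrt(np.mean((yo - y_hat) ** 2)))
    return CvReport(
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float(acc),
        rmsecv=rmsecv,
        n_folds=n_folds,
        y_true=yo,
        y_pred=y_pred,
        y_hat=y_hat,
        sample_order=order,
    )


def pls_rmsecv(
    X: np.ndarray,
    y: Sequence[float],
    max_components: int = 3,
    n_folds: int = 10,
) -> float:
    """Minimum venetian-blind RMSECV of PLS1 over 1..max_components.

    This is the GA fitness. An empty feature set scores +inf; the
    intercept-only predictor bounds the useful range from above.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if X.shape[1] == 0:
        return float("inf")
    n_folds = min(n_folds, n)
    folds = venetian_blind_folds(n, n_folds)
    press = np.zeros(max_components)
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        Xs, means, scales = autoscale(X[train])
        model = pls1_fit(Xs, y[train], max_components)
        Xt = apply_scaling(X[f], means, scales)
        for k in range(1, max_components + 1):
            yh = pls1_predict(model, Xt, n_components=k)
            press[k - 1] += np.sum((y[f] - yh) ** 2)
    return float(np.sqrt(press.min() / n))


# ---------------------------------------------------------------------------
# permutation test

def separation_statistic(scores: np.ndarray, y: Sequence[float]) -> float:
    """Between/within-class sum-of-squares ratio of 1-D model scores."""
    t = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    grand = t.mean()
    between = 0.0
    within = 0.0
    for c in np.unique(y):
        tc = t[y == c]
        between += tc.size * (tc.mean() - grand) ** 2
        within += np.sum((tc - tc.mean()) ** 2)
    if within == 0:
        return float("inf")
    return float(between / within)


def permutation_test(
    X: np.ndarray,
    y: Sequence[float],
    n_orth: int = 1,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation test of oPLS-DA group separation.

    The statistic is B/W of the predictive scores of a model refit on the
    given labels; p = (1 + #{permuted >= observed}) / (1 + n_perm). Label
    permutation preserves class counts by construction.
    """
    if n_perm < 1:
        raise ModelError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def _stat(labels: np.ndarray) -> float:
        model = opls_da_fit(X, labels, n_orth=n_orth, scale=True)
        return separation_statistic(model.t_pred, labels)

    observed = _stat(y)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _stat(rng.permutation(y))
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return observed, float(p), null
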