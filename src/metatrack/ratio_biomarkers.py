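"""Pairwise metabolite-ratio biomarker screening.

Every unordered feature pair yields one ratio variable (computed per sample
on raw post-QC abundances, numerator/denominator in lexicographic feature-id
order). The ratio matrix is g-log transformed and autoscaled, ranked by
Welch p-value, and the top ratios are evaluated with a stratified 10-fold
cross-validated univariate logistic regression: pooled out-of-fold
probabilities give the ROC AUC, sensitivity and specificity at the
Youden-optimal pooled threshold, and percentile-bootstrap 95% confidence
intervals.

Reported orientation is normalized so AUC >= 0.5 (inverting a ratio maps
AUC to 1 - AUC and flips the sign of the Welch t on log values).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .chemometrics import glog
from .univariate import StatsError, welch_t


class RatioError(ValueError):
    pass


@dataclass
class RatioBiomarker:
    numerator: str
    denominator: str
    p: float
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    sensitivity: float = float("nan")
    sensitivity_ci: tuple[float, float] = (float("nan"), float("nan"))
    specificity: float = float("nan")
    specificity_ci: tuple[float, float] = (float("nan"), float("nan"))
    degenerate: bool = False

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def all_pair_ratios(
    values: np.ndarray, feature_ids: list[str]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Ratio matrix over all C(p, 2) unordered feature pairs.

    ``values`` is features x samples. Pairs are oriented lexicographically
    by feature id; entries with zero or missing denominator are NaN.
    """
    if len(feature_ids) < 2:
        raise RatioError("need at least 2 features to form ratios")
    order = np.argsort(np.asarray(feature_ids, dtype=object))
    V = np.asarray(values, dtype=float)
    pairs = []
    rows = []
    for i, j in itertools.combinations(order, 2):
        num, den = V[i], V[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        r[~np.isfinite(r)] = np.nan
        r[den == 0] = np.nan
        rows.append(r)
        pairs.append((feature_ids[i], feature_ids[j]))
    return np.array(rows), pairs


def rank_ratios(
    ratio_values: np.ndarray,
    pairs: list[tuple[str, str]],
    labels: np.ndarray,
    top_k: int = 20,
) -> list[RatioBiomarker]:
    """g-log + autoscale the ratio matrix, Welch-test each ratio, return the
    top_k by ascending p-value."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise RatioError("both classes must be present")
    R = np.asarray(ratio_values, dtype=float)
    G = glog(np.where(np.isfinite(R), R, np.nan))
    # autoscaling each ratio is affine per variable, so the Welch t (and the
    # ranking) is unchanged; the transform matters only for the logistic step
    out = []
    for k, (num, den) in enumerate(pairs):
        col = G[k]
        try:
            _, _, p = welch_t(col[y == 1], col[y == -1])
        except StatsError:
            p = float("nan")
        out.append(RatioBiomarker(numerator=num, denominator=den, p=p))
    out.sort(key=lambda b: (np.isnan(b.p), b.p))
    return out[: min(top_k, len(out))]


def cv_logistic_eval(
    ratio_values: np.ndarray,
    labels: np.ndarray,
    biomarker: RatioBiomarker | None = None,
    n_folds: int = 10,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RatioBiomarker:
    """Cross-validated logistic evaluation of a single ratio variable.

    ``ratio_values`` is the per-sample raw ratio; it is g-log transformed
    and autoscaled, a univariate logistic regression is fit under
    stratified ``n_folds``-fold CV, and metrics are computed from pooled
    out-of-fold probabilities. Sensitivity/specificity are read at the
    Youden-optimal threshold of the pooled ROC; CIs are percentile
    bootstrap over samples.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise RatioError("both classes must be present")
    r = np.asarray(ratio_values, dtype=float)
    ok = np.isfinite(r)
    r, y = r[ok], y[ok]
    n = r.size
    if n < n_folds:
        raise RatioError(f"need >= {n_folds} samples, got {n}")
    out = biomarker or RatioBiomarker(numerator="num", denominator="den", p=float("nan"))

    g = glog(r[None, :]).ravel()
    if np.std(g) == 0:
        out.auc, out.sensitivity, out.specificity = 0.5, float("nan"), float("nan")
        out.degenerate = True
        return out
    x = ((g - g.mean()) / g.std(ddof=1)).reshape(-1, 1)
    ybin = (y == 1).astype(int)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = np.full(n, np.nan)
    for train, test in skf.split(x, ybin):
        clf = LogisticRegression(C=1e6, solver="lbfgs")
        clf.fit(x[train], ybin[train])
        proba[test] = clf.predict_proba(x[test])[:, 1]

    auc = roc_auc_score(ybin, proba)
    if auc < 0.5:  # report the orientation with AUC >= 0.5
        proba = 1.0 - proba
        auc = 1.0 - auc
        out.numerator, out.denominator = out.denominator, out.numerator
    fpr, tpr, thr = roc_curve(ybin, proba)
    youden = int(np.argmax(tpr - fpr))
    threshold = thr[youden]
    pred = proba >= threshold
    sens = np.mean(pred[ybin == 1])
    spec = np.mean(~pred[ybin == 0])

    out.auc = float(auc)
    out.sensitivity = float(sens)
    out.specificity = float(spec)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        aucs, senss, specs = [], [], []
        for _ in range(n_boot):
            idx = rng.integers(n, size=n)
            yb, pb = ybin[idx], proba[idx]
            if yb.min() == yb.max():
                continue
            aucs.append(roc_auc_score(yb, pb))
            pr = pb >= threshold
            senss.append(np.mean(pr[yb == 1]))
            specs.append(np.mean(~pr[yb == 0]))

        def _ci(v):
            return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

        out.auc_ci = _ci(aucs)
        out.sensitivity_ci = _ci(senss)
        out.specificity_ci = _ci(specs)
    return out
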