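"""Sparse partial least squares-discriminant analysis from first
principles.

PLS-DA regresses a dummy-coded class matrix Y on the (centered,
unit-variance scaled) feature matrix X by NIPALS-style alternating
iteration; sparsity is obtained by soft-thresholding each X-loading so
that exactly ``keepX`` features stay nonzero per component, after which
X and Y are deflated by regression on the component score. New samples
are classified by the nearest class centroid (Euclidean distance in
score space).

Tuning selects the number of features per component by forward,
one-component-at-a-time minimization of the balanced error rate (BER,
the unweighted mean of per-class misclassification rates) under repeated
stratified k-fold cross-validation; evaluation reports mean and standard
deviation of the overall and per-class BER over repeats together with
per-feature selection frequencies (stability).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import AlignmentError, ParameterError

__all__ = [
    "SplsdaModel",
    "CvPerformance",
    "fit_splsda",
    "predict_splsda",
    "tune_splsda",
    "evaluate_splsda",
    "balanced_error_rate",
]

logger = logging.getLogger(__name__)

_MAX_ITER = 500
_TOL = 1e-9


@dataclass
class SplsdaModel:
    """A fitted sparse PLS-DA model."""

    classes: np.ndarray                 # sorted unique class labels
    feature_names: np.ndarray           # features kept (nonzero variance)
    x_mean: np.ndarray
    x_scale: np.ndarray
    keepX: list[int]
    x_weights: np.ndarray               # p x H sparse weight vectors (unit norm)
    x_loadings: np.ndarray              # p x H regression loadings for deflation
    scores: np.ndarray                  # n x H training scores
    y_classes: np.ndarray               # training labels
    centroids: np.ndarray               # K x H class centroids in score space
    explained_variance: np.ndarray      # per-component fraction of X variance

    @property
    def ncomp(self) -> int:
        return self.x_weights.shape[1]

    def selected(self, component: int) -> np.ndarray:
        """Names of the features with nonzero weight on a component."""
        return self.feature_names[self.x_weights[:, component] != 0]


@dataclass
class CvPerformance:
    """Cross-validated classification performance and selection stability."""

    overall_ber: tuple[float, float]                 # mean, sd over repeats
    per_class_ber: dict                              # class -> (mean, sd)
    stability: pd.DataFrame                          # feature x component freq
    n_repeats: int
    n_folds: int

    def stable_features(self, threshold: float = 0.9) -> pd.DataFrame:
        mask = (self.stability > threshold).any(axis=1)
        return self.stability.loc[mask]


def _as_matrix(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), np.asarray(X.columns, dtype=object)
    X = np.asarray(X, dtype=float)
    return X, np.array([f"x{i}" for i in range(X.shape[1])], dtype=object)


def _soft_threshold_keep(a: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold at the (keep+1)-th largest magnitude so exactly
    ``keep`` entries stay nonzero; ties broken by feature order."""
    p = a.size
    if keep >= p:
        return a.copy()
    order = np.argsort(-np.abs(a), kind="stable")
    selected = order[:keep]
    lam = np.abs(a[order[keep]])
    out = np.zeros_like(a)
    out[selected] = np.sign(a[selected]) * np.maximum(np.abs(a[selected]) - lam, 0.0)
    # ties at the threshold would zero a selected entry; keep determinism
    # by nudging exact ties to a minimal positive magnitude
    dead = selected[out[selected] == 0.0]
    if dead.size:
        out[dead] = np.sign(a[dead]) * (np.abs(a[dead]) * 1e-12 + 1e-300)
    return out


def fit_splsda(X, classes: Sequence, ncomp: int = 2,
               keepX: Sequence[int] | int | None = None,
               scale: bool = True) -> SplsdaModel:
    """Fit a sparse PLS-DA model.

    ``keepX`` gives the number of features retained per component (a
    scalar is broadcast; ``None`` keeps all, i.e. dense PLS-DA).
    Zero-variance features are dropped with a warning.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(classes)
    if Xm.shape[0] != y.shape[0]:
        raise AlignmentError("X rows and class labels differ in length")
    if ncomp < 1:
        raise ParameterError("ncomp must be >= 1")
    labels = np.unique(y)
    if labels.size < 2:
        raise ParameterError("need at least two classes")

    x_mean = Xm.mean(axis=0)
    x_sd = Xm.std(axis=0, ddof=1)
    keep_feat = x_sd > 0
    if not keep_feat.all():
        logger.warning("dropping %d zero-variance feature(s)",
                       int((~keep_feat).sum()))
        Xm, names, x_mean, x_sd = (Xm[:, keep_feat], names[keep_feat],
                                   x_mean[keep_feat], x_sd[keep_feat])
    p = Xm.shape[1]
    if p == 0:
        raise ParameterError("no features with nonzero variance")
    x_scale = x_sd if scale else np.ones(p)
    Xc = (Xm - x_mean) / x_scale

    if keepX is None:
        keep_list = [p] * ncomp
    elif np.isscalar(keepX):
        keep_list = [int(keepX)] * ncomp
    else:
        keep_list = [int(k) for k in keepX]
        if len(keep_list) < ncomp:
            raise ParameterError("keepX shorter than ncomp")
        keep_list = keep_list[:ncomp]
    if any(k < 1 or k > p for k in keep_list):
        raise ParameterError(f"keepX entries must lie in 1..{p}")

    # dummy-coded, centered and scaled class matrix
    Y = (y[:, None] == labels[None, :]).astype(float)
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)

    total_var = float((Xc**2).sum())
    n = Xc.shape[0]
    Xd, Yd = Xc.copy(), Y.copy()
    Wmat = np.zeros((p, ncomp))
    Pmat = np.zeros((p, ncomp))
    Tmat = np.zeros((n, ncomp))
    ev = np.zeros(ncomp)
    for h in range(ncomp):
        M = Xd.T @ Yd                       # p x K cross-covariance
        # initialize from the dominant column of M
        v = np.zeros(M.shape[1])
        v[int(np.argmax((M**2).sum(axis=0)))] = 1.0
        a = np.zeros(p)
        for _ in range(_MAX_ITER):
            a_new = M @ v
            norm = np.linalg.norm(a_new)
            if norm == 0:
                break
            a_new = _soft_threshold_keep(a_new, keep_list[h])
            a_new /= np.linalg.norm(a_new)
            v_new = M.T @ a_new
            nv = np.linalg.norm(v_new)
            if nv == 0:
                break
            v_new /= nv
            if (np.linalg.norm(a_new - a) < _TOL
                    and np.linalg.norm(v_new - v) < _TOL):
                a, v = a_new, v_new
                break
            a, v = a_new, v_new
        t = Xd @ a
        tt = float(t @ t)
        if tt == 0:
            warnings.warn(f"component {h + 1} degenerate; truncating model")
            Wmat, Pmat, Tmat, ev = (Wmat[:, :h], Pmat[:, :h], Tmat[:, :h], ev[:h])
            keep_list = keep_list[:h]
            break
        pvec = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, (Yd.T @ t) / tt)   # regression-mode deflation
        Wmat[:, h], Pmat[:, h], Tmat[:, h] = a, pvec, t
        ev[h] = tt * float(pvec @ pvec) / total_var if total_var > 0 else 0.0

    if Tmat.shape[1] == 0:
        raise ParameterError("model has no non-degenerate component")
    centroids = np.stack([Tmat[y == lab].mean(axis=0) for lab in labels])
    return SplsdaModel(labels, names, x_mean, x_scale, keep_list, Wmat, Pmat,
                       Tmat, y, centroids, ev)


def transform_splsda(m: SplsdaModel, Xnew) -> np.ndarray:
    """Score coordinates of new samples under the training fit."""
    Xm, names = _as_matrix(Xnew)
    if isinstance(Xnew, pd.DataFrame):
        if list(names) != list(m.feature_names):
            try:
                Xm = Xnew[list(m.feature_names)].to_numpy(dtype=float)
            except KeyError as exc:
                raise AlignmentError("features of new data do not match "
                                     "training features") from exc
    elif Xm.shape[1] != m.feature_names.size:
        raise AlignmentError("feature count mismatch with training data")
    Xd = (Xm - m.x_mean) / m.x_scale
    T = np.zeros((Xd.shape[0], m.ncomp))
    for h in range(m.ncomp):
        T[:, h] = Xd @ m.x_weights[:, h]
        Xd = Xd - np.outer(T[:, h], m.x_loadings[:, h])
    return T


def predict_splsda(m: SplsdaModel, Xnew) -> np.ndarray:
    """Nearest-centroid class prediction; ties go to the
    lexicographically smallest class label."""
    T = transform_splsda(m, Xnew)
    d2 = ((T[:, None, :] - m.centroids[None, :, :]) ** 2).sum(axis=2)
    # classes are sorted, so argmin's first-hit rule is the lexicographic
    # tie-break
    return m.classes[np.argmin(d2, axis=1)]


def balanced_error_rate(truth: np.ndarray, predicted: np.ndarray,
                        classes: np.ndarray | None = None) -> float:
    """Unweighted mean of per-class misclassification rates."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if classes is None:
        classes = np.unique(truth)
    rates = []
    for lab in classes:
        mask = truth == lab
        if mask.any():
            rates.append(float((predicted[mask] != lab).mean()))
    if not rates:
        raise ParameterError("no class present in the truth labels")
    return float(np.mean(rates))


def _cv_ber(X: np.ndarray, y: np.ndarray, ncomp: int, keepX: Sequence[int],
            folds: int, repeats: int, rng: np.random.Generator,
            scale: bool, collect: list | None = None) -> np.ndarray:
    """Overall BER per repeat of stratified k-fold CV; optionally collects
    (per-class errors, selected-feature masks) for evaluation."""
    classes = np.unique(y)
    bers = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        pred = np.empty(y.shape, dtype=y.dtype)
        done = np.zeros(y.shape, dtype=bool)
        sel_masks = []
        for train, test in skf.split(X, y):
            if np.unique(y[train]).size < classes.size:
                warnings.warn("a class is absent from a training fold; "
                              "skipping the fold")
                continue
            m = fit_splsda(X[train], y[train], ncomp=ncomp, keepX=keepX,
                           scale=scale)
            pred[test] = predict_splsda(m, X[test])
            done[test] = True
            if collect is not None:
                full = np.zeros((X.shape[1], m.ncomp), dtype=bool)
                kept = np.isin(np.array([f"x{i}" for i in range(X.shape[1])],
                                        dtype=object), m.feature_names)
                full[kept, :] = m.x_weights != 0
                sel_masks.append(full)
        if not done.any():
            raise ParameterError("no fold could be evaluated")
        per_class = {lab: float((pred[done & (y == lab)] != lab).mean())
                     for lab in classes if (done & (y == lab)).any()}
        bers[r] = float(np.mean(list(per_class.values())))
        if collect is not None:
            collect.append((per_class, sel_masks))
    return bers


def tune_splsda(X, classes: Sequence, keepX_grid: Sequence[int],
                max_ncomp: int = 4, folds: int = 5, repeats: int = 10,
                seed: int | None = 0, scale: bool = True) -> dict:
    """Forward per-component selection of keepX by mean CV BER.

    For each component in turn (earlier components fixed) every grid
    value is scored by repeated stratified k-fold CV; the value with the
    smallest mean BER wins, ties going to the smaller keepX. Components
    are added while the best mean BER strictly improves, up to
    ``max_ncomp``. Returns ``{"ncomp", "keepX", "ber_path"}``.
    """
    grid = sorted({int(k) for k in keepX_grid})
    if not grid:
        raise ParameterError("empty keepX grid")
    Xm, _ = _as_matrix(X)
    y = np.asarray(classes)
    grid = [k for k in grid if 1 <= k <= Xm.shape[1]]
    if not grid:
        raise ParameterError("no grid value within 1..p")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    ber_path: list[float] = []
    best_prev = np.inf
    for h in range(max_ncomp):
        scores = []
        for k in grid:
            sub_rng = np.random.default_rng(rng.integers(2**31))
            bers = _cv_ber(Xm, y, ncomp=h + 1, keepX=chosen + [k], folds=folds,
                           repeats=repeats, rng=sub_rng, scale=scale)
            scores.append(float(bers.mean()))
        best_idx = int(np.argmin(scores))     # grid sorted -> smallest k wins ties
        best = scores[best_idx]
        if h > 0 and best >= best_prev:
            break
        chosen.append(grid[best_idx])
        ber_path.append(best)
        best_prev = best
        if best == 0.0:
            break
    return {"ncomp": len(chosen), "keepX": chosen, "ber_path": ber_path}


def evaluate_splsda(X, classes: Sequence, ncomp: int, keepX: Sequence[int],
                    folds: int = 5, repeats: int = 1000,
                    seed: int | None = 0, scale: bool = True) -> CvPerformance:
    """Repeated stratified k-fold CV performance of a fixed model.

    Stratification places 1/folds (20% at the default 5 folds) of each
    class in every validation set. Returns mean and sd of the overall and
    per-class BER over repeats and the per-feature selection frequency
    across all folds x repeats (stability).
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(classes)
    rng = np.random.default_rng(seed)
    collect: list = []
    bers = _cv_ber(Xm, y, ncomp=ncomp, keepX=keepX, folds=folds,
                   repeats=repeats, rng=rng, scale=scale, collect=collect)
    labels = np.unique(y)
    per_class = {}
    for lab in labels:
        vals = np.array([pc[lab] for pc, _ in collect if lab in pc])
        per_class[lab] = (float(vals.mean()), float(vals.std(ddof=0)))
    sel_counts = np.zeros((Xm.shape[1], ncomp))
    n_fits = 0
    for _, masks in collect:
        for mask in masks:
            sel_counts[:, :mask.shape[1]] += mask
            n_fits += 1
    stability = pd.DataFrame(sel_counts / max(n_fits, 1), index=names,
                             columns=[f"comp{h + 1}" for h in range(ncomp)])
    return CvPerformance((float(bers.mean()), float(bers.std(ddof=0))),
                         per_class, stability, repeats, folds)
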