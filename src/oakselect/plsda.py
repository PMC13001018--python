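"""Partial least squares discriminant analysis of leaf spectra (SIMPLS).

Populations are classified from band-resampled reflectance using PLSDA: the
class labels are one-hot coded, column-centered, and regressed on the
centered spectral matrix with the SIMPLS algorithm (de Jong 1993), which
extracts successive weight vectors maximizing covariance with the indicator
matrix under score orthogonality. Class posteriors follow Bayes' rule with
Gaussian class-conditional densities on the latent score space (pooled
covariance) and empirical class priors.

Model size (number of components) is chosen by bootstrap out-of-bag Cohen's
kappa across candidate sizes, taking the smallest size whose mean kappa sits
in the Tukey-HSD homogeneous group of the best mean (a parsimony "plateau"
rule). Influential wavelengths are ranked by the maximum absolute loading
across components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "PLSDAModel",
    "partition",
    "fit_simpls",
    "predict",
    "confusion_matrix",
    "kappa",
    "bootstrap_kappa",
    "select_ncomp",
    "top_loading_bands",
]


@dataclass
class PLSDAModel:
    """Fitted SIMPLS discriminant model.

    Attributes
    ----------
    weights : (p, ncomp) array
        SIMPLS weight vectors mapping centered predictors to scores.
    loadings : (p, ncomp) array
        Predictor loadings P = Xc^T T.
    classes : list of class labels (column order of the indicator matrix).
    priors : (k,) empirical class priors.
    x_mean : (p,) predictor column means.
    score_means : (k, ncomp) per-class mean in score space.
    score_cov : (ncomp, ncomp) pooled within-class score covariance.
    bands : (p,) training band grid (wavelengths), or None.
    """

    weights: np.ndarray
    loadings: np.ndarray
    classes: list
    priors: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray
    score_means: np.ndarray
    score_cov: np.ndarray
    bands: np.ndarray | None = None
    kept_columns: np.ndarray | None = None

    @property
    def ncomp(self) -> int:
        return self.weights.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kept_columns is not None:
            X = X[:, self.kept_columns]
        return (X - self.x_mean) @ self.weights


def partition(ids, labels, mode: str, value, seed: int):
    """Stratified train/test split of sample ids.

    ``mode='fraction'``: take ``value`` (0-1) of each class for training,
    rounding to the nearest count. ``mode='per_class_count'``: take exactly
    ``value`` samples from each class for training. Reproducible by seed.
    """
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels lengths differ")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for i, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(i)
    train, test = [], []
    for lab in sorted(by_class, key=str):
        members = by_class[lab]
        if mode == "fraction":
            if not 0 < value < 1:
                raise ValueError("fraction must be in (0, 1)")
            n_train = int(round(value * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1) if len(members) > 1 else n_train
        elif mode == "per_class_count":
            n_train = int(value)
            if n_train > len(members):
                raise ValueError(
                    f"class {lab!r} has {len(members)} members < requested {n_train}"
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        perm = rng.permutation(len(members))
        train.extend(members[j] for j in perm[:n_train])
        test.extend(members[j] for j in perm[n_train:])
    return train, test


def _one_hot(labels, classes=None):
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(set(labels.tolist()), key=str)
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, list(classes)


def fit_simpls(X, labels, ncomp: int, bands=None) -> PLSDAModel:
    """Fit a SIMPLS PLSDA model of the one-hot class indicator on X.

    Constant predictor columns are dropped with a warning. ``ncomp`` may not
    exceed the rank of the centered predictor matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x bands)")
    Y, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape

    col_sd = X.std(axis=0)
    kept = None
    if np.any(col_sd == 0):
        warnings.warn(
            f"dropping {int((col_sd == 0).sum())} constant predictor column(s)",
            stacklevel=2,
        )
        kept = np.flatnonzero(col_sd > 0)
        X = X[:, kept]
        if bands is not None:
            bands = np.asarray(bands)[kept]
        p = X.shape[1]

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if ncomp < 1 or ncomp > rank:
        raise ValueError(f"ncomp={ncomp} outside [1, rank={rank}]")

    # de Jong's SIMPLS: deflate the cross-product matrix, not X
    S = Xc.T @ Yc
    R = np.zeros((p, ncomp))  # weights
    T = np.zeros((n, ncomp))  # scores
    P = np.zeros((p, ncomp))  # x-loadings
    Q = np.zeros((Y.shape[1], ncomp))  # y-loadings
    V = np.zeros((p, ncomp))  # orthonormal basis of P for deflation
    for a in range(ncomp):
        u, sv, vt = linalg.svd(S, full_matrices=False)
        r = u[:, 0]
        t = Xc @ r
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise np.linalg.LinAlgError("degenerate SIMPLS direction")
        t /= normt
        r /= normt
        pvec = Xc.T @ t
        q = Yc.T @ t
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, pvec, q, v

    scores = Xc @ R
    counts = Y.sum(axis=0)
    priors = counts / counts.sum()
    k = len(classes)
    lab_arr = np.asarray(labels)
    means = np.vstack([scores[lab_arr == c].mean(axis=0) for c in classes])
    class_idx = np.array([classes.index(l) for l in lab_arr.tolist()])
    resid = scores - means[class_idx]
    dof = max(n - k, 1)
    cov = resid.T @ resid / dof
    cov += 1e-10 * np.eye(ncomp) * max(np.trace(cov) / ncomp, 1e-12)

    return PLSDAModel(
        weights=R,
        loadings=P,
        classes=classes,
        priors=priors,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=R @ Q.T,
        score_means=means,
        score_cov=cov,
        bands=None if bands is None else np.asarray(bands, dtype=float),
        kept_columns=kept,
    )


def predict(model: PLSDAModel, X, bands=None):
    """Predict class labels and Bayes posteriors for new samples.

    Posteriors come from Gaussian class-conditional densities on the
    ncomp-dimensional score space with pooled covariance and the stored
    empirical priors. Returns ``(labels, posteriors)`` where posteriors is a
    DataFrame with one column per class, rows summing to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if bands is not None and model.bands is not None:
        bands = np.asarray(bands, dtype=float)
        if bands.shape != model.bands.shape or not np.allclose(bands, model.bands):
            raise ValueError("band grid does not match training grid")
    if model.kept_columns is None and X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} bands, got {X.shape[1]}"
        )
    scores = model.transform(X)
    cov_inv = np.linalg.inv(model.score_cov)
    _, logdet = np.linalg.slogdet(model.score_cov)
    loglik = np.empty((X.shape[0], len(model.classes)))
    for j in range(len(model.classes)):
        d = scores - model.score_means[j]
        maha = np.einsum("ij,jk,ik->i", d, cov_inv, d)
        loglik[:, j] = -0.5 * (maha + logdet) + np.log(model.priors[j])
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    post /= post.sum(axis=1, keepdims=True)
    labels = [model.classes[j] for j in post.argmax(axis=1)]
    return labels, pd.DataFrame(post, columns=[str(c) for c in model.classes])


def confusion_matrix(true_labels, pred_labels, classes=None) -> pd.DataFrame:
    """Predicted (rows) x true (columns) count matrix."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if classes is None:
        classes = sorted(set(true_labels) | set(pred_labels), key=str)
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        cm.loc[p, t] += 1
    return cm


def kappa(cm) -> float:
    """Cohen's kappa (p_o - p_e)/(1 - p_e) from a confusion matrix."""
    arr = np.asarray(cm, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(arr) / total
    p_e = float((arr.sum(axis=1) / total) @ (arr.sum(axis=0) / total))
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0",
                      stacklevel=2)
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def bootstrap_kappa(X, labels, ncomp: int, n_boot: int, seed: int) -> np.ndarray:
    """Out-of-bag kappa over stratified bootstrap resamples at fixed ncomp."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = sorted(set(labels.tolist()), key=str)
    idx_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    out = np.full(n_boot, np.nan)
    for b in range(n_boot):
        in_bag = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True)
             for idx in idx_by_class.values()]
        )
        oob = np.setdiff1d(np.arange(labels.size), np.unique(in_bag))
        if oob.size == 0 or len(set(labels[oob].tolist())) < 2:
            continue
        try:
            m = fit_simpls(X[in_bag], labels[in_bag], ncomp)
            pred, _ = predict(m, X[oob])
        except (ValueError, np.linalg.LinAlgError):
            continue
        out[b] = kappa(confusion_matrix(labels[oob], pred, classes))
    return out[~np.isnan(out)]


def select_ncomp(
    X, labels, max_comp: int, n_boot: int = 200, alpha: float = 0.05,
    seed: int = 0
) -> int:
    """Choose the number of SIMPLS components by the kappa-plateau rule.

    For each candidate size, ``n_boot`` stratified bootstrap refits score
    out-of-bag kappa; Tukey's HSD compares the kappa distributions and the
    smallest size not significantly below the best mean (at ``alpha``) is
    returned — the parsimonious end of the maximal plateau.
    """
    if max_comp < 1:
        raise ValueError("max_comp must be >= 1")
    if max_comp == 1:
        return 1
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    groups = []
    sizes = list(range(1, max_comp + 1))
    for i, nc in enumerate(sizes):
        ks = bootstrap_kappa(X, labels, nc, n_boot, seed=seed + 1000 * i)
        if ks.size < 2:
            raise ValueError(f"degenerate bootstrap kappas at ncomp={nc}")
        groups.append(ks)
    means = np.array([g.mean() for g in groups])
    if np.allclose(means, means[0]) and all(
        np.allclose(g, g.mean()) for g in groups
    ):
        raise ValueError("all bootstrap kappas degenerate")
    best = int(np.argmax(means))
    res = stats.tukey_hsd(*groups)
    for i, nc in enumerate(sizes):
        if i == best or res.pvalue[i, best] > alpha:
            return nc
    return sizes[best]


def top_loading_bands(model: PLSDAModel, k: int) -> pd.DataFrame:
    """Rank bands by maximum absolute loading across components; top k.

    Returns a DataFrame with columns ``band`` (wavelength, or column index
    if the model carries no band grid) and ``loading`` (the max-|loading|),
    sorted descending.
    """
    p = model.loadings.shape[0]
    if k > p:
        raise ValueError(f"k={k} exceeds number of bands {p}")
    score = np.abs(model.loadings).max(axis=1)
    order = np.argsort(-score)[:k]
    bands = (
        model.bands[order]
        if model.bands is not None
        else order.astype(float)
    )
    return pd.DataFrame({"band": bands, "loading": score[order]})
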