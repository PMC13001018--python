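"""Two-node life-history fitness model: survival, then height given survival.

Lifetime fitness is modeled with a minimal life-history graph of two
dependent components: two-year survival (Bernoulli, logit link) and final
height conditional on survival (normal, identity link). The joint likelihood

    L = prod_i Bern(s_i; p_i) * [N(h_i; mu_i, sigma^2)]^{s_i}

is maximized jointly over the coefficients of both nodes by Newton-Raphson
on the full parameter vector. Predictors at both nodes are maternal family,
height at initial planting, and garden block, all fixed effects (reference
coding, first level baseline). Because the two nodes have disjoint
parameters the joint MLE coincides with the two-stage fit (logistic
regression on survival; least squares on survivors' heights), which serves
as an independent oracle in the test-suite.

Expected fitness per individual is the unconditional mean of the terminal
node, W_hat = p_hat * mu_hat (cm) — individuals observed dead still receive
a model-based expected fitness so that downstream selection analysis
accounts for mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitnessModel",
    "fit_fitness_model",
    "predict_fitness",
    "block_omnibus_test",
]


@dataclass
class FitnessModel:
    """Fitted two-node fitness model (shared design at both nodes)."""

    surv_coef: np.ndarray      # logit scale
    height_coef: np.ndarray    # cm
    sigma2: float              # residual variance of the height node (MLE)
    loglik: float
    columns: list[str]
    family_levels: list | None
    block_levels: list | None
    include_family: bool
    include_init_height: bool
    include_block: bool
    all_survived: bool = False
    n: int = 0

    @property
    def n_params(self) -> int:
        return 2 * len(self.columns) + (0 if self.all_survived else 0) + 1


def _build_design(records: pd.DataFrame, include_family, include_init_height,
                  include_block, family_levels=None, block_levels=None):
    cols = ["intercept"]
    X = [np.ones(len(records))]
    if include_family:
        if family_levels is None:
            family_levels = sorted(records["family"].astype(str).unique())
        fam = records["family"].astype(str)
        unseen = set(fam) - set(family_levels)
        if unseen:
            raise ValueError(f"unseen family level(s): {sorted(unseen)}")
        for lv in family_levels[1:]:
            X.append((fam == lv).to_numpy(float))
            cols.append(f"family[{lv}]")
    if include_init_height:
        X.append(records["height_init"].to_numpy(float))
        cols.append("height_init")
    if include_block:
        if block_levels is None:
            block_levels = sorted(records["block"].astype(str).unique())
        blk = records["block"].astype(str)
        unseen = set(blk) - set(block_levels)
        if unseen:
            raise ValueError(f"unseen block level(s): {sorted(unseen)}")
        for lv in block_levels[1:]:
            X.append((blk == lv).to_numpy(float))
            cols.append(f"block[{lv}]")
    return np.column_stack(X), cols, family_levels, block_levels


def _check_rank(X, cols):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name columns whose removal restores full column rank
        aliased = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == r:
                aliased.append(cols[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def _joint_nll_grad_hess(theta, X, surv, h):
    """Joint negative log-likelihood, gradient and Hessian.

    theta = [a (survival, logit), c (height mean), log sigma]. The height
    terms involve survivors only; the Hessian is block diagonal across
    nodes because the parameters are disjoint.
    """
    k = X.shape[1]
    a, c, logs = theta[:k], theta[k:2 * k], theta[-1]
    s2 = np.exp(2 * logs)
    eta = X @ a
    p = 1.0 / (1.0 + np.exp(-eta))
    # survival node
    nll = -np.sum(surv * eta - np.log1p(np.exp(eta)))
    g_a = -X.T @ (surv - p)
    w = p * (1 - p)
    H_aa = (X * w[:, None]).T @ X
    # height node over survivors
    m = surv.astype(bool)
    Xs, hs = X[m], h[m]
    resid = hs - Xs @ c
    ns = int(m.sum())
    nll += 0.5 * np.sum(resid**2) / s2 + ns * logs + 0.5 * ns * np.log(2 * np.pi)
    g_c = -Xs.T @ resid / s2
    g_s = -np.sum(resid**2) / s2 + ns
    H_cc = Xs.T @ Xs / s2
    H_cs = 2.0 * Xs.T @ resid / s2
    H_ss = 2.0 * np.sum(resid**2) / s2
    grad = np.concatenate([g_a, g_c, [g_s]])
    H = np.zeros((2 * k + 1, 2 * k + 1))
    H[:k, :k] = H_aa
    H[k:2 * k, k:2 * k] = H_cc
    H[k:2 * k, -1] = H[-1, k:2 * k] = H_cs
    H[-1, -1] = H_ss
    return nll, grad, H


def _raise_if_separated(a, X, surv):
    """Detect (quasi-)complete separation: saturated fitted probabilities."""
    eta = X @ a
    alive = surv.astype(bool)
    # perfect separation: the fitted linear predictor orders the outcomes
    # (a separated likelihood has no stationary point, so this is only
    # checked when Newton failed to converge)
    separated = (alive.any() and (~alive).any()
                 and eta[alive].min() >= eta[~alive].max() - 1e-8)
    if separated or np.linalg.norm(a) > 1e3:
        raise ValueError(
            "complete separation in the survival node; consider a "
            "penalized (Firth) logistic fit"
        )


def fit_fitness_model(
    records: pd.DataFrame,
    include_family: bool = True,
    include_init_height: bool = True,
    include_block: bool = True,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> FitnessModel:
    """Jointly fit both fitness nodes by Newton-Raphson.

    ``records`` needs columns ``survival`` (0/1), ``height_final`` (present
    for survivors), and whichever of ``family``, ``height_init``, ``block``
    the flags request. Raises on complete separation in the survival node
    (advising a penalized fit) and on rank-deficient designs.
    """
    surv = records["survival"].to_numpy(float)
    if not np.all(np.isin(surv, [0.0, 1.0])):
        raise ValueError("survival must be 0/1")
    h = records["height_final"].to_numpy(float)
    if np.any(surv.astype(bool) & ~np.isfinite(h)):
        raise ValueError("missing final height for a survivor")
    X, cols, fam_lv, blk_lv = _build_design(
        records, include_family, include_init_height, include_block
    )
    _check_rank(X, cols)
    ns = int(surv.sum())
    if ns == 0:
        raise ValueError("no survivors: height node cannot be fit")
    Xs = X[surv.astype(bool)]
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        raise ValueError(
            "design rank-deficient among survivors; drop aliased predictors"
        )

    k = X.shape[1]
    all_survived = ns == len(records)

    # starting values: null survival rate, survivor mean height
    p0 = np.clip(surv.mean(), 1e-3, 1 - 1e-3)
    theta = np.zeros(2 * k + 1)
    theta[0] = np.log(p0 / (1 - p0))
    theta[k] = h[surv.astype(bool)].mean()
    theta[-1] = 0.5 * np.log(max(h[surv.astype(bool)].var(), 1e-6))

    if all_survived:
        # survival node saturates at p = 1; fit the height node only
        c, *_ = np.linalg.lstsq(Xs, h, rcond=None)
        resid = h - Xs @ c
        s2 = float(np.mean(resid**2))
        ll = -0.5 * ns * (np.log(2 * np.pi * s2) + 1.0)
        return FitnessModel(
            surv_coef=np.full(k, np.nan), height_coef=c, sigma2=s2,
            loglik=ll, columns=cols, family_levels=fam_lv,
            block_levels=blk_lv, include_family=include_family,
            include_init_height=include_init_height,
            include_block=include_block, all_survived=True, n=len(records),
        )

    nll, grad, H = _joint_nll_grad_hess(theta, X, surv, h)
    for it in range(max_iter):
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            raise ValueError(
                "singular Hessian in joint fit; check for separation or "
                "aliased predictors"
            )
        # damped Newton with step halving
        lam = 1.0
        for _ in range(60):
            cand = theta - lam * step
            nll_new, grad_new, H_new = _joint_nll_grad_hess(cand, X, surv, h)
            if nll_new <= nll + 1e-14:
                break
            lam *= 0.5
        theta, nll, grad, H = cand, nll_new, grad_new, H_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(nll)):
            break
    else:
        _raise_if_separated(theta[:k], X, surv)
        raise ValueError("joint Newton fit did not converge")

    return FitnessModel(
        surv_coef=theta[:k],
        height_coef=theta[k:2 * k],
        sigma2=float(np.exp(2 * theta[-1])),
        loglik=float(-nll),
        columns=cols,
        family_levels=fam_lv,
        block_levels=blk_lv,
        include_family=include_family,
        include_init_height=include_init_height,
        include_block=include_block,
        n=len(records),
    )


def predict_fitness(model: FitnessModel, records: pd.DataFrame) -> np.ndarray:
    """Expected fitness W_hat = p_hat * mu_hat per individual (cm)."""
    X, _, _, _ = _build_design(
        records, model.include_family, model.include_init_height,
        model.include_block, model.family_levels, model.block_levels,
    )
    mu = X @ model.height_coef
    if model.all_survived:
        p = np.ones(len(records))
    else:
        p = 1.0 / (1.0 + np.exp(-(X @ model.surv_coef)))
    return p * mu


def block_omnibus_test(records: pd.DataFrame, include_family: bool = True,
                       include_init_height: bool = True):
    """Omnibus LRT for block across both fitness nodes.

    Compares the joint likelihood with and without block at both nodes;
    df = number of block parameters across the two nodes. Returns
    ``(statistic, df, p)``.
    """
    full = fit_fitness_model(records, include_family, include_init_height,
                             include_block=True)
    null = fit_fitness_model(records, include_family, include_init_height,
                             include_block=False)
    n_block_levels = len(full.block_levels)
    df = 2 * (n_block_levels - 1)
    stat = max(-2.0 * (null.loglik - full.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df=df))
    return stat, df, p
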