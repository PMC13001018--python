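"""REML variance components and broad-sense heritability for family designs.

Model: for trait value y_ij of individual j in maternal family i,

    y = X beta + Z u + e,    u ~ N(0, V_g I),  e ~ N(0, V_e I)

with block entering as a fixed effect (columns of X) and one random
intercept per family. Families raised from open-pollinated acorns of a
single mother are treated as full siblings, so the between-family variance
component is reported directly as the genetic variance V_g (no sib-covariance
conversion), and broad-sense heritability is H^2 = V_g / (V_g + V_e).

Estimation maximizes the restricted (residual) likelihood, which is
unbiased by the fixed-effect estimation and robust to unbalanced family
sizes (mortality). The covariance matrix V = V_e I + V_g Z Z^T is block
diagonal by family, and each family block (V_e I + V_g J) has a closed-form
inverse and determinant, so the restricted likelihood is evaluated exactly
in O(n) per call. The likelihood is profiled over the variance ratio
lambda = V_g / V_e on a log grid and polished with Brent's method; V_g is
constrained to be non-negative (boundary at lambda = 0).

Evidence for V_g > 0 uses the likelihood-ratio statistic
LRT = -2 (L_0 - L_max) referred to a chi-square distribution with 1 df.
Because the null pins V_g to the boundary of its parameter space the
chi-square-1 reference is conservative (the asymptotic null is the mixture
0.5*chi2_0 + 0.5*chi2_1); the plain chi-square-1 reference is used here.
Standard errors of (V_g, V_e) are square roots of the diagonal of the
inverse observed information (numerical Hessian of the restricted
log-likelihood) at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceEstimate",
    "fit_reml",
    "fit_null",
    "lrt",
    "heritability",
    "run_quantgen",
]

_TWO_PI = 2.0 * np.pi


@dataclass
class VarianceEstimate:
    """Per-trait variance decomposition for one population x garden cell."""

    trait: str
    V_g: float
    V_e: float
    se_Vg: float
    se_Ve: float
    logLik_full: float
    logLik_null: float
    lrt_stat: float
    p_value: float
    H2: float
    n_individuals: int
    n_families: int
    beta: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("beta")
        return d


def _design(y, family, block):
    """Sort by family; build fixed-effect matrix and family index/sizes."""
    y = np.asarray(y, dtype=float)
    family = np.asarray(family)
    mask = np.isfinite(y)
    y, family = y[mask], family[mask]
    block = None if block is None else np.asarray(block)[mask]

    fams, fam_idx = np.unique(family, return_inverse=True)
    order = np.argsort(fam_idx, kind="stable")
    # center for numerical stability; REML is location invariant and the
    # intercept is restored after the fit
    y_mean = float(y.mean())
    y, fam_idx = y[order] - y_mean, fam_idx[order]
    sizes = np.bincount(fam_idx)

    X = np.ones((y.size, 1))
    if block is not None:
        block = block[order]
        levels = np.unique(block)
        if levels.size > 1:
            dummies = np.column_stack(
                [(block == lv).astype(float) for lv in levels[1:]]
            )
            X = np.hstack([X, dummies])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design (aliased block levels)")
    return y, X, fam_idx, sizes, fams.size, y_mean


def _loglik_parts(lam, y, X, fam_idx, sizes):
    """Profiled REML pieces at variance ratio lam = V_g/V_e.

    With A = I + lam * Z Z^T, returns (logdet A, logdet X'A^-1 X, r'A^-1 r,
    beta_gls, Ve_hat) using the per-family Sherman-Morrison identity
    A_i^{-1} = I - (lam / (1 + n_i lam)) J.
    """
    n, p = X.shape
    shrink = lam / (1.0 + sizes * lam)  # per family
    logdet_A = float(np.sum(np.log1p(sizes * lam)))

    # family-wise column sums of X and y
    Sx = np.zeros((sizes.size, p))
    for j in range(p):
        Sx[:, j] = np.bincount(fam_idx, weights=X[:, j], minlength=sizes.size)
    Sy = np.bincount(fam_idx, weights=y, minlength=sizes.size)

    XtAX = X.T @ X - (Sx * shrink[:, None]).T @ Sx
    XtAy = X.T @ y - Sx.T @ (shrink * Sy)
    ytAy = y @ y - shrink @ Sy**2

    sign, logdet_XtAX = np.linalg.slogdet(XtAX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'A^{-1}X not positive definite")
    beta = np.linalg.solve(XtAX, XtAy)
    quad = ytAy - XtAy @ beta  # r' A^-1 r for the GLS residual
    quad = max(quad, 1e-300)
    ve = quad / (n - p)
    return logdet_A, logdet_XtAX, quad, beta, ve


def _profile_reml(lam, y, X, fam_idx, sizes):
    """Profiled restricted log-likelihood at ratio lam (V_e maximized out)."""
    n, p = X.shape
    logdet_A, logdet_XtAX, _, _, ve = _loglik_parts(lam, y, X, fam_idx, sizes)
    return -0.5 * (
        (n - p) * (np.log(_TWO_PI) + np.log(ve) + 1.0)
        + logdet_A
        + logdet_XtAX
    )


def reml_loglik(V_g, V_e, y, family, block=None) -> float:
    """Restricted log-likelihood at arbitrary (V_g, V_e); exact, O(n)."""
    yv, X, fam_idx, sizes, _, _ = _design(y, family, block)
    n, p = X.shape
    lam = V_g / V_e
    logdet_A, logdet_XtAX, quad, _, _ = _loglik_parts(
        lam, yv, X, fam_idx, sizes
    )
    # V = V_e * A:  log|V| = n log V_e + log|A|;  X'V^-1X = X'A^-1X / V_e
    return -0.5 * (
        (n - p) * np.log(_TWO_PI)
        + n * np.log(V_e)
        + logdet_A
        - p * np.log(V_e)
        + logdet_XtAX
        + quad / V_e
    )


def _optimize_lambda(y, X, fam_idx, sizes):
    obj = lambda lam: -_profile_reml(lam, y, X, fam_idx, sizes)
    grid = np.concatenate([[0.0], np.logspace(-6, 3, 55)])
    vals = np.array([obj(l) for l in grid])
    k = int(np.argmin(vals))
    if k == 0:
        lo, hi = 0.0, grid[1]
    else:
        lo = grid[k - 1]
        hi = grid[k + 1] if k + 1 < grid.size else grid[k] * 10.0
    res = optimize.minimize_scalar(
        obj, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    lam = res.x if res.fun <= vals[k] else grid[k]
    if obj(0.0) <= obj(lam):
        lam = 0.0
    return lam


def fit_reml(y, design: pd.DataFrame | None = None, *, family=None,
             block=None, trait: str = "trait") -> VarianceEstimate:
    """REML fit of the family variance-component model for one trait.

    Parameters
    ----------
    y : trait values per individual (NaN = missing, dropped listwise).
    design : optional DataFrame with columns ``family`` and ``block``;
        alternatively pass ``family=`` and ``block=`` arrays directly.
    """
    if design is not None:
        family = design["family"].to_numpy()
        block = design["block"].to_numpy() if "block" in design else None
    if family is None:
        raise ValueError("family assignment required")
    yv, X, fam_idx, sizes, n_fam, y_mean = _design(y, family, block)
    if n_fam < 2 or np.sum(sizes >= 2) < 2:
        raise ValueError(
            "need >= 2 families with >= 2 individuals after dropping missing"
        )
    n, p = X.shape
    if n - p < 2:
        raise ValueError("too few residual degrees of freedom")

    lam = _optimize_lambda(yv, X, fam_idx, sizes)
    _, _, _, beta, ve = _loglik_parts(lam, yv, X, fam_idx, sizes)
    beta = beta.copy()
    beta[0] += y_mean  # undo the centering in the reported intercept
    vg = lam * ve
    ll_full = _profile_reml(lam, yv, X, fam_idx, sizes)
    ll_null = _profile_reml(0.0, yv, X, fam_idx, sizes)

    se_vg, se_ve = _asymptotic_se(vg, ve, yv, X, fam_idx, sizes)
    stat, p_val = lrt(ll_full, ll_null)
    return VarianceEstimate(
        trait=trait,
        V_g=vg,
        V_e=ve,
        se_Vg=se_vg,
        se_Ve=se_ve,
        logLik_full=ll_full,
        logLik_null=ll_null,
        lrt_stat=stat,
        p_value=p_val,
        H2=heritability(vg, ve),
        n_individuals=int(n),
        n_families=int(n_fam),
        beta=beta,
    )


def _asymptotic_se(vg, ve, y, X, fam_idx, sizes):
    """SEs from the inverse observed information of (V_g, V_e)."""

    def ll(theta):
        g, e = theta
        if e <= 0 or g < 0:
            return -np.inf
        lam = g / e
        n, p = X.shape
        logdet_A, logdet_XtAX, quad, _, _ = _loglik_parts(
            lam, y, X, fam_idx, sizes
        )
        return -0.5 * (
            (n - p) * np.log(_TWO_PI)
            + (n - p) * np.log(e)
            + logdet_A
            + logdet_XtAX
            + quad / e
        )

    theta = np.array([vg, ve])
    h = np.maximum(1e-5 * np.maximum(np.abs(theta), 1e-8), 1e-10)
    H = np.zeros((2, 2))
    try:
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                base = np.array([max(vg, h[0]), ve])
                H[i, j] = (
                    ll(base + ei + ej) - ll(base + ei - ej)
                    - ll(base - ei + ej) + ll(base - ei - ej)
                ) / (4 * h[i] * h[j])
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
        return float(se[0]), float(se[1])
    except (np.linalg.LinAlgError, FloatingPointError):
        return float("nan"), float("nan")


def fit_null(y, design: pd.DataFrame | None = None, *, family=None,
             block=None) -> float:
    """Restricted log-likelihood of the fixed-effects-only model (V_g = 0)."""
    if design is not None:
        family = design["family"].to_numpy()
        block = design["block"].to_numpy() if "block" in design else None
    yv, X, fam_idx, sizes, _, _ = _design(y, family, block)
    return _profile_reml(0.0, yv, X, fam_idx, sizes)


def lrt(logLik_full: float, logLik_null: float, tol: float = 1e-6):
    """Likelihood-ratio statistic -2(L_0 - L_max) vs chi-square, 1 df."""
    stat = -2.0 * (logLik_null - logLik_full)
    if stat < -tol * max(1.0, abs(logLik_full)):
        raise ValueError(
            f"null likelihood exceeds full ({logLik_null:g} > {logLik_full:g})"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def heritability(V_g: float, V_e: float) -> float:
    """Broad-sense heritability H^2 = V_g / (V_g + V_e)."""
    if V_g < 0 or V_e <= 0:
        raise ValueError("require V_g >= 0 and V_e > 0")
    vp = V_g + V_e
    if vp == 0:
        raise ValueError("zero phenotypic variance")
    return V_g / vp


def anova_oracle(y, family):
    """Balanced one-way ANOVA estimators of (V_g, V_e) — method of moments.

    For a balanced design with q families of size m:
    V_g = (MS_between - MS_within) / m (clipped at 0), V_e = MS_within.
    Used as an independent check of REML, which coincides with ANOVA on
    balanced data when the estimate is interior.
    """
    y = np.asarray(y, dtype=float)
    family = np.asarray(family)
    fams = np.unique(family)
    m = np.unique([np.sum(family == f) for f in fams])
    if m.size != 1:
        raise ValueError("anova_oracle requires a balanced design")
    m = int(m[0])
    grand = y.mean()
    fam_means = np.array([y[family == f].mean() for f in fams])
    ss_b = m * np.sum((fam_means - grand) ** 2)
    ss_w = sum(np.sum((y[family == f] - fm) ** 2)
               for f, fm in zip(fams, fam_means))
    ms_b = ss_b / (fams.size - 1)
    ms_w = ss_w / (fams.size * (m - 1))
    return max((ms_b - ms_w) / m, 0.0), ms_w


def run_quantgen(
    table: pd.DataFrame,
    traits,
    by=("population", "garden"),
    family_col: str = "family",
    block_col: str = "block",
) -> pd.DataFrame:
    """Per-trait REML estimates for every cell of the grouping grid.

    Cells with too few surviving families are flagged ``estimable = False``
    rather than raising. Returns a long-format table (one row per
    cell x trait) with V_g, V_e, SEs, LRT, p, H2 and sample sizes.
    """
    rows = []
    by = list(by)
    for keys, sub in table.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for trait in traits:
            base = dict(zip(by, keys))
            base["trait"] = trait
            if trait not in sub.columns:
                raise KeyError(f"trait column {trait!r} missing")
            try:
                est = fit_reml(
                    sub[trait].to_numpy(float),
                    family=sub[family_col].to_numpy(),
                    block=sub[block_col].to_numpy()
                    if block_col in sub else None,
                    trait=trait,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                base.update(estimable=False, note=str(exc))
                rows.append(base)
                continue
            d = est.to_dict()
            d.pop("trait")
            base.update(estimable=True, note="", **d)
            rows.append(base)
    return pd.DataFrame(rows)
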