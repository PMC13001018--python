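"""Phenotypic selection analysis: gradients, differentials, and response.

Following the Lande-Arnold regression framework, selection on a set of
traits is measured on relative fitness w = W / mean(W) (mean 1 within each
garden) against traits standardized to zero mean and unit SD:

* linear selection gradients (beta): partial regression coefficients of w
  on the standardized traits — direct selection;
* selection differentials (S): sample covariance of w with each
  standardized trait — total (direct + indirect) selection;
* quadratic gradients (gamma): coefficients of the squared trait terms in a
  separate quadratic regression — negative values indicate stabilizing
  selection, positive disruptive. Reported as the raw regression
  coefficient (not doubled).

Trait collinearity is screened beforehand with variance inflation factors
(traits with VIF > 5 dropped iteratively, largest first). Gradients are
estimated with linear mixed models (random intercepts for block and, at the
garden level, population) fit by REML, falling back to ordinary least
squares when no random structure is available; coefficient significance
uses two-tailed t-tests. The breeder's equation R = H^2 * S converts a
selection differential into the predicted one-generation response.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "relative_fitness",
    "standardize",
    "vif_screen",
    "linear_gradients",
    "selection_differentials",
    "quadratic_gradients",
    "response_to_selection",
    "analyze_selection",
]


def relative_fitness(fitness, group=None) -> np.ndarray:
    """w_i = W_i / mean(W) within each group (garden); group mean of w is 1."""
    fitness = np.asarray(fitness, dtype=float)
    if group is None:
        group = np.zeros(fitness.size, dtype=int)
    group = np.asarray(group)
    w = np.empty_like(fitness)
    for g in np.unique(group):
        m = group == g
        mu = fitness[m].mean()
        if mu <= 0:
            raise ValueError(f"non-positive mean fitness in group {g!r}")
        w[m] = fitness[m] / mu
    return w


def standardize(table: pd.DataFrame, traits, group=None) -> pd.DataFrame:
    """Z-score the trait columns within groups (sample SD, ddof=1)."""
    out = table.copy()
    if group is None:
        grouper = [True] * len(table)
    else:
        grouper = table[group] if isinstance(group, str) else group
    for t in traits:
        def _z(col):
            sd = col.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"constant trait {t!r} within a group")
            return (col - col.mean()) / sd
        out[t] = table.groupby(grouper)[t].transform(_z)
    return out


def vif_screen(table: pd.DataFrame, candidates, threshold: float = 5.0):
    """Iteratively drop predictors with variance inflation factor > threshold.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on all the others
    (with intercept). The worst offender is dropped and VIFs recomputed
    until all retained predictors pass. Exact collinearity yields an
    infinite VIF. Returns ``(retained, report)`` where report lists each
    round's VIFs and any dropped column.
    """
    retained = list(candidates)
    if len(retained) < 2:
        raise ValueError("need at least 2 candidate predictors")
    X_all = table[retained].to_numpy(float)
    if np.any(~np.isfinite(X_all)):
        raise ValueError("VIF screen requires complete cases")
    rows = []
    round_no = 0
    while True:
        round_no += 1
        vifs = {}
        for j, name in enumerate(retained):
            others = [c for c in retained if c != name]
            X = sm.add_constant(table[others].to_numpy(float))
            y = table[name].to_numpy(float)
            res = sm.OLS(y, X).fit()
            r2 = min(res.rsquared, 1.0)
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda k: vifs[k])
        drop = vifs[worst] > threshold and len(retained) > 2
        for name, v in vifs.items():
            rows.append({"round": round_no, "trait": name, "vif": v,
                         "dropped": drop and name == worst})
        if not drop:
            if vifs[worst] > threshold:
                warnings.warn(
                    f"only 2 predictors left; {worst} retained with "
                    f"VIF={vifs[worst]:.2f}", stacklevel=2)
            break
        retained.remove(worst)
    return retained, pd.DataFrame(rows)


def _mixed_or_ols(df: pd.DataFrame, response: str, fixed_terms, random_groups):
    """Fit response ~ fixed_terms with optional crossed random intercepts.

    Returns (params, bse, resid_df, used_random). Random groups with < 2
    levels are dropped with a warning; non-convergence falls back to OLS.
    """
    usable = []
    for g in random_groups or []:
        if df[g].nunique() >= 2:
            usable.append(g)
        else:
            warnings.warn(f"random group {g!r} has < 2 levels; dropped",
                          stacklevel=3)
    formula = f"{response} ~ " + " + ".join(fixed_terms)
    n = len(df)
    k = len(fixed_terms) + 1
    if usable:
        work = df.copy()
        work["_unit"] = 1
        vc = {g: f"0 + C({g})" for g in usable}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(formula, work, groups="_unit", vc_formula=vc)
                res = md.fit(reml=True, method="lbfgs")
            if not res.converged:
                raise RuntimeError("mixed model did not converge")
            return res.params, res.bse, n - k, True
        except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(
                f"mixed model failed ({exc}); falling back to fixed-intercept "
                "least squares", stacklevel=3)
    res = smf.ols(formula, df).fit()
    return res.params, res.bse, res.df_resid, False


def _term_table(params, bse, names, resid_df):
    rows = []
    for name in names:
        est = float(params[name])
        se = float(bse[name])
        t = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), resid_df) if np.isfinite(t) else np.nan
        rows.append({"estimate": est, "se": se, "t": t, "p": p})
    return rows


def linear_gradients(df: pd.DataFrame, traits, w_col: str = "w",
                     random_groups=None) -> pd.DataFrame:
    """Linear selection gradients beta per trait (partial regression of w).

    ``df`` carries relative fitness in ``w_col`` and standardized traits.
    Returns one row per trait: beta estimate, SE, t and two-tailed p.
    """
    clean = [t for t in traits]
    params, bse, rdf, used_random = _mixed_or_ols(df, w_col, clean,
                                                  random_groups)
    rows = _term_table(params, bse, clean, rdf)
    out = pd.DataFrame(rows)
    out.insert(0, "trait", clean)
    out["parameter"] = "beta"
    out.attrs["random_effects_used"] = used_random
    return out


def selection_differentials(df: pd.DataFrame, traits,
                            w_col: str = "w") -> pd.DataFrame:
    """Selection differentials S_j = cov(w, z_j) (sample covariance)."""
    w = df[w_col].to_numpy(float)
    rows = []
    for t in traits:
        z = df[t].to_numpy(float)
        s = float(np.cov(w, z, ddof=1)[0, 1]) if w.size > 1 else np.nan
        rows.append({"trait": t, "estimate": s, "parameter": "S"})
    return pd.DataFrame(rows)


def quadratic_gradients(df: pd.DataFrame, traits, w_col: str = "w",
                        random_groups=None) -> pd.DataFrame:
    """Quadratic selection gradients gamma (coefficients of squared traits).

    Linear terms are included alongside the pure squared terms; cross
    products (correlational selection) are not fit. Each gamma carries a
    label: negative -> "stabilizing", positive -> "disruptive".
    """
    work = df.copy()
    sq_names = []
    for t in traits:
        name = f"{t}_sq"
        work[name] = work[t] ** 2
        sq_names.append(name)
    params, bse, rdf, used_random = _mixed_or_ols(
        work, w_col, list(traits) + sq_names, random_groups
    )
    rows = _term_table(params, bse, sq_names, rdf)
    out = pd.DataFrame(rows)
    out.insert(0, "trait", list(traits))
    out["parameter"] = "gamma"
    out["selection_mode"] = np.where(out["estimate"] < 0, "stabilizing",
                                     "disruptive")
    out.attrs["random_effects_used"] = used_random
    return out


def response_to_selection(H2, S):
    """Breeder's equation R = H^2 * S (per-SD predicted response)."""
    H2 = np.asarray(H2, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any((H2 < 0) | (H2 > 1)):
        raise ValueError("H^2 must lie in [0, 1]")
    r = H2 * S
    return float(r) if r.ndim == 0 else r


def analyze_selection(
    df: pd.DataFrame,
    traits,
    level: str = "garden",
    fitness_col: str = "fitness_hat",
    garden_col: str = "garden",
    population_col: str = "population",
    block_col: str = "block",
    vif_threshold: float = 5.0,
    standardize_within: str = "garden",
) -> pd.DataFrame:
    """Full selection analysis at garden or population x garden level.

    Relative fitness and trait standardization are computed within garden
    (configurable via ``standardize_within``: "garden" or "cell"). The
    garden-level models use block and population random intercepts; the
    population-level models (per garden x population subset) use block
    only. Returns a long table: garden, population (empty at garden level),
    trait, parameter (beta | S | gamma), estimate, se, t, p.
    """
    work = df.dropna(subset=list(traits) + [fitness_col]).copy()
    work["w"] = relative_fitness(work[fitness_col], work[garden_col])
    if standardize_within == "garden":
        work = standardize(work, traits, garden_col)
    elif standardize_within == "cell":
        work["_cell"] = (work[garden_col].astype(str) + ":"
                         + work[population_col].astype(str))
        work = standardize(work, traits, "_cell")
    else:
        raise ValueError("standardize_within must be 'garden' or 'cell'")

    retained, _vif_report = vif_screen(work, list(traits), vif_threshold)

    results = []
    if level == "garden":
        groups = [(g, None, sub) for g, sub in work.groupby(garden_col)]
        random_groups = [block_col, population_col]
    elif level == "population":
        groups = [(g, p, sub) for (g, p), sub in
                  work.groupby([garden_col, population_col])]
        random_groups = [block_col]
    else:
        raise ValueError("level must be 'garden' or 'population'")

    for garden, population, sub in groups:
        beta = linear_gradients(sub, retained, random_groups=random_groups)
        s = selection_differentials(sub, retained)
        gamma = quadratic_gradients(sub, retained,
                                    random_groups=random_groups)
        for part in (beta, s, gamma):
            part = part.copy()
            part["garden"] = garden
            part["population"] = population if population is not None else ""
            part["level"] = level
            results.append(part)
    out = pd.concat(results, ignore_index=True)
    out.attrs["retained_traits"] = retained
    # plain records, not a DataFrame: attrs must stay comparable for concat
    out.attrs["vif_report"] = _vif_report.to_dict("records")
    return out
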