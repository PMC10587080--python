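"""Random-intercept mixed models, Nakagawa R2, scans and partitioning.

All fits are linear mixed models with a single random intercept for
site, estimated by REML with a profiled solver written for exactly this
model class (see ``_reml_random_intercept``): after profiling out the
fixed effects and the residual variance the criterion depends on one
scalar, the group/residual variance ratio, which is minimized by a
bracketed search.  Variance-explained summaries follow Nakagawa &
Schielzeth:

    R2_marginal    = s2_f / (s2_f + s2_a + s2_e)
    R2_conditional = (s2_f + s2_a) / (s2_f + s2_a + s2_e)

with s2_f the sample variance of the fixed-effect linear predictor,
s2_a the site-intercept variance and s2_e the residual variance.

``hierarchical_partition`` attributes the full model's marginal R2 to
individual predictors by averaging each predictor's incremental R2 over
all orderings of model entry (computed with Shapley subset weights, so
2^p rather than p! fits), then sums the contributions within named
predictor groups; the random share is conditional minus marginal R2 of
the full model and the remainder is unexplained.  Negative averaged
contributions are truncated at zero and the positive ones rescaled so
the reported shares still sum to 100%; raw values are kept for audit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import factorial
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from stomacomm.environment import MODEL_VARS
from stomacomm.moments import MOMENTS, TRAITS, pivot_moments

log = logging.getLogger(__name__)

LOG_MOMENTS = ("cwm", "cwv")  # responses natural-log transformed before fitting


@dataclass
class FitResult:
    """One random-intercept LMM fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    var_fixed: float  # variance of the fixed-effect linear predictor
    var_group: float  # site random-intercept variance
    var_resid: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool  # var_group estimated at (near) zero


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str = "site_id",
    reml: bool = True,
) -> FitResult:
    """Fit ``response ~ 1 + fixed + (1 | group)`` by REML.

    Rows with missing response/predictor values are dropped (and
    counted in the log).  A singular fit (group variance pinned at ~0)
    is retained and flagged rather than raised.
    """
    fixed = list(fixed)
    cols = [response] + fixed + [group]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns {missing}")
    df = data[cols].replace([np.inf, -np.inf], np.nan).dropna()
    dropped = len(data) - len(df)
    if dropped:
        log.debug("fit_lmm(%s): dropped %d incomplete rows", response, dropped)
    n_groups = df[group].nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 groups in the random factor")

    # standardize predictors for a well-conditioned optimization, then map
    # the estimates back to the raw scale (R2 and variance components are
    # invariant to this affine reparameterization)
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    centers, scales = {}, {}
    for c in fixed:
        x = df[c].astype(float)
        m, s = float(x.mean()), float(x.std())
        if s == 0 or not np.isfinite(s):
            s = 1.0
        centers[c], scales[c] = m, s
        X[c] = (x - m) / s
    y = df[response].to_numpy(dtype=float)

    beta, cov_beta, var_group, var_resid, llf = _reml_random_intercept(
        y, X.to_numpy(), df[group].to_numpy(), reml=reml
    )
    pred = X.to_numpy() @ beta
    var_fixed = float(np.var(pred, ddof=1)) if fixed else 0.0
    k = len(beta)

    # beta_raw = A @ beta_std undoes the predictor standardization
    names = ["Intercept"] + fixed
    A = np.eye(k)
    for j, c in enumerate(fixed, start=1):
        A[j, j] = 1.0 / scales[c]
        A[0, j] = -centers[c] / scales[c]
    beta_raw = A @ beta
    cov_raw = A @ cov_beta @ A.T
    bse_raw = np.sqrt(np.diag(cov_raw))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta_raw / bse_raw
    pvals = 2.0 * norm.sf(np.abs(zvals))
    return FitResult(
        params=pd.Series(beta_raw, index=names),
        bse=pd.Series(bse_raw, index=names),
        pvalues=pd.Series(pvals, index=names),
        var_fixed=var_fixed,
        var_group=max(var_group, 0.0),
        var_resid=var_resid,
        llf=llf,
        n_obs=len(df),
        n_groups=int(n_groups),
        converged=True,
        singular=var_group < 1e-8 * max(var_resid, 1e-12),
    )


def _reml_random_intercept(y, X, groups, reml: bool = True):
    """Profiled (RE)ML for ``y = X beta + u_group + eps``.

    The only free parameter after profiling beta and the residual
    variance is the variance ratio theta = s2_group / s2_resid.  For a
    given theta the marginalized precision is block diagonal with
    W_g = I - theta/(1 + theta n_g) * 11', so all GLS quantities reduce
    to per-group sums and the criterion is minimized by a bracketed
    scalar search on log(theta) — fast and free of the convergence
    failures iterative multiparameter optimizers can hit on this model.
    Returns (beta, cov_beta, var_group, var_resid, llf).
    """
    n, p = X.shape
    codes, _ = pd.factorize(groups)
    G = codes.max() + 1
    ng = np.bincount(codes, minlength=G).astype(float)
    # per-group sufficient statistics
    Sx = np.zeros((G, p))
    for j in range(p):
        Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=G)
    Sy = np.bincount(codes, weights=y, minlength=G)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    dof = n - p if reml else n

    def gls(theta):
        c = theta / (1.0 + theta * ng)  # shrinkage per group
        XtWX = XtX - Sx.T @ (Sx * c[:, None])
        XtWy = Xty - Sx.T @ (c * Sy)
        ytWy = yty - float(c @ Sy**2)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - float(beta @ XtWy), 1e-300)
        return beta, XtWX, rss

    def criterion(theta):
        _, XtWX, rss = gls(theta)
        crit = dof * np.log(rss) + float(np.sum(np.log1p(theta * ng)))
        if reml:
            sign, logdet = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return np.inf
            crit += logdet
        return crit

    # bracket the optimum on a log grid (criterion is smooth; theta = 0
    # boundary handled explicitly)
    ts = np.concatenate([[-np.inf], np.linspace(-14.0, 14.0, 57)])
    vals = np.array([criterion(0.0 if t == -np.inf else np.exp(t)) for t in ts])
    i = int(np.argmin(vals))
    if i == 0:
        theta = 0.0
        # refine near zero in case the minimum sits just off the boundary
        res = minimize_scalar(
            lambda t: criterion(np.exp(t)),
            bounds=(-20.0, -10.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < vals[0]:
            theta = float(np.exp(res.x))
    else:
        lo = ts[i - 1] if i - 1 >= 1 else -20.0
        hi = ts[i + 1] if i + 1 < len(ts) else 16.0
        res = minimize_scalar(
            lambda t: criterion(np.exp(t)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        theta = float(np.exp(res.x))
        if criterion(0.0) < res.fun:
            theta = 0.0

    beta, XtWX, rss = gls(theta)
    var_resid = rss / dof
    var_group = theta * var_resid
    cov_beta = var_resid * np.linalg.inv(XtWX)
    llf = -0.5 * (
        dof * np.log(2.0 * np.pi * var_resid)
        + float(np.sum(np.log1p(theta * ng)))
        + dof
    )
    if reml:
        sign, logdet = np.linalg.slogdet(XtWX)
        llf -= 0.5 * logdet
    return beta, cov_beta, var_group, var_resid, llf


def r2_nakagawa(fit: FitResult) -> Dict[str, float]:
    """Marginal and conditional R2 of a random-intercept fit."""
    total = fit.var_fixed + fit.var_group + fit.var_resid
    if total <= 0:
        raise ValueError("all variance components are zero")
    marginal = fit.var_fixed / total
    conditional = (fit.var_fixed + fit.var_group) / total
    return {
        "marginal": float(np.clip(marginal, 0.0, 1.0)),
        "conditional": float(np.clip(conditional, 0.0, 1.0)),
    }


def _prepare_responses(
    moments_long: pd.DataFrame, log_moments: Sequence[str] = LOG_MOMENTS
) -> pd.DataFrame:
    """Wide per-plot table with one response column per trait x moment.

    Columns are named ``<trait>_<moment>`` (e.g. SD_cwm); CWM and CWV
    are natural-log transformed, with non-positive values (possible for
    CWV in single-species plots) set to missing.
    """
    wide = pivot_moments(moments_long)
    keep = ["plot_id", "site_id"] + (
        ["vegetation"] if "vegetation" in wide.columns else []
    )
    out = wide[keep].drop_duplicates("plot_id").set_index("plot_id")
    for trait, grp in wide.groupby("trait"):
        grp = grp.set_index("plot_id")
        for moment in MOMENTS:
            col = grp[moment]
            if moment in log_moments:
                col = np.log(col.where(col > 0))
            out[f"{trait}_{moment}"] = col
    return out.reset_index()


def bivariate_scan(
    moments_long: pd.DataFrame,
    env: pd.DataFrame,
    env_vars: Optional[Sequence[str]] = None,
    traits: Sequence[str] = TRAITS,
) -> pd.DataFrame:
    """One LMM per trait-moment response per environmental variable.

    Responses are the plot-level moments (CWM/CWV on the natural-log
    scale); each fit is ``response ~ variable + (1 | site)``.  Rows are
    ranked within each response by marginal R2 (rank 1 = strongest).
    """
    if env_vars is None:
        env_vars = [v for v in MODEL_VARS if v in env.columns]
    responses = _prepare_responses(moments_long)
    joined = responses.merge(env, on="site_id", how="inner")
    if len(joined) < 10:
        raise ValueError("fewer than 10 plots after joining moments with env")
    rows = []
    for trait in traits:
        for moment in MOMENTS:
            col = f"{trait}_{moment}"
            y = joined[col]
            flat = bool(y.dropna().nunique() <= 1)
            for var in env_vars:
                if flat:
                    rec = {"marginal_r2": 0.0, "conditional_r2": 0.0,
                           "slope": np.nan, "slope_se": np.nan, "pvalue": np.nan,
                           "n_obs": int(y.notna().sum())}
                else:
                    fit = fit_lmm(joined, col, [var])
                    r2 = r2_nakagawa(fit)
                    rec = {
                        "marginal_r2": r2["marginal"],
                        "conditional_r2": r2["conditional"],
                        "slope": float(fit.params[var]),
                        "slope_se": float(fit.bse[var]),
                        "pvalue": float(fit.pvalues[var]),
                        "n_obs": fit.n_obs,
                    }
                rows.append({"trait": trait, "moment": moment, "env_var": var,
                             "flat_response": flat, **rec})
    scan = pd.DataFrame(rows)
    scan["rank"] = (
        scan.groupby(["trait", "moment"])["marginal_r2"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    return scan.sort_values(["trait", "moment", "rank"]).reset_index(drop=True)


@dataclass
class PartitionResult:
    """Variance shares (% of total) per predictor group for one response."""

    response: str
    shares: pd.DataFrame  # columns: component, share_pct, raw_pct
    predictor_contributions: pd.DataFrame  # predictor, group, raw_pct, share_pct
    marginal_r2: float
    conditional_r2: float
    method: str = "all-orderings hierarchical partitioning (Shapley weights), REML"


def shapley_contributions(
    r2_by_subset: Dict[frozenset, float], predictors: Sequence[str]
) -> Dict[str, float]:
    """Average incremental R2 of each predictor over all entry orderings.

    Computed with the subset-weighting identity
    sum_S |S|!(p-|S|-1)!/p! * (R2(S+{j}) - R2(S)); contributions sum to
    R2 of the full set.
    """
    p = len(predictors)
    out = {}
    for j in predictors:
        others = [q for q in predictors if q != j]
        total = 0.0
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for S in itertools.combinations(others, r):
                s = frozenset(S)
                total += w * (r2_by_subset[s | {j}] - r2_by_subset[s])
        out[j] = total
    return out


def hierarchical_partition(
    data: pd.DataFrame,
    response: str,
    groups: Dict[str, Sequence[str]],
    group_col: str = "site_id",
) -> PartitionResult:
    """Grouped variance partitioning of one trait-moment response.

    ``groups`` maps group names (e.g. temperature/precipitation/soil) to
    predictor columns, typically the per-group PCA scores.  All 2^p
    subsets of the pooled predictors are fitted; each predictor's
    hierarchical-partitioning contribution is summed within its group.
    """
    predictors: List[str] = []
    owner: Dict[str, str] = {}
    for g, cols in groups.items():
        for c in cols:
            predictors.append(c)
            owner[c] = g
    if len(predictors) != len(set(predictors)):
        raise ValueError("a predictor appears in more than one group")
    if len(predictors) > 10:
        raise ValueError("more than 10 predictors (2^p subset fits)")

    df = data[[response, group_col] + predictors].replace(
        [np.inf, -np.inf], np.nan
    ).dropna()

    r2_by_subset: Dict[frozenset, float] = {frozenset(): 0.0}
    cond_full = marg_full = 0.0
    for r in range(1, len(predictors) + 1):
        for S in itertools.combinations(predictors, r):
            fit = fit_lmm(df, response, list(S), group=group_col)
            r2 = r2_nakagawa(fit)
            r2_by_subset[frozenset(S)] = r2["marginal"]
            if r == len(predictors):
                marg_full, cond_full = r2["marginal"], r2["conditional"]

    contrib = shapley_contributions(r2_by_subset, predictors)
    raw_pct = {j: 100.0 * v for j, v in contrib.items()}
    clipped = {j: max(v, 0.0) for j, v in raw_pct.items()}
    pos_total = sum(clipped.values())
    target = 100.0 * marg_full
    if pos_total > 0:
        adj = {j: v * target / pos_total for j, v in clipped.items()}
    else:
        adj = {j: 0.0 for j in clipped}
    if any(v < 0 for v in raw_pct.values()):
        log.info(
            "%s: negative hierarchical contributions truncated: %s",
            response,
            {j: round(v, 4) for j, v in raw_pct.items() if v < 0},
        )

    pred_df = pd.DataFrame(
        {
            "predictor": predictors,
            "group": [owner[j] for j in predictors],
            "raw_pct": [raw_pct[j] for j in predictors],
            "share_pct": [adj[j] for j in predictors],
        }
    )
    rows = []
    for g in groups:
        sub = pred_df[pred_df["group"] == g]
        rows.append(
            {"component": g, "share_pct": sub["share_pct"].sum(),
             "raw_pct": sub["raw_pct"].sum()}
        )
    random_pct = 100.0 * (cond_full - marg_full)
    unexplained = 100.0 - 100.0 * cond_full
    rows.append({"component": "random", "share_pct": random_pct, "raw_pct": random_pct})
    rows.append(
        {"component": "unexplained", "share_pct": unexplained, "raw_pct": unexplained}
    )
    shares = pd.DataFrame(rows)
    assert abs(shares["share_pct"].sum() - 100.0) < 1e-6
    return PartitionResult(
        response=response,
        shares=shares,
        predictor_contributions=pred_df,
        marginal_r2=marg_full,
        conditional_r2=cond_full,
    )


def partition_all_moments(
    moments_long: pd.DataFrame,
    env: pd.DataFrame,
    scheme: str = "TPS",
    traits: Sequence[str] = TRAITS,
) -> Tuple[pd.DataFrame, Dict[str, PartitionResult]]:
    """Variance partitioning of every trait x moment under one scheme."""
    from stomacomm.environment import scheme_pca_scores

    scores, _ = scheme_pca_scores(env, scheme)
    groups = {
        g: [f"{g}_PC1", f"{g}_PC2"]
        for g in group_names(scheme)
        if f"{g}_PC1" in scores.columns
    }
    responses = _prepare_responses(moments_long).merge(scores, on="site_id")
    rows = []
    results: Dict[str, PartitionResult] = {}
    for trait in traits:
        for moment in MOMENTS:
            col = f"{trait}_{moment}"
            res = hierarchical_partition(responses, col, groups)
            results[col] = res
            for rec in res.shares.itertuples():
                rows.append(
                    {"response": col, "trait": trait, "moment": moment,
                     "component": rec.component, "share_pct": rec.share_pct}
                )
    return pd.DataFrame(rows), results


def group_names(scheme: str) -> List[str]:
    from stomacomm.environment import group_variables

    return list(group_variables(scheme).keys())


def vegetation_contrast(
    moments_long: pd.DataFrame, traits: Sequence[str] = TRAITS
) -> pd.DataFrame:
    """Forest-grassland contrast per trait x moment.

    Fits ``response ~ vegetation + (1 | site)`` with forest coded 1 and
    grassland 0, so the coefficient is the forest minus grassland
    difference (on the log scale for CWM/CWV).
    """
    responses = _prepare_responses(moments_long)
    if "vegetation" not in responses.columns:
        raise ValueError("moments table has no vegetation column")
    levels = set(responses["vegetation"].dropna().unique())
    if not {"forest", "grassland"} <= levels:
        raise ValueError(f"both vegetation levels required, found {sorted(levels)}")
    responses = responses.assign(
        is_forest=(responses["vegetation"] == "forest").astype(float)
    )
    rows = []
    for trait in traits:
        for moment in MOMENTS:
            col = f"{trait}_{moment}"
            fit = fit_lmm(responses, col, ["is_forest"])
            rows.append(
                {
                    "trait": trait,
                    "moment": moment,
                    "contrast": float(fit.params["is_forest"]),
                    "se": float(fit.bse["is_forest"]),
                    "z": float(fit.params["is_forest"] / fit.bse["is_forest"]),
                    "pvalue": float(fit.pvalues["is_forest"]),
                    "n_obs": fit.n_obs,
                    "log_scale": moment in LOG_MOMENTS,
                }
            )
    return pd.DataFrame(rows)
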