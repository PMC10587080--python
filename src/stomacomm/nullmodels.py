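"""Trait-randomization null models and standardized effect sizes.

Environmental filtering is tested by shuffling trait values across all
species-site records while keeping each plot's species set and biomass
weights intact.  For each trait the test statistics are

    SES_var(CWM) = (var(CWM_obs) - mean(var(CWM_ran))) / sd(var(CWM_ran))
    SES_mean(X)  = (mean(X_obs)  - mean(mean(X_ran))) / sd(mean(X_ran))

for X in {CWV, CWS, CWK}, where var/mean/sd run across plots (inner) and
across randomizations (outer), with the sample (n-1) denominator.
Filtering predicts across-plot divergence of CWMs (positive SES of their
variance) and within-plot convergence (negative SES of the CWV/CWS/CWK
means).

By default the (SD, SL, SPI) triplet of each record is permuted jointly,
preserving the density-size trade-off inside the null so that only
community assembly is randomized; ``joint=False`` shuffles each trait
independently for sensitivity analysis.  The permutation pool is always
the full set of species-site records, including for the forest-only and
grassland-only strata; ``within_stratum=True`` restricts the pool to the
stratum's own records instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from stomacomm.moments import TRAITS, build_weight_matrix, weighted_moment_arrays

log = logging.getLogger(__name__)

MOMENT_STATS = (
    ("cwm", "var"),  # across-plot variance of CWMs
    ("cwv", "mean"),
    ("cws", "mean"),
    ("cwk", "mean"),
)


@dataclass(frozen=True)
class NullModelConfig:
    n_randomizations: int = 500
    seed: int = 0
    strata: str = "each"  # all | forest | grassland | each
    joint: bool = True  # permute (SD, SL, SPI) triplets jointly
    within_stratum: bool = False  # restrict permutation pool to the stratum
    log_scale: bool = False  # feed log(CWM)/log(CWV) into the statistics

    def __post_init__(self):
        if self.n_randomizations < 2:
            raise ValueError("n_randomizations must be >= 2")
        if self.strata not in ("all", "forest", "grassland", "each"):
            raise ValueError(f"unknown strata {self.strata!r}")


def permute_traits(
    species_traits: pd.DataFrame,
    rng: np.random.Generator,
    joint: bool = True,
    traits: Sequence[str] = TRAITS,
) -> pd.DataFrame:
    """Shuffle trait values across all species-site records.

    With ``joint=True`` the whole trait tuple of each record moves as
    one, so the multiset of (SD, SL, SPI) triplets is conserved exactly.
    """
    if len(species_traits) < 2:
        raise ValueError("need at least two species-site records")
    out = species_traits.copy()
    n = len(out)
    if joint:
        perm = rng.permutation(n)
        out[list(traits)] = out[list(traits)].to_numpy()[perm]
    else:
        for trait in traits:
            out[trait] = out[trait].to_numpy()[rng.permutation(n)]
    return out


def _stat(values: np.ndarray, kind: str, axis: int = 0) -> np.ndarray:
    """Across-plot summary; NaN plot values (undefined moments) are dropped."""
    if kind == "var":
        return _nanvar1(values, axis=axis)
    return np.nanmean(values, axis=axis)


def _nanvar1(values: np.ndarray, axis: int = 0) -> np.ndarray:
    n = np.sum(~np.isnan(values), axis=axis)
    with np.errstate(invalid="ignore"):
        v = np.nanvar(values, axis=axis, ddof=1)
    return np.where(n >= 2, v, np.nan)


def ses_statistics(observed: float, null: np.ndarray) -> Dict[str, float]:
    """SES of one observed statistic against its null draws."""
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    if null.size < 2:
        return {"null_mean": np.nan, "null_sd": np.nan, "ses": np.nan}
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0 or not np.isfinite(observed):
        log.warning("degenerate null distribution (sd=0) or undefined observation")
        return {"null_mean": null_mean, "null_sd": null_sd, "ses": np.nan}
    return {
        "null_mean": null_mean,
        "null_sd": null_sd,
        "ses": (float(observed) - null_mean) / null_sd,
    }


def _plot_masks(plot_meta: pd.DataFrame, strata: str) -> Dict[str, np.ndarray]:
    masks = {}
    names = ["all", "forest", "grassland"] if strata == "each" else [strata]
    for name in names:
        if name == "all":
            mask = np.ones(len(plot_meta), dtype=bool)
        else:
            if "vegetation" not in plot_meta.columns:
                raise ValueError("plots table has no vegetation column")
            mask = (plot_meta["vegetation"] == name).to_numpy()
        if mask.sum() < 2:
            log.warning("stratum %r has < 2 plots; skipped", name)
            continue
        masks[name] = mask
    return masks


def _moment_matrices(W, t_obs, t_null):
    """(obs arrays, null arrays) of plot moments; null has shape (plots, K)."""
    obs = weighted_moment_arrays(W, t_obs)
    null = weighted_moment_arrays(W, t_null)
    return obs, null


def run_null_model(
    species_traits: pd.DataFrame,
    plots: pd.DataFrame,
    config: NullModelConfig = NullModelConfig(),
    traits: Sequence[str] = TRAITS,
) -> pd.DataFrame:
    """SES table for traits x moments x strata.

    Returns one row per trait x moment x stratum with columns
    ``trait, moment, stratum, observed, null_mean, null_sd, ses,
    filtering_consistent, n_randomizations, seed``.
    """
    rng = np.random.default_rng(config.seed)
    W, plot_meta, records = build_weight_matrix(species_traits, plots)
    n_rec = len(records)
    if n_rec < 2:
        raise ValueError("need at least two species-site records")
    masks = _plot_masks(plot_meta, config.strata)
    K = config.n_randomizations

    # permutation index matrix, one column per randomization
    def draw_perms(pool: np.ndarray) -> np.ndarray:
        idx = np.tile(np.arange(n_rec)[:, None], (1, K))
        for k in range(K):
            idx[pool, k] = pool[rng.permutation(pool.size)]
        return idx

    full_pool = np.arange(n_rec)
    site_veg = None
    if "vegetation" in plots.columns:
        site_veg = (
            plots[["site_id", "vegetation"]]
            .drop_duplicates("site_id")
            .set_index("site_id")["vegetation"]
        )

    T = records[list(traits)].to_numpy(dtype=float)
    rows = []
    for stratum, mask in masks.items():
        if config.within_stratum and stratum != "all":
            if site_veg is None:
                raise ValueError("within_stratum requires a vegetation column")
            pool = np.flatnonzero(
                records["site_id"].map(site_veg).to_numpy() == stratum
            )
            if pool.size < 2:
                log.warning("stratum %r has < 2 records for permutation; skipped", stratum)
                continue
        else:
            pool = full_pool

        if config.joint:
            perms = draw_perms(pool)  # shared across traits
        for j, trait in enumerate(traits):
            if not config.joint:
                perms = draw_perms(pool)
            t = T[:, j]
            t_null = t[perms]  # (n_rec, K)
            (m_obs, v_obs, s_obs, k_obs), (m_n, v_n, s_n, k_n) = _moment_matrices(
                W[mask], t, t_null
            )
            obs_by = {"cwm": m_obs, "cwv": v_obs, "cws": s_obs, "cwk": k_obs}
            null_by = {"cwm": m_n, "cwv": v_n, "cws": s_n, "cwk": k_n}
            if config.log_scale:
                with np.errstate(divide="ignore", invalid="ignore"):
                    for key in ("cwm", "cwv"):
                        obs_by[key] = np.where(
                            obs_by[key] > 0, np.log(np.maximum(obs_by[key], 1e-300)), np.nan
                        )
                        null_by[key] = np.where(
                            null_by[key] > 0,
                            np.log(np.maximum(null_by[key], 1e-300)),
                            np.nan,
                        )
            for moment, kind in MOMENT_STATS:
                observed = float(_stat(obs_by[moment], kind, axis=0))
                null_stats = _stat(null_by[moment], kind, axis=0)  # (K,)
                ses = ses_statistics(observed, null_stats)
                sign_ok = ses["ses"] > 0 if moment == "cwm" else ses["ses"] < 0
                rows.append(
                    {
                        "trait": trait,
                        "moment": moment,
                        "stratum": stratum,
                        "statistic": f"{kind}(CW{moment[-1].upper()})",
                        "observed": observed,
                        "null_mean": ses["null_mean"],
                        "null_sd": ses["null_sd"],
                        "ses": ses["ses"],
                        "filtering_consistent": bool(sign_ok)
                        if np.isfinite(ses["ses"])
                        else None,
                        "n_randomizations": K,
                        "seed": config.seed,
                    }
                )
    return pd.DataFrame(rows)
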