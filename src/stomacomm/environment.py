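"""Bioclimatic variables, growing season, variable groups and group PCA.

From per-site monthly climate (mean/min/max temperature, precipitation,
potential evapotranspiration) this module derives the 19 standard
bioclim summaries (bio1-bio19), the UNEP aridity index MAP/PET, and
growing-season temperature/precipitation/aridity, then assembles soil
variables, partitions the variables under two grouping schemes and runs
a per-group PCA whose first two axes feed the mixed-model analyses.

Quarters are the 12 rolling 3-month windows with December-January
wraparound; the wettest/driest quarter is the window with the extreme
precipitation sum and the warmest/coldest the one with the extreme mean
temperature, ties broken by the earliest window.  Temperature
seasonality (bio4) is the sample standard deviation of monthly means
x 100 and precipitation seasonality (bio15) the plain coefficient of
variation x 100 (``cv_guard=True`` switches the denominator to
1 + bio12/12, the dialect some tools use for arid sites).

The growing season is the longest circular run of months with monthly
mean temperature >= 5 degC and monthly precipitation/PET >= 0.05; ties
between equally long runs are broken in favour of the run containing
the warmest month, then the earliest start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

BIOCLIM_VARS = [f"bio{i}" for i in range(1, 20)]
GROWING_SEASON_VARS = ["gst", "gsp", "gsai"]
CLIMATE_VARS = BIOCLIM_VARS + ["aridity_index"] + GROWING_SEASON_VARS  # 23
SOIL_VARS = ["bulk_density", "soil_n", "soil_ph", "sand", "silt", "clay", "soil_moisture"]

# the 27 variables entering the regression scans and variance partitioning:
# bio1-bio19 + aridity index + the 7 soil variables (growing-season summaries
# are derived and reported but belong to no group)
MODEL_CLIMATE_VARS = BIOCLIM_VARS + ["aridity_index"]
MODEL_VARS = MODEL_CLIMATE_VARS + SOIL_VARS

GROUP_SCHEMES = {
    "TPS": {
        "temperature": [f"bio{i}" for i in range(1, 12)],
        "precipitation": [f"bio{i}" for i in range(12, 20)] + ["aridity_index"],
        "soil": SOIL_VARS,
    },
    "mean_seas_extreme": {
        "climatic_mean": ["bio1", "bio12", "aridity_index"],
        "climatic_seasonality": ["bio2", "bio3", "bio4", "bio7", "bio15"],
        "climatic_extreme": [
            "bio5", "bio6", "bio8", "bio9", "bio10", "bio11",
            "bio13", "bio14", "bio16", "bio17", "bio18", "bio19",
        ],
        "soil": SOIL_VARS,
    },
}


def _check_monthly(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (12,):
        raise ValueError(f"{name} must have 12 monthly values, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _quarter_windows() -> np.ndarray:
    """Indices of the 12 wrapping 3-month windows, one row per start month."""
    base = np.arange(12)
    return np.stack([(base + k) % 12 for k in range(3)], axis=1)


_WINDOWS = _quarter_windows()


def bioclim(
    tmean: Sequence[float],
    tmin: Sequence[float],
    tmax: Sequence[float],
    prec: Sequence[float],
    cv_guard: bool = False,
) -> Dict[str, float]:
    """The 19 standard bioclim variables from monthly climate."""
    tmean = _check_monthly("tmean", tmean)
    tmin = _check_monthly("tmin", tmin)
    tmax = _check_monthly("tmax", tmax)
    prec = _check_monthly("prec", prec)
    if np.any(tmin > tmean) or np.any(tmean > tmax):
        raise ValueError("monthly tmin <= tmean <= tmax violated")

    qt = tmean[_WINDOWS].mean(axis=1)  # quarter mean temperature
    qp = prec[_WINDOWS].sum(axis=1)  # quarter precipitation

    b: Dict[str, float] = {}
    b["bio1"] = float(tmean.mean())
    b["bio2"] = float((tmax - tmin).mean())
    b["bio5"] = float(tmax.max())
    b["bio6"] = float(tmin.min())
    b["bio7"] = b["bio5"] - b["bio6"]
    b["bio3"] = 100.0 * b["bio2"] / b["bio7"] if b["bio7"] != 0 else 0.0
    b["bio4"] = float(tmean.std(ddof=1)) * 100.0
    b["bio8"] = float(qt[np.argmax(qp)])
    b["bio9"] = float(qt[np.argmin(qp)])
    b["bio10"] = float(qt[np.argmax(qt)])
    b["bio11"] = float(qt[np.argmin(qt)])
    b["bio12"] = float(prec.sum())
    b["bio13"] = float(prec.max())
    b["bio14"] = float(prec.min())
    pmean = (1.0 + b["bio12"] / 12.0) if cv_guard else float(prec.mean())
    b["bio15"] = 100.0 * float(prec.std(ddof=1)) / pmean if pmean > 0 else 0.0
    b["bio16"] = float(qp.max())
    b["bio17"] = float(qp.min())
    b["bio18"] = float(qp[np.argmax(qt)])
    b["bio19"] = float(qp[np.argmin(qt)])
    return {k: b[k] for k in BIOCLIM_VARS}


def aridity_index(map_mm: float, pet_annual_mm: float) -> float:
    """UNEP aridity index: mean annual precipitation / annual PET."""
    if pet_annual_mm <= 0 or not np.isfinite(pet_annual_mm):
        raise ValueError("annual PET must be positive")
    if map_mm < 0:
        raise ValueError("MAP must be non-negative")
    return float(map_mm) / float(pet_annual_mm)


def growing_season(
    tmean: Sequence[float],
    prec: Sequence[float],
    pet: Sequence[float],
    t_threshold: float = 5.0,
    ratio_threshold: float = 0.05,
) -> np.ndarray:
    """Month indices (0-based, in run order) of the growing season.

    The longest circular run of months with tmean >= 5 degC and
    prec/PET >= 0.05; months with PET = 0 fail the moisture condition by
    convention.  Returns an empty array when no month qualifies.
    """
    tmean = _check_monthly("tmean", tmean)
    prec = _check_monthly("prec", prec)
    pet = _check_monthly("pet", pet)
    if np.any(pet < 0):
        raise ValueError("PET must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pet > 0, prec / np.where(pet > 0, pet, 1.0), -np.inf)
    q = (tmean >= t_threshold) & (ratio >= ratio_threshold)
    if q.all():
        return np.arange(12)
    if not q.any():
        return np.array([], dtype=int)

    runs: List[np.ndarray] = []
    starts = [i for i in range(12) if q[i] and not q[(i - 1) % 12]]
    for s in starts:
        months = [s]
        while q[(months[-1] + 1) % 12]:
            months.append((months[-1] + 1) % 12)
        runs.append(np.array(months, dtype=int))
    longest = max(len(r) for r in runs)
    candidates = [r for r in runs if len(r) == longest]
    if len(candidates) > 1:
        warmest = int(np.argmax(tmean))
        holding = [r for r in candidates if warmest in r]
        if holding:
            candidates = holding
        candidates.sort(key=lambda r: int(r[0]))
    return candidates[0]


def growing_season_summaries(
    tmean: Sequence[float], prec: Sequence[float], pet: Sequence[float]
) -> Dict[str, float]:
    """gst (mean tmean, degC), gsp (precip sum, mm), gsai (gsp / season PET)."""
    months = growing_season(tmean, prec, pet)
    if months.size == 0:
        return {"gst": np.nan, "gsp": np.nan, "gsai": np.nan}
    tmean = np.asarray(tmean, dtype=float)
    prec = np.asarray(prec, dtype=float)
    pet = np.asarray(pet, dtype=float)
    gsp = float(prec[months].sum())
    pet_sum = float(pet[months].sum())
    return {
        "gst": float(tmean[months].mean()),
        "gsp": gsp,
        "gsai": gsp / pet_sum if pet_sum > 0 else np.nan,
    }


CLIMATE_LONG_COLUMNS = ["site_id", "month", "tmean", "tmin", "tmax", "prec", "pet"]


def derive_site_variables(
    climate: pd.DataFrame,
    soil: Optional[pd.DataFrame] = None,
    cv_guard: bool = False,
) -> pd.DataFrame:
    """One row per site with the 23 climatic variables (+ soil).

    ``climate`` is a long table with columns site_id, month (1-12),
    tmean, tmin, tmax, prec, pet; ``soil`` (optional) one row per site
    with the soil columns.  Output columns: site_id, bio1..bio19, mat,
    map, aridity_index, gst, gsp, gsai and any soil variables.  mat and
    map are aliases of bio1 and bio12 kept for readability.
    """
    missing = [c for c in CLIMATE_LONG_COLUMNS if c not in climate.columns]
    if missing:
        raise ValueError(f"climate table missing columns {missing}")
    rows = []
    for site_id, grp in climate.groupby("site_id", sort=True):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"site {site_id!r}: months must be exactly 1..12")
        tmean = grp["tmean"].to_numpy(float)
        tmin = grp["tmin"].to_numpy(float)
        tmax = grp["tmax"].to_numpy(float)
        prec = grp["prec"].to_numpy(float)
        pet = grp["pet"].to_numpy(float)
        row: Dict[str, float] = {"site_id": site_id}
        row.update(bioclim(tmean, tmin, tmax, prec, cv_guard=cv_guard))
        row["mat"] = row["bio1"]
        row["map"] = row["bio12"]
        row["aridity_index"] = aridity_index(row["bio12"], float(pet.sum()))
        row.update(growing_season_summaries(tmean, prec, pet))
        rows.append(row)
    env = pd.DataFrame(rows)
    if soil is not None:
        unknown = [c for c in soil.columns if c not in ["site_id"] + SOIL_VARS]
        if unknown:
            raise ValueError(f"unknown soil columns {unknown}")
        env = env.merge(soil, on="site_id", how="left")
        texture = env[["sand", "silt", "clay"]].sum(axis=1)
        if np.any(np.abs(texture - 100.0) > 1.0):
            raise ValueError("sand + silt + clay must be ~100%")
    return env


def group_variables(scheme: str = "TPS") -> Dict[str, List[str]]:
    """Named variable groups under one of the two grouping schemes.

    ``TPS``: temperature / precipitation / soil, with the aridity index
    grouped with precipitation.  ``mean_seas_extreme`` (alias ``mse``):
    climatic mean / seasonality / extreme / soil, with MAT, MAP and the
    aridity index forming the mean group.
    """
    key = {"mse": "mean_seas_extreme"}.get(scheme, scheme)
    if key not in GROUP_SCHEMES:
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    return {g: list(v) for g, v in GROUP_SCHEMES[key].items()}


@dataclass(frozen=True)
class GroupPCA:
    group: str
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # site_id, PC1, PC2
    variance_explained: np.ndarray  # % per retained axis
    all_variance: np.ndarray  # % per full-rank axis, sums to 100
    dropped: Tuple[str, ...] = ()


def group_pca(
    env: pd.DataFrame, columns: Sequence[str], group: str = "", n_components: int = 2
) -> GroupPCA:
    """PCA of standardized variables, first two axes retained.

    Constant columns are dropped with a warning.  Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    if len(env) < 3:
        raise ValueError("need at least 3 sites")
    cols = list(columns)
    X = env[cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError(f"non-finite values in columns {cols}")
    sd = X.std(axis=0)
    dropped = tuple(c for c, s in zip(cols, sd) if s == 0)
    if dropped:
        log.warning("constant columns dropped from PCA: %s", dropped)
        keep = [c for c in cols if c not in dropped]
        cols, X = keep, env[keep].to_numpy(dtype=float)
        sd = X.std(axis=0)
    if len(cols) < 2:
        raise ValueError("need at least 2 non-constant variables")
    Z = (X - X.mean(axis=0)) / sd

    k_full = min(Z.shape)
    pca = PCA(n_components=k_full)
    scores_full = pca.fit_transform(Z)
    all_var = pca.explained_variance_ratio_ * 100.0

    k = min(n_components, k_full)
    load = pca.components_[:k].T.copy()  # variables x components
    scores = scores_full[:, :k].copy()
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return GroupPCA(
        group=group,
        loadings=pd.DataFrame(load, index=cols, columns=comp_names),
        scores=pd.DataFrame(
            {"site_id": env["site_id"].to_numpy(), **{c: scores[:, j] for j, c in enumerate(comp_names)}}
        ),
        variance_explained=all_var[:k],
        all_variance=all_var,
        dropped=dropped,
    )


def scheme_pca_scores(
    env: pd.DataFrame, scheme: str = "TPS"
) -> Tuple[pd.DataFrame, Dict[str, GroupPCA]]:
    """Per-site PC1/PC2 scores for every group of a scheme.

    Returns (scores table with columns site_id, <group>_PC1, <group>_PC2,
    dict of per-group GroupPCA results).
    """
    groups = group_variables(scheme)
    scores = env[["site_id"]].copy()
    results: Dict[str, GroupPCA] = {}
    for name, cols in groups.items():
        res = group_pca(env, cols, group=name)
        results[name] = res
        for comp in ("PC1", "PC2"):
            if comp in res.scores.columns:
                scores[f"{name}_{comp}"] = res.scores[comp].to_numpy()
    return scores, results
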