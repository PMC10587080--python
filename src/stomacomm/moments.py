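"""Biomass-weighted community trait moments.

For a plot with species relative biomass weights p_i (sum 1) and trait
values t_i, the community-weighted moments are

    CWM = sum_i p_i t_i
    CWV = sum_i p_i (t_i - CWM)^2
    CWS = sum_i p_i (t_i - CWM)^3 / CWV^(3/2)
    CWK = sum_i p_i (t_i - CWM)^4 / CWV^2

These are population (biased) moments with no small-sample correction,
and CWK is non-excess (a normal-shaped distribution gives 3; the lower
bound CWK >= CWS^2 + 1 is attained by two-point distributions).  When
CWV = 0 (e.g. a single-species plot) CWS and CWK are undefined and
encoded as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRAITS = ("SD", "SL", "SPI")
MOMENTS = ("cwm", "cwv", "cws", "cwk")


@dataclass(frozen=True)
class TraitMoments:
    """CWM/CWV/CWS/CWK of one trait in one plot."""

    mean: float
    variance: float
    skewness: float  # NaN when variance == 0
    kurtosis: float  # NaN when variance == 0
    n_species: int
    plot_id: Optional[str] = None
    trait: Optional[str] = None


def normalize_weights(weights: Sequence[float]) -> np.ndarray:
    """Convert biomass weights to proportions summing to 1.

    Zero-weight entries are dropped.  Raises on negative, non-finite or
    all-zero weights.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    w = w[w > 0]
    return w / w.sum()


def community_moments(
    traits: Sequence[float], weights: Sequence[float]
) -> TraitMoments:
    """Weighted mean, variance, skewness and kurtosis of one plot.

    ``weights`` need not be pre-normalized; zero-weight species are
    dropped (they contribute to no moment).
    """
    t = np.asarray(traits, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape or t.ndim != 1:
        raise ValueError("traits and weights must be 1-d of equal length")
    if not np.all(np.isfinite(t)):
        raise ValueError("trait values must be finite")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and non-negative")
    keep = w > 0
    if not keep.any():
        raise ValueError("all weights are zero")
    t, w = t[keep], w[keep]
    p = w / w.sum()

    mean = float(p @ t)
    d = t - mean
    var = float(p @ d**2)
    if var > 0:
        skew = float(p @ d**3) / var**1.5
        kurt = float(p @ d**4) / var**2
    else:
        var = 0.0
        skew = np.nan
        kurt = np.nan
    return TraitMoments(
        mean=mean, variance=var, skewness=skew, kurtosis=kurt, n_species=int(t.size)
    )


def weighted_moment_arrays(W: np.ndarray, t: np.ndarray):
    """Vectorized plot moments for a plot x record weight matrix.

    ``W`` has one row per plot with non-negative weights summing to 1;
    ``t`` is a record trait vector or a record x K matrix (e.g. one
    column per trait randomization).  Returns (mean, var, skew, kurt)
    arrays with a leading plot axis.  Trait values are standardized
    internally so the power-sum expansion stays well conditioned.
    """
    t = np.asarray(t, dtype=float)
    mu = t.mean()
    s = t.std()
    if s == 0:
        s = 1.0
    z = (t - mu) / s
    m1 = W @ z
    m2 = W @ z**2
    m3 = W @ z**3
    m4 = W @ z**4
    var = m2 - m1**2
    np.clip(var, 0.0, None, out=var)
    c3 = m3 - 3 * m1 * m2 + 2 * m1**3
    c4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
    # guard: single-species plots (or exact ties) have no defined shape
    tiny = np.maximum(m2 - m1**2, 0) <= 1e-12 * np.maximum(m2, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(tiny, np.nan, c3 / np.where(var > 0, var, 1.0) ** 1.5)
        kurt = np.where(tiny, np.nan, c4 / np.where(var > 0, var, 1.0) ** 2)
    mean = mu + s * m1
    var = s * s * var
    var = np.where(tiny, 0.0, var)
    return mean, var, skew, kurt


def build_weight_matrix(species_traits: pd.DataFrame, plots: pd.DataFrame):
    """Row-normalized plot x species-site-record weight matrix.

    Records are the unique (species_id, site_id) pairs of
    ``species_traits``; plot entries that resolve to no record are
    dropped (with a log message) and the remaining weights renormalized.
    Returns ``(W, plot_meta, records)`` where ``plot_meta`` has one row
    per plot (plot_id, site_id, vegetation, n_species) aligned with the
    rows of W, and ``records`` is the species_traits subframe aligned
    with the columns of W.
    """
    st = species_traits.reset_index(drop=True)
    key = pd.MultiIndex.from_frame(st[["species_id", "site_id"]])
    if key.duplicated().any():
        raise ValueError("duplicate (species_id, site_id) rows in species_traits")
    record_index = pd.Series(np.arange(len(st)), index=key)

    merged = plots.merge(
        st[["species_id", "site_id"]].assign(_rec=np.arange(len(st))),
        on=["species_id", "site_id"],
        how="left",
    )
    n_missing = int(merged["_rec"].isna().sum())
    if n_missing:
        log.warning(
            "%d plot entries have no matching species-site trait record; dropped "
            "and plot weights renormalized",
            n_missing,
        )
        merged = merged.dropna(subset=["_rec"])
    if merged.empty:
        raise ValueError("no plot entry resolves to a trait record")

    plot_ids = merged["plot_id"].drop_duplicates().to_numpy()
    plot_pos = {p: i for i, p in enumerate(plot_ids)}
    W = np.zeros((len(plot_ids), len(st)))
    rows = merged["plot_id"].map(plot_pos).to_numpy()
    cols = merged["_rec"].to_numpy(dtype=int)
    np.add.at(W, (rows, cols), merged["weight"].to_numpy(dtype=float))
    totals = W.sum(axis=1)
    if np.any(totals <= 0):
        bad = plot_ids[totals <= 0]
        raise ValueError(f"plots with zero total weight: {list(bad)[:5]}")
    W /= totals[:, None]

    meta_cols = ["plot_id", "site_id"]
    if "vegetation" in plots.columns:
        meta_cols.append("vegetation")
    plot_meta = (
        plots[meta_cols].drop_duplicates("plot_id").set_index("plot_id").loc[plot_ids]
    ).reset_index()
    plot_meta["n_species"] = (W > 0).sum(axis=1)
    return W, plot_meta, st


def moments_table(
    species_traits: pd.DataFrame,
    plots: pd.DataFrame,
    traits: Sequence[str] = TRAITS,
) -> pd.DataFrame:
    """Long-format moments for every plot x trait.

    Parameters
    ----------
    species_traits : columns species_id, site_id and one column per trait.
    plots : long composition table with columns plot_id, site_id,
        vegetation, species_id, weight (biomass, any non-negative unit).

    Returns a frame with columns ``plot_id, site_id, vegetation, trait,
    moment, value, n_species`` (moments: cwm, cwv, cws, cwk).  Plot
    species missing a trait record are dropped from that plot with the
    weights renormalized; a plot losing all species yields NaN moments.
    """
    W, plot_meta, records = build_weight_matrix(species_traits, plots)
    lost = plots.loc[
        ~plots["plot_id"].isin(plot_meta["plot_id"]),
        [c for c in ("plot_id", "site_id", "vegetation") if c in plots.columns],
    ].drop_duplicates("plot_id")
    if len(lost):
        log.warning(
            "%d plots lost every species to missing trait records; emitted with "
            "undefined moments",
            len(lost),
        )
        lost = lost.assign(n_species=0)
        plot_meta = pd.concat([plot_meta, lost], ignore_index=True)
        W = np.vstack([W, np.zeros((len(lost), W.shape[1]))])
    out = []
    for trait in traits:
        t = records[trait].to_numpy(dtype=float)
        mean, var, skew, kurt = weighted_moment_arrays(W, t)
        for moment, vals in zip(MOMENTS, (mean, var, skew, kurt)):
            block = plot_meta.copy()
            block["trait"] = trait
            block["moment"] = moment
            block["value"] = np.where(block["n_species"] > 0, vals, np.nan)
            out.append(block)
    cols = ["plot_id", "site_id"]
    if "vegetation" in plot_meta.columns:
        cols.append("vegetation")
    cols += ["trait", "moment", "value", "n_species"]
    return pd.concat(out, ignore_index=True)[cols]


def pivot_moments(long_table: pd.DataFrame) -> pd.DataFrame:
    """Widen the long moments table to one row per plot x trait."""
    idx = ["plot_id", "site_id"]
    if "vegetation" in long_table.columns:
        idx.append("vegetation")
    idx += ["trait", "n_species"]
    wide = (
        long_table.pivot(index=idx, columns="moment", values="value")
        .reset_index()
        .rename_axis(columns=None)
    )
    return wide


def fold_range(values: Sequence[float]) -> float:
    """max/min ratio of a strictly positive vector (>= 2 values)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("values must be finite and strictly positive")
    return float(v.max() / v.min())
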