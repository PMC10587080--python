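"""Synthetic survey generator with known ground truth.

Emulates a regional vegetation survey: a species pool with a log-scale
negative density-size trade-off, sites spanning a temperature and
precipitation gradient with sinusoidal monthly climate and correlated
soil properties, plots nested in sites with lognormal biomass weights,
and Gaussian environmental filtering of community trait composition
along a standardized climate score.

Defaults mirror the survey design the pipeline is built for: 57 sites
(28 forest with 4 plots each, 29 grassland with 8 plots each, i.e.
112 + 232 plots), species stomatal length spanning 17-47 um, and a
trade-off slope of -1.3 on the log10 scale.  ``filtering_strength = 0``
yields neutral assembly (uniform species sampling), the null scenario
used to calibrate the SES machinery.

Filtering model: for site i with standardized climate score z_i the
optimal standardized log10 stomatal density is ``env_effect_slope *
z_i``; a species with standardized log10 density u is included in a
plot's sample with probability proportional to
``exp(-F_i (u - opt_i)^2 / 2)`` where F_i is ``filtering_strength``
(times ``grassland_filter_factor`` in grasslands).  The quantitative
form is a standard Gaussian-filter choice, not a field measurement.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from stomacomm.environment import derive_site_variables
from stomacomm.traits import SPI_PERCENT_FACTOR

SL_LOG10_RANGE = (float(np.log10(17.0)), float(np.log10(47.0)))


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int = 400
    n_sites: int = 57
    plots_per_site: int = 6
    species_per_plot_mean: int = 15
    tradeoff_intercept: float = 4.3  # log10 pores mm^-2 at log10(SL) = 0
    tradeoff_slope: float = -1.3
    trait_noise_sd: float = 0.15  # log10 units around the trade-off line
    filtering_strength: float = 1.0  # 0 = neutral assembly
    env_effect_slope: float = 0.8  # standardized trait units per env sd
    abundance_lognormal_sd: float = 1.0
    seed: int = 0
    # survey-design extensions
    n_forest_sites: Optional[int] = None  # default: n_sites // 2
    plots_per_site_forest: Optional[int] = None  # default: plots_per_site
    plots_per_site_grassland: Optional[int] = None
    grassland_filter_factor: float = 1.5  # grassland filtering multiplier
    sl_log10_range: Tuple[float, float] = SL_LOG10_RANGE

    def __post_init__(self):
        for name in ("n_species", "n_sites", "plots_per_site", "species_per_plot_mean"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be >= 0")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be >= 0")
        if self.abundance_lognormal_sd < 0:
            raise ValueError("abundance_lognormal_sd must be >= 0")
        if self.grassland_filter_factor <= 0:
            raise ValueError("grassland_filter_factor must be > 0")
        nf = self.forest_sites
        if not 0 <= nf <= self.n_sites:
            raise ValueError("n_forest_sites out of range")

    @property
    def forest_sites(self) -> int:
        return self.n_sites // 2 if self.n_forest_sites is None else self.n_forest_sites

    def plots_for(self, vegetation: str) -> int:
        if vegetation == "forest" and self.plots_per_site_forest is not None:
            return self.plots_per_site_forest
        if vegetation == "grassland" and self.plots_per_site_grassland is not None:
            return self.plots_per_site_grassland
        return self.plots_per_site


def study_design_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Config emulating the survey layout (28 forest x 4, 29 grassland x 8)."""
    kwargs = dict(
        n_species=600,
        n_sites=57,
        n_forest_sites=28,
        plots_per_site_forest=4,
        plots_per_site_grassland=8,
        species_per_plot_mean=20,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@dataclass
class SyntheticDataset:
    species_traits: pd.DataFrame  # species_id, site_id, SD, SL, SPI
    plots: pd.DataFrame  # plot_id, site_id, vegetation, species_id, weight
    climate: pd.DataFrame  # long monthly climate per site
    soil: pd.DataFrame  # one row per site
    environment: pd.DataFrame  # derived per-site variable set
    sites: pd.DataFrame  # site_id, vegetation, climate_score, trait_optimum
    pool: pd.DataFrame  # full species pool (species_id, SD, SL, SPI)
    truth: Dict = field(default_factory=dict)


def _streams(seed: int):
    pool_ss, env_ss, asm_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(pool_ss),
        np.random.default_rng(env_ss),
        np.random.default_rng(asm_ss),
    )


def generate_species_pool(
    config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Locally measured traits: one row per species x site record.

    Per record, log10(SL) ~ Uniform over ``sl_log10_range`` and
    log10(SD) = intercept + slope*log10(SL) + Normal(0, trait_noise_sd),
    independently across records.  Drawing each species-site combination
    independently mirrors a survey that measures traits locally (strong
    intraspecific, between-site variation) and makes the neutral
    assembly scenario exchangeable under the record-level permutation
    null, which is what calibrates the SES machinery.  Non-finite draws
    are resampled; all traits are strictly positive by construction.
    """
    lo, hi = config.sl_log10_range
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("invalid sl_log10_range")
    n = config.n_species * config.n_sites
    log_sl = rng.uniform(lo, hi, size=n)
    log_sd = (
        config.tradeoff_intercept
        + config.tradeoff_slope * log_sl
        + rng.normal(0.0, config.trait_noise_sd, size=n)
    )
    bad = ~(np.isfinite(log_sl) & np.isfinite(log_sd))
    while bad.any():  # pragma: no cover - finite by construction
        log_sl[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
        log_sd[bad] = (
            config.tradeoff_intercept
            + config.tradeoff_slope * log_sl[bad]
            + rng.normal(0.0, config.trait_noise_sd, size=int(bad.sum()))
        )
        bad = ~(np.isfinite(log_sl) & np.isfinite(log_sd))
    sl = 10.0**log_sl
    sd = 10.0**log_sd
    species = [f"sp{i:04d}" for i in range(config.n_species)]
    sites = [f"site{i:03d}" for i in range(config.n_sites)]
    return pd.DataFrame(
        {
            "species_id": np.repeat(species, config.n_sites),
            "site_id": np.tile(sites, config.n_species),
            "SD": sd,
            "SL": sl,
            "SPI": sd * sl * sl * SPI_PERCENT_FACTOR,
        }
    )


def generate_environment(
    config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Monthly climate, soil table and site metadata.

    Each site gets a latent gradient position g ~ N(0,1) driving mean
    annual temperature (approx -6..22 degC) and log annual
    precipitation (approx 150..1800 mm); monthly series follow a
    July-peaking sinusoid, precipitation is monsoon-concentrated in
    summer, and PET increases with temperature (always positive).  Soil
    texture, pH, nitrogen, bulk density and moisture co-vary with the
    precipitation gradient.  The standardized climate score (z of log
    MAP across sites) is stored per site and later drives filtering.
    Vegetation: the wettest ``forest_sites`` sites are forest.
    """
    ns = config.n_sites
    g = rng.normal(0.0, 1.0, size=ns)
    mat = 8.0 + 9.0 * g + rng.normal(0.0, 3.0, size=ns)
    log_map = 6.3 + 0.55 * g + rng.normal(0.0, 0.35, size=ns)
    map_mm = np.exp(log_map)
    amp = np.clip(18.0 - 0.5 * mat + rng.normal(0.0, 2.0, size=ns), 2.0, 26.0)
    dtr = np.clip(10.0 + rng.normal(0.0, 2.0, size=ns), 4.0, 18.0)

    months = np.arange(1, 13)
    phase = np.cos(2.0 * np.pi * (months - 7) / 12.0)  # +1 in July
    conc = 1.2  # summer precipitation concentration
    pw = np.exp(conc * phase)
    pw = pw / pw.sum()

    clim_rows = []
    for i in range(ns):
        tmean = mat[i] + amp[i] * phase
        prec = map_mm[i] * pw
        pet = 20.0 + 4.5 * np.clip(tmean, 0.0, None)
        for m in range(12):
            clim_rows.append(
                {
                    "site_id": f"site{i:03d}",
                    "month": int(months[m]),
                    "tmean": tmean[m],
                    "tmin": tmean[m] - dtr[i] / 2.0,
                    "tmax": tmean[m] + dtr[i] / 2.0,
                    "prec": prec[m],
                    "pet": pet[m],
                }
            )
    climate = pd.DataFrame(clim_rows)

    z_map = (log_map - log_map.mean()) / (log_map.std() if log_map.std() > 0 else 1.0)
    pet_annual = climate.groupby("site_id")["pet"].sum().to_numpy()
    ai = map_mm / pet_annual
    sand = np.clip(65.0 - 20.0 * z_map + rng.normal(0.0, 8.0, size=ns), 5.0, 92.0)
    clay = np.clip(
        0.45 * (100.0 - sand) + rng.normal(0.0, 4.0, size=ns), 2.0, None
    )
    clay = np.minimum(clay, (100.0 - sand) - 2.0)
    silt = 100.0 - sand - clay
    soil = pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(ns)],
            "bulk_density": np.clip(
                1.45 - 0.10 * z_map + rng.normal(0.0, 0.08, size=ns), 0.8, 1.8
            ),
            "soil_n": np.exp(0.2 + 0.5 * z_map + rng.normal(0.0, 0.3, size=ns)),
            "soil_ph": np.clip(
                8.2 - 1.1 * z_map + rng.normal(0.0, 0.4, size=ns), 4.0, 9.5
            ),
            "sand": sand,
            "silt": silt,
            "clay": clay,
            "soil_moisture": np.clip(
                0.08 + 0.15 * np.minimum(ai, 2.0) + rng.normal(0.0, 0.03, size=ns),
                0.01,
                0.6,
            ),
        }
    )

    order = np.argsort(-map_mm)  # wettest sites first
    vegetation = np.full(ns, "grassland", dtype=object)
    vegetation[order[: config.forest_sites]] = "forest"
    sites = pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(ns)],
            "vegetation": vegetation,
            "climate_score": z_map,
            "mat": mat,
            "map": map_mm,
        }
    )
    return climate, soil, sites


def assemble_communities(
    pool: pd.DataFrame,
    sites: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sample plot compositions under Gaussian environmental filtering.

    Returns (plots, sites-with-optima).  With ``filtering_strength = 0``
    species are sampled uniformly; biomass weights are lognormal
    (equal weights when ``abundance_lognormal_sd = 0``).
    """
    if pool.empty or sites.empty:
        raise ValueError("pool and sites must be non-empty")
    log_sd_all = np.log10(pool["SD"].to_numpy(dtype=float))
    mu, sd = log_sd_all.mean(), log_sd_all.std()
    sd = sd if sd > 0 else 1.0

    sites = sites.copy()
    sites["trait_optimum"] = config.env_effect_slope * sites["climate_score"]

    by_site = dict(tuple(pool.groupby("site_id", sort=True)))
    rows = []
    plot_counter = 0
    for site in sites.itertuples():
        local = by_site.get(site.site_id)
        if local is None or local.empty:
            raise ValueError(f"no trait records for {site.site_id}")
        u = (np.log10(local["SD"].to_numpy(dtype=float)) - mu) / sd
        F = config.filtering_strength * (
            config.grassland_filter_factor if site.vegetation == "grassland" else 1.0
        )
        w = np.exp(-F * (u - site.trait_optimum) ** 2 / 2.0)
        if w.sum() <= 0:
            raise ValueError(
                f"filtering leaves no admissible species at {site.site_id} "
                "(filtering_strength too large for the pool)"
            )
        p = w / w.sum()
        n_local = len(local)
        species_ids = local["species_id"].to_numpy()
        n_plots = config.plots_for(site.vegetation)
        for _ in range(n_plots):
            k = 0
            while k < 1:
                k = int(rng.poisson(config.species_per_plot_mean))
            k = min(k, int(np.sum(p > 0)), n_local)
            chosen = rng.choice(n_local, size=k, replace=False, p=p)
            if config.abundance_lognormal_sd > 0:
                biomass = rng.lognormal(0.0, config.abundance_lognormal_sd, size=k)
            else:
                biomass = np.ones(k)
            plot_id = f"plot{plot_counter:04d}"
            plot_counter += 1
            for idx, b in zip(chosen, biomass):
                rows.append(
                    {
                        "plot_id": plot_id,
                        "site_id": site.site_id,
                        "vegetation": site.vegetation,
                        "species_id": species_ids[idx],
                        "weight": b,
                    }
                )
    return pd.DataFrame(rows), sites


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the three substreams (pool / environment / assembly) end to end.

    The per-dataset random stream is split by purpose, so e.g. changing
    the plot count does not perturb the species pool.
    """
    rng_pool, rng_env, rng_asm = _streams(config.seed)
    pool = generate_species_pool(config, rng_pool)
    climate, soil, sites = generate_environment(config, rng_env)
    plots, sites = assemble_communities(pool, sites, config, rng_asm)

    used = plots[["species_id", "site_id"]].drop_duplicates()
    species_traits = used.merge(pool, on=["species_id", "site_id"], how="left")[
        ["species_id", "site_id", "SD", "SL", "SPI"]
    ].sort_values(["site_id", "species_id"], ignore_index=True)

    environment = derive_site_variables(climate, soil)
    cfg = asdict(config)
    cfg["sl_log10_range"] = [float(x) for x in cfg["sl_log10_range"]]
    truth = {
        "config": cfg,
        "spi_scale": "percent (SD * SL^2 * 1e-4)",
        "site_optima": {
            k: float(v) for k, v in zip(sites["site_id"], sites["trait_optimum"])
        },
        "pool_log10_sd_mean": float(np.log10(pool["SD"]).mean()),
        "pool_log10_sd_sd": float(np.log10(pool["SD"]).std()),
    }
    return SyntheticDataset(
        species_traits=species_traits,
        plots=plots,
        climate=climate,
        soil=soil,
        environment=environment,
        sites=sites,
        pool=pool,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the standard input CSVs plus a ground-truth YAML sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.species_traits.to_csv(out / "species_traits.csv", index=False)
    dataset.plots.to_csv(out / "plots.csv", index=False)
    dataset.climate.to_csv(out / "climate.csv", index=False)
    dataset.soil.to_csv(out / "soil.csv", index=False)
    dataset.environment.to_csv(out / "environment.csv", index=False)
    dataset.sites.to_csv(out / "sites.csv", index=False)
    with open(out / "truth.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataset.truth, fh, sort_keys=False)
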