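"""Species-level stomatal traits.

Stomatal density (SD, pores mm^-2) is the stomata count per unit imaged
epidermis area; stomatal length (SL, um) is the guard-cell pair length
averaged over measured stomata; the stomatal pore index

    SPI = SD * SL^2

summarises the fraction of the epidermis allocated to stomata.  With SD
in mm^-2 and SL in um the raw product SD*SL^2 is 1e-6 of the area
fraction; this module reports SPI as a percentage, i.e. SD*SL^2*1e-4,
and exposes ``scale="raw"`` for the unscaled product used by some
cross-study comparisons.

Amphistomatous species (stomata on both surfaces) are aggregated as
SD = SD_upper + SD_lower and SL = (SL_upper + SL_lower)/2 before SPI is
computed; hypostomatic species pass their lower-surface values through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

SPI_PERCENT_FACTOR = 1e-4  # mm^-2 * um^2 -> % of epidermis area

SURFACES = ("upper", "lower")


@dataclass(frozen=True)
class StomatalMeasurement:
    """One photograph of one leaf surface."""

    species_id: str
    site_id: str
    surface: str  # "upper" or "lower"
    stomata_count: int
    field_area: float  # mm^2
    stomatal_lengths: Tuple[float, ...] = field(default_factory=tuple)  # um

    def __post_init__(self):
        if self.surface not in SURFACES:
            raise ValueError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        if self.field_area <= 0 or not np.isfinite(self.field_area):
            raise ValueError("field_area must be positive and finite")
        if self.stomata_count < 0:
            raise ValueError("stomata_count must be >= 0")
        lengths = np.asarray(self.stomatal_lengths, dtype=float)
        if lengths.size and (not np.all(np.isfinite(lengths)) or np.any(lengths <= 0)):
            raise ValueError("stomatal lengths must be finite and positive")


@dataclass(frozen=True)
class SpeciesTrait:
    """Aggregated stomatal traits of one species at one site."""

    species_id: str
    site_id: str
    SD: float  # pores mm^-2
    SL: float  # um
    SPI: float  # % of epidermis area (default scale)


def stomatal_density(count: float, area: float) -> float:
    """Stomata per unit area (pores mm^-2) from one photograph.

    Parameters
    ----------
    count : number of stomata in the field of view (>= 0).
    area : imaged field area in mm^2 (> 0).
    """
    if area <= 0 or not np.isfinite(area):
        raise ValueError("area must be positive and finite")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / area


def aggregate_surfaces(
    upper: Optional[Tuple[float, float]],
    lower: Optional[Tuple[float, float]],
) -> Tuple[float, float]:
    """Combine per-surface (SD, SL) into whole-leaf values.

    Amphistomatous: SD is summed over surfaces, SL averaged.
    Hypostomatic (``upper is None``): lower-surface values pass through.
    """
    if lower is None and upper is None:
        raise ValueError("at least one surface must be present")
    if lower is None:
        # epistomatous leaves are rare but symmetric under the same rule
        return float(upper[0]), float(upper[1])
    if upper is None:
        return float(lower[0]), float(lower[1])
    sd = float(upper[0]) + float(lower[0])
    sl = (float(upper[1]) + float(lower[1])) / 2.0
    return sd, sl


def stomatal_pore_index(SD: float, SL: float, scale: str = "percent") -> float:
    """Stomatal pore index from density (mm^-2) and length (um).

    ``scale="percent"`` (default) returns SD*SL^2*1e-4, the percentage of
    epidermis area; ``scale="raw"`` returns the unscaled SD*SL^2 product.
    """
    if SD <= 0 or SL <= 0 or not (np.isfinite(SD) and np.isfinite(SL)):
        raise ValueError("SD and SL must be positive and finite")
    raw = SD * SL * SL
    if scale == "percent":
        return raw * SPI_PERCENT_FACTOR
    if scale == "raw":
        return raw
    raise ValueError(f"unknown scale {scale!r}")


def species_site_trait(
    measurements: Iterable[StomatalMeasurement], scale: str = "percent"
) -> SpeciesTrait:
    """Average photograph-level measurements into one SpeciesTrait.

    Per surface, SD is the mean of per-photograph count/area ratios and
    SL the mean over all recorded stomatal lengths; surfaces are then
    combined with :func:`aggregate_surfaces` and SPI computed from the
    combined SD and SL.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("at least one measurement required")
    species = {m.species_id for m in measurements}
    sites = {m.site_id for m in measurements}
    if len(species) != 1 or len(sites) != 1:
        raise ValueError("measurements must belong to a single species-site")

    per_surface: dict[str, Tuple[float, float]] = {}
    for surface in SURFACES:
        ms = [m for m in measurements if m.surface == surface]
        if not ms:
            continue
        sd = float(np.mean([stomatal_density(m.stomata_count, m.field_area) for m in ms]))
        lengths = np.concatenate(
            [np.asarray(m.stomatal_lengths, dtype=float) for m in ms]
        ) if any(m.stomatal_lengths for m in ms) else np.array([])
        if lengths.size == 0:
            raise ValueError(f"no stomatal lengths recorded on {surface} surface")
        per_surface[surface] = (sd, float(np.mean(lengths)))

    sd, sl = aggregate_surfaces(per_surface.get("upper"), per_surface.get("lower"))
    return SpeciesTrait(
        species_id=measurements[0].species_id,
        site_id=measurements[0].site_id,
        SD=sd,
        SL=sl,
        SPI=stomatal_pore_index(sd, sl, scale=scale),
    )


MEASUREMENT_COLUMNS = {"species_id", "site_id", "surface", "stomata_count", "field_area"}
TRAIT_COLUMNS = {"species_id", "site_id", "SD", "SL"}


def read_species_traits(path, scale: str = "percent") -> pd.DataFrame:
    """Read a species-trait table, auto-detecting the input level.

    A measurement-level CSV (columns species_id, site_id, surface,
    stomata_count, field_area, stomatal_lengths as ';'-joined um values)
    is aggregated via :func:`species_site_trait`.  A trait-level CSV
    (species_id, site_id, SD, SL[, SPI]) is validated and passed
    through; SPI is recomputed when absent.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if MEASUREMENT_COLUMNS <= cols:
        rows = []
        for (sp, site), grp in df.groupby(["species_id", "site_id"], sort=True):
            ms = [
                StomatalMeasurement(
                    species_id=str(sp),
                    site_id=str(site),
                    surface=rec.surface,
                    stomata_count=int(rec.stomata_count),
                    field_area=float(rec.field_area),
                    stomatal_lengths=tuple(
                        float(x) for x in str(rec.stomatal_lengths).split(";") if x
                    ),
                )
                for rec in grp.itertuples()
            ]
            tr = species_site_trait(ms, scale=scale)
            rows.append((tr.species_id, tr.site_id, tr.SD, tr.SL, tr.SPI))
        return pd.DataFrame(rows, columns=["species_id", "site_id", "SD", "SL", "SPI"])
    if TRAIT_COLUMNS <= cols:
        out = df.copy()
        if "SPI" not in out.columns:
            out["SPI"] = [
                stomatal_pore_index(sd, sl, scale=scale)
                for sd, sl in zip(out["SD"], out["SL"])
            ]
        bad = (out[["SD", "SL", "SPI"]] <= 0).any(axis=1)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} rows with non-positive trait values")
        return out[["species_id", "site_id", "SD", "SL", "SPI"]]
    raise ValueError(
        "unrecognized columns: expected a measurement-level or trait-level table"
    )
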