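"""Synthetic input generator.

Produces every input the simulator needs with the statistical structure of
the real sources: seasonal monthly climate with a latitudinal gradient and a
secular warming trend, yearly primary+secondary land fractions with
geometric decay, log-normal body masses, taxon-structured trophic-level
distributions that increase with body mass, and resource-consumer
interaction records whose body-mass-ratio distributions differ by taxon
pair.

The stationary climate variant (trend 0, noise 0) is exactly periodic with
period 12, which is what the equilibrium tests rely on: every future month
repeats a calibration month, so a community filtered on the calibration
window can never meet a condition it has not already survived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gridio import GridSeries, LandUseSeries
from .species import TAXA

__all__ = ["TraitTables", "make_climate", "make_trait_tables", "make_landuse"]

#: per-taxon log-mass parameters (natural log of grams): roughly mouse-to-deer
#: mammals, songbird-to-raptor birds, gecko-to-monitor reptiles, small anurans
MASS_LOGMEAN = {"mammal": 4.5, "bird": 3.5, "reptile": 3.0, "amphibian": 2.0}
MASS_LOGSD = {"mammal": 2.0, "bird": 1.2, "reptile": 1.5, "amphibian": 1.0}


@dataclass
class TraitTables:
    """Bundle of synthetic trait inputs.

    ``niche``: one row per species (taxon, mass, samples_T, samples_P with
    the sample columns holding numpy arrays of monthly values from the
    species' home region); ``trophic``: (taxon, mass, trophic_level,
    breadth_floor); ``interactions``: resource-consumer records; ``ratio_params``:
    the injected per-taxon-pair log-ratio (mu, sigma), kept so tests can
    recover the implied percentiles.
    """

    niche: pd.DataFrame
    trophic: pd.DataFrame
    interactions: pd.DataFrame
    ratio_params: dict = field(default_factory=dict)


def make_climate(
    grid_shape: tuple[int, int],
    years: int,
    trend: float = 0.0,
    seasonal_amplitude: float = 5.0,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    base_T: float = 20.0,
    lat_gradient: float = 1.0,
    base_P: float = 80.0,
    seasonal_amplitude_P: float = 30.0,
    noise_sd_P: float = 8.0,
    trend_P: float = 0.0,
    start_year: int = 2015,
) -> tuple[GridSeries, GridSeries]:
    """Monthly temperature (degC) and precipitation (mm) series.

    ``trend`` is in degC per decade (``trend_P`` in mm per decade); ``years``
    counts calendar years including the calibration window at the start.
    Temperature decreases poleward (northward) by ``lat_gradient`` degC per
    grid row; precipitation is clamped at zero.
    """
    nrows, ncols = grid_shape
    if nrows <= 0 or ncols <= 0 or years <= 0:
        raise ValueError("grid dimensions and years must be positive")
    rng = rng or np.random.default_rng()
    n_cells = nrows * ncols
    n_months = years * 12
    m = np.arange(n_months)
    season = np.sin(2 * np.pi * (m % 12) / 12.0)
    decades = m / 120.0

    rows = np.repeat(np.arange(nrows), ncols)
    lat_term = -lat_gradient * rows  # row 0 is the "pole-most" (coolest+gradient) edge

    T = (
        base_T
        + lat_term[None, :]
        + seasonal_amplitude * season[:, None]
        + trend * decades[:, None]
    )
    if noise_sd > 0:
        T = T + rng.normal(0.0, noise_sd, size=T.shape)
    P = (
        base_P
        + seasonal_amplitude_P * season[:, None]
        + trend_P * decades[:, None]
        + np.zeros((n_months, n_cells))
    )
    if noise_sd_P > 0 and noise_sd > 0:
        P = P + rng.normal(0.0, noise_sd_P, size=P.shape)
    P = np.clip(P, 0.0, None)
    return (
        GridSeries(T, nrows, ncols, start_year),
        GridSeries(P, nrows, ncols, start_year),
    )


def _region_samples(
    series: GridSeries, center: int, months: int, margin: float
) -> np.ndarray:
    """Calibration-window values over the center cell and its 8-neighbourhood.

    The recorded spread is widened by ``margin`` (a fraction of the regional
    range appended at each end) because a real species' range spans far more
    cells than this neighbourhood: the home cell's conditions must sit
    strictly inside the tolerance edges, not on them, or a noise-free
    periodic climate would pin every species at exactly the edge survival
    probability in its most extreme month.
    """
    nrows, ncols = series.nrows, series.ncols
    r, c = divmod(center, ncols)
    cells = [
        rr * ncols + cc
        for rr in range(max(0, r - 1), min(nrows, r + 2))
        for cc in range(max(0, c - 1), min(ncols, c + 2))
    ]
    vals = series.data[:months, cells].ravel()
    if margin > 0:
        span = vals.max() - vals.min()
        pad = margin * span if span > 0 else max(abs(vals.max()), 1.0) * 1e-3
        vals = np.append(vals, [vals.min() - pad, vals.max() + pad])
    return vals


def make_trait_tables(
    n_per_taxon: int | dict[str, int],
    climate: tuple[GridSeries, GridSeries],
    rng: np.random.Generator,
    calibration_months: int = 60,
    trophic_factor: int = 3,
    n_interactions_per_pair: int = 60,
    mass_logmean: dict | None = None,
    mass_logsd: dict | None = None,
    range_margin: float = 0.05,
) -> TraitTables:
    """Synthetic niche-source, trophic and interaction tables.

    Each niche-source species gets a random home region on the grid and its
    climate samples from the calibration window there.  Trophic level rises
    with body mass within each taxon (rank-based, plus noise), reproducing
    the qualitative mass-trophic-level association of real food-web data;
    the breadth floor is level minus a uniform breadth, clamped at the
    plant/invertebrate level 0, so small low-level species tend to be basal.
    Interaction records per ordered taxon pair have log-normal resource:
    consumer mass ratios with pair-specific location.
    """
    T, P = climate
    if isinstance(n_per_taxon, int):
        n_per_taxon = {t: n_per_taxon for t in TAXA}
    lm = mass_logmean or MASS_LOGMEAN
    ls = mass_logsd or MASS_LOGSD

    niche_rows = []
    trophic_rows = []
    for taxon in TAXA:
        n = int(n_per_taxon.get(taxon, 0))
        if n == 0:
            continue
        masses = np.exp(rng.normal(lm[taxon], ls[taxon], size=n))
        centers = rng.integers(0, T.n_cells, size=n)
        for mass, center in zip(masses, centers):
            niche_rows.append(
                {
                    "taxon": taxon,
                    "mass": float(mass),
                    "samples_T": _region_samples(
                        T, int(center), calibration_months, range_margin
                    ),
                    "samples_P": _region_samples(
                        P, int(center), calibration_months, range_margin
                    ),
                }
            )
        nt = n * trophic_factor
        tmass = np.exp(rng.normal(lm[taxon], ls[taxon], size=nt))
        z = (np.log(tmass) - lm[taxon]) / ls[taxon]
        tl = 1.0 + 2.5 * norm.cdf(z) + rng.normal(0.0, 0.3, size=nt)
        tl = np.clip(tl, 1.0, 4.5)
        breadth = rng.uniform(0.8, 2.2, size=nt)
        floor = np.maximum(0.0, tl - breadth)
        # Invertebrate/plant access declines with body mass: a small vertebrate
        # whose diet cannot span down to vertebrate prey of feasible size is an
        # insectivore in real diet data, not an obligate carnivore with nothing
        # to eat.  Species retaining that access have floor 0 (basal); obligate
        # vertebrate-eaters get a strictly positive floor.
        invert_access = rng.random(nt) < (1.0 - norm.cdf(z))
        floor = np.where(invert_access, 0.0, np.maximum(floor, 0.5))
        for mass, lvl, fl in zip(tmass, tl, floor):
            trophic_rows.append(
                {
                    "taxon": taxon,
                    "mass": float(mass),
                    "trophic_level": float(lvl),
                    "breadth_floor": float(fl),
                }
            )

    inter_rows = []
    ratio_params = {}
    for rt in TAXA:
        for ct in TAXA:
            mu = float(rng.uniform(np.log(0.01), np.log(0.4)))
            sigma = 1.0
            ratio_params[(rt, ct)] = (mu, sigma)
            cmass = np.exp(rng.normal(lm[ct], ls[ct], size=n_interactions_per_pair))
            ratio = np.exp(rng.normal(mu, sigma, size=n_interactions_per_pair))
            for cm, r in zip(cmass, ratio):
                inter_rows.append(
                    {
                        "resource_taxon": rt,
                        "resource_mass": float(cm * r),
                        "consumer_taxon": ct,
                        "consumer_mass": float(cm),
                    }
                )

    return TraitTables(
        niche=pd.DataFrame(niche_rows),
        trophic=pd.DataFrame(trophic_rows),
        interactions=pd.DataFrame(inter_rows),
        ratio_params=ratio_params,
    )


def make_landuse(
    grid_shape: tuple[int, int],
    years: int,
    annual_loss_rate: float | np.ndarray = 0.0,
    u0: float | np.ndarray = 1.0,
    rng: np.random.Generator | None = None,
    rate_jitter: float = 0.0,
    start_year: int = 2015,
) -> LandUseSeries:
    """Yearly land-fraction series u(cell, y+1) = u(cell, y) * (1 - rate).

    ``annual_loss_rate`` and ``u0`` may be scalars or per-cell arrays;
    ``rate_jitter`` adds independent per-cell uniform jitter to the rate for
    spatially heterogeneous decay.
    """
    nrows, ncols = grid_shape
    n_cells = nrows * ncols
    rate = np.broadcast_to(np.asarray(annual_loss_rate, dtype=float), (n_cells,)).copy()
    if ((rate < 0) | (rate > 1)).any():
        raise ValueError("annual_loss_rate must lie in [0, 1]")
    if rate_jitter > 0:
        rng = rng or np.random.default_rng()
        rate = np.clip(rate + rng.uniform(-rate_jitter, rate_jitter, size=n_cells), 0, 1)
    u = np.empty((years, n_cells))
    u[0] = np.broadcast_to(np.asarray(u0, dtype=float), (n_cells,))
    for y in range(1, years):
        u[y] = u[y - 1] * (1.0 - rate)
    return LandUseSeries(u, nrows, ncols, start_year)
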