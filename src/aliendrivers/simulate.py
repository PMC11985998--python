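"""Synthetic country-level invasion datasets with known ground truth.

The generator emulates the statistical structure the downstream stages
assume: per-country species richness drawn from a negative binomial whose
log-mean is a linear combination of standardized predictors; predictors
organized in four driver categories with one deliberately collinear block
(so VIF filtering has something to remove); regionally clustered species
pools (higher within-region Jaccard similarity); and annual first-record
series with a monotone trend plus AR(1) noise (so the autocorrelation
correction of the trend test has something to act on).

Everything is a pure function of the configuration: a fixed seed gives
bitwise-identical output, and the ground truth (coefficients, dispersion,
slopes, region labels) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import (
    AnnualSeries,
    OccurrenceMatrix,
    PredictorTable,
    records_to_frame,
    SpeciesRecord,
)

__all__ = [
    "PredictorSpec",
    "SynthConfig",
    "SyntheticDataset",
    "generate_predictors",
    "generate_richness",
    "generate_species_pools",
    "generate_annual_series",
    "generate_dataset",
]


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor column: name, driver category, marginal, correlation block.

    Predictors sharing a ``block`` id are generated from a common latent
    factor with loading ``sqrt(block_correlation)`` each, so their pairwise
    correlation is approximately ``block_correlation``.
    """

    name: str
    category: str  # A research, B economy, C environment & culture, D land use
    dist: str = "normal"  # normal | lognormal | uniform
    params: tuple[float, float] = (0.0, 1.0)
    block: str | None = None


def _default_predictor_specs() -> tuple[PredictorSpec, ...]:
    """21 predictors in the four driver categories.

    One four-member high-correlation block spans airports, international
    airports, import volume and research expenditure — the kind of
    trade/infrastructure collinearity that VIF screening removes.
    """
    B = "trade_infrastructure"
    return (
        PredictorSpec("n_time_series", "A", "lognormal", (2.0, 1.0)),
        PredictorSpec("research_expenditure", "A", "normal", (1.5, 0.5), block=B),
        PredictorSpec("n_researchers", "A", "lognormal", (8.0, 1.0)),
        PredictorSpec("gdp", "B", "lognormal", (12.0, 1.2)),
        PredictorSpec("n_tourists", "B", "lognormal", (2.0, 1.5)),
        PredictorSpec("n_airports", "B", "normal", (60.0, 25.0), block=B),
        PredictorSpec("n_intl_airports", "B", "normal", (12.0, 5.0), block=B),
        PredictorSpec("port_traffic", "B", "lognormal", (13.0, 1.5)),
        PredictorSpec("import_volume", "B", "normal", (200.0, 80.0), block=B),
        PredictorSpec("gni_per_capita", "B", "lognormal", (10.0, 0.7)),
        PredictorSpec("country_growth", "B", "normal", (2.0, 2.0)),
        PredictorSpec("n_borders", "B", "uniform", (0.0, 9.0)),
        PredictorSpec("population_density", "C", "lognormal", (4.5, 0.9)),
        PredictorSpec("sustainability_index", "C", "uniform", (0.3, 0.9)),
        PredictorSpec("ecological_footprint", "C", "normal", (4.5, 1.5)),
        PredictorSpec("trompenaars_1", "C", "uniform", (0.0, 100.0)),
        PredictorSpec("trompenaars_7", "C", "uniform", (0.0, 100.0)),
        PredictorSpec("native_biodiversity", "C", "lognormal", (9.0, 0.8)),
        PredictorSpec("surface_area", "D", "lognormal", (11.5, 1.3)),
        PredictorSpec("agricultural_land_pct", "D", "uniform", (5.0, 70.0)),
        PredictorSpec("urban_population_pct", "D", "uniform", (50.0, 98.0)),
    )


def _default_beta() -> dict[str, float]:
    """Log-scale effects on richness, mirroring the qualitative pattern the
    driver models are meant to recover: monitoring effort, population
    density, sustainability and tourism raise reported richness; an
    internally-directed culture score lowers it."""
    return {
        "n_time_series": 0.45,
        "population_density": 0.35,
        "sustainability_index": 0.30,
        "n_tourists": 0.30,
        "country_growth": 0.20,
        "trompenaars_7": -0.25,
    }


@dataclass(frozen=True)
class SynthConfig:
    """Full configuration of the synthetic study system.

    Defaults describe a Europe-sized study: ~40 countries in 4 geographic
    regions, 21 predictors in categories A-D, moderately overdispersed
    richness (theta = 2, variance = mu + mu^2/theta), a shared-species
    fraction of 0.6 drawn from regional pools, and 60-year reporting series
    with positive trends and AR(1) noise.
    """

    n_countries: int = 40
    n_regions: int = 4
    seed: int = 0
    predictor_specs: tuple[PredictorSpec, ...] = field(
        default_factory=_default_predictor_specs
    )
    true_beta: dict[str, float] = field(default_factory=_default_beta)
    intercept: float = 5.0  # log scale; exp(5) ~ 150 species per country
    nb_dispersion: float = 2.0  # theta
    regional_pool_size: int = 3000
    global_pool_size: int = 8000
    within_region_share: float = 0.6
    trend_slope_range: tuple[float, float] = (0.02, 0.12)
    ar1_rho: float = 0.4
    noise_sd: float = 1.0
    n_years: int = 60
    block_correlation: float = 0.95

    def __post_init__(self) -> None:
        if self.n_countries < 4:
            raise ValueError("n_countries must be >= 4")
        if not 0.0 <= self.within_region_share <= 1.0:
            raise ValueError("within_region_share must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion (theta) must be positive")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")
        per_cat: dict[str, int] = {}
        for s in self.predictor_specs:
            per_cat[s.category] = per_cat.get(s.category, 0) + 1
        thin = [c for c in "ABCD" if per_cat.get(c, 0) < 2]
        if thin:
            raise ValueError(
                f"need >= 2 predictors in every category; too few in: {thin}"
            )


def _country_labels(n: int) -> list[str]:
    return [f"C{i:03d}" for i in range(n)]


def _region_labels(config: SynthConfig) -> pd.Series:
    regions = [f"R{i % config.n_regions}" for i in range(config.n_countries)]
    return pd.Series(regions, index=_country_labels(config.n_countries), name="region")


def _marginal(rng: np.random.Generator, spec: PredictorSpec, n: int) -> np.ndarray:
    a, b = spec.params
    if spec.dist == "normal":
        return rng.normal(a, b, n)
    if spec.dist == "lognormal":
        return rng.lognormal(a, b, n)
    if spec.dist == "uniform":
        return rng.uniform(a, b, n)
    raise ValueError(f"unknown distribution family {spec.dist!r}")


def generate_predictors(config: SynthConfig) -> PredictorTable:
    """Draw the country × predictor table.

    Blocked predictors are affine transforms of ``sqrt(r)·z + sqrt(1-r)·e``
    with a shared latent ``z`` per block, giving pairwise correlation ≈ r
    (default 0.95); their stated ``params`` act as (mean, sd).  Unblocked
    predictors are independent draws from their marginal family.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    latents = {
        b: rng.standard_normal(n)
        for b in sorted({s.block for s in config.predictor_specs if s.block})
    }
    r = config.block_correlation
    cols: dict[str, np.ndarray] = {}
    for spec in config.predictor_specs:
        if spec.block is None:
            cols[spec.name] = _marginal(rng, spec, n)
        else:
            z = np.sqrt(r) * latents[spec.block] + np.sqrt(1 - r) * rng.standard_normal(n)
            mean, sd = spec.params
            cols[spec.name] = mean + sd * z
    data = pd.DataFrame(cols, index=_country_labels(n))
    categories = {s.name: s.category for s in config.predictor_specs}
    return PredictorTable(data=data, categories=categories)


def standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-score columns; constant columns become all-zero."""
    sd = frame.std(ddof=0).replace(0.0, 1.0)
    return (frame - frame.mean()) / sd


def generate_richness(
    predictors: PredictorTable,
    true_beta: dict[str, float],
    theta: float,
    seed: int,
    intercept: float = 5.0,
) -> pd.Series:
    """Negative-binomial richness with log-mean = intercept + Xz·beta.

    Predictors are standardized before the linear combination so the
    coefficients are scale-free.  Variance is mu + mu^2/theta.
    """
    rng = np.random.default_rng(seed)
    X = standardize(predictors.data)
    eta = np.full(len(X), float(intercept))
    for name, b in true_beta.items():
        if name not in X.columns:
            raise KeyError(f"true_beta names unknown predictor {name!r}")
        eta += b * X[name].to_numpy()
    bad = ~np.isfinite(eta)
    if bad.any():
        offender = X.index[bad][0]
        raise ValueError(f"non-finite linear predictor for country {offender!r}")
    mu = np.exp(eta)
    # numpy's NB: n successes, success prob p; mean n(1-p)/p => p = theta/(theta+mu)
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.Series(counts, index=X.index, name="richness")


def generate_species_pools(
    richness: pd.Series, config: SynthConfig, seed: int
) -> tuple[OccurrenceMatrix, pd.Series]:
    """Assemble per-country species sets from regional and global pools.

    Each country draws ``round(within_region_share · richness)`` species
    from its region's pool (pools are disjoint across regions) and the rest
    from a shared global pool, all without replacement within a country.
    Returns the presence matrix and the country → region labels.
    """
    rng = np.random.default_rng(seed)
    regions = _region_labels(config).reindex(richness.index)
    if regions.isna().any():
        raise ValueError("richness index does not match the configured countries")
    region_ids = sorted(regions.unique())
    regional = {
        rid: [f"sp_{rid}_{i:05d}" for i in range(config.regional_pool_size)]
        for rid in region_ids
    }
    global_pool = [f"sp_G_{i:05d}" for i in range(config.global_pool_size)]

    chosen: dict[str, list[str]] = {}
    for country, k in richness.items():
        k = int(k)
        k_reg = int(round(config.within_region_share * k))
        k_glob = k - k_reg
        pool_r = regional[regions[country]]
        if k_reg > len(pool_r) or k_glob > len(global_pool):
            raise ValueError(
                f"country {country!r} richness {k} exceeds pool capacity"
            )
        picks = list(rng.choice(pool_r, size=k_reg, replace=False)) + list(
            rng.choice(global_pool, size=k_glob, replace=False)
        )
        chosen[country] = picks

    species = sorted({s for picks in chosen.values() for s in picks})
    sj = {s: j for j, s in enumerate(species)}
    presence = np.zeros((len(richness), len(species)), dtype=bool)
    for i, country in enumerate(richness.index):
        for s in chosen[country]:
            presence[i, sj[s]] = True
    matrix = OccurrenceMatrix(
        countries=list(richness.index), species=species, presence=presence
    )
    return matrix, regions


def generate_annual_series(
    country_trend: float,
    ar1_rho: float,
    n_years: int,
    seed: int,
    *,
    base_level: float = 2.0,
    noise_sd: float = 1.0,
    country: str = "synthetic",
) -> AnnualSeries:
    """Integer annual counts from a latent linear trend plus AR(1) noise.

    The latent path ``base + slope·t + e_t`` (e an AR(1) process with
    marginal sd ``noise_sd``) is rounded and floored at zero.  This keeps
    counts integer-valued while leaving the serial correlation that the
    variance-corrected trend test is designed for.
    """
    if n_years < 3:
        raise ValueError("need at least 3 years for a trend test")
    rng = np.random.default_rng(seed)
    innov_sd = noise_sd * np.sqrt(1 - ar1_rho**2)
    e = np.empty(n_years)
    e[0] = rng.normal(0.0, noise_sd)
    for t in range(1, n_years):
        e[t] = ar1_rho * e[t - 1] + rng.normal(0.0, innov_sd)
    latent = base_level + country_trend * np.arange(n_years) + e
    counts = np.maximum(np.rint(latent), 0).astype(int)
    years = np.arange(1960, 1960 + n_years)
    return AnnualSeries(country=country, years=years, counts=counts)


@dataclass
class SyntheticDataset:
    """A complete generated study with its ground truth."""

    config: SynthConfig
    predictors: PredictorTable
    richness: pd.Series
    occurrence: OccurrenceMatrix
    regions: pd.Series
    annual_series: dict[str, AnnualSeries]
    records: list[SpeciesRecord]
    true_slopes: pd.Series

    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def _year_weights(slope: float, n_years: int) -> np.ndarray:
    """Increasing (or flat/decreasing) multinomial weights over the window."""
    w = 1.0 + slope * np.arange(n_years)
    w = np.clip(w, 1e-6, None)
    return w / w.sum()


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate the full study: predictors, richness, assemblages, series.

    Sub-stage seeds are spawned deterministically from ``config.seed``.
    Per-country first-record years are assigned multinomially over an
    increasing latent profile so that annual counts sum exactly to the
    country's richness (the round-trip with the record reader conserves
    counts); the standalone AR(1) series generator remains the reference
    process for trend-test simulations.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    predictors = generate_predictors(config)
    richness = generate_richness(
        predictors,
        config.true_beta,
        config.nb_dispersion,
        seeds[0],
        intercept=config.intercept,
    )
    occurrence, regions = generate_species_pools(richness, config, seeds[1])

    rng = np.random.default_rng(seeds[2])
    lo, hi = config.trend_slope_range
    slopes = pd.Series(
        rng.uniform(lo, hi, config.n_countries),
        index=occurrence.countries,
        name="true_slope",
    )

    rng_years = np.random.default_rng(seeds[3])
    years_axis = np.arange(1960, 1960 + config.n_years)
    annual: dict[str, AnnualSeries] = {}
    records: list[SpeciesRecord] = []
    frame = occurrence.to_frame()
    phyla = ["Tracheophyta", "Arthropoda", "Chordata", "Mollusca"]
    classes = ["Magnoliopsida", "Insecta", "Aves", "Gastropoda"]
    for country in occurrence.countries:
        spp = list(frame.columns[frame.loc[country]])
        weights = _year_weights(slopes[country], config.n_years)
        counts = rng_years.multinomial(len(spp), weights)
        annual[country] = AnnualSeries(
            country=country, years=years_axis, counts=counts
        )
        year_of = np.repeat(years_axis, counts)
        for sp, yr in zip(spp, year_of):
            h = zlib.crc32(sp.encode()) % len(phyla)
            records.append(
                SpeciesRecord(
                    species_name=sp,
                    phylum=phyla[h],
                    taxon_class=classes[h],
                    country=country,
                    first_record_year=int(yr),
                    degree_of_establishment="ESTABLISHED",
                    occurrence_status="PRESENT",
                )
            )

    return SyntheticDataset(
        config=config,
        predictors=predictors,
        richness=richness,
        occurrence=occurrence,
        regions=regions,
        annual_series=annual,
        records=records,
        true_slopes=slopes,
    )


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """Copy of a configuration with a different master seed."""
    return replace(config, seed=seed)
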