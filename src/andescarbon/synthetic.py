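"""Synthetic two-census mountain-forest networks with known ground truth.

The generator emulates the data a plot network produces — census tables,
plot metadata, species traits, a dated phylogeny, bioclim-style climate
variables and a band-by-year forest-cover table — with every generating
parameter (size-dependent mortality slope, thermophilization drift, growth
and recruitment rates) known, so each downstream estimator has a
parameter-recovery surface.

Generating process per plot:

* census-1 stems get DBH = 10 + Exponential(8) cm (a right-skewed census
  size structure) and species sampled from the pool with weights peaked on
  species whose thermal optimum matches the plot's temperature;
* each stem dies over the interval with probability
  logistic(a_true + beta_true * DBH);
* survivors grow at Normal(growth_mean, growth_sd) cm/y plus, when
  ``thermo_drift`` is non-zero, an optimum-dependent tilt whose coefficient
  is solved per plot so the expected change of the basal-area-weighted
  community temperature index equals the drift;
* recruits appear at Poisson(recruit_rate * area * t) with DBH in
  [10, 12] cm, sampled from the resident community with an exponential
  tilt on thermal optimum so their mean optimum sits ``thermo_drift * t``
  above the resident mean.

Temperature follows a fixed -5.5 degC/km lapse rate from a 24 degC foothill
baseline; the climate table's temperature block is driven by elevation with
a secondary latitude signal, mirroring the elevation/latitude structure of
real Andean bioclim extractions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .regional import DEFAULT_BAND_EDGES, band_label

LAPSE_RATE_C_PER_KM = -5.5
FOOTHILL_MAT_C = 24.0   # mean annual temperature at 500 m asl
FOOTHILL_ELEVATION_M = 500.0
NICHE_WIDTH_C = 3.0     # sd of the species-filtering kernel, degC


def mean_annual_temperature(elevation_m) -> np.ndarray:
    """Lapse-rate MAT (degC) at a given elevation."""
    elev = np.asarray(elevation_m, dtype=float)
    return FOOTHILL_MAT_C + LAPSE_RATE_C_PER_KM * (elev - FOOTHILL_ELEVATION_M) / 1000.0


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic plot network."""

    n_plots: int = 20
    plot_area_ha: float = 1.0
    elevation_range: tuple[float, float] = (500.0, 3500.0)
    latitude_range: tuple[float, float] = (-27.8, 7.1)
    n_species_pool: int = 80
    stems_per_plot: int = 400
    census_interval_years: float = 5.0
    a_true: float = -3.5            # mortality logit intercept (per interval)
    beta_true: float = -0.02        # mortality logit slope, per cm DBH
    growth_mean: float = 0.25       # cm / y
    growth_sd: float = 0.15         # cm / y
    recruit_rate: float = 2.0       # stems / ha / y reaching 10 cm
    thermo_drift: float = 0.0       # degC / y shift in community optimum
    height_measure_fraction: float = 0.3   # stems with a field height
    height_plot_fraction: float = 0.85     # plots with any field heights
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.elevation_range
        if not (500.0 <= lo < hi <= 3600.0):
            raise ValueError("elevation_range must lie within [500, 3600] m")
        if self.stems_per_plot < 86:
            raise ValueError("stems_per_plot must be >= 86 so rarefaction at 86 is defined")
        if self.plot_area_ha <= 0:
            raise ValueError("plot_area_ha must be positive")
        if self.census_interval_years <= 0:
            raise ValueError("census interval must be positive")


# ---------------------------------------------------------------------------
# species pool

def generate_species_pool(
    config: SimulationConfig, all_am: bool = False
) -> tuple[pd.DataFrame, str]:
    """Species-trait table and dated newick phylogeny for the pool.

    Traits: wood density (g cm^-3), thermal optimum (degC, spanning the
    elevational temperature gradient), mycorrhizal type (AM/EcM, all AM if
    ``all_am``), plus genus and family groupings.  The phylogeny is an
    ultrametric pure-birth tree whose tip labels are the species ids.
    """
    n = config.n_species_pool
    if n < 2:
        raise ValueError("need at least 2 species in the pool")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    species = [f"sp{i:04d}" for i in range(n)]
    n_genera = max(2, n // 4)
    n_families = max(2, n // 10)
    genus_idx = rng.integers(0, n_genera, size=n)
    genus_family = rng.integers(0, n_families, size=n_genera)

    mat_lo = float(mean_annual_temperature(config.elevation_range[1]))
    mat_hi = float(mean_annual_temperature(config.elevation_range[0]))
    traits = pd.DataFrame(
        {
            "species": species,
            "genus": [f"gen{g:03d}" for g in genus_idx],
            "family": [f"fam{genus_family[g]:02d}" for g in genus_idx],
            "wd_g_cm3": np.clip(rng.normal(0.60, 0.15, size=n), 0.15, 1.15),
            "thermal_optimum": rng.uniform(mat_lo, mat_hi, size=n),
            "myco_type": (
                ["AM"] * n
                if all_am
                else np.where(rng.random(n) < 0.75, "AM", "EcM").tolist()
            ),
        }
    )

    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n,
        rng=random.Random(config.seed + 1_000_003),
    )
    for leaf, name in zip(tree.leaf_node_iter(), species):
        leaf.taxon.label = name
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return traits, newick


# ---------------------------------------------------------------------------
# censuses

def _recruit_tilt(optima: np.ndarray, weights: np.ndarray, target: float) -> np.ndarray:
    """Exponential tilt of recruit species weights to hit a mean optimum."""
    lo, hi = optima.min(), optima.max()
    target = np.clip(target, lo + 1e-9, hi - 1e-9)

    def mean_at(eta):
        w = weights * np.exp(eta * (optima - optima.mean()))
        return float(np.sum(w * optima) / np.sum(w)) - target

    if abs(mean_at(0.0)) < 1e-12:
        return weights
    try:
        eta = brentq(mean_at, -20.0, 20.0)
    except ValueError:  # target unreachable within the bracket
        eta = 20.0 if mean_at(20.0) < 0 else -20.0
    w = weights * np.exp(eta * (optima - optima.mean()))
    return w / w.sum()


def generate_census_pair(
    config: SimulationConfig, pool: tuple[pd.DataFrame, str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-census table, plot table and climate table for the network.

    Each plot runs on its own seed substream, so subsetting plots does not
    change their stems.  Returns ``(census, plots, climate)``.
    """
    traits, _ = pool
    t = config.census_interval_years
    optimum = traits.set_index("species")["thermal_optimum"]
    pool_species = traits["species"].to_numpy()
    pool_opt = traits["thermal_optimum"].to_numpy()
    sp_genus = traits.set_index("species")["genus"]
    sp_family = traits.set_index("species")["family"]

    census_rows: list[pd.DataFrame] = []
    plot_rows = []
    climate_rows = []
    countries_with_heights: set[str] = set()

    root = np.random.SeedSequence([config.seed, 1])
    streams = root.spawn(config.n_plots)

    for i in range(config.n_plots):
        rng = np.random.default_rng(streams[i])
        plot_id = f"plot{i:03d}"
        elev = rng.uniform(*config.elevation_range)
        lat = rng.uniform(*config.latitude_range)
        lon = rng.uniform(-79.5, -63.8)
        country = "south" if lat < -10.0 else "north"
        mat_plot = float(mean_annual_temperature(elev))

        n0 = config.stems_per_plot
        weights = np.exp(-((pool_opt - mat_plot) ** 2) / (2 * NICHE_WIDTH_C**2))
        weights /= weights.sum()
        sp_idx = rng.choice(len(pool_species), size=n0, p=weights)
        species1 = pool_species[sp_idx]
        dbh1 = 10.0 + rng.exponential(8.0, size=n0)

        # heights: true curve is Michaelis-Menten with an asymptote that
        # shortens with elevation; a fraction of stems carries a noisy field
        # measurement
        has_heights = rng.random() < config.height_plot_fraction
        if country not in countries_with_heights:
            has_heights = True  # keep every country pool fittable
        if has_heights:
            countries_with_heights.add(country)
        h_asym = 48.0 - 0.006 * elev
        true_h = h_asym * dbh1 / (20.0 + dbh1)
        height1 = np.full(n0, np.nan)
        if has_heights:
            measured = rng.random(n0) < config.height_measure_fraction
            height1[measured] = true_h[measured] * np.exp(
                rng.normal(0.0, 0.08, size=int(measured.sum()))
            )

        # mortality: one Bernoulli per stem over the whole interval
        p_death = expit(config.a_true + config.beta_true * dbh1)
        died = rng.random(n0) < p_death
        surv = ~died

        # survivor growth, with the optimum tilt that realizes the CTI drift
        stem_opt = optimum.loc[species1].to_numpy()
        growth = rng.normal(config.growth_mean, config.growth_sd, size=n0)
        if config.thermo_drift != 0.0:
            ba = np.pi * (dbh1 / 2.0) ** 2
            cti1 = float(np.average(stem_opt, weights=ba))
            dev = stem_opt[surv] - cti1
            d_surv = dbh1[surv]
            denom = float(np.sum(d_surv * dev**2))
            if denom > 0:
                gamma = (
                    config.thermo_drift * ba.sum() * 2.0 / np.pi
                    - config.growth_mean * float(np.sum(d_surv * dev))
                ) / denom
                growth[surv] += gamma * dev
        growth = np.clip(growth, -0.1, 7.5)
        dbh2 = dbh1 + growth * t

        # recruits, tilted toward warmer optima when drifting
        n_rec = rng.poisson(config.recruit_rate * config.plot_area_ha * t)
        if n_rec > 0:
            resident_sp, counts = np.unique(species1, return_counts=True)
            res_opt = optimum.loc[resident_sp].to_numpy()
            w = counts / counts.sum()
            target = float(np.average(res_opt, weights=w)) + config.thermo_drift * t
            w = _recruit_tilt(res_opt, w, target)
            rec_sp = rng.choice(resident_sp, size=n_rec, p=w / w.sum())
            rec_dbh = rng.uniform(10.0, 12.0, size=n_rec)
        else:
            rec_sp = np.array([], dtype=object)
            rec_dbh = np.array([])

        date1 = pd.Timestamp("2005-01-01") + pd.Timedelta(
            days=int(rng.integers(0, 365))
        )
        date2 = date1 + pd.Timedelta(days=round(t * 365.25))

        tags = np.array([f"{plot_id}-{k:05d}" for k in range(n0 + n_rec)])

        def rows(tag, sp, cen, date, dbh, status, height=None):
            return pd.DataFrame(
                {
                    "plot_id": plot_id,
                    "tag": tag,
                    "census": cen,
                    "date": date,
                    "dbh_cm": dbh,
                    "height_m": np.nan if height is None else height,
                    "species": sp,
                    "genus": sp_genus.loc[sp].to_numpy(),
                    "family": sp_family.loc[sp].to_numpy(),
                    "status": status,
                }
            )

        census_rows.append(rows(tags[:n0], species1, 1, date1, dbh1, "alive", height1))
        census_rows.append(
            rows(tags[:n0][surv], species1[surv], 2, date2, dbh2[surv], "alive")
        )
        census_rows.append(
            rows(tags[:n0][died], species1[died], 2, date2, dbh1[died], "dead")
        )
        if n_rec > 0:
            census_rows.append(
                rows(tags[n0:], rec_sp, 2, date2, rec_dbh, "recruit")
            )

        plot_rows.append(
            {
                "plot_id": plot_id,
                "latitude": lat,
                "longitude": lon,
                "elevation_m": elev,
                "area_ha": config.plot_area_ha,
                "country": country,
            }
        )
        climate_rows.append(_climate_row(plot_id, elev, lat, rng))

    census = pd.concat(census_rows, ignore_index=True)
    plots = pd.DataFrame(plot_rows)
    climate = pd.DataFrame(climate_rows)
    return census, plots, climate


def _climate_row(plot_id: str, elev: float, lat: float, rng) -> dict:
    """Bioclim-style variables driven by elevation with a latitude signal."""
    e = (elev - 2000.0) / 1000.0
    a = abs(lat) / 10.0
    base = 16.75 - 5.5 * e
    n = rng.normal
    mapc = 1800.0 - 300.0 * e - 150.0 * a
    return {
        "plot_id": plot_id,
        "MAT": base + 0.2 * a + n(0, 0.3),
        "MDR": 10.0 + 3.0 * a + n(0, 0.5),
        "Isoth": 85.0 - 12.0 * a + n(0, 1.0),
        "TS": 300.0 + 250.0 * a + 10.0 * e + n(0, 15.0),
        "MaxTWarmM": base + 5.0 + 2.0 * a + n(0, 0.4),
        "MinTCM": base - 5.0 - 2.0 * a + n(0, 0.4),
        "TAR": 12.0 + 5.0 * a + 0.3 * e + n(0, 0.5),
        "MeanTWarmQ": base + 2.0 + 0.5 * a + n(0, 0.3),
        "MeanTDQ": base - 1.0 + 0.3 * a + n(0, 0.3),
        "MeanTWetQ": base + 1.0 + 0.3 * a + n(0, 0.3),
        "MeanTCQ": base - 2.0 - 0.5 * a + n(0, 0.3),
        "MAP": mapc + n(0, 100.0),
        "PWetM": 0.15 * mapc + 40.0 * a + n(0, 20.0),
        "PDM": 0.02 * mapc * (1.0 - 0.2 * a) + n(0, 5.0),
        "PS": 40.0 + 25.0 * a + 5.0 * e + n(0, 3.0),
        "PWetQ": 0.40 * mapc + n(0, 40.0),
        "PDQ": 0.08 * mapc + n(0, 10.0),
        "PWarmQ": 0.30 * mapc + n(0, 30.0),
        "PCQ": 0.20 * mapc + n(0, 20.0),
    }


# ---------------------------------------------------------------------------
# forest cover

def generate_cover_table(
    edges=DEFAULT_BAND_EDGES,
    cover_initial=(240000.0, 175000.0, 95000.0, 39000.0),
    loss_rates=(0.032, 0.020, 0.012, 0.011),
) -> pd.DataFrame:
    """Band-by-year forest-cover table: cover_final = cover_initial*(1-loss).

    ``edges`` are ordered, non-overlapping band boundaries; ``loss_rates``
    are fractional losses per band in [0, 1).
    """
    bands = [band_label(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    if len(cover_initial) != len(bands) or len(loss_rates) != len(bands):
        raise ValueError("cover_initial and loss_rates must match the band count")
    loss = np.asarray(loss_rates, dtype=float)
    if np.any(loss < 0) or np.any(loss >= 1):
        raise ValueError("loss rates must lie in [0, 1)")
    cover0 = np.asarray(cover_initial, dtype=float)
    if np.any(cover0 <= 0):
        raise ValueError("initial cover must be positive")
    return pd.DataFrame(
        {
            "band": bands,
            "cover_initial": cover0,
            "cover_final": cover0 * (1.0 - loss),
        }
    )


# ---------------------------------------------------------------------------
# convenience bundle

@dataclass
class SimulatedNetwork:
    config: SimulationConfig
    traits: pd.DataFrame
    newick: str
    census: pd.DataFrame
    plots: pd.DataFrame
    climate: pd.DataFrame
    cover: pd.DataFrame = field(default_factory=generate_cover_table)


def simulate_network(config: SimulationConfig | None = None, **kwargs) -> SimulatedNetwork:
    """Generate a full synthetic network (all six input tables)."""
    if config is None:
        config = SimulationConfig(**kwargs)
    pool = generate_species_pool(config)
    census, plots, climate = generate_census_pair(config, pool)
    return SimulatedNetwork(
        config=config,
        traits=pool[0],
        newick=pool[1],
        census=census,
        plots=plots,
        climate=climate,
    )
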