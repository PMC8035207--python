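"""End-to-end analysis: census tables in, per-plot metrics table out.

Chains validation, census pairing, growth cleaning, height-diameter fitting
(plot-level with country fallback), wood-density assignment, carbon
dynamics, and the community driver metrics into a single per-plot frame
ready for driver inference and regional scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import census as census_mod
from .allometry import TreeValuer, assign_wood_density, fit_hd_hierarchy
from .drivers import (
    beta_mortality,
    mycorrhizal_ratio,
    pd_standardized_effect,
    plot_structure,
    rarefied_richness,
    thermophilization_rate,
    PhylogeneticDiversity,
)
from .dynamics import compute_dynamics
from .inference import ClimatePCA


def presence_matrix(pairs) -> pd.DataFrame:
    """Plots-by-species binary presence over both censuses of each pair."""
    rows = {}
    for pair in pairs:
        species = set(pair.survivors["species"])
        species |= set(pair.deaths["species"])
        species |= set(pair.recruits["species"])
        rows[pair.plot_id] = species
    all_species = sorted(set().union(*rows.values())) if rows else []
    mat = pd.DataFrame(
        [[1 if s in rows[p] else 0 for s in all_species] for p in rows],
        index=list(rows),
        columns=all_species,
        dtype=np.int8,
    )
    return mat


def analyze_network(
    census: pd.DataFrame,
    plots: pd.DataFrame,
    traits: pd.DataFrame,
    climate: pd.DataFrame | None = None,
    newick: str | None = None,
    rarefaction_m: int = 86,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-plot metrics frame (stocks, fluxes, drivers, climate axes).

    ``traits`` must carry species, genus, family, wd_g_cm3, and optionally
    thermal_optimum and myco_type; the corresponding metrics are skipped
    when a trait column is absent.  ``climate`` (plots-by-bioclim) and
    ``newick`` enable the PCA axes and the phylogenetic-diversity metrics.
    """
    census = census_mod.load_census(census)
    pairs = census_mod.pair_censuses(census, plots)
    pairs = [census_mod.cap_growth(p)[0] for p in pairs]

    hd_models = fit_hd_hierarchy(census, plots)

    optima = (
        traits.set_index("species")["thermal_optimum"]
        if "thermal_optimum" in traits.columns
        else None
    )

    rows = []
    for pair in pairs:
        for frame in (pair.survivors, pair.deaths, pair.recruits):
            if not frame.empty:
                frame[["wd", "wd_level"]] = assign_wood_density(frame, traits)
            elif "wd" not in frame.columns:
                frame["wd"] = pd.Series(dtype=float)
        valuer = TreeValuer(hd_models[pair.plot_id])
        dyn = compute_dynamics(pair, valuer)

        first_stems = pd.concat(
            [
                pair.survivors.rename(columns={"dbh1": "dbh"}),
                pair.deaths.rename(columns={"dbh1": "dbh"}),
            ],
            ignore_index=True,
        )
        structure = plot_structure(first_stems["dbh"], pair.area_ha)
        counts = first_stems["species"].value_counts().to_numpy()
        sr = (
            rarefied_richness(counts, rarefaction_m)
            if counts.sum() >= rarefaction_m
            else np.nan
        )
        mort = beta_mortality(pair)

        row = {
            "plot_id": pair.plot_id,
            "elevation_m": pair.elevation_m,
            "latitude": pair.latitude,
            "longitude": pair.longitude,
            "area_ha": pair.area_ha,
            "t_years": pair.t_years,
            "year_first": pair.date_first.year,
            "year_last": pair.date_last.year,
            "agc1": dyn.agc1,
            "agc_final": dyn.agc_final,
            "mortality": dyn.mortality,
            "recruitment": dyn.recruitment,
            "growth": dyn.growth,
            "productivity": dyn.productivity,
            "net_change": dyn.net_change,
            "pct_change": dyn.pct_change,
            "residual": dyn.residual,
            "hd_form": hd_models[pair.plot_id].form_,
            "hd_scope": hd_models[pair.plot_id].scope,
            "dq": structure.dq,
            "n_stems": structure.n,
            "stem_density": structure.stem_density,
            "sr_rarefied": sr,
            "beta": mort.beta,
            "beta_a": mort.a,
            "beta_se": mort.beta_se,
        }
        if optima is not None:
            thermo = thermophilization_rate(pair, optima)
            row.update(
                cti_first=thermo.cti_first, cti_final=thermo.cti_final, tr=thermo.tr
            )
        if "myco_type" in traits.columns:
            myco = mycorrhizal_ratio(first_stems, traits)
            row.update(
                n_am=myco.n_am, n_ecm=myco.n_ecm, sra=myco.sra,
                myco_coverage=myco.coverage,
            )
        rows.append(row)

    metrics = pd.DataFrame(rows).set_index("plot_id")

    if newick is not None:
        calc = PhylogeneticDiversity.from_newick(newick)
        matrix = presence_matrix(pairs)
        pdz = pd_standardized_effect(matrix, calc, n_null=n_null, seed=seed)
        metrics = metrics.join(pdz)

    if climate is not None:
        axes = ClimatePCA().fit(climate.set_index("plot_id")).scores_
        metrics = metrics.join(axes)

    return metrics.reset_index()
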