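"""Elevation-band aggregation, bootstrap CIs, and regional carbon balance.

Plot-level stocks (Mg C ha^-1) are grouped into half-open elevation bands,
band means get plot-resampling bootstrap confidence intervals, and each band
mean is multiplied by the band's forest cover (km^2) to give total stocks in
Pg (1 Mg C ha^-1 x 1 km^2 = 100 Mg = 1e-7 Pg).  The regional balance is the
difference of total stocks between the two epochs divided by the elapsed
years, and deforestation emissions convert the carbon on lost cover to CO2
equivalents with the 44/12 mass ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Mg C ha^-1 times km^2 -> Pg
MG_HA_KM2_TO_PG = 1e-7
CO2_PER_C = 44.0 / 12.0
DEFAULT_BAND_EDGES = (500.0, 1200.0, 2000.0, 2800.0, 3600.0)


def assign_bands(elevations, edges=DEFAULT_BAND_EDGES) -> pd.Series:
    """Band label per plot; half-open [low, high) intervals.

    Plots outside every band get a null label (pd.NA) and are excluded
    downstream.
    """
    elev = pd.Series(elevations, dtype=float)
    labels = [f"{int(lo)}-{int(hi)}" for lo, hi in zip(edges[:-1], edges[1:])]
    out = pd.cut(elev, bins=list(edges), labels=labels, right=False)
    return out.astype(object).where(out.notna(), pd.NA)


def band_label(low: float, high: float) -> str:
    return f"{int(low)}-{int(high)}"


def bootstrap_mean_ci(
    values, n_boot: int = 1000, seed: int | None = None, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Plot-resampling bootstrap mean and percentile CI.

    A single-plot band has a defined mean but an undefined CI (nan, nan).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot bootstrap an empty band")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boots = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return mean, float(lo), float(hi)


@dataclass
class BandSummary:
    band: str
    mean_initial: float       # Mg C ha^-1
    mean_final: float
    ci_initial: tuple[float, float]
    ci_final: tuple[float, float]
    cover_initial: float      # km^2
    cover_final: float
    total_initial: float      # Pg
    total_final: float


@dataclass
class RegionalBalance:
    weighted_mean_initial: float  # Mg C ha^-1, cover-weighted across bands
    weighted_mean_final: float
    total_initial: float          # Pg
    total_final: float
    elapsed_years: float
    rate_per_ha: float            # Mg C ha^-1 y^-1
    net_balance: float            # Pg C y^-1
    cover_loss: float             # km^2
    emissions: float              # Pg CO2e from deforested area


def band_totals(
    stocks: pd.DataFrame, cover: pd.DataFrame, elapsed_years: float = 11.0
) -> tuple[list[BandSummary], RegionalBalance]:
    """Combine band stock means with forest cover into totals and balance.

    ``stocks`` needs columns band, mean_initial, mean_final (optional
    ci_*_low/high); ``cover`` needs band, cover_initial, cover_final.  Bands
    must match exactly between the two tables.
    """
    s = stocks.set_index("band")
    c = cover.set_index("band")
    if set(s.index) != set(c.index):
        raise ValueError(
            f"band mismatch between stocks ({sorted(s.index)}) and "
            f"cover ({sorted(c.index)})"
        )
    c = c.loc[s.index]

    summaries: list[BandSummary] = []
    for band in s.index:
        mi, mf = float(s.at[band, "mean_initial"]), float(s.at[band, "mean_final"])
        ci_i = (
            float(s.at[band, "ci_initial_low"]),
            float(s.at[band, "ci_initial_high"]),
        ) if "ci_initial_low" in s.columns else (float("nan"), float("nan"))
        ci_f = (
            float(s.at[band, "ci_final_low"]),
            float(s.at[band, "ci_final_high"]),
        ) if "ci_final_low" in s.columns else (float("nan"), float("nan"))
        cov_i = float(c.at[band, "cover_initial"])
        cov_f = float(c.at[band, "cover_final"])
        summaries.append(
            BandSummary(
                band=str(band),
                mean_initial=mi,
                mean_final=mf,
                ci_initial=ci_i,
                ci_final=ci_f,
                cover_initial=cov_i,
                cover_final=cov_f,
                total_initial=mi * cov_i * MG_HA_KM2_TO_PG,
                total_final=mf * cov_f * MG_HA_KM2_TO_PG,
            )
        )

    cov_i_sum = sum(b.cover_initial for b in summaries)
    cov_f_sum = sum(b.cover_final for b in summaries)
    total_i = sum(b.total_initial for b in summaries)
    total_f = sum(b.total_final for b in summaries)
    wm_i = sum(b.mean_initial * b.cover_initial for b in summaries) / cov_i_sum
    wm_f = sum(b.mean_final * b.cover_final for b in summaries) / cov_f_sum
    balance = RegionalBalance(
        weighted_mean_initial=wm_i,
        weighted_mean_final=wm_f,
        total_initial=total_i,
        total_final=total_f,
        elapsed_years=elapsed_years,
        rate_per_ha=(wm_f - wm_i) / elapsed_years,
        net_balance=(total_f - total_i) / elapsed_years,
        cover_loss=cov_i_sum - cov_f_sum,
        emissions=deforestation_emissions(stocks, cover),
    )
    return summaries, balance


def deforestation_emissions(stocks: pd.DataFrame, cover: pd.DataFrame) -> float:
    """Pg CO2e released by the cover lost per band at initial stock density.

    emissions = sum_b loss_b(km^2) * 100 * mean_initial_b(Mg C ha^-1)
                * (44/12) / 1e9.  Negative band losses (regrowth) are flagged
    and contribute zero.
    """
    s = stocks.set_index("band")
    c = cover.set_index("band").loc[s.index]
    loss = c["cover_initial"] - c["cover_final"]
    if (loss < 0).any():
        import logging

        logging.getLogger(__name__).warning(
            "negative cover loss (regrowth) in band(s) %s; excluded from emissions",
            list(loss.index[loss < 0]),
        )
    loss = loss.clip(lower=0.0)
    carbon_pg = float((loss * s["mean_initial"]).sum()) * MG_HA_KM2_TO_PG
    return carbon_pg * CO2_PER_C


def band_stock_table(
    plot_stocks: pd.DataFrame,
    edges=DEFAULT_BAND_EDGES,
    n_boot: int = 1000,
    seed: int | None = None,
    cut_year: int = 2009,
) -> pd.DataFrame:
    """Per-band bootstrap means of plot stocks for the two epochs.

    ``plot_stocks`` needs columns elevation_m, agc1, agc_final, and the
    census years ``year_first``/``year_last``.  Initial-epoch means use
    plots whose first census is in or before ``cut_year``; final-epoch means
    use plots whose last census falls after it.
    """
    df = plot_stocks.copy()
    df["band"] = assign_bands(df["elevation_m"].to_numpy(), edges).to_numpy()
    df = df[df["band"].notna()]
    rng = np.random.default_rng(seed)
    rows = []
    for band, grp in df.groupby("band", sort=False):
        initial = grp.loc[grp["year_first"] <= cut_year, "agc1"]
        final = grp.loc[grp["year_last"] > cut_year, "agc_final"]
        if initial.empty or final.empty:
            raise ValueError(f"band {band}: no plots in one of the epochs")
        mi, lo_i, hi_i = bootstrap_mean_ci(
            initial, n_boot, int(rng.integers(2**31))
        )
        mf, lo_f, hi_f = bootstrap_mean_ci(final, n_boot, int(rng.integers(2**31)))
        rows.append(
            {
                "band": band,
                "mean_initial": mi,
                "ci_initial_low": lo_i,
                "ci_initial_high": hi_i,
                "mean_final": mf,
                "ci_final_low": lo_f,
                "ci_final_high": hi_f,
                "n_plots": len(grp),
            }
        )
    order = [band_label(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    out = pd.DataFrame(rows).set_index("band").reindex(
        [b for b in order if b in {r["band"] for r in rows}]
    )
    return out.reset_index()


def regional_summary_table(
    summaries: list[BandSummary], balance: RegionalBalance
) -> pd.DataFrame:
    """Band-by-band table with a cover-weighted summary row."""
    rows = [
        {
            "band": b.band,
            "mean_initial": b.mean_initial,
            "mean_final": b.mean_final,
            "cover_initial": b.cover_initial,
            "cover_final": b.cover_final,
            "total_initial": b.total_initial,
            "total_final": b.total_final,
        }
        for b in summaries
    ]
    rows.append(
        {
            "band": "weighted mean",
            "mean_initial": balance.weighted_mean_initial,
            "mean_final": balance.weighted_mean_final,
            "cover_initial": sum(b.cover_initial for b in summaries),
            "cover_final": sum(b.cover_final for b in summaries),
            "total_initial": balance.total_initial,
            "total_final": balance.total_final,
        }
    )
    return pd.DataFrame(rows)
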