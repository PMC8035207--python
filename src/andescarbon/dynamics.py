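"""Annualized aboveground-carbon dynamics of a censused plot.

Components (all Mg C ha^-1 y^-1):

* mortality    — AGC of stems that died, valued at their first-census size
* recruitment  — AGC of new >=10 cm stems minus the AGC of a 9.99-cm tree of
                 the same wood density on the same allometry (the stem was
                 just below the detection limit at the first census, so only
                 the growth since then is new carbon)
* growth       — summed AGC increment of survivors (can be negative for
                 stems shrinking within the -0.1 cm/y cleaning bound)
* productivity — recruitment + growth
* net change   — (final stock - initial stock) / t, computed from the stock
                 difference, with the component sum kept as an audit

The bookkeeping identity net = productivity - mortality + residual holds
exactly, where the residual is the 9.99-cm baseline carbon of the recruits
(plus any floored negative recruit contributions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import TreeValuer, plot_agc_stock
from .census import PlotCensusPair

RECRUIT_BASELINE_DBH = 9.99  # cm, just below the 10-cm census threshold


@dataclass
class PlotDynamics:
    plot_id: str
    agc1: float           # Mg C ha^-1
    agc_final: float      # Mg C ha^-1
    mortality: float      # Mg C ha^-1 y^-1
    recruitment: float    # Mg C ha^-1 y^-1
    growth: float         # Mg C ha^-1 y^-1
    productivity: float   # Mg C ha^-1 y^-1
    net_change: float     # Mg C ha^-1 y^-1
    pct_change: float     # % y^-1 (nan when agc1 == 0)
    residual: float       # net - (productivity - mortality), Mg C ha^-1 y^-1
    t_years: float
    area_ha: float


def agc_mortality(pair: PlotCensusPair, valuer: TreeValuer) -> float:
    """Sum of the AGC of dead stems at census-1 size, annualized."""
    if pair.deaths.empty:
        return 0.0
    agc = valuer.agc(pair.deaths["wd"].to_numpy(), pair.deaths["dbh1"].to_numpy())
    return float(np.sum(agc)) / 1000.0 / pair.area_ha / pair.t_years


def agc_recruitment(pair: PlotCensusPair, valuer: TreeValuer) -> float:
    """Annualized AGC gain from recruits, net of the 9.99-cm baseline."""
    if pair.recruits.empty:
        return 0.0
    wd = pair.recruits["wd"].to_numpy()
    agc_obs = valuer.agc(wd, pair.recruits["dbh2"].to_numpy())
    agc_base = valuer.agc(wd, np.full(len(wd), RECRUIT_BASELINE_DBH))
    contrib = np.maximum(agc_obs - agc_base, 0.0)
    return float(np.sum(contrib)) / 1000.0 / pair.area_ha / pair.t_years


def agc_growth(pair: PlotCensusPair, valuer: TreeValuer) -> float:
    """Annualized summed AGC increment of surviving stems."""
    if pair.survivors.empty:
        return 0.0
    wd = pair.survivors["wd"].to_numpy()
    inc = valuer.agc(wd, pair.survivors["dbh2"].to_numpy()) - valuer.agc(
        wd, pair.survivors["dbh1"].to_numpy()
    )
    return float(np.sum(inc)) / 1000.0 / pair.area_ha / pair.t_years


def compute_dynamics(pair: PlotCensusPair, valuer: TreeValuer) -> PlotDynamics:
    """All stock and flux components for one plot.

    The pair's ``survivors``/``deaths``/``recruits`` frames must already
    carry a ``wd`` column (see :func:`allometry.assign_wood_density`) and the
    growth caps should have been applied.
    """
    for frame in (pair.survivors, pair.deaths, pair.recruits):
        if not frame.empty and "wd" not in frame.columns:
            raise ValueError("stems must carry a 'wd' column; assign wood density first")

    surv, dead, rec = pair.survivors, pair.deaths, pair.recruits
    agc1_kg = np.concatenate([
        valuer.agc(surv["wd"].to_numpy(), surv["dbh1"].to_numpy()) if len(surv) else np.zeros(0),
        valuer.agc(dead["wd"].to_numpy(), dead["dbh1"].to_numpy()) if len(dead) else np.zeros(0),
    ])
    agc2_kg = np.concatenate([
        valuer.agc(surv["wd"].to_numpy(), surv["dbh2"].to_numpy()) if len(surv) else np.zeros(0),
        valuer.agc(rec["wd"].to_numpy(), rec["dbh2"].to_numpy()) if len(rec) else np.zeros(0),
    ])
    agc1 = plot_agc_stock(agc1_kg, pair.area_ha)
    agc_final = plot_agc_stock(agc2_kg, pair.area_ha)

    mortality = agc_mortality(pair, valuer)
    recruitment = agc_recruitment(pair, valuer)
    growth = agc_growth(pair, valuer)
    productivity = recruitment + growth
    net_change = (agc_final - agc1) / pair.t_years
    pct_change = 100.0 * net_change / agc1 if agc1 > 0 else float("nan")
    residual = net_change - (productivity - mortality)

    return PlotDynamics(
        plot_id=pair.plot_id,
        agc1=agc1,
        agc_final=agc_final,
        mortality=mortality,
        recruitment=recruitment,
        growth=growth,
        productivity=productivity,
        net_change=net_change,
        pct_change=pct_change,
        residual=residual,
        t_years=pair.t_years,
        area_ha=pair.area_ha,
    )


def dynamics_table(dynamics: list[PlotDynamics]) -> pd.DataFrame:
    """One row per plot, all :class:`PlotDynamics` fields."""
    return pd.DataFrame([vars(d) for d in dynamics])
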