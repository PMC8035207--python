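"""Census data model: validation, census pairing, and growth-rate cleaning.

A census table holds one row per tagged stem per census.  Required columns:

    plot_id, tag, census, date, dbh_cm, species, genus, family, status

with optional ``height_m`` for the subset of stems measured in the field.
``status`` is one of ``alive``, ``dead`` or ``recruit`` (``recruit`` is
treated as alive; the survivor/death/recruit partition is re-derived from
tag presence across censuses, not trusted from the column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "plot_id", "tag", "census", "date", "dbh_cm",
    "species", "genus", "family", "status",
)
ALIVE_STATUSES = frozenset({"alive", "recruit"})
VALID_STATUSES = frozenset({"alive", "dead", "recruit"})

#: annualized DBH increment bounds (cm / y) used to clean survivor growth
GROWTH_RATE_MIN = -0.1
GROWTH_RATE_MAX = 7.5

DAYS_PER_YEAR = 365.25


class CensusValidationError(ValueError):
    """Raised when a census table violates the documented schema."""


def load_census(path_or_df) -> pd.DataFrame:
    """Load and validate a census table from CSV (or an in-memory frame).

    Every offending row is reported (with its 0-based row number) in a single
    :class:`CensusValidationError`; nothing is silently dropped.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype={"plot_id": str, "tag": str})

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CensusValidationError(
            f"census table is missing mandatory column(s): {', '.join(missing)}"
        )

    problems: list[str] = []

    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    for idx in df.index[dates.isna()]:
        problems.append(f"row {idx}: unparseable date {df.at[idx, 'date']!r}")
    df["date"] = dates

    dbh = pd.to_numeric(df["dbh_cm"], errors="coerce")
    for idx in df.index[dbh.isna()]:
        problems.append(f"row {idx}: non-numeric dbh_cm {df.at[idx, 'dbh_cm']!r}")
    for idx in df.index[dbh <= 0]:
        problems.append(f"row {idx}: non-positive dbh_cm {dbh[idx]!r}")
    df["dbh_cm"] = dbh

    bad_status = ~df["status"].isin(VALID_STATUSES)
    for idx in df.index[bad_status]:
        problems.append(f"row {idx}: unknown status {df.at[idx, 'status']!r}")

    dup = df.duplicated(subset=["plot_id", "census", "tag"], keep=False)
    if dup.any():
        for (plot, cen, tag), grp in df[dup].groupby(["plot_id", "census", "tag"]):
            problems.append(
                f"duplicate tag {tag!r} in plot {plot!r} census {cen} "
                f"(rows {list(grp.index)})"
            )

    if "height_m" in df.columns:
        df["height_m"] = pd.to_numeric(df["height_m"], errors="coerce")
    else:
        df["height_m"] = np.nan

    if problems:
        raise CensusValidationError(
            "census table failed validation:\n  " + "\n  ".join(problems)
        )
    return df


@dataclass
class PlotCensusPair:
    """First and last census of one plot, with stems partitioned by fate.

    ``survivors`` carries one row per stem alive in both censuses with
    ``dbh1``/``dbh2`` columns; ``deaths`` are stems alive in the first census
    but dead or absent in the last; ``recruits`` are stems absent from the
    first census and alive in the last.
    """

    plot_id: str
    area_ha: float
    elevation_m: float
    latitude: float
    longitude: float
    t_years: float
    date_first: pd.Timestamp
    date_last: pd.Timestamp
    survivors: pd.DataFrame
    deaths: pd.DataFrame
    recruits: pd.DataFrame
    country: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def n_first(self) -> int:
        return len(self.survivors) + len(self.deaths)

    @property
    def n_last(self) -> int:
        return len(self.survivors) + len(self.recruits)


def _alive(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["status"].isin(ALIVE_STATUSES)]


def pair_censuses(census: pd.DataFrame, plots: pd.DataFrame) -> list[PlotCensusPair]:
    """Align the first and last census of each plot.

    ``plots`` must carry ``plot_id, area_ha, elevation_m, latitude, longitude``
    (``country`` optional).  Plots censused only once are excluded with a
    warning.  The census interval t is the date difference in decimal years
    (day count / 365.25).
    """
    pairs: list[PlotCensusPair] = []
    meta = plots.set_index("plot_id")
    for plot_id, grp in census.groupby("plot_id", sort=True):
        censuses = sorted(grp["census"].unique())
        if len(censuses) < 2:
            logger.warning("plot %s has a single census; excluded", plot_id)
            continue
        first = grp[grp["census"] == censuses[0]]
        last = grp[grp["census"] == censuses[-1]]
        d1 = first["date"].iloc[0]
        d2 = last["date"].iloc[0]
        t = (d2 - d1).days / DAYS_PER_YEAR
        if t <= 0:
            raise CensusValidationError(
                f"plot {plot_id}: non-positive census interval ({t:.3f} y)"
            )

        alive1 = _alive(first).set_index("tag")
        last_idx = last.set_index("tag")
        alive2 = _alive(last).set_index("tag")

        surv_tags = alive1.index.intersection(alive2.index)
        death_tags = alive1.index.difference(surv_tags)  # dead or absent later
        recruit_tags = alive2.index.difference(alive1.index)

        survivors = alive1.loc[surv_tags, ["species", "genus", "family", "dbh_cm"]].rename(
            columns={"dbh_cm": "dbh1"}
        )
        survivors["dbh2"] = alive2.loc[surv_tags, "dbh_cm"]
        deaths = alive1.loc[death_tags, ["species", "genus", "family", "dbh_cm"]].rename(
            columns={"dbh_cm": "dbh1"}
        )
        recruits = alive2.loc[recruit_tags, ["species", "genus", "family", "dbh_cm"]].rename(
            columns={"dbh_cm": "dbh2"}
        )

        # sanity: every census-2 alive tag is survivor or recruit, census-1
        # alive tag survivor or death
        assert len(survivors) + len(deaths) == len(alive1)
        assert len(survivors) + len(recruits) == len(alive2)
        del last_idx

        row = meta.loc[plot_id]
        pairs.append(
            PlotCensusPair(
                plot_id=str(plot_id),
                area_ha=float(row["area_ha"]),
                elevation_m=float(row["elevation_m"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                t_years=float(t),
                date_first=d1,
                date_last=d2,
                survivors=survivors.reset_index(),
                deaths=deaths.reset_index(),
                recruits=recruits.reset_index(),
                country=str(row["country"]) if "country" in row.index else "",
            )
        )
    return pairs


def cap_growth(
    pair: PlotCensusPair,
    rate_min: float = GROWTH_RATE_MIN,
    rate_max: float = GROWTH_RATE_MAX,
) -> tuple[PlotCensusPair, pd.DataFrame]:
    """Clamp survivor DBH increments to [rate_min, rate_max] cm/y.

    Out-of-bounds second-census diameters are rewritten to
    ``dbh1 + bound * t``; census-1 diameters are never touched.  Returns the
    adjusted pair (a copy) and a log frame of every rewritten stem.
    Idempotent: re-applying leaves the pair unchanged.
    """
    surv = pair.survivors.copy()
    t = pair.t_years
    rate = (surv["dbh2"] - surv["dbh1"]) / t
    tol = 1e-9  # ignore float jitter from a previous capping pass
    low = rate < rate_min - tol
    high = rate > rate_max + tol
    log_rows = []
    for mask, bound in ((low, rate_min), (high, rate_max)):
        for idx in surv.index[mask]:
            new = surv.at[idx, "dbh1"] + bound * t
            log_rows.append(
                {
                    "plot_id": pair.plot_id,
                    "tag": surv.at[idx, "tag"],
                    "dbh2_old": surv.at[idx, "dbh2"],
                    "dbh2_new": new,
                    "rate_old": rate[idx],
                    "bound": bound,
                }
            )
            surv.at[idx, "dbh2"] = new
    log = pd.DataFrame(
        log_rows,
        columns=["plot_id", "tag", "dbh2_old", "dbh2_new", "rate_old", "bound"],
    )
    return replace(pair, survivors=surv), log
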