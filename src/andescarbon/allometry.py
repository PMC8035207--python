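"""Height-diameter allometry, wood-density assignment, and per-tree carbon.

Tree height is rarely measured on every stem, so per-plot height-diameter
(H:DBH) models are fitted to the measured subset and used to predict the
height of every stem.  Four candidate forms compete:

    loglog1   ln H = c0 + c1 ln D
    loglog2   ln H = c0 + c1 ln D + c2 (ln D)^2
    weibull3  H = c0 (1 - exp(-(D / c1)^c2))
    mm2       H = c0 D / (c1 + D)          (Michaelis-Menten)

The winner is the form with the lowest residual standard error on the metre
scale, with ties (within 1% relative RSE) broken by smaller mean bias and
then by fewer parameters.  Log-scale fits are back-transformed with the
Baskerville correction exp(RSE_log^2 / 2), without which predicted heights
are systematically low.

Biomass follows the pantropical moist-forest allometry
AGB (kg) = 0.0673 (WD · DBH^2 · H)^0.976 with DBH in cm, H in m and wood
density WD in g cm^-3, and carbon is AGC = 0.456 · AGB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

CARBON_FRACTION = 0.456
HD_FORMS = ("loglog1", "loglog2", "weibull3", "mm2")
_N_PARAMS = {"loglog1": 2, "loglog2": 3, "weibull3": 3, "mm2": 2}


def agb_chave(wd, dbh, h):
    """Aboveground biomass (kg) from wood density, diameter and height."""
    wd = np.asarray(wd, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(wd <= 0) or np.any(dbh <= 0) or np.any(h <= 0):
        raise ValueError("wood density, DBH and height must all be positive")
    return 0.0673 * (wd * dbh**2 * h) ** 0.976


def agc_from_agb(agb):
    """Aboveground carbon (kg C) from aboveground biomass (kg)."""
    agb = np.asarray(agb, dtype=float)
    if np.any(agb < 0):
        raise ValueError("AGB must be non-negative")
    return CARBON_FRACTION * agb


def plot_agc_stock(agc_kg, area_ha: float) -> float:
    """Per-hectare stock (Mg C ha^-1) from per-tree AGC values in kg."""
    if area_ha <= 0:
        raise ValueError("plot area must be positive")
    return float(np.sum(agc_kg)) / 1000.0 / area_ha


@dataclass
class HDFit:
    """One fitted candidate H:DBH form."""

    form: str
    coef: np.ndarray
    rse: float          # residual standard error, m
    bias: float         # mean signed residual (predicted - observed), m
    correction: float   # Baskerville factor (1.0 for arithmetic-scale fits)
    converged: bool

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.form]

    def predict(self, dbh) -> np.ndarray:
        d = np.asarray(dbh, dtype=float)
        c = self.coef
        if self.form == "loglog1":
            return np.exp(c[0] + c[1] * np.log(d)) * self.correction
        if self.form == "loglog2":
            ld = np.log(d)
            return np.exp(c[0] + c[1] * ld + c[2] * ld**2) * self.correction
        if self.form == "weibull3":
            return c[0] * (1.0 - np.exp(-((d / c[1]) ** c[2])))
        if self.form == "mm2":
            return c[0] * d / (c[1] + d)
        raise ValueError(f"unknown form {self.form!r}")


def _fit_loglog(dbh, h, order):
    ld, lh = np.log(dbh), np.log(h)
    X = np.vander(ld, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, lh, rcond=None)
    resid_log = lh - X @ coef
    dof = max(len(h) - (order + 1), 1)
    rse_log = np.sqrt(np.sum(resid_log**2) / dof)
    return coef, float(np.exp(rse_log**2 / 2.0))


def fit_hd_candidates(dbh, height, forms=HD_FORMS) -> dict[str, HDFit]:
    """Fit each candidate form to (DBH, H) pairs.

    Nonlinear forms that fail to converge are returned with
    ``converged=False`` and infinite RSE so the selection can skip them.
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    ok = np.isfinite(dbh) & np.isfinite(height) & (dbh > 0) & (height > 0)
    dbh, height = dbh[ok], height[ok]
    fits: dict[str, HDFit] = {}
    for form in forms:
        coef, correction, converged = None, 1.0, True
        try:
            if form == "loglog1":
                coef, correction = _fit_loglog(dbh, height, 1)
            elif form == "loglog2":
                coef, correction = _fit_loglog(dbh, height, 2)
            elif form == "weibull3":
                p0 = (float(height.max()) * 1.1, float(np.median(dbh)), 1.0)
                coef, _ = curve_fit(
                    lambda d, a, b, c: a * (1 - np.exp(-((d / b) ** c))),
                    dbh, height, p0=p0, maxfev=20000,
                    bounds=([1e-3, 1e-3, 1e-2], [1e4, 1e4, 20.0]),
                )
            elif form == "mm2":
                p0 = (float(height.max()) * 1.5, float(np.median(dbh)))
                coef, _ = curve_fit(
                    lambda d, a, b: a * d / (b + d),
                    dbh, height, p0=p0, maxfev=20000,
                    bounds=([1e-3, 1e-3], [1e4, 1e4]),
                )
            else:
                raise ValueError(f"unknown form {form!r}")
        except (RuntimeError, ValueError):
            converged = False

        if converged:
            fit = HDFit(form, np.asarray(coef, float), np.nan, np.nan,
                        correction, True)
            pred = fit.predict(dbh)
            resid = pred - height
            dof = max(len(height) - fit.n_params, 1)
            fit.rse = float(np.sqrt(np.sum(resid**2) / dof))
            fit.bias = float(np.mean(resid))
        else:
            fit = HDFit(form, np.array([]), np.inf, np.inf, 1.0, False)
        fits[form] = fit
    return fits


def select_hd_model(fits: dict[str, HDFit], tie_tol: float = 0.01) -> HDFit:
    """Pick the candidate with the lowest metre-scale RSE.

    Candidates within ``tie_tol`` relative RSE of the best (plus a tiny
    absolute epsilon so exact fits tie) compete on smaller \\|bias\\|, then on
    fewer parameters.
    """
    avail = [f for f in fits.values() if f.converged]
    if not avail:
        raise ValueError("no H:DBH candidate converged")
    best_rse = min(f.rse for f in avail)
    window = best_rse * (1.0 + tie_tol) + 1e-9
    tied = [f for f in avail if f.rse <= window]
    tied.sort(key=lambda f: (abs(f.bias), f.n_params, f.rse))
    return tied[0]


class HeightDiameterModel(BaseEstimator, RegressorMixin):
    """Height-diameter allometry with internal candidate-form selection.

    Parameters
    ----------
    forms : tuple of str
        Candidate forms to fit (subset of ``HD_FORMS``).
    min_obs : int
        Minimum number of (DBH, H) pairs required to fit.
    tie_tol : float
        Relative RSE window within which candidates are considered tied.

    Attributes
    ----------
    candidates_ : dict mapping form name to :class:`HDFit`
    best_ : the selected :class:`HDFit`
    form_, coef_, rse_, bias_ : selected-model summaries
    scope : provenance label ("plot", "country" or "regional"), settable
    """

    def __init__(self, forms=HD_FORMS, min_obs: int = 10, tie_tol: float = 0.01):
        self.forms = forms
        self.min_obs = min_obs
        self.tie_tol = tie_tol

    def fit(self, X, y):
        dbh = np.asarray(X, dtype=float).reshape(-1)
        height = np.asarray(y, dtype=float).reshape(-1)
        if len(dbh) != len(height):
            raise ValueError("DBH and height must have equal length")
        if len(dbh) < self.min_obs:
            raise ValueError(
                f"need at least {self.min_obs} height observations, got {len(dbh)}"
            )
        self.candidates_ = fit_hd_candidates(dbh, height, self.forms)
        self.best_ = select_hd_model(self.candidates_, self.tie_tol)
        self.form_ = self.best_.form
        self.coef_ = self.best_.coef
        self.rse_ = self.best_.rse
        self.bias_ = self.best_.bias
        self.n_obs_ = len(dbh)
        self.scope = getattr(self, "scope", "plot")
        return self

    def predict(self, X):
        check_is_fitted(self, "best_")
        return self.best_.predict(np.asarray(X, dtype=float).reshape(-1))


def fit_hd_hierarchy(
    census: pd.DataFrame,
    plots: pd.DataFrame,
    min_obs: int = 10,
    min_dbh: float = 5.0,
) -> dict[str, HeightDiameterModel]:
    """Fit one H:DBH model per plot, falling back to a country-level pool.

    Plots with fewer than ``min_obs`` measured heights (DBH >= ``min_dbh``)
    receive the pooled model of all measured stems in their country, the way
    height-poor plots are handled in practice when a national subnetwork
    carries the height data.
    """
    meas = census[
        census["height_m"].notna() & (census["dbh_cm"] >= min_dbh)
    ]
    country_of = plots.set_index("plot_id")["country"].to_dict() \
        if "country" in plots.columns else {}
    models: dict[str, HeightDiameterModel] = {}
    plot_ids = plots["plot_id"].astype(str).tolist()

    country_models: dict[str, HeightDiameterModel] = {}
    for plot_id in plot_ids:
        sub = meas[meas["plot_id"] == plot_id]
        if len(sub) >= min_obs:
            m = HeightDiameterModel(min_obs=min_obs).fit(
                sub["dbh_cm"], sub["height_m"]
            )
            m.scope = "plot"
            models[plot_id] = m
        else:
            country = str(country_of.get(plot_id, ""))
            if country not in country_models:
                plots_in_country = [
                    p for p in plot_ids if str(country_of.get(p, "")) == country
                ]
                pool = meas[meas["plot_id"].isin(plots_in_country)]
                if len(pool) < min_obs:
                    raise ValueError(
                        f"plot {plot_id}: no plot-level heights and the "
                        f"country pool ({country!r}) has only {len(pool)} "
                        "measured stems"
                    )
                cm = HeightDiameterModel(min_obs=min_obs).fit(
                    pool["dbh_cm"], pool["height_m"]
                )
                cm.scope = "country"
                country_models[country] = cm
            models[plot_id] = country_models[country]
    return models


def assign_wood_density(
    stems: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Assign wood density (g cm^-3) to each stem by taxonomic cascade.

    Lookup order: species value -> genus mean -> family mean -> mean of the
    wood densities already assigned to the other stems of the plot.  Returns
    a frame with ``wd`` and provenance ``wd_level`` aligned to ``stems``.
    """
    sp = traits.groupby("species")["wd_g_cm3"].mean()
    gen = traits.groupby("genus")["wd_g_cm3"].mean()
    fam = traits.groupby("family")["wd_g_cm3"].mean()

    wd = stems["species"].map(sp)
    level = pd.Series(np.where(wd.notna(), "species", None), index=stems.index,
                      dtype=object)
    m = wd.isna()
    wd[m] = stems.loc[m, "genus"].map(gen)
    level[m & wd.notna()] = "genus"
    m = wd.isna()
    wd[m] = stems.loc[m, "family"].map(fam)
    level[m & wd.notna()] = "family"
    m = wd.isna()
    if m.any():
        assigned = wd[~m]
        if assigned.empty:
            raise ValueError("no stem in the plot could be assigned a wood density")
        wd[m] = assigned.mean()
        level[m] = "plot-mean"
    return pd.DataFrame({"wd": wd.astype(float), "wd_level": level})


class TreeValuer:
    """Values individual stems in kg C on a plot's allometric surface."""

    def __init__(self, hd_model: HeightDiameterModel):
        self.hd_model = hd_model

    def height(self, dbh) -> np.ndarray:
        return self.hd_model.predict(dbh)

    def agc(self, wd, dbh) -> np.ndarray:
        dbh = np.asarray(dbh, dtype=float)
        if dbh.size == 0:
            return np.zeros(0)
        return agc_from_agb(agb_chave(wd, dbh, self.height(dbh)))
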