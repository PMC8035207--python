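"""Climate ordination and information-theoretic multimodel inference.

The 19 bioclimatic variables are reduced to two principal-component axes per
block (11 temperature variables, 8 precipitation variables) fitted on
centred, unit-variance data.  Driver inference then enumerates Gaussian
linear models over all predictor subsets, retains the set with AIC within 4
of the best model, and reports natural (conditional) model-averaged
coefficients: each coefficient is averaged, with Akaike weights renormalized
over the retained models that contain it.  Coefficients are reported both
raw and standardized by the partial standard deviation

    S*_xi = S_xi * sqrt(1 / VIF_xi) * sqrt((n - 1) / (n - p))

which discounts predictors in proportion to their collinearity (VIF) with
the other predictors of the same model.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

TEMPERATURE_VARS = (
    "MAT", "MDR", "Isoth", "TS", "MaxTWarmM", "MinTCM", "TAR",
    "MeanTWarmQ", "MeanTDQ", "MeanTWetQ", "MeanTCQ",
)
PRECIPITATION_VARS = (
    "MAP", "PWetM", "PDM", "PS", "PWetQ", "PDQ", "PWarmQ", "PCQ",
)


class ClimatePCA(BaseEstimator, TransformerMixin):
    """Separate two-axis PCAs of the temperature and precipitation blocks.

    Fitted attributes: ``scores_`` (frame with PCA_temp_1/2, PCA_prec_1/2),
    ``loadings_`` (variable-by-axis frame), ``variance_explained_`` (fraction
    per axis).  Axis signs follow the convention that the variable with the
    largest absolute loading on an axis loads positively.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        self._fits = {}
        loadings = {}
        variance = {}
        for block, variables in (("temp", TEMPERATURE_VARS),
                                 ("prec", PRECIPITATION_VARS)):
            missing = [v for v in variables if v not in X.columns]
            if missing:
                raise ValueError(
                    f"climate table is missing variable(s): {', '.join(missing)}"
                )
            data = X[list(variables)].to_numpy(dtype=float)
            scaler = StandardScaler().fit(data)
            pca = PCA(n_components=self.n_components).fit(
                scaler.transform(data)
            )
            # sign convention: dominant variable loads positive
            for axis in range(self.n_components):
                load = pca.components_[axis]
                if load[np.argmax(np.abs(load))] < 0:
                    pca.components_[axis] = -load
            self._fits[block] = (scaler, pca, list(variables))
            for axis in range(self.n_components):
                loadings[f"PCA_{block}_{axis + 1}"] = pd.Series(
                    pca.components_[axis], index=list(variables)
                )
                variance[f"PCA_{block}_{axis + 1}"] = float(
                    pca.explained_variance_ratio_[axis]
                )
        self.loadings_ = pd.DataFrame(loadings)
        self.variance_explained_ = pd.Series(variance)
        self.scores_ = self.transform(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "_fits")
        out = {}
        for block, (scaler, pca, variables) in self._fits.items():
            scores = pca.transform(scaler.transform(X[variables].to_numpy(float)))
            for axis in range(self.n_components):
                out[f"PCA_{block}_{axis + 1}"] = scores[:, axis]
        return pd.DataFrame(out, index=X.index)


def climate_pca(climate: pd.DataFrame) -> ClimatePCA:
    """Fit a :class:`ClimatePCA` on a plots-by-variables climate table."""
    return ClimatePCA().fit(climate)


# ---------------------------------------------------------------------------
# partial standard deviations

def variance_inflation(X: np.ndarray) -> np.ndarray:
    """VIF of each column of ``X``: 1 / (1 - R^2) of it on the others.

    A single predictor has VIF 1 by convention; perfect collinearity yields
    an infinite VIF.
    """
    n, p = X.shape
    if p == 1:
        return np.ones(1)
    vifs = np.empty(p)
    for i in range(p):
        y = X[:, i]
        others = np.column_stack([np.ones(n), np.delete(X, i, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        vifs[i] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def partial_sd(S: np.ndarray, vif: np.ndarray, n: int, p: int) -> np.ndarray:
    """S* = S * sqrt(1/VIF) * sqrt((n - 1) / (n - p)); p = predictor count."""
    return S * np.sqrt(1.0 / vif) * np.sqrt((n - 1) / (n - p))


def partial_sd_standardize(X: pd.DataFrame, coefs: pd.Series) -> pd.DataFrame:
    """Partial-SD-standardized coefficients for one fitted linear model.

    ``X`` holds the model's predictors (one column each, no intercept) and
    ``coefs`` the raw slope estimates.  Returns beta, S, VIF, S_star and
    beta_star (= beta * S_star) per predictor.
    """
    names = list(coefs.index)
    data = X[names].to_numpy(dtype=float)
    n, p = data.shape
    if n <= p:
        raise ValueError("need more observations than predictors")
    S = data.std(axis=0, ddof=1)
    vif = variance_inflation(data)
    s_star = partial_sd(S, vif, n, p)
    beta = coefs.to_numpy(dtype=float)
    return pd.DataFrame(
        {"beta": beta, "S": S, "VIF": vif, "S_star": s_star,
         "beta_star": beta * s_star},
        index=names,
    )


# ---------------------------------------------------------------------------
# all-subsets AIC model averaging

def _ols_aic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS fit and Gaussian AIC with the ML variance estimate.

    The parameter count includes the intercept and the variance, matching
    the likelihood-based AIC convention of the multimodel-inference
    literature.
    """
    n = len(y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    k = X.shape[1] + 1  # + variance
    aic = n * (np.log(2.0 * np.pi * rss / n) + 1.0) + 2.0 * k
    return coef, aic


class AICModelAverager(BaseEstimator, RegressorMixin):
    """All-subsets Gaussian linear models with natural model averaging.

    Parameters
    ----------
    delta_max : float
        AIC window; models with AIC within ``delta_max`` of the best are
        retained (use ``np.inf`` to retain all).
    standardize : bool
        Standardize predictors to mean 0, sd 1 (ddof=1) before fitting.
    max_predictors : int
        Guard against enumerating more than 2^max_predictors subsets.

    Attributes
    ----------
    models_ : frame with one row per candidate subset (aic, delta, weight,
        retained flag; weights are Akaike weights over the retained set)
    coef_table_ : per-predictor natural averages: raw coefficient,
        partial-SD-standardized coefficient, selection weight
    best_subset_ : tuple of predictor names of the AIC-best model
    """

    def __init__(self, delta_max: float = 4.0, standardize: bool = True,
                 max_predictors: int = 12):
        self.delta_max = delta_max
        self.standardize = standardize
        self.max_predictors = max_predictors

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X).copy()
        names = list(X.columns)
        y = np.asarray(y, dtype=float).reshape(-1)
        n, p_full = X.shape
        if p_full > self.max_predictors:
            raise ValueError(
                f"{p_full} predictors exceed the all-subsets limit of "
                f"{self.max_predictors}"
            )
        if n <= p_full + 2:
            raise ValueError("too few observations for the full model")

        data = X.to_numpy(dtype=float)
        self._center = data.mean(axis=0)
        self._scale = data.std(axis=0, ddof=1) if self.standardize else np.ones(p_full)
        if self.standardize:
            data = (data - self._center) / self._scale

        rows = []
        fits = {}
        for size in range(p_full + 1):
            for subset in combinations(range(p_full), size):
                cols = np.column_stack(
                    [np.ones(n)] + [data[:, j] for j in subset]
                )
                coef, aic = _ols_aic(cols, y)
                fits[subset] = coef
                rows.append({"subset": tuple(names[j] for j in subset),
                             "_idx": subset, "aic": aic})
        models = pd.DataFrame(rows)
        models["delta"] = models["aic"] - models["aic"].min()
        models["retained"] = models["delta"] <= self.delta_max
        w = np.where(models["retained"], np.exp(-models["delta"] / 2.0), 0.0)
        models["weight"] = w / w.sum()
        self.models_ = models.drop(columns="_idx").sort_values(
            "aic", ignore_index=True
        )
        best = models.loc[models["delta"].idxmin(), "_idx"]
        self.best_subset_ = tuple(names[j] for j in best)

        # natural (conditional) averages over retained models containing each term
        retained = models[models["retained"]]
        raw_avg, std_avg, sel_weight = {}, {}, {}
        intercept_num = 0.0
        for _, row in retained.iterrows():
            subset = row["_idx"]
            coef = fits[subset]
            intercept_num += row["weight"] * coef[0]
            if len(subset) == 0:
                continue
            sub_data = data[:, list(subset)]
            vif = variance_inflation(sub_data)
            S = sub_data.std(axis=0, ddof=1)
            s_star = partial_sd(S, vif, n, len(subset))
            for pos, j in enumerate(subset):
                name = names[j]
                raw_avg.setdefault(name, []).append((row["weight"], coef[pos + 1]))
                std_avg.setdefault(name, []).append(
                    (row["weight"], coef[pos + 1] * s_star[pos])
                )
        records = []
        for name in names:
            if name in raw_avg:
                wts = np.array([w for w, _ in raw_avg[name]])
                raw = np.array([b for _, b in raw_avg[name]])
                std = np.array([b for _, b in std_avg[name]])
                records.append({
                    "predictor": name,
                    "coef": float(np.sum(wts * raw) / np.sum(wts)),
                    "coef_partial_sd": float(np.sum(wts * std) / np.sum(wts)),
                    "selection_weight": float(np.sum(wts)),
                    "n_models": len(wts),
                })
            else:
                records.append({"predictor": name, "coef": np.nan,
                                "coef_partial_sd": np.nan,
                                "selection_weight": 0.0, "n_models": 0})
        self.coef_table_ = pd.DataFrame(records).set_index("predictor")
        self.intercept_ = float(intercept_num)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def predict(self, X: pd.DataFrame):
        check_is_fitted(self, "coef_table_")
        data = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(float)
        if self.standardize:
            data = (data - self._center) / self._scale
        coef = self.coef_table_["coef"].fillna(0.0).to_numpy()
        return self.intercept_ + data @ coef

    @property
    def retained_(self) -> pd.DataFrame:
        check_is_fitted(self, "models_")
        return self.models_[self.models_["retained"]].reset_index(drop=True)


def it_model_average(X: pd.DataFrame, y, delta_max: float = 4.0) -> AICModelAverager:
    """Fit an :class:`AICModelAverager` on a predictor frame and response."""
    return AICModelAverager(delta_max=delta_max).fit(X, y)
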