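import numpy as np
import pandas as pd
import pytest

from andescarbon.inference import (
    AICModelAverager,
    ClimatePCA,
    PRECIPITATION_VARS,
    TEMPERATURE_VARS,
    it_model_average,
    partial_sd,
    partial_sd_standardize,
    variance_inflation,
)


# ---------------------------------------------------------------------------
# climate PCA

def test_pca_requires_every_block_variable(small_network):
    climate = small_network.climate.set_index("plot_id")
    with pytest.raises(ValueError, match="MinTCM"):
        ClimatePCA().fit(climate.drop(columns=["MinTCM"]))


def test_pca_scores_loadings_and_variance(small_network):
    climate = small_network.climate.set_index("plot_id")
    pca = ClimatePCA().fit(climate)
    assert list(pca.scores_.columns) == [
        "PCA_temp_1", "PCA_temp_2", "PCA_prec_1", "PCA_prec_2"
    ]
    ve = pca.variance_explained_
    assert ve.between(0, 1).all()
    assert ve["PCA_temp_1"] >= ve["PCA_temp_2"]
    assert ve["PCA_prec_1"] >= ve["PCA_prec_2"]
    # identical plots must receive identical scores
    twin = pd.concat([climate.iloc[[0]], climate.iloc[[0]]])
    scores = pca.transform(twin)
    assert np.allclose(scores.iloc[0], scores.iloc[1])


def test_pca_reconstruction_matches_retained_variance():
    rng = np.random.default_rng(0)
    n = 60
    latent = rng.normal(size=(n, 2))
    climate = pd.DataFrame(
        {v: latent @ rng.normal(size=2) + 0.1 * rng.normal(size=n)
         for v in TEMPERATURE_VARS + PRECIPITATION_VARS}
    )
    pca = ClimatePCA().fit(climate)
    scaler, fit, variables = pca._fits["temp"]
    scaled = scaler.transform(climate[variables].to_numpy())
    scores = pca.scores_[["PCA_temp_1", "PCA_temp_2"]].to_numpy()
    recon = scores @ fit.components_
    resid = np.sum((scaled - scaled.mean(0) - recon) ** 2) / np.sum(
        (scaled - scaled.mean(0)) ** 2
    )
    kept = pca.variance_explained_[["PCA_temp_1", "PCA_temp_2"]].sum()
    assert resid == pytest.approx(1.0 - kept, abs=1e-6)


def test_first_temperature_axis_tracks_elevation():
    from andescarbon import SimulationConfig, simulate_network

    net = simulate_network(SimulationConfig(n_plots=60, stems_per_plot=86, seed=4))
    scores = ClimatePCA().fit(net.climate.set_index("plot_id")).scores_
    r = np.corrcoef(scores["PCA_temp_1"], net.plots["elevation_m"])[0, 1]
    assert abs(r) > 0.9


# ---------------------------------------------------------------------------
# partial standard deviations

def test_vif_of_orthogonal_and_collinear_predictors():
    rng = np.random.default_rng(1)
    # orthonormal columns that are also orthogonal to the intercept
    Q, _ = np.linalg.qr(np.column_stack([np.ones(50), rng.normal(size=(50, 3))]))
    X = Q[:, 1:]
    assert np.allclose(variance_inflation(X), 1.0, atol=1e-8)
    X2 = np.column_stack([X[:, 0], 2.0 * X[:, 0]])
    assert np.isinf(variance_inflation(X2)).all()
    assert variance_inflation(X[:, :1]) == pytest.approx([1.0])


def test_partial_sd_printed_formula_value():
    # n=100, p=3, S=1, VIF=4 -> sqrt(1/4) * sqrt(99/97)
    expected = 0.5 * np.sqrt(99.0 / 97.0)
    assert partial_sd(np.array([1.0]), np.array([4.0]), 100, 3)[0] == pytest.approx(
        expected, rel=1e-12
    )
    assert expected == pytest.approx(0.5051, abs=5e-4)


def test_standardization_identity_at_unit_vif():
    """beta*/beta = sqrt((n-1)/(n-p)) exactly for orthonormal predictors."""
    rng = np.random.default_rng(2)
    n, p = 80, 4
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, p))]))
    Q = Q[:, 1:]
    X = pd.DataFrame(Q / Q.std(axis=0, ddof=1), columns=list("abcd"))
    coefs = pd.Series([1.5, -2.0, 0.3, 0.0], index=list("abcd"))
    out = partial_sd_standardize(X, coefs)
    ratio = out["beta_star"] / out["beta"]
    expected = np.sqrt((n - 1) / (n - p))
    assert np.allclose(ratio.dropna(), expected, rtol=1e-10)
    assert (out["S_star"] <= out["S"] * expected + 1e-12).all()


# ---------------------------------------------------------------------------
# AIC model averaging

def test_best_model_has_zero_delta_and_retained_definition():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x1", "x2", "x3"])
    y = 2.0 * X["x1"] + rng.normal(size=80)
    fit = it_model_average(X, y)
    assert fit.models_["delta"].min() == 0.0
    assert (fit.retained_["delta"] <= 4.0).all()
    assert "x1" in fit.best_subset_
    assert fit.coef_table_.at["x1", "coef"] == pytest.approx(2.0, rel=0.2)


def test_single_predictor_average_equals_ols():
    rng = np.random.default_rng(4)
    x = rng.normal(size=60)
    y = 1.3 * x + rng.normal(size=60) * 0.5
    X = pd.DataFrame({"x": x})
    fit = AICModelAverager(delta_max=np.inf, standardize=False).fit(X, y)
    beta_ols = np.polyfit(x, y, 1)[0]
    # conditional average over models containing x = the single OLS slope
    assert fit.coef_table_.at["x", "coef"] == pytest.approx(beta_ols, rel=1e-10)


def test_pure_noise_keeps_intercept_only_in_retained_set():
    rng = np.random.default_rng(5)
    hits = 0
    for _ in range(100):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=60)
        fit = it_model_average(X, y)
        hits += any(len(s) == 0 for s in fit.retained_["subset"])
    assert hits >= 80


def test_too_many_predictors_or_observations_rejected():
    X = pd.DataFrame(np.random.default_rng(6).normal(size=(30, 13)))
    with pytest.raises(ValueError, match="all-subsets"):
        AICModelAverager().fit(X, np.zeros(30))
    X2 = X.iloc[:6, :4]
    with pytest.raises(ValueError, match="too few"):
        AICModelAverager().fit(X2, np.zeros(6))
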