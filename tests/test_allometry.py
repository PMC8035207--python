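import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from andescarbon.allometry import (
    HDFit,
    HeightDiameterModel,
    agb_chave,
    agc_from_agb,
    assign_wood_density,
    fit_hd_candidates,
    fit_hd_hierarchy,
    plot_agc_stock,
    select_hd_model,
)

RNG = np.random.default_rng(42)
DBH_GRID = np.sort(RNG.uniform(5.0, 90.0, 80))

TRUE_CURVES = {
    "loglog1": lambda d: np.exp(0.5 + 0.6 * np.log(d)),
    "loglog2": lambda d: np.exp(0.3 + 0.9 * np.log(d) - 0.05 * np.log(d) ** 2),
    "weibull3": lambda d: 35.0 * (1.0 - np.exp(-((d / 25.0) ** 1.2))),
    "mm2": lambda d: 40.0 * d / (20.0 + d),
}
TRUE_COEFS = {
    "loglog1": [0.5, 0.6],
    "loglog2": [0.3, 0.9, -0.05],
    "weibull3": [35.0, 25.0, 1.2],
    "mm2": [40.0, 20.0],
}


@pytest.mark.parametrize("form", list(TRUE_CURVES))
def test_noise_free_data_recovers_generating_form(form):
    """Each candidate refits its own noise-free curve and wins selection."""
    heights = TRUE_CURVES[form](DBH_GRID)
    model = HeightDiameterModel().fit(DBH_GRID, heights)
    assert model.form_ == form
    assert np.allclose(model.coef_, TRUE_COEFS[form], atol=1e-3)
    assert model.rse_ == pytest.approx(0.0, abs=1e-6)
    assert np.allclose(model.predict(DBH_GRID), heights, rtol=1e-5)


def test_nonconvergent_candidate_does_not_block_the_rest():
    fits = fit_hd_candidates([10, 20, 30, 40] * 5, [8, 12, 15, 17] * 5)
    assert any(f.converged for f in fits.values())
    best = select_hd_model(fits)
    assert best.converged


def _fit(form, rse, bias, n=2):
    forms = {2: "mm2", 3: "weibull3"}
    return HDFit(form=forms[n] if form is None else form,
                 coef=np.zeros(n), rse=rse, bias=bias, correction=1.0,
                 converged=True)


def test_selection_prefers_lowest_rse_then_bias_then_parsimony():
    fits = {f: _fit(f, r, b) for f, r, b in [
        ("loglog1", 2.1, 0.1), ("loglog2", 1.8, 0.5),
        ("weibull3", 1.9, 0.0), ("mm2", 2.0, 0.0)]}
    assert select_hd_model(fits).form == "loglog2"
    # within the 1% tie window the smaller |bias| wins
    fits = {"loglog1": _fit("loglog1", 1.80, 0.5), "mm2": _fit("mm2", 1.81, 0.01)}
    assert select_hd_model(fits).form == "mm2"
    # single surviving candidate returned unconditionally
    only = {"weibull3": _fit("weibull3", 9.0, 9.0, n=3)}
    assert select_hd_model(only).form == "weibull3"


def test_log_back_transform_bias_correction():
    """With lognormal height noise, mean prediction tracks mean height."""
    rng = np.random.default_rng(7)
    dbh = rng.uniform(5, 80, 4000)
    h = np.exp(0.6 + 0.55 * np.log(dbh) + rng.normal(0, 0.3, dbh.size))
    fits = fit_hd_candidates(dbh, h, forms=("loglog1",))
    pred = fits["loglog1"].predict(dbh)
    assert np.mean(pred) == pytest.approx(np.mean(h), rel=0.02)
    assert fits["loglog1"].correction > 1.0


def test_too_few_height_pairs_rejected():
    with pytest.raises(ValueError, match="at least 10"):
        HeightDiameterModel().fit([10, 20, 30], [8, 12, 15])


def test_country_fallback_for_height_poor_plot(small_network):
    census = small_network.census.copy()
    victim = small_network.plots["plot_id"].iloc[0]
    census.loc[census["plot_id"] == victim, "height_m"] = np.nan
    models = fit_hd_hierarchy(census, small_network.plots)
    assert models[victim].scope == "country"
    others = [m for p, m in models.items() if p != victim and m.scope == "plot"]
    assert others, "remaining plots keep their local models"


# ---------------------------------------------------------------------------
# biomass and carbon arithmetic

def test_agb_chave_reference_values():
    assert agb_chave(1.0, 1.0, 1.0) == pytest.approx(0.0673)
    # WD=0.6, DBH=20, H=15 -> 0.0673 * 3600^0.976
    assert agb_chave(0.6, 20.0, 15.0) == pytest.approx(199.1, abs=0.3)
    ratio = agb_chave(1.2, 20, 15) / agb_chave(0.6, 20, 15)
    assert ratio == pytest.approx(2**0.976, rel=1e-12)


@given(
    wd=st.floats(0.2, 1.1), dbh=st.floats(10, 120), h=st.floats(3, 50),
    bump=st.floats(1.01, 1.5),
)
@settings(max_examples=60, deadline=None)
def test_agb_strictly_increasing_in_each_argument(wd, dbh, h, bump):
    base = agb_chave(wd, dbh, h)
    assert agb_chave(wd * bump, dbh, h) > base
    assert agb_chave(wd, dbh * bump, h) > base
    assert agb_chave(wd, dbh, h * bump) > base


def test_carbon_fraction_and_linearity():
    assert agc_from_agb(1000.0) == pytest.approx(456.0)
    assert agc_from_agb(0.0) == 0.0
    assert agc_from_agb(3.0) + agc_from_agb(4.0) == pytest.approx(agc_from_agb(7.0))
    with pytest.raises(ValueError):
        agc_from_agb(-1.0)


def test_plot_stock_interpolates_to_one_hectare():
    assert plot_agc_stock([456.0, 456.0], 0.5) == pytest.approx(1.824)
    assert plot_agc_stock([], 1.0) == 0.0
    assert plot_agc_stock([100_000.0], 1.0) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        plot_agc_stock([1.0], 0.0)


# ---------------------------------------------------------------------------
# wood density cascade

TRAITS = pd.DataFrame({
    "species": ["spA", "spB", "spC"],
    "genus": ["gA", "gA", "gC"],
    "family": ["fA", "fA", "fC"],
    "wd_g_cm3": [0.5, 0.7, 0.9],
})


def test_wood_density_cascade_levels():
    stems = pd.DataFrame({
        "species": ["spA", "spX", "spY", "spZ"],
        "genus": ["gA", "gA", "gNope", "gNope"],
        "family": ["fA", "fA", "fA", "fNope"],
    })
    out = assign_wood_density(stems, TRAITS)
    assert out["wd"].tolist() == pytest.approx([0.5, 0.6, 0.6, 0.5666667], abs=1e-6)
    assert out["wd_level"].tolist() == ["species", "genus", "family", "plot-mean"]


def test_wood_density_fails_when_nothing_assignable():
    stems = pd.DataFrame({"species": ["x"], "genus": ["y"], "family": ["z"]})
    with pytest.raises(ValueError, match="wood density"):
        assign_wood_density(stems, TRAITS)
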