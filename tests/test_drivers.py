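import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from andescarbon.drivers import (
    PhylogeneticDiversity,
    community_temperature_index,
    faith_pd,
    fit_size_mortality,
    independent_swap,
    mycorrhizal_ratio,
    pd_standardized_effect,
    quadratic_mean_diameter,
    rarefied_richness,
    thermal_optima,
    thermophilization_rate,
)


# ---------------------------------------------------------------------------
# thermal optima / CTI / TR

def test_thermal_optima_species_then_genus_fallback():
    occ = pd.DataFrame({
        "species": ["a"] * 12 + ["b"] * 3 + ["c"] * 2,
        "genus": ["gA"] * 12 + ["gA"] * 3 + ["gLost"] * 2,
        "mat": [18, 20, 22] * 4 + [30, 30, 30] + [5, 5],
    })
    # drop genus gLost records so species c has no genus pool either
    occ = occ[occ["genus"] != "gLost"]
    occ = pd.concat([occ, pd.DataFrame({"species": ["c"], "genus": ["gLost"],
                                        "mat": [np.nan]})]).dropna(subset=["mat"])
    out = thermal_optima(occ).set_index("species")
    assert out.at["a", "optimum"] == pytest.approx(20.0)
    assert out.at["a", "level"] == "species"
    # b has 3 records -> pooled congeneric mean (12 a-records + 3 b-records)
    assert out.at["b", "optimum"] == pytest.approx((20 * 12 + 90) / 15)
    assert out.at["b", "level"] == "genus"


def test_cti_is_basal_area_weighted_mean():
    optima = pd.Series({"warm": 20.0, "cold": 10.0})
    stems = pd.DataFrame({
        "species": ["warm"] * 3 + ["cold"],
        "dbh": [10.0, 10.0, 10.0, 10.0],   # equal stems -> BA 3:1
    })
    assert community_temperature_index(stems, optima) == pytest.approx(17.5)
    mono = stems[stems["species"] == "warm"]
    assert community_temperature_index(mono, optima) == pytest.approx(20.0)
    # removing basal area of the coldest species raises the CTI
    assert community_temperature_index(mono, optima) > community_temperature_index(
        stems, optima
    )


def test_cti_bounded_by_included_optima(small_network, small_pairs):
    optima = small_network.traits.set_index("species")["thermal_optimum"]
    for pair in small_pairs:
        m = thermophilization_rate(pair, optima)
        present = pd.concat([pair.survivors, pair.deaths])["species"].unique()
        opts = optima.loc[present]
        assert opts.min() - 1e-9 <= m.cti_first <= opts.max() + 1e-9


def test_tr_zero_for_identical_communities(micro_pair):
    optima = pd.Series({"spA": 15.0, "spB": 18.0})
    static = micro_pair
    static.survivors["dbh2"] = static.survivors["dbh1"]
    static.recruits.drop(static.recruits.index, inplace=True)
    static.deaths.drop(static.deaths.index, inplace=True)
    assert thermophilization_rate(static, optima).tr == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# mycorrhizal ratio

MYCO_TRAITS = pd.DataFrame({
    "genus": ["gAM", "gEcM", "gX"],
    "family": ["fAM", "fEcM", "fEcM"],
    "myco_type": ["AM", "EcM", "EcM"],
})


def _stems(n_am, n_ecm, n_unknown=0):
    return pd.DataFrame({
        "genus": ["gAM"] * n_am + ["gEcM"] * n_ecm + ["g?"] * n_unknown,
        "family": ["fAM"] * n_am + ["fEcM"] * n_ecm + ["f?"] * n_unknown,
    })


def test_sra_log_ratio_and_coverage():
    assert mycorrhizal_ratio(_stems(50, 50), MYCO_TRAITS).sra == pytest.approx(0.0)
    out = mycorrhizal_ratio(_stems(90, 10), MYCO_TRAITS)
    assert out.sra == pytest.approx(np.log(9.0))
    out = mycorrhizal_ratio(_stems(90, 10, n_unknown=20), MYCO_TRAITS)
    assert (out.n_am, out.n_ecm) == (90, 10)
    assert out.coverage == pytest.approx(100 / 120)


def test_sra_family_fallback_and_zero_count_flag():
    stems = pd.DataFrame({"genus": ["gNew"], "family": ["fEcM"]})
    out = mycorrhizal_ratio(stems, MYCO_TRAITS)
    assert out.n_ecm == 1  # family-level assignment
    assert np.isnan(out.sra)  # zero AM count -> undefined


# ---------------------------------------------------------------------------
# phylogenetic diversity

def test_faith_pd_hand_enumeration(toy_tree_newick):
    assert faith_pd({"A", "B"}, toy_tree_newick) == pytest.approx(3.0)
    assert faith_pd({"A", "B", "C"}, toy_tree_newick) == pytest.approx(5.0)
    # single species scores its root-to-tip path
    assert faith_pd({"C"}, toy_tree_newick) == pytest.approx(2.0)
    assert faith_pd({"A"}, toy_tree_newick) == pytest.approx(2.0)


def test_pd_monotone_under_species_addition(species_pool):
    calc = PhylogeneticDiversity.from_newick(species_pool[1])
    rng = np.random.default_rng(5)
    community = list(rng.choice(calc.taxa, size=5, replace=False))
    pd_small = calc.pd(community)
    extra = next(t for t in calc.taxa if t not in community)
    assert calc.pd(community + [extra]) >= pd_small


@given(
    matrix=arrays(np.int8, (8, 10), elements=st.integers(0, 1)),
    seed=st.integers(0, 2**16),
)
@settings(max_examples=30, deadline=None)
def test_independent_swap_preserves_margins(matrix, seed):
    swapped = independent_swap(matrix, 500, np.random.default_rng(seed))
    assert np.array_equal(swapped.sum(axis=0), matrix.sum(axis=0))
    assert np.array_equal(swapped.sum(axis=1), matrix.sum(axis=1))


def test_pdz_degenerate_matrix_flagged(species_pool):
    matrix = pd.DataFrame(
        1, index=["p1", "p2", "p3"],
        columns=species_pool[0]["species"].tolist(),
    )
    out = pd_standardized_effect(matrix, species_pool[1], n_null=19, seed=0)
    assert out["pdz"].isna().all()
    assert (out["null_sd"] == 0).all()


def test_pdz_seed_reproducible(species_pool):
    rng = np.random.default_rng(9)
    species = species_pool[0]["species"].tolist()
    matrix = pd.DataFrame(
        (rng.random((10, len(species))) < 0.4).astype(np.int8),
        index=[f"p{i}" for i in range(10)], columns=species,
    )
    a = pd_standardized_effect(matrix, species_pool[1], n_null=49, seed=123)
    b = pd_standardized_effect(matrix, species_pool[1], n_null=49, seed=123)
    pd.testing.assert_frame_equal(a, b)
    assert a["pd_obs"].notna().all()


# ---------------------------------------------------------------------------
# rarefaction

def test_rarefaction_degenerate_cases():
    assert rarefied_richness([200], m=86) == pytest.approx(1.0)
    assert rarefied_richness([1] * 86, m=86) == pytest.approx(86.0)
    with pytest.raises(ValueError, match="undefined"):
        rarefied_richness([40, 40], m=86)


def test_rarefaction_matches_resampling_oracle():
    counts = np.array([60, 25, 10])
    analytic = rarefied_richness(counts, m=20)
    rng = np.random.default_rng(0)
    pool = np.repeat(np.arange(3), counts)
    draws = [
        len(np.unique(rng.choice(pool, size=20, replace=False)))
        for _ in range(10_000)
    ]
    assert analytic == pytest.approx(np.mean(draws), abs=0.1)


# ---------------------------------------------------------------------------
# size-dependent mortality

def test_mortality_requires_both_outcomes():
    with pytest.raises(ValueError, match="death and one survivor"):
        fit_size_mortality([10, 20, 30], [0, 0, 0])


def test_mortality_flags_complete_separation():
    dbh = np.linspace(10, 60, 200)
    died = (dbh > 30).astype(int)
    fit = fit_size_mortality(dbh, died)
    assert fit.separated
    assert np.isnan(fit.beta)


def test_mortality_null_is_size_independent():
    """Random deaths: beta consistent with zero in >=90% of replicates."""
    rng = np.random.default_rng(21)
    hits = 0
    for _ in range(100):
        dbh = 10 + rng.exponential(8.0, 2000)
        died = rng.random(2000) < 0.05
        if died.sum() == 0:
            continue
        fit = fit_size_mortality(dbh, died.astype(int))
        hits += abs(fit.beta) < 2 * fit.beta_se
    assert hits >= 90


# ---------------------------------------------------------------------------
# stand structure

def test_quadratic_mean_diameter():
    assert quadratic_mean_diameter([10, 10, 10]) == pytest.approx(10.0)
    assert quadratic_mean_diameter([6, 8]) == pytest.approx(np.sqrt(50.0))
    assert quadratic_mean_diameter([17.3]) == pytest.approx(17.3)
    d = np.random.default_rng(1).uniform(10, 50, 30)
    assert d.min() <= quadratic_mean_diameter(d) <= d.max()
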