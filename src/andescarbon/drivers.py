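"""Per-plot biotic driver metrics.

Covers the community-level quantities used to explain carbon dynamics:
thermophilization rate (change in the basal-area-weighted community
temperature index), mycorrhizal stem ratio ln(AM/EcM), Faith's phylogenetic
diversity and its standardized effect size under an independent-swap null,
rarefied species richness, the size-dependent mortality slope from a
per-plot logistic regression of death on DBH, and the quadratic mean
diameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .census import PlotCensusPair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thermal optima and community temperature index

def thermal_optima(occurrences: pd.DataFrame, min_records: int = 10) -> pd.DataFrame:
    """Species thermal optima from occurrence-location temperatures.

    A species with >= ``min_records`` occurrence records gets the mean
    temperature of its own records; below that, the mean over all congeneric
    records; species with neither are left unassigned (and excluded from the
    CTI downstream).  ``occurrences`` needs columns species, genus, mat.
    """
    counts = occurrences.groupby("species")["mat"].agg(["mean", "count"])
    genus_of = occurrences.groupby("species")["genus"].first()
    genus_mean = occurrences.groupby("genus")["mat"].mean()

    rows = []
    for species, (mean, count) in counts.iterrows():
        if count >= min_records:
            rows.append({"species": species, "optimum": mean, "level": "species"})
        else:
            g = genus_of[species]
            if g in genus_mean.index:
                rows.append({"species": species, "optimum": genus_mean[g],
                             "level": "genus"})
            else:
                logger.info("species %s: no usable occurrence records", species)
                rows.append({"species": species, "optimum": np.nan,
                             "level": "unassigned"})
    return pd.DataFrame(rows)


def community_temperature_index(stems: pd.DataFrame, optima: pd.Series) -> float:
    """Basal-area-weighted mean thermal optimum of a stem table (deg C).

    ``stems`` needs species and a diameter column (``dbh_cm`` or ``dbh``);
    ``optima`` maps species -> optimum.  Species without an optimum carry no
    weight.  Undefined (nan) when no stem has an assigned optimum.
    """
    dbh_col = "dbh_cm" if "dbh_cm" in stems.columns else "dbh"
    opt = stems["species"].map(optima)
    ba = np.pi * (stems[dbh_col].to_numpy() / 2.0) ** 2
    mask = opt.notna().to_numpy()
    if not mask.any():
        return float("nan")
    return float(np.average(opt.to_numpy()[mask], weights=ba[mask]))


@dataclass
class ThermoMetrics:
    cti_first: float
    cti_final: float
    tr: float  # deg C / y


def thermophilization_rate(pair: PlotCensusPair, optima: pd.Series) -> ThermoMetrics:
    """Annualized change in CTI between the first and last census."""
    first = pd.concat(
        [
            pair.survivors.rename(columns={"dbh1": "dbh"})[["species", "dbh"]],
            pair.deaths.rename(columns={"dbh1": "dbh"})[["species", "dbh"]],
        ],
        ignore_index=True,
    )
    last = pd.concat(
        [
            pair.survivors.rename(columns={"dbh2": "dbh"})[["species", "dbh"]],
            pair.recruits.rename(columns={"dbh2": "dbh"})[["species", "dbh"]],
        ],
        ignore_index=True,
    )
    cti1 = community_temperature_index(first, optima)
    cti2 = community_temperature_index(last, optima)
    return ThermoMetrics(cti1, cti2, (cti2 - cti1) / pair.t_years)


# ---------------------------------------------------------------------------
# mycorrhizal ratio

@dataclass
class MycorrhizalSummary:
    n_am: int
    n_ecm: int
    sra: float       # ln(AM / EcM); nan when either count is zero
    coverage: float  # fraction of stems with an assignment


def mycorrhizal_ratio(stems: pd.DataFrame, traits: pd.DataFrame) -> MycorrhizalSummary:
    """ln(AM/EcM) stem ratio, genus-level assignment first, then family.

    ``traits`` carries genus, family and ``myco_type`` in {AM, EcM}; the
    modal type per genus (then family) is used.  Stems that match neither are
    excluded from both counts and reported through ``coverage``.
    """
    def modal(level):
        return traits.groupby(level)["myco_type"].agg(
            lambda s: s.mode().iloc[0] if len(s.mode()) else np.nan
        )

    genus_type = modal("genus")
    family_type = modal("family")
    assigned = stems["genus"].map(genus_type)
    m = assigned.isna()
    assigned[m] = stems.loc[m, "family"].map(family_type)

    n_am = int((assigned == "AM").sum())
    n_ecm = int((assigned == "EcM").sum())
    coverage = float(assigned.notna().mean()) if len(stems) else 0.0
    if n_am > 0 and n_ecm > 0:
        sra = float(np.log(n_am / n_ecm))
    else:
        sra = float("nan")
        logger.warning("SRA undefined: counts AM=%d EcM=%d", n_am, n_ecm)
    return MycorrhizalSummary(n_am, n_ecm, sra, coverage)


# ---------------------------------------------------------------------------
# phylogenetic diversity

class PhylogeneticDiversity:
    """Faith's PD on a dated tree, with fast community-matrix evaluation.

    PD of a community is the summed branch length of the minimum spanning
    subtree that connects the community's species to the root (the root path
    is included, so a single species scores its root-to-tip path length).
    Internally an edge-by-species incidence matrix is precomputed so that PD
    for many communities (e.g. null-model draws) is a single matrix product.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._build_incidence()

    @classmethod
    def from_newick(cls, newick: str) -> "PhylogeneticDiversity":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def _build_incidence(self):
        taxa = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        self.taxa = taxa
        index = {label: i for i, label in enumerate(taxa)}
        edges = []
        lengths = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.edge.length is None:
                continue  # root edge carries no length
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            row = np.zeros(len(taxa), dtype=bool)
            for lab in leaves:
                row[index[lab]] = True
            edges.append(row)
            lengths.append(float(node.edge.length))
        self.incidence = np.asarray(edges)          # edges x species
        self.lengths = np.asarray(lengths, float)   # edge lengths

    def pd(self, species) -> float:
        """PD of one community given as an iterable of species labels."""
        index = {label: i for i, label in enumerate(self.taxa)}
        present = np.zeros(len(self.taxa), dtype=bool)
        matched = 0
        for s in set(species):
            if s in index:
                present[index[s]] = True
                matched += 1
            else:
                logger.info("species %s is not a tip of the tree; excluded", s)
        if matched < 1:
            return float("nan")
        return self.pd_matrix(present[None, :], self.taxa)[0]

    def pd_matrix(self, matrix: np.ndarray, species_order) -> np.ndarray:
        """PD for each row of a plots-by-species presence matrix."""
        index = {label: i for i, label in enumerate(self.taxa)}
        order = [index[s] for s in species_order]
        sub = self.incidence[:, order]               # edges x matrix species
        touched = (matrix.astype(bool) @ sub.T)      # plots x edges
        return touched @ self.lengths


def faith_pd(species, tree) -> float:
    """Convenience wrapper: Faith's PD for one species set.

    ``tree`` may be a dendropy Tree or a newick string.
    """
    calc = (
        PhylogeneticDiversity.from_newick(tree)
        if isinstance(tree, str)
        else PhylogeneticDiversity(tree)
    )
    return calc.pd(species)


def _swap_chain(state: list[list[int]], n_attempts: int,
                rng: np.random.Generator) -> None:
    """Run ``n_attempts`` checkerboard-swap attempts in place."""
    n_r = len(state)
    n_c = len(state[0])
    rt = rng.integers(0, n_r, size=2 * n_attempts).tolist()
    ct = rng.integers(0, n_c, size=2 * n_attempts).tolist()
    for k in range(n_attempts):
        r1 = rt[2 * k]
        r2 = rt[2 * k + 1]
        if r1 == r2:
            continue
        c1 = ct[2 * k]
        c2 = ct[2 * k + 1]
        row1 = state[r1]
        row2 = state[r2]
        a = row1[c1]
        if a == row2[c2] and a != row1[c2] and row1[c2] == row2[c1]:
            row1[c1] = row2[c2] = 1 - a
            row1[c2] = row2[c1] = a


def independent_swap(matrix: np.ndarray, n_attempts: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Randomize a binary matrix by attempted checkerboard swaps.

    Each attempt picks two rows and two columns; if the 2x2 submatrix is a
    checkerboard it is flipped, which preserves every row and column total
    (plot richness and species frequency).  Returns a new matrix.
    """
    state = np.asarray(matrix).astype(np.int8).tolist()
    _swap_chain(state, n_attempts, rng)
    return np.asarray(state, dtype=np.int8)


@dataclass
class DiversityMetrics:
    pd_obs: float
    null_mean: float
    null_sd: float
    pdz: float


def pd_standardized_effect(
    matrix: pd.DataFrame,
    tree,
    n_null: int = 999,
    swaps_per_draw: int = 10_000,
    burn_in: int = 1_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """PDz per plot against an independent-swap null.

    ``matrix`` is a plots-by-species binary presence frame.  The null is a
    sequential checkerboard-swap chain: ``burn_in`` attempted swaps from the
    observed matrix, then one draw every ``swaps_per_draw`` further attempts,
    for ``n_null`` draws.  Each swap preserves row and column totals.  PDz is
    (PD_obs - null mean) / null sd; degenerate matrices with no swappable
    checkerboard (constant columns everywhere) yield zero null variance and a
    flagged nan PDz.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 plots and 2 species for the null model")
    calc = tree if isinstance(tree, PhylogeneticDiversity) else (
        PhylogeneticDiversity.from_newick(tree) if isinstance(tree, str)
        else PhylogeneticDiversity(tree)
    )
    species = [s for s in matrix.columns if s in set(calc.taxa)]
    dropped = set(matrix.columns) - set(species)
    if dropped:
        logger.info("%d species absent from the tree excluded from PDz", len(dropped))
    obs = matrix[species].to_numpy().astype(np.int8)

    rng = np.random.default_rng(seed)
    pd_obs = calc.pd_matrix(obs, species)

    state = obs.tolist()
    _swap_chain(state, burn_in, rng)
    nulls = np.empty((n_null, obs.shape[0]))
    for i in range(n_null):
        _swap_chain(state, swaps_per_draw, rng)
        nulls[i] = calc.pd_matrix(np.asarray(state, dtype=np.int8), species)

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    # a variance at float rounding scale means the chain never moved
    degenerate = null_sd <= 1e-9 * np.maximum(1.0, np.abs(null_mean))
    null_sd = np.where(degenerate, 0.0, null_sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        pdz = np.where(~degenerate, (pd_obs - null_mean) / null_sd, np.nan)
    if degenerate.any():
        logger.warning("degenerate null distribution for %d plot(s); PDz undefined",
                       int(degenerate.sum()))
    return pd.DataFrame(
        {"pd_obs": pd_obs, "null_mean": null_mean, "null_sd": null_sd, "pdz": pdz},
        index=matrix.index,
    )


# ---------------------------------------------------------------------------
# rarefied richness

def rarefied_richness(abundances, m: int = 86) -> float:
    """Expected species count in a draw of ``m`` stems without replacement.

    Analytic hypergeometric expectation: E[S] = sum_s 1 - C(N - n_s, m)/C(N, m).
    Undefined (raises) when the plot holds fewer than ``m`` stems.
    """
    n = np.asarray(abundances, dtype=np.int64)
    n = n[n > 0]
    total = int(n.sum())
    if total < m:
        raise ValueError(f"rarefaction to {m} stems undefined for a plot of {total}")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = np.where(
        total - n >= m,
        np.exp(log_comb(total - n, m) - log_comb(total, m)),
        0.0,
    )
    return float(np.sum(1.0 - terms))


# ---------------------------------------------------------------------------
# size-dependent mortality

@dataclass
class MortalityFit:
    a: float         # intercept, logit units
    beta: float      # logit per cm of DBH
    beta_se: float
    n: int
    n_deaths: int
    separated: bool  # True when the fit was abandoned (complete separation)


class SizeMortalityModel(BaseEstimator):
    """Logistic regression of the death indicator on first-census DBH.

    logit(P(death over the census interval)) = a + beta * DBH.  A negative
    beta means small stems die preferentially (competitive self-thinning
    during post-disturbance recovery); a positive beta means large trees are
    being lost, as under active disturbance.
    """

    def fit(self, X, y):
        dbh = np.asarray(X, dtype=float).reshape(-1)
        died = np.asarray(y, dtype=int).reshape(-1)
        if died.min() == died.max():
            raise ValueError("need at least one death and one survivor")
        exog = sm.add_constant(dbh)
        self.separated_ = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(died, exog).fit(disp=0, maxiter=200)
            params, bse = res.params, res.bse
            if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 1e3):
                raise ValueError("diverged")
        except Exception:
            self.separated_ = True
            params = np.array([np.nan, np.nan])
            bse = np.array([np.nan, np.nan])
        self.intercept_ = float(params[0])
        self.beta_ = float(params[1])
        self.beta_se_ = float(bse[1])
        self.n_ = len(died)
        self.n_deaths_ = int(died.sum())
        return self

    def predict_proba_dbh(self, dbh):
        check_is_fitted(self, "beta_")
        z = self.intercept_ + self.beta_ * np.asarray(dbh, dtype=float)
        p = 1.0 / (1.0 + np.exp(-z))
        return p


def fit_size_mortality(dbh, died) -> MortalityFit:
    """Functional wrapper around :class:`SizeMortalityModel`."""
    model = SizeMortalityModel().fit(dbh, died)
    return MortalityFit(
        a=model.intercept_,
        beta=model.beta_,
        beta_se=model.beta_se_,
        n=model.n_,
        n_deaths=model.n_deaths_,
        separated=model.separated_,
    )


def beta_mortality(pair: PlotCensusPair) -> MortalityFit:
    """Per-plot size-dependent mortality fit from a census pair."""
    dbh = np.concatenate([
        pair.survivors["dbh1"].to_numpy(dtype=float),
        pair.deaths["dbh1"].to_numpy(dtype=float),
    ])
    died = np.concatenate([
        np.zeros(len(pair.survivors), dtype=int),
        np.ones(len(pair.deaths), dtype=int),
    ])
    return fit_size_mortality(dbh, died)


# ---------------------------------------------------------------------------
# stand structure

@dataclass
class PlotStructure:
    dq: float            # quadratic mean diameter, cm
    n: int
    stem_density: float  # stems / ha


def quadratic_mean_diameter(dbh) -> float:
    """Dq = sqrt(sum DBH_i^2 / n), cm."""
    d = np.asarray(dbh, dtype=float)
    if d.size == 0:
        raise ValueError("Dq undefined for an empty plot")
    return float(np.sqrt(np.mean(d**2)))


def plot_structure(dbh, area_ha: float) -> PlotStructure:
    d = np.asarray(dbh, dtype=float)
    return PlotStructure(
        dq=quadratic_mean_diameter(d),
        n=int(d.size),
        stem_density=float(d.size / area_ha),
    )
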