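# Methods

## Census model

A census table holds one row per tagged stem per census. Analysis is
restricted to the first and last census of each plot; the interval t is the
date difference in days divided by 365.25 (census dates are known to the
day in the synthetic data; with real year-only dates the convention is the
same and the error is below 0.3% on a 5-year interval). Stems are
partitioned by fate: alive in both censuses (survivors), alive first and
dead *or absent* last (deaths — the two are not distinguished, since an
untraceable tag is operationally a death), absent first and alive last
(recruits). Each tagged stem is treated independently; no multi-stem
aggregation is attempted.

Survivor growth is cleaned before any carbon is computed: annualized DBH
increments outside [−0.1, 7.5] cm y⁻¹ are rewritten to the bound (the
second-census diameter is replaced by DBH₁ + bound·t). The transformation
is idempotent (a 10⁻⁹ cm y⁻¹ tolerance absorbs float jitter from a
previous pass) and never touches first-census diameters; every adjustment
is logged.

## Height–diameter allometry

Candidate forms, fitted to the measured-height subset (DBH ≥ 5 cm,
minimum 10 pairs):

| form | equation | parameters |
|---|---|---|
| loglog1 | ln H = c₀ + c₁ ln D | 2 |
| loglog2 | ln H = c₀ + c₁ ln D + c₂ (ln D)² | 3 |
| weibull3 | H = c₀(1 − exp(−(D/c₁)^c₂)) | 3 |
| mm2 | H = c₀D/(c₁ + D) | 2 |

Log-log forms are ordinary least squares on the log scale; predictions are
back-transformed with the Baskerville factor exp(RSE_log²/2), without
which E[H] is systematically under-predicted under lognormal errors (the
package's test verifies mean prediction tracks mean observation within 2%
at noise sd 0.3). Nonlinear forms use Levenberg–Marquardt-style bounded
least squares with data-driven starts (asymptote from max height, scale
from median diameter); a non-convergent candidate is flagged and skipped
rather than failing the plot.

RSE (= √(RSS/(n−p))) and mean signed residual (bias) are computed on the
metre scale for all forms so the selection compares like with like. The
lowest RSE wins; candidates within 1% relative RSE of the best (plus a
10⁻⁹ absolute epsilon so exact fits tie) compete on smaller |bias|, then
fewer parameters. The parsimony tie-break matters for noise-free nested
cases: data generated from loglog1 is fitted exactly by loglog2 as well,
and the 2-parameter form must be the one reported.

Plots with fewer than 10 measured heights use a pooled fit over all
measured stems of their country — the realistic situation where one
national subnetwork lacks height campaigns. A pantropical coefficient
fallback is deliberately not wired in by default: regional curves flatten
elevational height gradients and homogenize stock estimates, which is the
failure mode plot-level fitting exists to avoid. One model is selected per
plot and used for both censuses.

## Carbon bookkeeping

AGB (kg) = 0.0673(WD·D²·H)^0.976 with D in cm, H in m, WD in g cm⁻³;
AGC = 0.456·AGB; stocks are ΣAGC/1000/area (Mg C ha⁻¹). Wood density is
assigned species → genus mean → family mean → plot mean of assigned stems,
with the level recorded for audit.

Fluxes are annualized per hectare. Deaths are valued at first-census size
(no growth is imputed between census and death — the conservative
convention). Each recruit contributes its AGC minus the AGC of a 9.99-cm
tree of the same wood density on the same plot allometry, floored at zero;
the baseline subtraction prevents counting carbon that was already standing
just below the detection threshold. Negative survivor increments (allowed
down to −0.1 cm y⁻¹) are kept inside growth, which is defined as the summed
AGC change of survivors.

Net change is computed from the stock difference (AGC_final − AGC1)/t, not
by summing components. The bookkeeping identity

    net = productivity − mortality + residual

holds exactly with residual = Σ AGC(9.99-cm baseline of recruits)/(area·t);
the residual is reported per plot and is ~3–4% of the network net change at
the generator defaults.

## Community drivers

* **Thermal optima**: species mean occurrence temperature when ≥ 10
  records exist, else the congeneric pooled mean, else unassigned (and
  excluded from the CTI, with coverage reported).
* **CTI / TR**: CTI is the basal-area-weighted mean optimum over stems of
  the census (stem-level weighting; aggregating to species first is
  algebraically identical since every stem carries its species optimum).
  TR = ΔCTI/t.
* **SRA**: stems assigned AM/EcM genus-first then family (modal type per
  taxon); SRA = ln(n_AM/n_EcM), undefined (not pseudo-counted) when either
  count is zero.
* **Faith's PD**: summed branch length of the minimum spanning subtree
  *including the root path*, so a one-species community scores its
  root-to-tip distance. Implementation precomputes an edge×species
  incidence matrix; PD over many communities is then one boolean matrix
  product, which is what makes the 999-draw null affordable.
* **PDz**: independent-swap null. A sequential chain starts at the observed
  plots×species matrix, burns in 1,000 attempted checkerboard swaps, and
  takes one draw every 10,000 further attempts (999 draws by default).
  Every accepted swap flips a 2×2 checkerboard, preserving all row and
  column totals exactly. PDz = (PD_obs − null mean)/null sd; when the null
  variance is at float-rounding scale the matrix had no swappable
  checkerboard and PDz is flagged undefined. Chain length is configurable;
  consecutive draws are mildly autocorrelated, which calibration tests show
  still yields mean ≈ 0, sd ≈ 1 z-scores on random matrices.
* **Rarefied richness** at m = 86 stems via the analytic hypergeometric
  expectation E[S] = Σ_s [1 − C(N−n_s, m)/C(N, m)] (log-gamma evaluated for
  stability); a resampling estimate is kept as a test oracle only, so the
  reported value is deterministic.
* **Size-dependent mortality**: per-plot ML logistic fit of the death
  indicator on first-census DBH, one interval per plot. Complete separation
  (or divergence, |params| > 10³) flags the plot instead of reporting
  estimates.

## Driver inference

The temperature (11 variables) and precipitation (8) blocks are centred,
scaled to unit variance, and decomposed separately; the first two axes per
block are kept, with signs fixed so each axis's dominant variable loads
positive. Predictors for model averaging are standardized to mean 0, sd 1
(ddof = 1).

All predictor subsets (≤ 12 predictors, including the intercept-only
model) are fitted by OLS. AIC uses the Gaussian likelihood at the ML
variance estimate with k = (slopes + intercept + variance), the convention
under which ΔAIC matches likelihood-based model selection in R-style
tooling. The retained set is ΔAIC ≤ 4; Akaike weights are renormalized
over it. The *natural* (conditional) average of a coefficient is its
weight-renormalized mean over retained models that contain the term — the
reading of "averaged over the models where the variable was selected";
weighting by Akaike weights rather than equally is a documented choice and
configurable through the model table the estimator exposes. Standardized
coefficients use the partial standard deviation
S\* = S·√(VIF⁻¹)·√((n−1)/(n−p)) computed *within each retained model* (its
own p and VIFs) and averaged the same way. With p = 3, n = 100, VIF = 4 and
S = 1 the formula gives 0.50513.

## Regional scaling

Bands are half-open [low, high) with default edges
500/1200/2000/2800/3600 m. Band means use a plot-resampling bootstrap
(1,000 draws, percentile 2.5/97.5 CI); a one-plot band keeps its mean but
flags the CI undefined. Totals are mean stock × cover × 10⁻⁷ Pg; the
regional weighted mean weights band means by cover; the net balance is the
total-stock difference over the elapsed years (11 for the 2003/2014
epochs). Deforestation emissions value each band's lost cover at its
*initial* stock and convert with 44/12; band-wise and aggregate-mean
variants agree to the reported precision on the published reference table.
Epoch assignment of plot censuses uses a configurable cut year (default
2009: first censuses ≤ 2009 feed the initial epoch, last censuses > 2009
the final one).

## Synthetic generator

The generator's defaults describe a mature Andean-type montane network and
were fixed once, from field magnitudes, not tuned to tests: 400 stems ≥
10 cm per 1-ha plot, initial DBH = 10 + Exponential(8) cm (right-skewed,
Dq ≈ 19 cm), growth 0.25 ± 0.15 cm y⁻¹, interval mortality
logit(P) = −3.5 − 0.02·DBH (≈ 0.4% y⁻¹, mildly small-stem-biased as in
self-thinning stands), recruitment 2 stems ha⁻¹ y⁻¹ (roughly balancing
deaths), a 5-year census interval, an 80-species pool filtered by a 3 °C
thermal niche kernel around the plot's lapse-rate temperature
(24 °C at 500 m, −5.5 °C km⁻¹), and heights from a Michaelis–Menten curve
whose asymptote shortens with elevation (48 − 0.006·elev m), measured with
8% lognormal error on 30% of stems in 85% of plots. These settings yield a
network-level sink on the order of 1 Mg C ha⁻¹ y⁻¹ — the magnitude
reported for Andean plot networks.

Thermophilization drift is injected where the basal-area budget actually
lives: recruits alone carry far too little basal area to move a
BA-weighted CTI measurably, so a drift of d °C y⁻¹ is realized through an
optimum-dependent survivor growth tilt g_i = g₀ + γ(opt_i − CTI₁), with γ
solved per plot from the identity dCTI/dt = (π/2)Σ D_i g_i (opt_i −
CTI)/ΣBA so that the expected CTI change matches d. Recruit species are
additionally sampled with an exponential tilt on optimum so their mean
optimum sits d·t above the resident community. Clipping of tilted growth
at the −0.1 cm y⁻¹ floor attenuates the realized drift by roughly 10%,
well inside the ±30% recovery band the tests check.

Each plot runs on its own spawned seed substream, so identical
configurations are byte-identical and subsetting plots never changes their
stems.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: spatial stem mapping and neighborhood
competition, more than two censuses, measurement error in DBH, taxonomic
misidentification, correlated disturbance events (deaths are independent
Bernoulli draws), trait phylogenetic signal (wood density and optima are
drawn independently of the tree), and empirically calibrated DBH/growth
distributions for any particular region.

## Known limitations

* Allometric parameter uncertainty is not propagated into stock CIs; the
  bootstrap covers only between-plot variance.
* The logistic mortality fit ignores interval-length differences between
  plots (one interval per plot).
* SEM-style path analysis is out of scope; the retained-set/averaged
  coefficient table is the inference surface.
* The independent-swap chain is sequential; draws are not independent
  samples, only marginally uniform, which slightly widens the PDz null in
  principle (calibration tests bound the effect).
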