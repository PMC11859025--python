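# Methods

`forestdiv` analyses stem-mapped censuses of rectangular forest plots: every
tree ≥ 3 cm DBH with its species/genus/family code, coordinates (m) and DBH
(cm), on a window gridded into 10 m × 10 m subplots (100 per hectare). This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic generator does and does not emulate.

## Composition and diversity summaries

Species are partitioned by abundance — rare (exactly 1 stem), common (2 to
49), dominant (≥ 50, `dominant_min` parameter) — and families by species
richness — single (1), common (2–4), dominant (≥ 5). Printed percentage
tables are recomputed from integer counts with decimal half-up rounding at
2 dp (`core_data.percentage`); the inventory convention of writing the
dominant threshold sometimes as "more than 50" and sometimes "≥ 50" is
resolved as inclusive (≥ 50), which is the variant consistent with published
1-ha dominant-species counts feeding n(n−1)/2 pair totals.

Importance value per species is IV = RF + RD + RA with relative frequency
(share of occupied subplots), relative dominance (share of basal area
π(DBH/2)², cm²) and relative density (share of stems), each summing to 100
over species, so IVs sum to 300; a family's IV is the sum over its species.

The species-abundance distribution is fitted as a log-normal: an MLE normal
fit (mean, ddof-0 sd) to ln(abundance). A humped species-sequence curve on a
log axis is the standard signature of this model; a plain-normal fit on raw
abundances is available via `log=False`. Accumulation (taxon–area) curves
average the distinct-taxon count over random permutations of the subplot
grid (default 200 orderings) rather than nested quadrats; the endpoint is
exact and the species ≥ genus ≥ family ordering holds pointwise for every
permutation. No Chao/iNEXT-style extrapolation is attempted.

## Point-pattern analysis

The pair correlation function g(r) is estimated with the standard kernel
estimator (Epanechnikov kernel, translation edge correction, exact on
rectangles):

g̃(r) = |W|² / (n(n−1)) · (2πr)⁻¹ · Σ_{i≠j} κ_h(r − d_ij) / A(x_i − x_j)

with A(t) = (a − |t_x|)(b − |t_y|). Bandwidth follows Stoyan's rule of thumb
h = c/√λ with c = 0.15 (for the cross version, λ is the geometric mean of
the two intensities, and the bandwidth computed from the observed patterns
is held fixed across null simulations). The default grid is 0.25–25 m in
0.25 m steps; r_max may not exceed a quarter of the shorter window side.
The cumulative mean-neighbour-count alternative to the cross pcf is
provided (`cross_neighbor_count`) without asserting which variant a given
published curve used.

Significance uses pointwise Monte-Carlo rank envelopes: the band at each r
is the k-th smallest/largest of nsim null statistics, a two-sided pointwise
test at level 2k/(nsim+1). The library default is nsim = 999, k = 5 (1%,
the conventional "999 fittings, 99% confidence"); batch runs scale down to
nsim = 199, k = 1, which is the *same* 1% level at a fifth of the cost.
Global (simultaneous) envelopes are out of scope. Ties in the null ranking
cannot occur for the continuous kernel statistic; all simulations descend
from one master seed via NumPy SeedSequence spawning.

Null models:

- **Univariate (one species):** CSR with the observed point count.
- **Bivariate, low-level default (`envelope_test`, `intraspecific_association`):**
  random toroidal shift of the second pattern, which conditions on each
  pattern's internal structure and tests independence proper.
- **Bivariate, batch interspecific default:** CSR of both patterns. This is
  a deliberate choice: the shift null proved so conservative for cluster
  processes that habitat-segregated pairs are almost never flagged at the
  1% level, while typical published negative-association curves (tens of
  percent of pairs) are only attainable under a CSR-type null. The caveat
  is real and documented here: under the CSR null part of the "negative"
  signal reflects each species' own patchiness, not pairwise repulsion.
  `null="shift"` switches to the strict independence test.

Per-scale summaries bin the r axis into (0–2.5, 2.5–5, 5–10, 10–15, 15–20,
20–25] m; a species (or pair) counts as clustered (or negatively
associated) in a bin when its call occurs at **any** r in the bin
(`rule="all"` requires every r). Batch filters follow the field
conventions: small-tree clustering uses stems with DBH ≤ 7.5 cm and
species with ≥ 10 such stems; interspecific association uses all unordered
pairs of species with ≥ 50 stems; the intraspecific (large-vs-small)
analysis needs ≥ 1 stem with DBH ≥ 25 cm and ≥ 2 (batch: ≥ 10) small
stems, and skips — with a logged reason — species that fail the filter.

## Niche indices

Resource states are the plot's 10 m subplots. Niche width is Levins'
B = 1/Σp² ∈ [1, K], computed on stem counts for all species (standardized
(B−1)/(K−1) available); niche overlap is Pianka's
O = Σp_i p_j / √(Σp_i² Σp_j²) ∈ [0, 1], computed on subplot occupancy
(0/1) for the top 25 species by total abundance, ties broken by species
code. Schoener's 1 − ½Σ|p_i − p_j| is provided as a labelled alternative.
These are the canonical defaults of the classical niche-index toolkits.
Width samples from two plots are compared with a two-sided Mann–Whitney U
test. No null-model (RA1–RA4 style) randomizations are included.

## Richness–environment regression

Per-subplot species richness is regressed on each soil variable (pH, SOM %,
WC %, TN/TP/TK g/kg) by OLS with Pearson r and its two-sided p
(`richness_env_regression(y, x)` is plain OLS of y on x; r and p are
orientation-free). No spatial autocorrelation correction is applied, so
p-values on real, spatially structured data are anti-conservative — a
stated limitation of this simple analysis, matching common field practice.

## Synthetic generator

`SyntheticDesign` draws a full plot with known ground truth:

- **SAD:** abundance = max(1, round(LogNormal(μ, σ))), defaults μ = 1.2,
  σ = 1.6, S = 150 species. These give ≈ 31% singleton species and ≈ 1,800
  expected stems per hectare — the realistic scale for a 1-ha tropical
  census (roughly a third of species rare, ~2,000 stems).
- **Spatial models per species:** Poisson (CSR); Thomas cluster process
  (parents uniform, Poisson(μ_c = 10) offspring, isotropic Gaussian
  σ_c = 3 m displacement, toroidal wrapping — which keeps the intensity
  uniform and the closed form g(r) = 1 + exp(−r²/4σ²)/(4πσ²κ) valid);
  or Thomas + conspecific negative density dependence (each recruit
  survives with probability (1−δ)^m, m = conspecific parents within
  ρ = 5 m; δ = 0.6). In the census generator the Thomas draw is
  count-conditioned (exactly n offspring over ~n/μ_c parents) so realized
  abundances match the SAD; the unconditional process is exposed as
  `simulate_thomas` for estimator checks.
- **Habitat filtering:** a smooth binary habitat field over the subplot
  grid (5×5 toroidal neighbour-averaged noise, median-thresholded; patches
  a few subplots wide). Each clustered species prefers one type (balanced
  across species) and rejects wrong-habitat parents with probability
  `habitat_segregation`. This is the generator's mechanism for niche
  differentiation: it produces interspecific segregation and lowers
  subplot-occupancy overlap between opposite-preference species.
- **DBH:** shifted exponential (min 3, mean 6 cm) giving the inverse-J
  diameter structure; optionally the most abundant species draws from
  Normal(18, 6) truncated at 3 cm, mimicking a canopy conifer whose
  diameter classes approach a normal distribution.
- **Taxonomy:** species→genus→family with 1+Poisson sizes, yielding a
  realistic mix of dominant, common and singleton families.
- **Environment:** each variable is linear in realized subplot richness
  with stated coefficients plus Gaussian noise (pH +0.03/species, SOM
  −0.25, WC −0.5, TN −0.05, TP −0.01, TK −0.2; intercepts keep pH in
  (0, 14)), so OLS of a variable on richness recovers its coefficient.

Two preset designs encode the study contrast: `lowland_like_design` (S=150,
70% clustered species of which 25% NDD-thinned, habitat_segregation 0.95)
and `montane_like_design` (S=120, 17% clustered, segregation 0.25). Run
through the pipeline, the lowland-like design shows a higher small-tree
clustered proportion (strongest at 2.5–5 m, declining by 15–20 m), a higher
negative-association proportion among dominant pairs, and lower mean niche
overlap — the qualitative diversity-maintenance contrast. One divergence
from typical field reports is expected and real: because clustering
concentrates stems in few subplots, the lowland-like design also has
systematically *narrower* Levins widths, so the width comparison comes out
significant on these synthetic plots.

What the generator does **not** emulate: topographic gradients and
autocorrelated environment driving placement (environment is derived from
richness, not the reverse), interspecific competition dynamics, size-
structured demography (DBH is independent of location), or measurement
error. Passing tests therefore demonstrate the estimators and tests behave
correctly on known structure, not that real plots satisfy these models.

## Problem sizes and tolerances

Simulation-based checks use deliberately modest sizes chosen to give stable
statistics: CSR pcf bias is checked at n = 500 (mean g over 5–20 m within
1 ± 0.1); the Thomas closed form at κ = 20 ha⁻¹, σ = 3 m over 20 replicates
(within 15%); envelope calibration at a fixed 5 m scale over 500 replicates
of a 50-point CSR pattern with nsim = 999, k = 5 (exceedance 1% ± 1 pp);
clustering power over 50 Thomas replicates (detection ≥ 90% at some
r ≤ 5 m); the design contrast over 3 replicate plot pairs at nsim = 199,
k = 1; SAD recovery at S = 200 (|Δμ|, |Δσ| ≤ 0.15); environment-slope
recovery over 30 plots × 3 variables (≥ 90% within 2 SE). Degenerate
inputs (empty censuses, single-point patterns, zero resource rows,
sub-minimum DBH, oversized r grids) raise explicit errors rather than
propagating NaNs.
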