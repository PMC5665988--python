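# Methods

This note documents the models implemented in `ncplink`, their assumptions,
the tunable parameters, numerical choices, and what the synthetic-data tests
do and do not establish.

## O₂/Ar net community production

The mixed layer is treated as a well-mixed box at steady state with no
vertical mixing across its base. Under these assumptions the biological O₂
air–sea flux equals NCP. Argon normalization removes solubility-driven O₂
anomalies (bubble injection, warming), so the biological supersaturation is

Δ(O₂/Ar) = [(O₂/Ar)ₛₐₘₚₗₑ / (O₂/Ar)ₛₐₜ − 1] × 100 %.

The flux is NCP(O₂) = k · [O₂]ₛₐₜ · Δ(O₂/Ar)/100 in mmol O₂ m⁻² day⁻¹, and
NCP(C) = NCP(O₂)/PQ with the photosynthetic quotient PQ = 1.4 mol O₂ per
mol C by default (`pq` is an argument everywhere; PQ = 1 reproduces the
sensitivity case in which carbon and oxygen fluxes coincide).

Parameters and conventions:

- **Solubility.** Garcia–Gordon combined fit (Benson–Krause scale), which
  returns µmol O₂ kg⁻¹. The flux equation needs a volumetric concentration,
  so the per-mass value is multiplied by the mixed-layer density ρ/1000 —
  this is where the explicit density factor of the flux formula lives. Both
  conventions are exposed (`o2_saturation_per_mass`,
  `o2_saturation_concentration`); the volumetric one feeds `compute_ncp`.
  Outside the fit's validity range (about −2…40 °C, 0…42 PSU) a warning is
  raised rather than an error.
- **Gas transfer.** Quadratic wind-speed law
  k = a·u₁₀²·(Sc/660)^(−1/2) with a = 0.251 cm hr⁻¹ (m s⁻¹)⁻², the standard
  reanalysis-wind calibration of the short-term quadratic form; `coeff` is
  configurable since calibrations differ at the ~10 % level. The Schmidt
  number uses the standard fourth-order O₂-in-seawater polynomial in
  temperature (S = 35); the `schmidt` callable is injectable, which the
  tests use to pin Sc = 660.
- **Wind-history weighting.** Daily piston velocities over a 60-day window
  (Δt = 1 day) are combined walking backward from the sampling day: day i
  receives weight ωᵢ = Π_{j>i}(1 − fⱼ) with fⱼ = min(kⱼΔt/MLD, 1) — the
  fraction of the mixed layer not yet ventilated by more recent days. The
  weighted k is Σωᵢkᵢ/Σωᵢ. For constant wind this is exactly the unweighted
  value; fⱼ is capped at 1 so a single violent day cannot produce negative
  weights.
- **Mixed-layer depth.** Shallowest depth at which σθ exceeds the
  shallowest-level value by 0.03 kg m⁻³, linearly interpolated between the
  bracketing levels. A profile that never crosses the threshold raises an
  explicit "MLD undefined" error rather than returning a sentinel.
- **Derived quantities.** O₂ residence time = MLD/k (days); NCP/POC
  (m day⁻¹) divides NCP(C) by the mixed-layer POC concentration
  (mmol C m⁻³) as a biomass-normalized export-potential index.

The steady-state assumption is documented, not tested: time-dependent
inversions and entrainment corrections are out of scope.

## OTU table operations

Tables are read and written in the QIIME-classic TSV dialect (rows = OTUs,
optional trailing taxonomy column). The network-stage preprocessing is
fixed: prevalence filter, then median-depth standardization.

- **Rare-taxa filter**: keep OTU j iff it has ≥ `min_count` (3) reads in at
  least `min_prevalence` (20 %) of samples, boundary inclusive. The
  alternative reading of this rule (drop OTUs below the count threshold in
  at least 20 % of samples) is a stricter filter some pipelines use; the
  prevalence form implemented here is the phyloseq-style convention the
  wording mirrors. The filter is idempotent.
- **Depth standardization** rescales each sample to the median total, which
  preserves within-sample proportions exactly (it is not rarefaction; the
  result is real-valued).
- **Dominance panel**: OTUs ranked by total raw reads, ties broken by id;
  `top_k_otus(table, 20)` defines the regression panel. Relative abundances
  for regression are computed on the unfiltered table — the rare filter
  applies only to the network stage.
- **Aggregation** sums counts within lineage prefixes or an explicit map,
  pooling unmapped OTUs (and optionally groups under 5 % of total reads)
  into "others".

## Spike-and-slab variable selection

Model: yᵢ | β, σ² ~ N(xᵢβ + α, σ²) with standardized predictors; prior
βⱼ ~ π·δ₀ + (1−π)·N(0, ψⱼ²); π ~ Beta(1,1); ψⱼ⁻² ~ Ga(aⱼ, bⱼ);
σ⁻² ~ Ga(a, b); α ~ N(µ₀, σ₀²). Defaults aⱼ = bⱼ = a = b = 0.01
(weakly informative), µ₀ = 0, σ₀² = 10⁴. Chain: 10 000 iterations, first
5 000 discarded, single chain, mandatory seed.

Gibbs updates run β₁…βₚ sequentially, then π, ψⱼ⁻², σ⁻², α. Each βⱼ is
updated by marginalizing it analytically: with partial residual r and
posterior precision q = ψⱼ⁻² + xⱼᵀxⱼ/σ², mean m = (xⱼᵀr/σ²)/q, the
inclusion log-odds are log((1−π)/π) + ½log(ψⱼ⁻²/q) + ½m²q; when included,
βⱼ is drawn from N(m, 1/q), otherwise set exactly to zero. ψⱼ⁻² uses the
conjugate update only when βⱼ ≠ 0 in the current state and is refreshed
from its prior otherwise.

Numerical choices: inclusion odds are computed entirely in log space
(the heavy-tailed Ga(0.01, 0.01) draws produce slab variances up to ~10²⁸);
sampled precisions are floored at 10⁻¹², capping the slab SD at 10⁶ —
effectively flat for standardized predictors and responses of magnitude
≲ 10², and without visible effect on inclusion behavior. A non-finite state
raises with the iteration index.

The inclusion probability p(βⱼ) is the fraction of kept draws with
βⱼ ≠ 0, recomputable exactly from the stored draws. Selection cuts the
descending p(βⱼ) curve at its largest consecutive gap within the first
max_k + 1 = 6 positions ("sharp drop" formalized as largest gap; the guard
prevents pathological deep cuts). Flat curves return an empty selection
with a `no_sharp_drop` flag. Selection is scale-invariant in y, so whether
the response is NCP in O₂ or C units does not matter after
standardization.

Companions: OLS (`fit_mlr`, via statsmodels) reports R², adjusted R², RSS
and AICc with the Gaussian-likelihood form
AIC = n·ln(RSS/n) + 2k, k = coefficients (incl. intercept) + 1 for the
variance, plus 2k(k+1)/(n−k−1) — the convention of common stepwise
implementations. Forward stepwise greedily adds the AICc-minimizing
predictor and stops when nothing improves. Variance partitioning fits all
2^m − 1 subset-union models for m = 2 or 3 disjoint predictor sets,
converts each R² to adjusted R², and solves the inclusion–exclusion linear
system for unique/shared Venn fractions; negative shared fractions are
possible and reported as-is, and the fractions recompose the full-model
adjusted R² to numerical precision by construction.

## SparCC co-occurrence networks

Counts are perturbed to fractions by Dirichlet resampling (gamma draws with
shape countᵢⱼ + 1, row-normalized), log-ratio variances
Tᵢⱼ = var(log(xᵢ/xⱼ)) are assembled from the log-fraction covariance, and
basis variances ω solve the linear system implied by
Tᵢⱼ ≈ ωᵢ + ωⱼ − 2ρᵢⱼ√(ωᵢωⱼ) under the sparse-correlation assumption
(M ω = rowsums(T) with M = (p−2)I + 11ᵀ). The most correlated pair above
0.1 is iteratively excluded from the system (up to 10 rounds) because it
violates that assumption; correlations are clipped to [−1, 1] and the
median over 20 resampled estimates is reported. Basis variances are floored
at 10⁻¹² before the square root. The original algorithm's additional rule of
fully dropping a component excluded more than p − 3 times is omitted; at
these exclusion budgets it never triggers. The non-resampled variant
(`dirichlet=False`, requiring strictly positive counts) is exactly
invariant to per-sample scaling and is used to test compositional
invariance.

Permutation p-values shuffle every OTU column independently, re-estimate
the full SparCC matrix per permutation, and use the add-one estimator
p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + N), two-sided, which is bounded in
(0, 1]. Fewer than 20 permutations triggers a resolution warning.

Stations are split at the median NCP/POC: `low` takes values ≤ median,
`high` values ≥ median. For even n with distinct values the halves are
equal and disjoint; for odd n the median station belongs to both halves
(the alternative — assigning it to one side — changes group sizes by one
and is left to the caller by dropping the station beforehand). Heavy ties
spanning the median raise a warning.

Networks take an edge where |r| > 0.75 **and** p < 0.05, signed by the
correlation. Isolated nodes are dropped before computing metrics. Topology
definitions: density 2E/(N(N−1)); average connected neighbors 2E/N; degree
centralization Σ(k_max − kᵢ)/((N−1)(N−2)); clustering coefficient = mean
local coefficient with degree-<2 nodes contributing 0; characteristic path
length and diameter over reachable pairs only (so disconnected clusters are
averaged within components); betweenness normalized by (N−1)(N−2)/2;
closeness within components ((reachable)/Σd). All metrics are verified
exactly against brute-force enumeration (Floyd–Warshall distances, shortest
paths counted as minimal-length walks via adjacency powers) on random
graphs of ≤ 12 nodes.

## Phenotype utilities

Specific growth rate is the OLS slope of ln(fluorescence) vs time (day⁻¹)
with its standard error; the exponential-phase window is the caller's
responsibility. Biovolumes: cylinder π(d/2)²h for centric diatoms, elliptic
prism (π/4)·AL·TW·PH for pennates; `log10_volume_ratio` reports
order-of-magnitude contrasts.

## Synthetic-data generator

The generator emulates the statistical regime of a 21-station summer
underway survey with a 464-OTU 18S table:

- **Abundance spectrum**: power-law dominance weights with the exponent
  solved so the top 20 OTUs hold 78 % of total weight (γ ≈ 1.33). The true
  family of OTU abundance distributions is unknown; the power law is an
  explicit stand-in for hyperdominance, not an inference.
- **Compositions**: per station, basis = weights × exp(z) with
  z ~ N(0, Σ) (Σ = identity by default; any PSD log-covariance can be
  planted), closed to a composition and realized as multinomial counts at a
  log-normal depth (mean 105 253 reads, CV 0.3 — matching overdispersed
  real library sizes). The exact log-basis correlation matrix is returned
  as ground truth for correlation estimators.
- **NCP link**: NCP = α + Σβⱼzⱼ + ε on per-OTU standardized relative
  abundances, α = 20 mmol C m⁻² day⁻¹, planted effects (6, −5, 4.5) on the
  three most dominant OTUs, ε ~ N(0, 1.5²) — i.e. standardized effect sizes
  of 4.0/3.3/3.0 residual SDs, chosen to sit at and above the 3-SD floor
  that defines the recovery conditions. POC = 5 + 7 × (scaled total basis
  biomass) × lognormal(0, 0.15) mmol C m⁻³, keeping NCP/POC positive-
  denominator and biomass-correlated.
- **Environment**: MLD ~ U(11, 22) m; 60-day AR(1) wind history (mean
  8 m s⁻¹, lag-1 coefficient 0.7, innovation SD 2 m s⁻¹, clipped at 0);
  T ~ U(−1.5, 2.5) °C, S ~ U(33, 34.5); a CTD σθ profile constant to
  MLD − 1 m then increasing at 0.03 kg m⁻³ m⁻¹, so the interpolated
  threshold MLD equals the drawn value exactly. The bundle sets each
  station's O₂/Ar sample ratio so that running the flux chain returns the
  planted NCP — making the whole pipeline end-to-end checkable.
- **Seeding**: one global seed spawns independent substreams per stage
  (compositions, link, environment), so stages regenerate in isolation.

What the generator does **not** emulate: sequencing error, chimeras and
taxonomy misassignment; EIMS instrument noise; spatial autocorrelation
between stations; zero-inflation beyond what multinomial sampling of a
hyperdominant composition produces; seasonality in the wind or density
fields. Passing tests therefore demonstrate correctness of the estimators
under the assumed generating model, not robustness to those real-data
features.

## Problem sizes and test design

The recovery experiments use the default scenario (n = 21 stations, top-20
panel, 20 seeded replicates) for selection, n = 100 samples for SparCC
recovery/null (p = 10 and 30), and n = 80 samples, p = 20 OTUs for the
network contrast — sizes at which the planted structure is comfortably
identifiable while a full test run completes in about a minute.

The coupled-vs-loose network contrast plants two covariance blocks chosen
for positive semi-definiteness and separation from the 0.75 edge threshold:
a *hub motif* (hub at r = 0.85 to four spokes, two spoke pairs at 0.9,
cross-spoke 0.55 — the PSD ceiling for a hub over spokes at 0.55/0.9 is
r ≈ 0.866) giving a 6-edge graph with high clustering and centralization,
and a *chain* (Toeplitz 1/0.85/0.55/0.3/0.15) giving a 4-edge path with
zero clustering and long paths. The expected orderings (edges, density,
clustering, centralization higher; path length lower in the coupled
community) follow from the planted graphs, not from tuning.

## Known limitations

- Single-chain MCMC with no convergence diagnostics beyond determinism and
  recovery tests; at n ≫ 100 or p ≫ 50 the per-coordinate Gibbs sweep
  becomes slow.
- The SparCC linear approximation degrades for p < ~10 or strongly
  non-sparse correlation structure; the exclusion heuristic mitigates but
  does not remove this.
- AICc's variance-parameter counting convention differs between software
  packages by a constant per model size; comparisons are only meaningful
  within this implementation.
- The median split duplicates the median station for odd n; network
  comparisons between overlapping subsets are slightly dependent.
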