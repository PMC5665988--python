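# ncplink

Tools for linking eukaryotic plankton community composition to net community
production (NCP) in the ocean mixed layer. The package implements the full
computational chain used in underway O₂/Ar surveys of polar shelf waters:

1. **O₂/Ar NCP fluxes** — biological oxygen supersaturation
   Δ(O₂/Ar) = [(O₂/Ar)ₛₐₘₚₗₑ/(O₂/Ar)ₛₐₜ − 1]·100 %, converted under steady
   state to NCP = k·[O₂]ₛₐₜ·Δ(O₂/Ar), with the gas-transfer (piston)
   velocity k from a quadratic wind-speed law weighted over the 60-day wind
   history by mixed-layer ventilation fractions, mixed-layer depth from a
   Δσθ = 0.03 kg m⁻³ density threshold, carbon conversion at PQ = O₂/C = 1.4,
   O₂ residence time MLD/k, and the biomass-normalized export-potential
   index NCP/POC (m day⁻¹).
2. **OTU table handling** — QIIME-classic TSV I/O, prevalence filtering
   (≥3 reads in ≥20 % of samples), median-sequencing-depth standardization,
   relative abundances, taxonomic aggregation, top-k dominance panels.
3. **Stochastic search variable selection (SSVS)** — Bayesian sparse
   regression of NCP (or NCP/POC) on standardized OTU relative abundances
   with a Dirac-spike / normal-slab prior
   βⱼ ~ π·δ₀ + (1−π)·N(0, ψⱼ²), sampled by Gibbs; predictors are ranked by
   posterior inclusion probability p(βⱼ) and selected at the sharpest drop
   of the ranked curve. Companions: forward stepwise regression under AICc,
   the final OLS fit, adjusted-R² variance partitioning (Venn fractions),
   and a univariate r² screen.
4. **Compositional co-occurrence networks** — SparCC correlations with
   permutation p-values on rare-filtered, depth-standardized counts; a
   median NCP/POC split of stations; signed networks at |r| > 0.75,
   p < 0.05; and their topology (density, degree centralization, clustering
   coefficient, characteristic path length, diameter, betweenness,
   closeness).
5. **Culture phenotypes** — specific growth rates from log-linear
   fluorescence regression and diatom biovolumes (cylinder / elliptic
   prism).
6. **Synthetic data** — a seeded generator producing a hyperdominant OTU
   table (multinomial reads over a log-normal compositional basis), station
   environments (MLD, AR(1) winds, CTD density profiles), and a sparse
   planted link from OTU abundances to NCP, so every estimator can be
   scored against known ground truth without any external data.

The sparse-regression and correlation estimators follow scikit-learn
conventions (`SSVSRegressor`, `SparCC` with `fit` and trailing-underscore
attributes); module-level functions wrap them.

## Worked example

```python
import numpy as np
from ncplink import simulate, ncp, community, selection

cfg = simulate.ScenarioConfig(seed=7)           # 21 stations, 464 OTUs
bundle = simulate.generate_bundle(cfg)

# per-station flux chain
res = ncp.station_ncp(bundle.stations[0])
print(f"station {res.station_id}: Delta(O2/Ar) = {res.delta_o2ar:.2f} %, "
      f"k = {res.k_weighted:.2f} m/day")
print(f"  NCP = {res.ncp_c:.1f} mmol C m-2 day-1, "
      f"residence time = {res.residence_days:.1f} days, "
      f"NCP/POC = {res.ncp_over_poc:.3f} m/day")

# SSVS on the top-20 OTU panel
panel = community.top_k_otus(bundle.otu_table, 20)
rel = community.relative_abundance(bundle.otu_table)
idx = [bundle.otu_table.otu_ids.index(o) for o in panel]
X = selection.standardize_predictors(rel.values[:, idx], panel)
fit = selection.ssvs_fit(X, bundle.true_ncp, selection.SsvsConfig(seed=0),
                         predictor_ids=panel)
print("selected:", fit.selected)
```

prints

```
station 600.000: Delta(O2/Ar) = 0.32 %, k = 3.53 m/day
  NCP = 2.9 mmol C m-2 day-1, residence time = 5.1 days, NCP/POC = 0.220 m/day
selected: ['OTU_2', 'OTU_1', 'OTU_3']
```

The selected set is exactly the three OTUs whose effects the generator
planted (inclusion probabilities 0.997/0.989/0.987 against ≤ 0.03 for all
others), and an OLS model on them explains R² = 0.95 of the synthetic NCP
variance. The small Δ(O₂/Ar) at this station corresponds to a weakly
autotrophic mixed layer; the ~5-day residence time means the flux reflects
roughly the past week of production.

A command-line interface mirrors the library:

```bash
ncplink simulate --outdir data --seed 7
ncplink ncp --stations data/stations.csv --winds data/winds.csv --out ncp.csv
ncplink select --otu-table data/otu_table.tsv --response ncp.csv:ncp_c_mmol_m2_day --out sel/
ncplink network --otu-table data/otu_table.tsv --ncp-poc ncp.csv:ncp_over_poc_m_day --out net/
```

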