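"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator emulates an Antarctic-shelf underway survey: a hyperdominant
18S OTU table (multinomial reads over a log-normal compositional basis), a
sparse linear link from a few OTU relative abundances to NCP, and station
environments (mixed-layer depth, AR(1) daily wind history, CTD density
profile) from which the O2/Ar flux chain can be run end to end. Every stage
carries its ground truth so downstream estimators can be scored against
planted values.

The abundance spectrum is a power law tuned so the 20 most dominant of 464
OTUs hold ~78% of the reads; the actual family of real OTU abundance
distributions is unknown, so this is an explicit stand-in (see docs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .community import OtuTable, write_otu_table
from .ncp import (
    StationRecord,
    delta_o2ar,
    o2_saturation_concentration,
    piston_velocity,
    weighted_piston_velocity,
)

__all__ = [
    "ScenarioConfig",
    "SyntheticBundle",
    "default_dominance_weights",
    "generate_log_basis",
    "generate_compositions",
    "plant_ncp_link",
    "generate_station_environment",
    "generate_bundle",
    "write_bundle",
]

# default station environment ranges (polar surface waters in summer)
_T_RANGE = (-1.5, 2.5)     # degC
_S_RANGE = (33.0, 34.5)    # PSU
_SIGMA_SURFACE = 27.1      # kg m-3, nominal surface sigma-theta
_O2AR_SAT = 20.0           # nominal equilibrium O2/Ar ratio
_POC_BASE = 5.0            # mmol C m-3 intercept of the POC model
_POC_SLOPE = 7.0           # mmol C m-3 per unit of scaled total biomass
_POC_LOG_NOISE = 0.15


def default_dominance_weights(n_otus: int = 464, top_k: int = 20,
                              top_share: float = 0.78) -> np.ndarray:
    """Power-law rank-abundance weights w_r ~ r^-gamma with gamma solved so
    the top ``top_k`` OTUs hold ``top_share`` of the total weight."""
    ranks = np.arange(1, n_otus + 1, dtype=float)

    def share(g):
        w = ranks ** -g
        return w[:top_k].sum() / w.sum() - top_share

    if n_otus <= top_k:
        return np.ones(n_otus) / n_otus
    gamma = brentq(share, 1e-3, 8.0)
    w = ranks ** -gamma
    return w / w.sum()


@dataclass
class ScenarioConfig:
    """Generator parameters; defaults mirror the survey being emulated
    (21 stations, 464 OTUs, ~105k reads per sample, hyperdominant top-20,
    3 planted NCP effects of at least 3 residual SDs)."""

    n_stations: int = 21
    n_otus: int = 464
    mean_depth: float = 105_253.0
    depth_cv: float = 0.3
    dominance_weights: np.ndarray | None = None
    basis_log_covariance: np.ndarray | None = None   # None -> identity
    planted_effects: tuple = ((0, 6.0), (1, -5.0), (2, 4.5))
    alpha: float = 20.0          # mmol C m-2 day-1 baseline NCP
    noise_sd: float = 1.5        # mmol C m-2 day-1 residual SD
    mld_range: tuple = (11.0, 22.0)          # m
    wind_ar1: tuple = (8.0, 0.7, 2.0)        # mean m s-1, lag-1 coeff, innovation sd
    wind_days: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 4:
            raise ValueError("need at least 4 stations")
        if self.dominance_weights is None:
            self.dominance_weights = default_dominance_weights(self.n_otus)
        self.dominance_weights = np.asarray(self.dominance_weights, dtype=float)
        if self.dominance_weights.shape != (self.n_otus,):
            raise ValueError("dominance_weights length must equal n_otus")
        if np.any(self.dominance_weights <= 0):
            raise ValueError("dominance_weights must be positive")
        if self.planted_effects:
            top = max(j for j, _ in self.planted_effects)
            if top >= self.n_otus:
                raise ValueError("planted OTU index out of range")
        mean, phi, sd = self.wind_ar1
        if not 0 <= phi < 1:
            raise ValueError("wind AR(1) lag-1 coefficient must be in [0, 1)")
        if sd < 0 or mean < 0:
            raise ValueError("wind mean and innovation sd must be nonnegative")
        if self.basis_log_covariance is not None:
            cov = np.asarray(self.basis_log_covariance, dtype=float)
            if cov.shape != (self.n_otus, self.n_otus):
                raise ValueError("basis_log_covariance shape mismatch")
            if not np.allclose(cov, cov.T):
                raise ValueError("basis_log_covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-8:
                raise ValueError("basis_log_covariance must be positive semi-definite")
            self.basis_log_covariance = cov


@dataclass
class SyntheticBundle:
    """A complete seeded dataset plus its planted ground truth."""

    otu_table: OtuTable
    stations: list[StationRecord]
    true_ncp: np.ndarray                 # mmol C m-2 day-1
    true_ncp_over_poc: np.ndarray        # m day-1
    true_effects: np.ndarray             # per-OTU coefficients, exact zeros
    true_basis_correlations: np.ndarray  # log-basis correlation matrix
    config: ScenarioConfig


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_log_basis(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the stations x OTUs log-basis matrix from N(0, Sigma)."""
    n, p = config.n_stations, config.n_otus
    if config.basis_log_covariance is None:
        return rng.standard_normal((n, p))
    cov = config.basis_log_covariance
    # eigen-based square root tolerates exact semi-definiteness
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return rng.standard_normal((n, p)) @ root.T


def _basis_and_counts(config: ScenarioConfig, rng: np.random.Generator):
    z = generate_log_basis(config, rng)
    basis = config.dominance_weights * np.exp(z)        # stations x OTUs
    totals = basis.sum(axis=1)
    comp = basis / totals[:, None]
    sigma2 = np.log1p(config.depth_cv ** 2)
    mu = np.log(config.mean_depth) - sigma2 / 2.0
    depths = np.maximum(
        np.round(rng.lognormal(mu, np.sqrt(sigma2), size=config.n_stations)), 1
    ).astype(int)
    counts = np.vstack([rng.multinomial(d, c) for d, c in zip(depths, comp)])
    if config.basis_log_covariance is None:
        corr = np.eye(config.n_otus)
    else:
        corr = _cov_to_corr(config.basis_log_covariance)
    return counts, corr, totals


def generate_compositions(config: ScenarioConfig,
                          rng: np.random.Generator | None = None):
    """Multinomial read counts over a log-normal compositional basis.

    Returns ``(counts, true_basis_correlations)`` — the exact correlation
    matrix of the generating log-basis, against which compositional
    correlation estimators can be scored.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts, corr, _ = _basis_and_counts(config, rng)
    return counts, corr


def plant_ncp_link(counts: np.ndarray, config: ScenarioConfig,
                   rng: np.random.Generator | None = None,
                   biomass: np.ndarray | None = None):
    """Plant a sparse linear link from OTU relative abundances to NCP.

    NCP_i = alpha + sum_j beta_j z_ij + eps_i, with z the per-OTU
    standardized relative abundances and eps ~ N(0, noise_sd^2). POC is
    generated positive and increasing with total biomass (the count totals
    when no basis biomass is supplied), so NCP/POC is well defined.

    Returns ``(true_ncp, poc, true_effects)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    counts = np.asarray(counts, dtype=float)
    n, p = counts.shape
    rel = counts / counts.sum(axis=1, keepdims=True)
    effects = np.zeros(p)
    for j, beta in config.planted_effects:
        col = rel[:, j]
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"planted OTU index {j} has zero variance")
        effects[j] = beta
    z = np.zeros((n, len(config.planted_effects)))
    for k, (j, _) in enumerate(config.planted_effects):
        col = rel[:, j]
        z[:, k] = (col - col.mean()) / col.std(ddof=1)
    betas = np.array([b for _, b in config.planted_effects])
    true_ncp = config.alpha + z @ betas + rng.normal(0.0, config.noise_sd, size=n)

    if biomass is None:
        biomass = counts.sum(axis=1)
    scaled = biomass / np.mean(biomass)
    poc = (_POC_BASE + _POC_SLOPE * scaled) * np.exp(
        rng.normal(0.0, _POC_LOG_NOISE, size=n))
    return true_ncp, poc, effects


def generate_station_environment(config: ScenarioConfig,
                                 rng: np.random.Generator | None = None
                                 ) -> list[StationRecord]:
    """Station environments: MLD, AR(1) wind history, T/S, density profile.

    The CTD profile is built so that the 0.03 kg m-3 threshold MLD equals
    the drawn MLD exactly under linear interpolation. O2/Ar is initialized
    at equilibrium; :func:`generate_bundle` overwrites it to be consistent
    with the planted NCP.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    mean_w, phi, sd_w = config.wind_ar1
    stations: list[StationRecord] = []
    for i in range(config.n_stations):
        mld = rng.uniform(*config.mld_range)
        if sd_w == 0:
            winds = np.full(config.wind_days, mean_w)
        else:
            w = np.empty(config.wind_days)
            w[0] = mean_w + rng.normal(0, sd_w / np.sqrt(1 - phi ** 2))
            for t in range(1, config.wind_days):
                w[t] = mean_w + phi * (w[t - 1] - mean_w) + rng.normal(0, sd_w)
            winds = np.clip(w, 0.0, None)
        temp = rng.uniform(*_T_RANGE)
        sal = rng.uniform(*_S_RANGE)
        line = 600 - 100 * (i // 5)
        sta = f"{line}.{40 * (i % 5):03d}"
        sigma0 = _SIGMA_SURFACE + rng.normal(0, 0.05)
        stations.append(StationRecord(
            station_id=sta,
            timestamp=f"2014-01-{5 + i:02d}T12:00:00",
            temperature=temp,
            salinity=sal,
            o2ar_sample=_O2AR_SAT,
            o2ar_sat=_O2AR_SAT,
            mld=mld,
            mixed_layer_density=1000.0 + sigma0,
            wind_history=winds,
            poc=10.0,
            latitude=-64.0 - 0.2 * i,
            longitude=-64.0 - 0.3 * i,
        ))
        stations[-1].sigma_profile = _density_profile(mld, sigma0)
    return stations


def _density_profile(mld: float, sigma0: float, slope: float = 0.03):
    """(depth, sigma-theta) levels whose interpolated threshold-MLD is ``mld``.

    Density is constant down to z0 = mld - 1 m then increases at
    ``slope`` kg m-3 per m, so the 0.03 threshold is crossed exactly at
    z0 + 0.03/slope = mld.
    """
    z0 = mld - MLD_DENSITY_THRESHOLD_OVER_SLOPE
    depths = np.array([0.0, z0 / 2.0, z0, z0 + 5.0, z0 + 10.0, 60.0])
    sigma = np.where(depths <= z0, sigma0, sigma0 + slope * (depths - z0))
    return depths, sigma


MLD_DENSITY_THRESHOLD_OVER_SLOPE = 1.0  # m: 0.03 kg m-3 / 0.03 kg m-3 m-1


def generate_bundle(config: ScenarioConfig) -> SyntheticBundle:
    """Full dataset: OTU table, stations, and consistent planted truth.

    One global seed feeds independent substreams per stage so stages can be
    regenerated in isolation. Station O2/Ar samples are set so that running
    the flux chain (weighted k, [O2]_sat, Delta) returns the planted NCP.
    """
    ss = np.random.SeedSequence(config.seed)
    r_comp, r_link, r_env = [np.random.default_rng(s) for s in ss.spawn(3)]
    counts, corr, biomass = _basis_and_counts(config, r_comp)
    true_ncp, poc, effects = plant_ncp_link(counts, config, r_link, biomass=biomass)
    stations = generate_station_environment(config, r_env)

    pq = 1.4
    ncp_over_poc = np.empty(config.n_stations)
    for i, st in enumerate(stations):
        st.poc = float(poc[i])
        k_daily = piston_velocity(st.wind_history, st.temperature)
        k_w = weighted_piston_velocity(k_daily, st.mld)
        o2sat = float(o2_saturation_concentration(
            st.temperature, st.salinity, st.mixed_layer_density))
        delta = true_ncp[i] * pq / (k_w * o2sat) * 100.0
        st.o2ar_sample = st.o2ar_sat * (1.0 + delta / 100.0)
        ncp_over_poc[i] = true_ncp[i] / st.poc

    otu_ids = [f"OTU_{j + 1}" for j in range(config.n_otus)]
    taxonomy = {oid: _LINEAGES[j % len(_LINEAGES)] for j, oid in enumerate(otu_ids)}
    sample_ids = [st.station_id for st in stations]
    table = OtuTable(counts, sample_ids, otu_ids, taxonomy)
    return SyntheticBundle(table, stations, true_ncp, ncp_over_poc, effects,
                           corr, config)


# lineage strings assigned cyclically so taxonomic aggregation is exercisable
_LINEAGES = [
    "Eukaryota;Stramenopiles;Bacillariophyta;Bacillariophyceae",
    "Eukaryota;Stramenopiles;Bacillariophyta;Mediophyceae",
    "Eukaryota;Stramenopiles;Bacillariophyta;Coscinodiscophyceae",
    "Eukaryota;Hacrobia;Haptophyta;Prymnesiophyceae",
    "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae",
    "Eukaryota;Hacrobia;Cryptophyta;Cryptophyceae",
    "Eukaryota;Opisthokonta;Metazoa;Maxillopoda",
    "Eukaryota;Alveolata;Ciliophora;Spirotrichea",
]


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write the bundle as plain-text files; returns the paths written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["otu_table"] = os.path.join(outdir, "otu_table.tsv")
    write_otu_table(bundle.otu_table, paths["otu_table"])

    paths["stations"] = os.path.join(outdir, "stations.csv")
    with open(paths["stations"], "w") as fh:
        fh.write("station_id,timestamp,latitude,longitude,temperature,salinity,"
                 "o2ar_sample,o2ar_sat,mld,mixed_layer_density,poc\n")
        for st in bundle.stations:
            fh.write(f"{st.station_id},{st.timestamp},{st.latitude},{st.longitude},"
                     f"{st.temperature:.4f},{st.salinity:.4f},"
                     f"{st.o2ar_sample:.8f},{st.o2ar_sat:.8f},{st.mld:.4f},"
                     f"{st.mixed_layer_density:.4f},{st.poc:.4f}\n")

    paths["winds"] = os.path.join(outdir, "winds.csv")
    with open(paths["winds"], "w") as fh:
        fh.write("station_id,day_offset,u10\n")
        for st in bundle.stations:
            m = len(st.wind_history)
            for d, u in enumerate(st.wind_history):
                fh.write(f"{st.station_id},{d - m + 1},{u:.5f}\n")

    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump({
            "true_ncp": bundle.true_ncp.tolist(),
            "true_ncp_over_poc": bundle.true_ncp_over_poc.tolist(),
            "true_effects": bundle.true_effects.tolist(),
            "planted_otus": [f"OTU_{j + 1}" for j, _ in
                             bundle.config.planted_effects],
        }, fh, indent=1)
    return paths
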