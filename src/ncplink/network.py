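"""Compositional co-occurrence networks and their topology.

Relative-abundance (compositional) data induce spurious negative
correlations when analyzed naively; SparCC sidesteps this by working with
log-ratio variances T_ij = var(log(x_i/x_j)) and solving an approximate
linear system for the basis variances under a sparsity assumption, from
which basis correlations follow. Counts are perturbed to fractions by
Dirichlet resampling and the procedure is repeated, taking the median.

Stations are split at the median NCP/POC, a network is built per subset
from correlations passing |r| and permutation-p thresholds, and standard
topology metrics (density, degree centralization, clustering coefficient,
characteristic path length, diameter, centralities) are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SparccConfig",
    "SparCC",
    "CooccurrenceNetwork",
    "TopologyMetrics",
    "median_split",
    "sparcc_correlations",
    "sparcc_pvalues",
    "build_network",
    "topology_metrics",
    "compare_networks",
]


@dataclass
class SparccConfig:
    """SparCC settings (the original algorithm's published defaults)."""

    n_estimates: int = 20          # Dirichlet-resampled replicates, median-aggregated
    exclusion_threshold: float = 0.1
    max_exclusions: int = 10
    n_permutations: int = 100
    dirichlet: bool = True         # False: plain fractions (needs all counts > 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_estimates, self.max_exclusions, self.n_permutations) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must be in (0, 1)")


def _fractions(counts: np.ndarray, rng: np.random.Generator,
               dirichlet: bool) -> np.ndarray:
    if dirichlet:
        g = rng.standard_gamma(counts + 1.0)
        return g / g.sum(axis=1, keepdims=True)
    if np.any(counts <= 0):
        raise ValueError("plain fractions require strictly positive counts")
    return counts / counts.sum(axis=1, keepdims=True)


def _basis_correlations(T: np.ndarray, exclusion_threshold: float,
                        max_exclusions: int) -> np.ndarray:
    """Solve the basis-variance linear system; iteratively exclude the most
    correlated pair (it violates the sparse-correlation assumption)."""
    p = T.shape[0]
    M = np.ones((p, p)) + np.diag(np.full(p, float(p - 2)))
    t = T.sum(axis=1)
    excluded = np.zeros((p, p), dtype=bool)
    rho = None
    for _ in range(max_exclusions + 1):
        w = np.linalg.solve(M, t)
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - T) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        a = np.abs(rho)
        np.fill_diagonal(a, 0.0)
        a[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(a), a.shape)
        if a[i, j] <= exclusion_threshold or excluded.sum() // 2 >= max_exclusions:
            break
        excluded[i, j] = excluded[j, i] = True
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] = M[j, i] = 0.0
        t[i] -= T[i, j]
        t[j] -= T[i, j]
    return rho


def _sparcc_once(counts: np.ndarray, rng: np.random.Generator,
                 cfg: SparccConfig) -> np.ndarray:
    f = _fractions(counts, rng, cfg.dirichlet)
    L = np.log(f)
    V = L.var(axis=0, ddof=1)
    C = np.cov(L.T, ddof=1)
    T = V[:, None] + V[None, :] - 2.0 * C
    np.fill_diagonal(T, 0.0)
    return _basis_correlations(T, cfg.exclusion_threshold, cfg.max_exclusions)


def sparcc_correlations(counts: np.ndarray,
                        config: SparccConfig | None = None) -> np.ndarray:
    """Median-aggregated SparCC correlation matrix (symmetric, unit diagonal)."""
    config = config or SparccConfig()
    counts = np.asarray(counts, dtype=float)
    n, p = counts.shape
    if p < 3:
        raise ValueError("SparCC needs at least 3 OTUs for the basis system")
    if n < 4:
        raise ValueError("SparCC needs at least 4 samples")
    rng = np.random.default_rng(config.seed)
    reps = [_sparcc_once(counts, rng, config) for _ in range(config.n_estimates)]
    rho = np.median(reps, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_pvalues(counts: np.ndarray, observed_corr: np.ndarray,
                   config: SparccConfig | None = None) -> np.ndarray:
    """Two-sided permutation p-values for SparCC correlations.

    Each permutation shuffles every OTU column independently across samples
    (destroying all between-OTU association while keeping marginals) and
    re-estimates the full SparCC matrix. The add-one estimator
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_permutations) keeps p in (0, 1].
    """
    config = config or SparccConfig()
    counts = np.asarray(counts, dtype=float)
    observed = np.abs(np.asarray(observed_corr))
    if config.n_permutations < 20:
        warnings.warn("fewer than 20 permutations: p-value resolution is coarse",
                      stacklevel=2)
    rng = np.random.default_rng(config.seed + 1)
    n, p = counts.shape
    exceed = np.zeros((p, p))
    perm_cfg = SparccConfig(
        n_estimates=config.n_estimates,
        exclusion_threshold=config.exclusion_threshold,
        max_exclusions=config.max_exclusions,
        n_permutations=config.n_permutations,
        dirichlet=config.dirichlet,
        seed=config.seed,
    )
    for _ in range(config.n_permutations):
        perm = np.empty_like(counts)
        for j in range(p):
            perm[:, j] = counts[rng.permutation(n), j]
        reps = [_sparcc_once(perm, rng, perm_cfg)
                for _ in range(perm_cfg.n_estimates)]
        r_perm = np.abs(np.median(reps, axis=0))
        exceed += r_perm >= observed
    pvals = (1.0 + exceed) / (1.0 + config.n_permutations)
    pvals = np.minimum(pvals, pvals.T)
    np.fill_diagonal(pvals, 1.0)
    return pvals


class SparCC:
    """Estimator-style wrapper: ``fit(counts)`` sets ``correlations_`` and,
    when ``compute_pvalues``, ``pvalues_``."""

    def __init__(self, n_estimates: int = 20, exclusion_threshold: float = 0.1,
                 max_exclusions: int = 10, n_permutations: int = 100,
                 dirichlet: bool = True, compute_pvalues: bool = False,
                 random_state: int = 0):
        self.n_estimates = n_estimates
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusions = max_exclusions
        self.n_permutations = n_permutations
        self.dirichlet = dirichlet
        self.compute_pvalues = compute_pvalues
        self.random_state = random_state

    def _config(self) -> SparccConfig:
        return SparccConfig(
            n_estimates=self.n_estimates,
            exclusion_threshold=self.exclusion_threshold,
            max_exclusions=self.max_exclusions,
            n_permutations=self.n_permutations,
            dirichlet=self.dirichlet,
            seed=self.random_state)

    def fit(self, X, y=None):
        cfg = self._config()
        self.correlations_ = sparcc_correlations(X, cfg)
        if self.compute_pvalues:
            self.pvalues_ = sparcc_pvalues(X, self.correlations_, cfg)
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_estimates", "exclusion_threshold", "max_exclusions",
            "n_permutations", "dirichlet", "compute_pvalues", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def median_split(sample_ids: list[str], values: np.ndarray
                 ) -> tuple[list[str], list[str]]:
    """Split samples at the median of ``values``.

    ``low`` takes values <= median, ``high`` values >= median: for an even
    number of distinct values the halves are disjoint and equal; for odd n
    the median sample belongs to both (documented convention). Heavy ties
    spanning the median trigger a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(sample_ids) != values.size or values.size < 4:
        raise ValueError("need >= 4 samples with matching ids")
    med = float(np.median(values))
    low = [s for s, v in zip(sample_ids, values) if v <= med]
    high = [s for s, v in zip(sample_ids, values) if v >= med]
    n = values.size
    if max(len(low), len(high)) > n // 2 + 1:
        warnings.warn("ties at the median make the split unequal", stacklevel=2)
    return low, high


@dataclass
class CooccurrenceNetwork:
    """Thresholded signed co-occurrence graph (isolated nodes dropped)."""

    graph: nx.Graph
    label: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return [(u, v, d["correlation"], d["sign"])
                for u, v, d in self.graph.edges(data=True)]

    def edge_table(self) -> pd.DataFrame:
        rows = [{"otu_a": u, "otu_b": v, "correlation": d["correlation"],
                 "p_value": d["p_value"], "sign": d["sign"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "correlation",
                                           "p_value", "sign"])


def build_network(corr: np.ndarray, pvals: np.ndarray, otu_ids: list[str],
                  r_threshold: float = 0.75, p_threshold: float = 0.05,
                  label: str = "") -> CooccurrenceNetwork:
    """Edges where |r| > r_threshold and p < p_threshold; sign from r.

    Nodes without any edge are dropped (only connected OTUs appear).
    """
    corr = np.asarray(corr, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    p = len(otu_ids)
    if corr.shape != (p, p) or pvals.shape != (p, p):
        raise ValueError("correlation/p-value matrices must be square and "
                         "match the id list")
    if not (np.allclose(corr, corr.T) and np.allclose(pvals, pvals.T)):
        raise ValueError("matrices must be symmetric")
    g = nx.Graph()
    for i in range(p):
        for j in range(i + 1, p):
            r = corr[i, j]
            if abs(r) > r_threshold and pvals[i, j] < p_threshold:
                g.add_edge(otu_ids[i], otu_ids[j], correlation=float(r),
                           p_value=float(pvals[i, j]),
                           sign="positive" if r > 0 else "negative")
    return CooccurrenceNetwork(graph=g, label=label)


@dataclass
class TopologyMetrics:
    """Whole-network statistics plus per-node centralities."""

    label: str
    n_nodes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    avg_connected_neighbors: float
    density: float
    centralization: float
    clustering_coefficient: float
    characteristic_path_length: float
    diameter: float
    node_table: pd.DataFrame = field(repr=False)

    def scalar_fields(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_nodes", "n_edges", "n_positive_edges", "n_negative_edges",
            "avg_connected_neighbors", "density", "centralization",
            "clustering_coefficient", "characteristic_path_length", "diameter")}


def topology_metrics(network: CooccurrenceNetwork) -> TopologyMetrics:
    """Topology statistics of a co-occurrence network.

    Density is 2E/(N(N-1)); the average number of connected neighbors is
    2E/N; degree centralization is sum(k_max - k_i)/((N-1)(N-2)); the
    clustering coefficient averages the local coefficient with degree-<2
    nodes contributing 0; characteristic path length and diameter are over
    reachable pairs only, so disconnected components are handled; closeness
    is computed within components.
    """
    g = network.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if e == 0:
        raise ValueError("network has no edges")
    signs = [d.get("sign", "positive") for _, _, d in g.edges(data=True)]
    degrees = dict(g.degree())
    kmax = max(degrees.values())
    centralization = 0.0
    if n > 2:
        centralization = sum(kmax - k for k in degrees.values()) / ((n - 1) * (n - 2))
    dist_sum = 0
    dist_count = 0
    diameter = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                dist_sum += d
                dist_count += 1
                diameter = max(diameter, d)
    cpl = dist_sum / dist_count  # ordered pairs; ratio equals unordered mean
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    node_table = pd.DataFrame({
        "degree": pd.Series(degrees),
        "betweenness": pd.Series(betweenness),
        "closeness": pd.Series(closeness),
    }).sort_index()
    return TopologyMetrics(
        label=network.label,
        n_nodes=n,
        n_edges=e,
        n_positive_edges=sum(s == "positive" for s in signs),
        n_negative_edges=sum(s == "negative" for s in signs),
        avg_connected_neighbors=2.0 * e / n,
        density=nx.density(g),
        centralization=centralization,
        clustering_coefficient=nx.average_clustering(g),
        characteristic_path_length=cpl,
        diameter=float(diameter),
        node_table=node_table,
    )


def compare_networks(low: TopologyMetrics, high: TopologyMetrics) -> pd.DataFrame:
    """Side-by-side metric table with low/high ratios."""
    rows = []
    low_f, high_f = low.scalar_fields(), high.scalar_fields()
    for key in low_f:
        lo, hi = low_f[key], high_f[key]
        ratio = lo / hi if hi not in (0, 0.0) else np.nan
        rows.append({"metric": key, "low": lo, "high": hi, "ratio_low_high": ratio})
    return pd.DataFrame(rows).set_index("metric")
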