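"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

from ncplink import community, simulate


# ---------------------------------------------------------------------------
# brute-force graph oracles (exhaustive, for graphs of ~12 nodes)
# ---------------------------------------------------------------------------

def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    return dist


def brute_metrics(adj: np.ndarray) -> dict:
    """Density, centralization, clustering, CPL, diameter, betweenness,
    closeness by direct enumeration (shortest paths counted as minimal-length
    walks via adjacency-matrix powers)."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    e = adj.sum() / 2.0
    dist = floyd_warshall(adj)

    # number of shortest paths between every pair: A^d[s, t] for d = dist
    powers = [np.eye(n)]
    for _ in range(n):
        powers.append(powers[-1] @ adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            d = dist[s, t]
            if np.isfinite(d):
                sigma[s, t] = powers[int(d)][s, t]

    finite = np.isfinite(dist) & (dist > 0)
    cpl = dist[finite].mean() if finite.any() else np.nan
    diameter = dist[finite].max() if finite.any() else 0.0

    clustering = []
    for v in range(n):
        k = deg[v]
        if k < 2:
            clustering.append(0.0)
            continue
        nb = np.nonzero(adj[v])[0]
        links = adj[np.ix_(nb, nb)].sum() / 2.0
        clustering.append(2.0 * links / (k * (k - 1)))

    betweenness = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if s == v or t == v or not np.isfinite(dist[s, t]):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    betweenness[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        betweenness /= (n - 1) * (n - 2) / 2.0

    closeness = np.zeros(n)
    for v in range(n):
        reach = [dist[v, u] for u in range(n)
                 if u != v and np.isfinite(dist[v, u])]
        if reach:
            closeness[v] = len(reach) / sum(reach)

    kmax = deg.max()
    centralization = (np.sum(kmax - deg) / ((n - 1) * (n - 2))) if n > 2 else 0.0
    return {
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        "avg_connected_neighbors": 2.0 * e / n,
        "centralization": centralization,
        "clustering": float(np.mean(clustering)),
        "cpl": float(cpl),
        "diameter": float(diameter),
        "betweenness": betweenness,
        "closeness": closeness,
    }


def brute_weighted_k(k_daily, mld) -> float:
    """Independent product-weight implementation (most recent day last)."""
    k = list(map(float, k_daily))
    m = len(k)
    weights = []
    for i in range(m):
        w = 1.0
        for j in range(i + 1, m):
            w *= 1.0 - min(k[j] / mld, 1.0)
        weights.append(w)
    return sum(w * v for w, v in zip(weights, k)) / sum(weights)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_table() -> community.OtuTable:
    counts = np.array([[10, 30, 60],
                       [5, 50, 45]])
    return community.OtuTable(counts, ["s1", "s2"], ["otu1", "otu2", "otu3"],
                              {"otu1": "Eukaryota;A", "otu2": "Eukaryota;A",
                               "otu3": "Eukaryota;B"})


@pytest.fixture(scope="session")
def small_bundle() -> simulate.SyntheticBundle:
    cfg = simulate.ScenarioConfig(n_stations=21, n_otus=60, mean_depth=20000,
                                  seed=42)
    return simulate.generate_bundle(cfg)
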