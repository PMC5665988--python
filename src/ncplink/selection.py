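"""Bayesian stochastic-search variable selection (SSVS) and companions.

The model is sparse linear regression of a station-level response (NCP or
NCP/POC) on standardized OTU relative abundances:

    y_i | beta, sigma^2 ~ N(x_i beta + alpha, sigma^2)
    beta_j ~ pi * delta_0 + (1 - pi) * N(0, psi_j^2)      (Dirac spike / slab)
    pi ~ Beta(1, 1),  psi_j^-2 ~ Gamma(a_j, b_j),
    sigma^-2 ~ Gamma(a, b),  alpha ~ N(mu_0, sigma_0^2)

sampled by a single-chain Gibbs sampler. The posterior inclusion
probability of predictor j is the fraction of post-burn-in draws with
beta_j != 0; predictors are ranked by it and a subset is selected at the
sharpest drop in the ranked probabilities.

The module also carries the frequentist cross-checks used alongside SSVS:
forward stepwise regression under AICc, the final OLS fit, adjusted-R^2
variance partitioning, and a univariate r^2 screen.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SsvsConfig",
    "SsvsResult",
    "SSVSRegressor",
    "LinearModelFit",
    "SelectionResult",
    "StepwiseResult",
    "VariancePartition",
    "standardize_predictors",
    "ssvs_fit",
    "inclusion_probabilities",
    "select_by_sharp_drop",
    "fit_mlr",
    "aicc",
    "forward_stepwise_aicc",
    "variance_partition",
    "simple_r2_scan",
]

# numerical floor on sampled precisions: the Gamma(0.01, 0.01) priors are so
# heavy-tailed that raw draws can underflow to 0; flooring caps the slab sd
# at 1e6 (effectively flat for standardized predictors) without changing the
# model in any practically observable way.
_PREC_FLOOR = 1e-12


@dataclass
class SsvsConfig:
    """Sampler settings and prior constants.

    The prior Gamma/Normal constants are weakly informative defaults; the
    chain length (10000 iterations, first 5000 discarded) matches standard
    practice for this sampler at n ~ 20.
    """

    iterations: int = 10_000
    burn_in: int = 5_000
    slab_shape: float = 0.01     # a_j
    slab_rate: float = 0.01      # b_j
    noise_shape: float = 0.01    # a
    noise_rate: float = 0.01     # b
    intercept_mean: float = 0.0  # mu_0
    intercept_var: float = 1e4   # sigma_0^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        for name in ("slab_shape", "slab_rate", "noise_shape", "noise_rate",
                     "intercept_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SsvsResult:
    """Posterior draws, inclusion probabilities and selection."""

    beta_draws: np.ndarray       # (iterations - burn_in) x p
    alpha_draws: np.ndarray
    sigma2_draws: np.ndarray
    pi_draws: np.ndarray         # spike (exclusion) weight draws
    inclusion_probs: np.ndarray  # p-vector in [0, 1]
    predictor_ids: list[str]
    ranking: list[str]           # ids by descending inclusion probability
    selected: list[str]
    no_sharp_drop: bool


def standardize_predictors(X: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Mean-center and scale each column to unit SD (denominator n-1)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0]
        names = [ids[j] if ids else f"column {j}" for j in bad]
        raise ValueError(f"constant predictor(s): {', '.join(map(str, names))}")
    return (X - X.mean(axis=0)) / sd


def _gibbs(X: np.ndarray, y: np.ndarray, cfg: SsvsConfig):
    """Dirac-spike / normal-slab Gibbs sampler.

    Each beta_j is updated by analytically comparing the slab and spike
    marginal likelihoods given the partial residual (conjugate normal
    algebra), drawing the inclusion indicator, then drawing beta_j from the
    slab's conditional normal when included. Log-space odds keep the
    heavy-tailed psi draws from overflowing.
    """
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)
    xtx = np.einsum("ij,ij->j", X, X)
    cols = [np.ascontiguousarray(X[:, j]) for j in range(p)]

    beta = np.zeros(p)
    alpha = float(np.mean(y))
    sigma2 = float(np.var(y)) or 1.0
    psi_prec = np.ones(p)
    pi = 0.5  # spike weight

    kept = cfg.iterations - cfg.burn_in
    beta_draws = np.empty((kept, p))
    alpha_draws = np.empty(kept)
    sigma2_draws = np.empty(kept)
    pi_draws = np.empty(kept)

    resid = y - alpha - X @ beta
    for it in range(cfg.iterations):
        inv_s2 = 1.0 / sigma2
        log_pi_ratio = math.log1p(-pi) - math.log(pi)  # log((1-pi)/pi)
        for j in range(p):
            xj = cols[j]
            bj = beta[j]
            if bj != 0.0:
                resid += xj * bj
            post_prec = psi_prec[j] + xtx[j] * inv_s2
            m = (xj @ resid) * inv_s2 / post_prec
            log_odds = (log_pi_ratio
                        + 0.5 * (math.log(psi_prec[j]) - math.log(post_prec))
                        + 0.5 * m * m * post_prec)
            if log_odds > 700:
                include = True
            elif log_odds < -700:
                include = False
            else:
                include = rng.random() < 1.0 / (1.0 + math.exp(-log_odds))
            if include:
                bj = m + rng.standard_normal() / math.sqrt(post_prec)
                beta[j] = bj
                resid -= xj * bj
            else:
                beta[j] = 0.0
        nonzero = beta != 0.0
        k_in = int(nonzero.sum())
        pi = rng.beta(1 + p - k_in, 1 + k_in)
        # slab precisions: conjugate update where included, prior elsewhere
        psi_prec = rng.gamma(cfg.slab_shape, 1.0 / cfg.slab_rate, size=p)
        if k_in:
            b_in = beta[nonzero]
            psi_prec[nonzero] = rng.gamma(
                cfg.slab_shape + 0.5,
                1.0 / (cfg.slab_rate + 0.5 * b_in * b_in))
        np.clip(psi_prec, _PREC_FLOOR, None, out=psi_prec)
        rss = float(resid @ resid)
        sigma2 = 1.0 / rng.gamma(cfg.noise_shape + 0.5 * n,
                                 1.0 / (cfg.noise_rate + 0.5 * rss))
        # intercept
        resid += alpha
        prec_a = 1.0 / cfg.intercept_var + n / sigma2
        mean_a = (cfg.intercept_mean / cfg.intercept_var
                  + resid.sum() / sigma2) / prec_a
        alpha = mean_a + rng.standard_normal() / math.sqrt(prec_a)
        resid -= alpha
        if not np.isfinite(alpha) or not np.isfinite(sigma2):
            raise RuntimeError(f"sampler diverged at iteration {it}")
        if it >= cfg.burn_in:
            k = it - cfg.burn_in
            beta_draws[k] = beta
            alpha_draws[k] = alpha
            sigma2_draws[k] = sigma2
            pi_draws[k] = pi
    return beta_draws, alpha_draws, sigma2_draws, pi_draws


class SSVSRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style spike-and-slab sparse linear regression.

    Parameters mirror :class:`SsvsConfig`. When ``standardize`` is true the
    predictors are mean-centered and variance-scaled inside ``fit`` (the
    convention for this analysis); coefficients are reported on the
    standardized scale either way.

    Attributes (after ``fit``): ``beta_draws_``, ``alpha_draws_``,
    ``sigma2_draws_``, ``pi_draws_``, ``inclusion_probs_``, ``ranking_``,
    ``coef_`` (posterior means), ``intercept_``.
    """

    def __init__(self, iterations: int = 10_000, burn_in: int = 5_000,
                 slab_shape: float = 0.01, slab_rate: float = 0.01,
                 noise_shape: float = 0.01, noise_rate: float = 0.01,
                 intercept_mean: float = 0.0, intercept_var: float = 1e4,
                 standardize: bool = True, random_state: int = 0):
        self.iterations = iterations
        self.burn_in = burn_in
        self.slab_shape = slab_shape
        self.slab_rate = slab_rate
        self.noise_shape = noise_shape
        self.noise_rate = noise_rate
        self.intercept_mean = intercept_mean
        self.intercept_var = intercept_var
        self.standardize = standardize
        self.random_state = random_state

    def _config(self) -> SsvsConfig:
        return SsvsConfig(
            iterations=self.iterations, burn_in=self.burn_in,
            slab_shape=self.slab_shape, slab_rate=self.slab_rate,
            noise_shape=self.noise_shape, noise_rate=self.noise_rate,
            intercept_mean=self.intercept_mean, intercept_var=self.intercept_var,
            seed=self.random_state)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        n, p = X.shape
        if n < 3 or p < 1 or len(y) != n:
            raise ValueError("need n >= 3 samples, p >= 1 predictors, matching y")
        cfg = self._config()
        if self.standardize:
            self._mean_ = X.mean(axis=0)
            self._scale_ = X.std(axis=0, ddof=1)
            if np.any(self._scale_ == 0):
                bad = np.nonzero(self._scale_ == 0)[0]
                raise ValueError(f"constant predictor column(s): {bad.tolist()}")
            Xs = (X - self._mean_) / self._scale_
        else:
            self._mean_ = np.zeros(p)
            self._scale_ = np.ones(p)
            Xs = X
        draws = _gibbs(Xs, y, cfg)
        self.beta_draws_, self.alpha_draws_, self.sigma2_draws_, self.pi_draws_ = draws
        self.inclusion_probs_ = inclusion_probabilities(self.beta_draws_)
        self.ranking_ = np.argsort(-self.inclusion_probs_, kind="stable")
        self.coef_ = self.beta_draws_.mean(axis=0)
        self.intercept_ = float(self.alpha_draws_.mean())
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self._mean_) / self._scale_
        return self.intercept_ + Xs @ self.coef_


def ssvs_fit(X: np.ndarray, y: np.ndarray, config: SsvsConfig | None = None,
             predictor_ids: list[str] | None = None,
             max_k: int = 5) -> SsvsResult:
    """Run the sampler on pre-standardized predictors; rank and select.

    ``X`` is expected already standardized (see
    :func:`standardize_predictors`); use :class:`SSVSRegressor` for the
    self-standardizing estimator interface.
    """
    config = config or SsvsConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    est = SSVSRegressor(
        iterations=config.iterations, burn_in=config.burn_in,
        slab_shape=config.slab_shape, slab_rate=config.slab_rate,
        noise_shape=config.noise_shape, noise_rate=config.noise_rate,
        intercept_mean=config.intercept_mean, intercept_var=config.intercept_var,
        standardize=False, random_state=config.seed)
    est.fit(X, y)
    p = X.shape[1]
    ids = predictor_ids or [f"x{j}" for j in range(p)]
    probs = est.inclusion_probs_
    sel = select_by_sharp_drop(probs, ids=ids, max_k=max_k)
    return SsvsResult(
        beta_draws=est.beta_draws_,
        alpha_draws=est.alpha_draws_,
        sigma2_draws=est.sigma2_draws_,
        pi_draws=est.pi_draws_,
        inclusion_probs=probs,
        predictor_ids=list(ids),
        ranking=sel.ranking,
        selected=sel.selected,
        no_sharp_drop=sel.no_sharp_drop,
    )


def inclusion_probabilities(beta_draws: np.ndarray) -> np.ndarray:
    """Posterior inclusion probabilities: per-predictor fraction of kept
    draws with a nonzero coefficient."""
    beta_draws = np.asarray(beta_draws)
    if beta_draws.ndim != 2 or beta_draws.shape[0] == 0:
        raise ValueError("need at least one post-burn-in draw")
    return (beta_draws != 0.0).mean(axis=0)


@dataclass
class SelectionResult:
    selected: list[str]
    ranking: list[str]
    no_sharp_drop: bool


def select_by_sharp_drop(inclusion_probs: np.ndarray,
                         ids: list[str] | None = None,
                         max_k: int = 5) -> SelectionResult:
    """Cut the descending inclusion-probability curve at its largest drop.

    Only drops within the first ``max_k + 1`` ranked positions are
    considered, so at most ``max_k`` predictors are selected. When the
    probabilities are flat there is no drop to find and the selection is
    empty with ``no_sharp_drop`` set.
    """
    probs = np.asarray(inclusion_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    p = probs.size
    ids = list(ids) if ids is not None else [f"x{j}" for j in range(p)]
    order = sorted(range(p), key=lambda j: (-probs[j], ids[j]))
    ranking = [ids[j] for j in order]
    sorted_probs = probs[order]
    limit = min(max_k, p - 1)
    if limit <= 0:
        return SelectionResult(ranking[:1] if p == 1 else [], ranking, p != 1)
    gaps = sorted_probs[:limit] - sorted_probs[1:limit + 1]
    if gaps.max() <= 1e-12:
        return SelectionResult([], ranking, True)
    cut = int(np.argmax(gaps)) + 1
    return SelectionResult(ranking[:cut], ranking, False)


@dataclass
class LinearModelFit:
    """OLS fit summary (intercept always included)."""

    predictor_ids: list[str]
    coefficients: np.ndarray  # intercept first
    rss: float
    r2: float
    adjusted_r2: float
    aicc: float
    n: int
    p: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.coefficients[0] + X @ self.coefficients[1:]


def aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample corrected AIC for a Gaussian linear model.

    ``n_params`` counts the regression coefficients including the intercept;
    the likelihood form adds one for the error variance, so
    k = n_params + 1 and AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1).
    """
    k = n_params + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k}")
    if rss <= 0:
        return -np.inf
    aic = n * math.log(rss / n) + 2 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mlr(X: np.ndarray, y: np.ndarray,
            predictor_ids: list[str] | None = None) -> LinearModelFit:
    """Ordinary least squares with intercept via statsmodels."""
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y).ravel()) > 1:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    ids = list(predictor_ids) if predictor_ids is not None \
        else [f"x{j}" for j in range(p)]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        # name the offending columns via the QR diagonal
        r = np.abs(np.diag(np.linalg.qr(design, mode="r")))
        bad = [ids[j - 1] for j in range(1, p + 1)
               if r[j] < 1e-10 * max(r.max(), 1.0)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    return LinearModelFit(
        predictor_ids=ids,
        coefficients=np.asarray(res.params),
        rss=rss,
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        aicc=aicc(rss, n, p + 1),
        n=n,
        p=p,
    )


@dataclass
class StepwiseResult:
    trace: list[tuple[str, float]]   # (added id, model AICc) per accepted step
    selected: list[str]
    final_model: LinearModelFit | None
    null_aicc: float


def forward_stepwise_aicc(X: np.ndarray, y: np.ndarray,
                          predictor_ids: list[str] | None = None) -> StepwiseResult:
    """Greedy forward selection minimizing AICc; stops when no addition helps.

    Starting from the intercept-only model, the predictor whose addition
    most lowers AICc is accepted at each step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    ids = list(predictor_ids) if predictor_ids is not None \
        else [f"x{j}" for j in range(p)]
    rss0 = float(np.sum((y - y.mean()) ** 2))
    current_aicc = aicc(rss0, n, 1)
    null_aicc = current_aicc
    chosen: list[int] = []
    trace: list[tuple[str, float]] = []
    remaining = list(range(p))
    final: LinearModelFit | None = None
    while remaining:
        best = None
        for j in remaining:
            cols = chosen + [j]
            if n <= len(cols) + 2:  # keep AICc defined (n > k + 1)
                continue
            try:
                fit = fit_mlr(X[:, cols], y, [ids[c] for c in cols])
            except ValueError:
                continue
            if best is None or fit.aicc < best[1].aicc:
                best = (j, fit)
        if best is None or best[1].aicc >= current_aicc:
            break
        j, fit = best
        chosen.append(j)
        remaining.remove(j)
        current_aicc = fit.aicc
        final = fit
        trace.append((ids[j], fit.aicc))
    return StepwiseResult(trace=trace, selected=[ids[c] for c in chosen],
                          final_model=final, null_aicc=null_aicc)


@dataclass
class VariancePartition:
    """Unique and shared adjusted-R^2 fractions over 2-3 predictor sets.

    ``fractions`` maps a frozenset of set labels to the Venn-region
    fraction; negative shared fractions are possible and reported as-is.
    """

    set_labels: list[str]
    fractions: dict[frozenset, float]
    subset_adj_r2: dict[frozenset, float]
    total_adjusted_r2: float


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition(X: np.ndarray, y: np.ndarray,
                       sets: dict[str, list[str]],
                       predictor_ids: list[str]) -> VariancePartition:
    """Decompose the full-model adjusted R^2 into Venn regions.

    Fits every union of the 2-3 disjoint predictor sets, then solves the
    inclusion-exclusion system A(S) = sum of regions touching S for the
    unique/shared fractions. The fractions recompose the full model's
    adjusted R^2 exactly.
    """
    labels = list(sets)
    m = len(labels)
    if not 2 <= m <= 3:
        raise ValueError("variance partitioning needs 2 or 3 predictor sets")
    all_ids = [i for lab in labels for i in sets[lab]]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("predictor sets must be disjoint")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    col = {pid: j for j, pid in enumerate(predictor_ids)}

    subsets = [frozenset(c) for r in range(1, m + 1)
               for c in itertools.combinations(labels, r)]
    adj: dict[frozenset, float] = {}
    for S in subsets:
        cols = [col[i] for lab in sorted(S) for i in sets[lab]]
        fit = fit_mlr(X[:, cols], y)
        adj[S] = _adjusted_r2(fit.r2, fit.n, len(cols))

    # regions indexed by nonempty label subsets T; A(S) = sum over T with
    # T intersecting S
    A = np.zeros((len(subsets), len(subsets)))
    b = np.zeros(len(subsets))
    for r, S in enumerate(subsets):
        b[r] = adj[S]
        for c, T in enumerate(subsets):
            if S & T:
                A[r, c] = 1.0
    sol = np.linalg.solve(A, b)
    fractions = {T: float(v) for T, v in zip(subsets, sol)}
    return VariancePartition(
        set_labels=labels,
        fractions=fractions,
        subset_adj_r2=adj,
        total_adjusted_r2=adj[frozenset(labels)],
    )


def simple_r2_scan(X: np.ndarray, y: np.ndarray,
                   predictor_ids: list[str] | None = None) -> pd.DataFrame:
    """Univariate OLS screen: per-column r^2 and two-sided slope p-value."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    ids = list(predictor_ids) if predictor_ids is not None \
        else [f"x{j}" for j in range(X.shape[1])]
    rows = []
    for j, pid in enumerate(ids):
        col = X[:, j]
        if np.ptp(col) == 0:
            rows.append({"predictor": pid, "r2": np.nan, "p_value": np.nan,
                         "constant": True})
            continue
        res = stats.linregress(col, y)
        rows.append({"predictor": pid, "r2": res.rvalue ** 2,
                     "p_value": res.pvalue, "constant": False})
    return pd.DataFrame(rows).set_index("predictor")
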