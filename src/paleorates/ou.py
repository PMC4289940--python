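"""Multi-regime Ornstein-Uhlenbeck model family on non-ultrametric trees.

Seven nested models are fitted to a univariate trait with edges painted
into selective regimes (e.g. a focal clade vs the background):

====== ======================================================
BM1    single Brownian rate sigma^2, no pull, single root mean
BMS    per-regime sigma^2, no pull, single root mean
OU1    single optimum theta, pull alpha, rate sigma^2
OUM    per-regime theta, shared alpha and sigma^2
OUMV   per-regime theta and sigma^2, shared alpha
OUMA   per-regime theta and alpha, shared sigma^2
OUMVA  per-regime theta, sigma^2 and alpha
====== ======================================================

No ancestral-state parameter theta_0 is estimated: the process starts at
the root regime's optimum (the mean of that regime's stationary
distribution), which makes the alpha -> 0 limit of every OU model
collapse smoothly onto the matching BM model.

Under piecewise-constant (alpha, sigma^2, theta) per edge both the tip
expectations and covariances have exact recursions:

* weights: w(child) = e^{-alpha t} w(parent) + (1 - e^{-alpha t}) 1[regime],
  so E[x_tip] is a convex combination of regime optima (rows sum to 1);
* variance at a node: P(child) = e^{-2 alpha t} P(parent)
  + sigma^2 (1 - e^{-2 alpha t}) / (2 alpha);
* Cov(x_i, x_j) = exp(-(A_i + A_j - 2 A_mrca)) P(mrca), with A the
  accumulated integral of alpha from the root.

All exponents are differences along paths, hence non-positive: no
overflow for any alpha in the searched range.  Optima are profiled by
GLS; a global sigma^2 scale is profiled analytically; the remaining
shape parameters (alphas, sigma ratios) are optimized numerically from
several deterministic starts on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from .bm import LOG2PI, aicc, align_traits, mrca_matrix
from .tree import Phylogeny, PhylogenyError

__all__ = [
    "RegimePainting",
    "OURegimeFit",
    "paint_regimes",
    "fit_ou",
    "compare_models",
    "simulate_ou",
    "read_clades_csv",
    "MODELS",
]

MODELS = ("BM1", "BMS", "OU1", "OUM", "OUMV", "OUMA", "OUMVA")
LOG10_ALPHA_BOUNDS = (-8.0, 2.0)
ALPHA_STARTS = (-6.0, -3.0, -1.5, -0.5, 0.5)  # log10 alpha multistarts


def read_clades_csv(path) -> dict[str, list[str]]:
    """Clade membership table with columns taxon, clade -> {clade: taxa}."""
    df = pd.read_csv(path)
    out: dict[str, list[str]] = {}
    for clade, grp in df.groupby("clade"):
        out[str(clade)] = list(grp["taxon"])
    return out


@dataclass
class RegimePainting:
    """Per-edge regime labels plus the regime holding at the root."""

    labels: list[str]            # ordered regime names; index 0 = root regime
    edge_regime: np.ndarray      # regime index of the edge above each node
    root_regime: int
    stem_inclusive: bool

    @property
    def k_regimes(self) -> int:
        return len(self.labels)


def paint_regimes(
    tree: Phylogeny,
    clades: dict[str, int] | None = None,
    stem_inclusive: bool = False,
    background: str = "background",
) -> RegimePainting:
    """Label edges by named clades; nested clades paint innermost-wins.

    ``clades`` maps labels to internal node indices (defaults to the
    tree's clade registry).  By default the stem edge leading to a clade
    keeps the surrounding regime (``stem_inclusive=False``); overlapping
    clades that are not nested are refused.
    """
    clades = dict(tree.clades if clades is None else clades)
    sub = {lab: set(int(v) for v in tree.subtree_nodes(nd)) for lab, nd in clades.items()}
    for a in sub:
        for b in sub:
            if a < b:
                inter = sub[a] & sub[b]
                if inter and not (sub[a] <= sub[b] or sub[b] <= sub[a]):
                    raise PhylogenyError(f"clades {a!r} and {b!r} overlap but are not nested")
    labels = [background] + sorted(clades, key=lambda l: -len(sub[l]))
    idx = {lab: i for i, lab in enumerate(labels)}
    regime = np.zeros(tree.n_nodes, dtype=np.int64)
    for lab in labels[1:]:
        nodes = tree.subtree_nodes(clades[lab])
        members = nodes if stem_inclusive else nodes[nodes != clades[lab]]
        regime[members] = idx[lab]
    return RegimePainting(labels, regime, int(regime[0]), stem_inclusive)


@dataclass
class OURegimeFit:
    model: str
    painting: RegimePainting
    alpha: np.ndarray            # per regime, 1/Ma
    sigma2: np.ndarray           # per regime, (log10 mm)^2/Ma
    theta: np.ndarray            # per regime optima (log10 mm); BM: root mean
    theta_se: np.ndarray
    loglik: float
    k: int
    n_obs: int
    converged: bool = True
    weight: float | None = None  # Akaike weight, filled by compare_models

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n_obs)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "regimes": self.painting.labels,
            "alpha": list(map(float, self.alpha)),
            "sigma2": list(map(float, self.sigma2)),
            "theta": list(map(float, self.theta)),
            "theta_se": list(map(float, self.theta_se)),
            "loglik": self.loglik,
            "k": self.k,
            "aicc": self.aicc,
            "akaike_weight": self.weight,
        }


# ------------------------------------------------------------------ kernels


def _ou_moments(tree: Phylogeny, painting: RegimePainting, alpha: np.ndarray,
                sigma2: np.ndarray, mrca: np.ndarray):
    """Return (W, V): tip weight matrix over regime optima and the tip
    covariance matrix, for per-regime alpha and sigma^2 arrays."""
    n_nodes = tree.n_nodes
    K = painting.k_regimes
    reg = painting.edge_regime
    A = np.zeros(n_nodes)        # integral of alpha root->node
    P = np.zeros(n_nodes)        # variance of the node state
    W = np.zeros((n_nodes, K))   # weights of regime optima in the mean
    W[0, painting.root_regime] = 1.0
    for i in range(1, n_nodes):
        p = tree.parent[i]
        k = reg[i]
        a, s2, t = alpha[k], sigma2[k], tree.edge_length[i]
        at = a * t
        A[i] = A[p] + at
        decay = np.exp(-at)
        W[i] = decay * W[p]
        W[i, k] += 1.0 - decay
        if at > 1e-9:
            accum = s2 * (1.0 - np.exp(-2.0 * at)) / (2.0 * a)
        else:
            accum = s2 * t * (1.0 - at)  # alpha -> 0 expansion
        P[i] = np.exp(-2.0 * at) * P[p] + accum
    tips = tree.tips
    At = A[tips]
    expo = At[:, None] + At[None, :] - 2.0 * A[mrca]
    V = np.exp(-expo) * P[mrca]
    return W[tips], V


def _model_structure(model: str, K: int):
    """Free-parameter layout: (n_alpha, n_sigma_ratio, theta_columns)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if K < 2 and model in {"BMS", "OUM", "OUMV", "OUMA", "OUMVA"}:
        raise ValueError(f"{model} needs at least two regimes")
    return {
        "BM1":   (0, 0, 1),
        "BMS":   (0, K - 1, 1),
        "OU1":   (1, 0, 1),
        "OUM":   (1, 0, K),
        "OUMV":  (1, K - 1, K),
        "OUMA":  (K, 0, K),
        "OUMVA": (K, K - 1, K),
    }[model]


def _expand_params(model: str, K: int, x: np.ndarray):
    n_a, n_s, _ = _model_structure(model, K)
    alphas = np.zeros(K)
    if n_a == 1:
        alphas[:] = 10.0 ** x[0]
    elif n_a == K:
        alphas[:] = 10.0 ** x[:K]
    ratios = np.ones(K)
    if n_s:
        ratios[1:] = np.exp(x[n_a:n_a + n_s])
    return alphas, ratios


def _profile_loglik(tree, painting, mrca, y, model, x):
    """Concentrated log-likelihood: thetas by GLS, sigma scale analytically."""
    K = painting.k_regimes
    alphas, ratios = _expand_params(model, K, x)
    W, V = _ou_moments(tree, painting, alphas, ratios, mrca)
    n = len(y)
    n_a, n_s, n_t = _model_structure(model, K)
    X = np.ones((n, 1)) if n_t == 1 else W
    try:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError:
        return -np.inf, None
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    theta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    e = yw - Xw @ theta
    rss = float(e @ e)
    if rss <= 0:
        return -np.inf, None
    s = rss / n                                  # profiled sigma^2 scale
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * LOG2PI + n * np.log(s) + logdetV + n)
    XtX = Xw.T @ Xw
    try:
        theta_cov = s * np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        theta_cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return float(ll), (alphas, s * ratios, theta, np.sqrt(np.diag(theta_cov)))


def _observed_info_theta_se(tree, painting, mrca, y, model, x_shape,
                            sigma_scale, theta, gls_se):
    """Optimum SEs from the observed information of the *full* likelihood.

    The GLS standard errors condition on the fitted alpha/sigma shape and
    therefore understate the optimum uncertainty; a central-difference
    Hessian over (shape params, log sigma-scale, thetas) restores the
    missing components.  Falls back to the GLS SEs when the Hessian is
    not positive definite at the optimum.
    """
    K = painting.k_regimes
    n = len(y)
    n_a, n_s, n_t = _model_structure(model, K)
    p0 = np.concatenate([x_shape, [np.log(sigma_scale)], theta])
    d_shape = len(x_shape)

    def nll(p):
        alphas, ratios = _expand_params(model, K, p[:d_shape])
        scale = np.exp(p[d_shape])
        th = p[d_shape + 1:]
        W, V = _ou_moments(tree, painting, alphas, scale * ratios, mrca)
        X = np.ones((n, 1)) if n_t == 1 else W
        try:
            L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        except np.linalg.LinAlgError:
            return np.inf
        e = solve_triangular(L, y - X @ th, lower=True)
        return 0.5 * (n * LOG2PI + 2.0 * np.sum(np.log(np.diag(L)))
                      + float(e @ e))

    d = len(p0)
    h = np.maximum(1e-4, 1e-4 * np.abs(p0))
    H = np.empty((d, d))
    f0 = nll(p0)
    if not np.isfinite(f0):
        return gls_se
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (nll(p0 + ei) - 2 * f0 + nll(p0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(p0 + ei + ej) - nll(p0 + ei - ej)
                    - nll(p0 - ei + ej) + nll(p0 - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return gls_se
    var_theta = np.diag(cov)[d_shape + 1:]
    if np.any(~np.isfinite(var_theta)) or np.any(var_theta <= 0):
        return gls_se
    return np.sqrt(var_theta)


def fit_ou(
    tree: Phylogeny,
    traits,
    painting: RegimePainting,
    model: str = "OUM",
    n_starts: int = 5,
) -> OURegimeFit:
    """ML fit of one model from the BM/OU family (univariate trait)."""
    y = align_traits(tree, traits)
    if y.shape[1] != 1:
        raise PhylogenyError("OU regime models are univariate; select one trait column")
    y = y[:, 0]
    if not tree.is_binary:
        raise PhylogenyError("resolve polytomies before likelihood work")
    K = painting.k_regimes
    mrca = mrca_matrix(tree)
    n_a, n_s, n_t = _model_structure(model, K)
    n_free = n_a + n_s
    k = n_a + (n_s + 1) + n_t     # alphas + sigma^2s + optima/root mean
    n = len(y)

    if n_free == 0:
        ll, packed = _profile_loglik(tree, painting, mrca, y, model, np.zeros(0))
        alphas, sig, theta, tse = packed
        return OURegimeFit(model, painting, alphas, sig, _pad(theta, K),
                           _pad(tse, K), ll, k, n)

    lo = np.full(n_free, -10.0)
    hi = np.full(n_free, 10.0)
    lo[:n_a], hi[:n_a] = LOG10_ALPHA_BOUNDS

    def nll(x):
        ll, _ = _profile_loglik(tree, painting, mrca, y, model, x)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    starts = list(ALPHA_STARTS[:max(n_starts, 1)])
    for a0 in starts:
        x0 = np.zeros(n_free)
        x0[:n_a] = a0
        res = minimize(nll, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if best is None or res.fun < best.fun:
            best = res
    ll, packed = _profile_loglik(tree, painting, mrca, y, model, best.x)
    alphas, sig, theta, tse = packed
    scale = sig[0]  # ratios are relative to regime 0
    tse = _observed_info_theta_se(tree, painting, mrca, y, model, best.x,
                                  scale, theta, tse)
    return OURegimeFit(model, painting, alphas, sig, _pad(theta, K), _pad(tse, K),
                       ll, k, n, converged=bool(best.success))


def _pad(v: np.ndarray, K: int) -> np.ndarray:
    v = np.atleast_1d(np.asarray(v, float))
    if len(v) == K:
        return v
    out = np.full(K, np.nan)
    out[: len(v)] = v
    return out


def compare_models(fits: list[OURegimeFit]) -> pd.DataFrame:
    """AICc comparison with Akaike weights (fits must share tree + data)."""
    if not fits:
        raise ValueError("no fits to compare")
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("fits come from different datasets; refusing to compare")
    a = np.array([f.aicc for f in fits])
    d = a - a.min()
    w = np.exp(-0.5 * d)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "loglik": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "AICc": a,
            "dAICc": d,
            "weight": w,
        }
    ).sort_values("AICc", ignore_index=True)


def simulate_ou(
    tree: Phylogeny,
    painting: RegimePainting,
    alpha,
    sigma2,
    theta,
    seed: int | None = None,
) -> np.ndarray:
    """Exact edge-by-edge OU simulation (the Monte-Carlo oracle for the
    analytic moments). Root starts at the root regime's optimum."""
    rng = np.random.default_rng(seed)
    alpha = np.asarray(alpha, float)
    sigma2 = np.asarray(sigma2, float)
    theta = np.asarray(theta, float)
    reg = painting.edge_regime
    x = np.zeros(tree.n_nodes)
    x[0] = theta[painting.root_regime]
    for i in range(1, tree.n_nodes):
        p = tree.parent[i]
        kk = reg[i]
        a, s2, th, t = alpha[kk], sigma2[kk], theta[kk], tree.edge_length[i]
        at = a * t
        decay = np.exp(-at)
        mean = x[p] * decay + th * (1.0 - decay)
        var = s2 * (1.0 - np.exp(-2 * at)) / (2 * a) if at > 1e-9 else s2 * t * (1 - at)
        x[i] = mean + np.sqrt(var) * rng.standard_normal()
    return x[tree.tips]
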