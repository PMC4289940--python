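"""Brownian motion vs directional (drift) evolution within a clade.

On a non-ultrametric tree the expected trait value under a directional
random walk grows linearly with root-to-tip duration, E[x_i] = mu0 +
mu * d_i, while the covariance stays the Brownian V.  Fossil tips at
different depths make mu identifiable; on an ultrametric tree the drift
is confounded with the root state and the fit is refused.

Model A fixes mu = 0 (plain BM); model B frees it.  Both are fitted by
GLS with the variance profiled (ML, divisor n) and compared by a
likelihood-ratio test on one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import chi2

from .bm import LOG2PI, align_traits, phylo_covariance
from .tree import Phylogeny, PhylogenyError

__all__ = ["TrendFit", "fit_trend"]


@dataclass
class TrendFit:
    mu0: float            # root state, log10 mm
    drift: float          # mu, log10 mm per Ma
    drift_se: float
    sigma2: float
    loglik_bm: float      # model A
    loglik_trend: float   # model B
    lrt: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "mu0": self.mu0, "drift": self.drift, "drift_se": self.drift_se,
            "sigma2": self.sigma2, "loglik_bm": self.loglik_bm,
            "loglik_trend": self.loglik_trend, "lrt": self.lrt,
            "df": self.df, "p_value": self.p_value,
        }


def _gls(L, X, y, n):
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    e = yw - Xw @ beta
    rss = float(e @ e)
    s = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * LOG2PI + n * np.log(s) + logdetV + n)
    cov = s * np.linalg.inv(Xw.T @ Xw)
    return beta, np.sqrt(np.diag(cov)), s, ll


def fit_trend(tree: Phylogeny, traits, rel_tol: float = 1e-6) -> TrendFit:
    """Likelihood-ratio test of directional evolution (univariate trait)."""
    y = align_traits(tree, traits)
    if y.shape[1] != 1:
        raise PhylogenyError("trend test is univariate; select one trait column")
    y = y[:, 0]
    n = len(y)
    if n < 4:
        raise PhylogenyError("trend test needs at least 4 tips")
    depths = tree.node_depths()[tree.tips]
    spread = (depths.max() - depths.min()) / max(depths.max(), 1e-300)
    if spread < rel_tol:
        raise PhylogenyError(
            "tree is ultrametric (all tips equally deep): the drift term is "
            "confounded with the root state, so the directional model is not "
            "identifiable; fossil (non-contemporaneous) tips are required"
        )
    V = phylo_covariance(tree)
    L = np.linalg.cholesky(V)
    ones = np.ones((n, 1))
    beta_a, _, _, ll_a = _gls(L, ones, y, n)
    X = np.column_stack([np.ones(n), depths])
    beta_b, se_b, s_b, ll_b = _gls(L, X, y, n)
    lrt = max(2.0 * (ll_b - ll_a), 0.0)
    return TrendFit(
        mu0=float(beta_b[0]),
        drift=float(beta_b[1]),
        drift_se=float(se_b[1]),
        sigma2=float(s_b),
        loglik_bm=float(ll_a),
        loglik_trend=float(ll_b),
        lrt=float(lrt),
        df=1,
        p_value=float(chi2.sf(lrt, 1)),
    )
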