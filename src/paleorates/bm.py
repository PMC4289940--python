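"""Brownian-motion likelihoods on time-scaled trees, with per-edge rate scalars.

Traits are log10 lengths (log10 mm); under Brownian motion (BM) each edge
contributes ``duration * r * sigma^2`` of variance, where ``r`` is a
dimensionless per-edge rate multiplier (1 everywhere for the homogeneous
model).  For ``m`` traits evolving with an m x m trait covariance-rate
matrix ``R``, tip data follow a matrix-normal distribution with row
covariance ``V`` (the phylogenetic covariance) and column covariance
``R``; rate scalars multiply ``R`` proportionally on the affected edges,
which is identical to inflating those edges' durations.

Two likelihood routes are provided and must agree to ~1e-8: Felsenstein's
pruning (contrasts) algorithm, and a dense GLS evaluation on the explicit
covariance matrix.  Both profile the root state (GLS mean) and use ML
variance estimates with divisor ``n`` so AICc comparisons across models
with different mean structures are coherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .tree import Phylogeny, PhylogenyError

__all__ = [
    "BMFit",
    "aicc",
    "phylo_covariance",
    "mrca_matrix",
    "bm_loglik",
    "scaled_loglik",
    "build_scaling",
    "read_traits_csv",
    "align_traits",
]

LOG2PI = float(np.log(2.0 * np.pi))


def aicc(loglik: float, k: int, n_obs: int) -> float:
    """Small-sample corrected AIC; requires ``n_obs > k + 1``."""
    if n_obs <= k + 1:
        raise ValueError(f"AICc undefined: n={n_obs} too small for k={k} parameters")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


@dataclass
class BMFit:
    """Maximum-likelihood BM fit.

    ``rate`` is sigma^2 ((log10 mm)^2/Ma) for one trait or the m x m
    covariance-rate matrix R; ``mu0`` the root state(s); ``k`` the
    parameter count (R entries + root states + any shift scalars, recorded
    so AICc values are auditable).
    """

    rate: np.ndarray
    mu0: np.ndarray
    loglik: float
    k: int
    n_obs: int

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n_obs)


def read_traits_csv(path, log10: bool = True) -> pd.DataFrame:
    """Trait table with a ``taxon`` column and raw lengths in mm.

    Returns a taxon-indexed frame, log10-transformed unless disabled.
    """
    df = pd.read_csv(path)
    if "taxon" not in df.columns:
        raise ValueError("trait table needs a 'taxon' column")
    df = df.set_index("taxon")
    num = df.select_dtypes("number")
    if log10:
        if (num <= 0).any().any():
            raise ValueError("raw lengths must be positive for log10 transform")
        num = np.log10(num)
    return num


def align_traits(tree: Phylogeny, traits: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Return an (n_tips, m) array in the tree's canonical tip order."""
    if isinstance(traits, pd.DataFrame):
        labels = tree.tip_label_list
        missing = set(labels) - set(traits.index)
        if missing:
            raise PhylogenyError(f"traits missing for taxa: {sorted(missing)[:5]}")
        Y = traits.loc[labels].to_numpy(dtype=float)
    else:
        Y = np.asarray(traits, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != tree.n_tips:
        raise PhylogenyError("trait rows do not match tree tips")
    if not np.all(np.isfinite(Y)):
        raise PhylogenyError("traits contain missing or non-finite values")
    return Y


# ---------------------------------------------------------------- covariance


def mrca_matrix(tree: Phylogeny) -> np.ndarray:
    """(n_tips, n_tips) matrix of MRCA node indices (diagonal = the tip)."""
    tips = tree.tips
    pos = {int(t): i for i, t in enumerate(tips)}
    n = len(tips)
    M = np.zeros((n, n), dtype=np.int64)
    for i, t in enumerate(tips):
        M[i, i] = t
    # postorder: tips in each child subtree, pairs across children meet here
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        kids = tree.children(node)
        if not kids:
            below[node] = [pos[node]]
            continue
        groups = [below.pop(c) for c in kids]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])
                ib = np.asarray(groups[b])
                M[np.ix_(ia, ib)] = node
                M[np.ix_(ib, ia)] = node
        below[node] = [x for g in groups for x in g]
    return M


def phylo_covariance(tree: Phylogeny, rates: np.ndarray | None = None) -> np.ndarray:
    """Phylogenetic covariance V: shared root-to-MRCA path length, with each
    edge contributing ``duration * r``. Excludes any root stem."""
    if not tree.has_lengths:
        raise PhylogenyError("tree has no branch lengths")
    r = np.ones(tree.n_nodes) if rates is None else np.asarray(rates, dtype=float)
    if np.any(r[1:] <= 0):
        raise PhylogenyError("rate multipliers must be > 0")
    depth = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        depth[i] = depth[tree.parent[i]] + tree.edge_length[i] * r[i]
    M = mrca_matrix(tree)
    return depth[M]


# ------------------------------------------------------------------ pruning


def _prune_quadratics(tree: Phylogeny, Y: np.ndarray, rates: np.ndarray | None):
    """Felsenstein pruning: returns (mu0, logdetV, Q) with
    Q = E' V^-1 E for E = Y - 1 mu0' and mu0 the GLS mean."""
    n, m = Y.shape
    r = np.ones(tree.n_nodes) if rates is None else rates
    val = np.zeros((tree.n_nodes, m))
    extra = np.zeros(tree.n_nodes)
    logdet = 0.0
    Q = np.zeros((m, m))
    tip_row = {int(t): i for i, t in enumerate(tree.tips)}
    for node in tree.postorder():
        kids = tree.children(node)
        if not kids:
            val[node] = Y[tip_row[node]]
            extra[node] = 0.0
            continue
        # combine children pairwise (exact for polytomies too)
        cv = val[kids[0]]
        ct = tree.edge_length[kids[0]] * r[kids[0]] + extra[kids[0]]
        for c in kids[1:]:
            t2 = tree.edge_length[c] * r[c] + extra[c]
            vsum = ct + t2
            if vsum <= 0:
                raise PhylogenyError(
                    f"singular covariance: zero-duration path at node {node}"
                )
            contrast = cv - val[c]
            Q += np.outer(contrast, contrast) / vsum
            logdet += np.log(vsum)
            cv = (cv * t2 + val[c] * ct) / vsum
            ct = ct * t2 / vsum
        val[node] = cv
        extra[node] = ct
    if extra[0] <= 0:
        raise PhylogenyError("singular covariance at the root")
    logdet += np.log(extra[0])
    return val[0].copy(), logdet, Q


def _gls_quadratics(V: np.ndarray, Y: np.ndarray):
    """Dense counterpart of :func:`_prune_quadratics` via Cholesky."""
    n = V.shape[0]
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise PhylogenyError(f"singular phylogenetic covariance: {exc}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Yt = solve_triangular(L, Y, lower=True)
    ones = solve_triangular(L, np.ones((n, 1)), lower=True)
    a = float((ones * ones).sum())
    b = (ones.T @ Yt).ravel()
    mu0 = b / a
    E = Yt - ones @ mu0[None, :]
    Q = E.T @ E
    return mu0, logdet, Q


def _loglik_from_quadratics(mu0, logdet, Q, n: int, m: int) -> tuple[float, np.ndarray]:
    R = Q / n
    sign, logdetR = np.linalg.slogdet(np.atleast_2d(R))
    if sign <= 0 or not np.isfinite(logdetR):
        raise PhylogenyError(
            "degenerate trait matrix: ML rate is singular "
            "(identical trait values or collinear traits)"
        )
    ll = -0.5 * (n * m * LOG2PI + m * logdet + n * logdetR + n * m)
    return float(ll), np.atleast_2d(R)


def bm_loglik(
    tree: Phylogeny,
    traits,
    rates: np.ndarray | None = None,
    method: str = "pruning",
    extra_k: int = 0,
) -> BMFit:
    """ML fit of (possibly rate-scaled) Brownian motion.

    ``method`` selects the pruning algorithm or the dense GLS route; the
    two agree to ~1e-8 and the dense route serves as an internal oracle.
    ``extra_k`` adds parameters (e.g. shift scalars) to the AICc count.
    """
    if not tree.is_binary:
        raise PhylogenyError(
            "tree has unresolved polytomies; resolve them before likelihood work"
        )
    bad = np.where(tree.edge_length[1:] <= 0)[0]
    if bad.size:
        raise PhylogenyError(
            f"zero-duration edge above node {int(bad[0]) + 1}: rescale the tree "
            "(or set a positive focal length) before likelihood work"
        )
    Y = align_traits(tree, traits)
    n, m = Y.shape
    if method == "pruning":
        mu0, logdet, Q = _prune_quadratics(tree, Y, rates)
    elif method == "gls":
        V = phylo_covariance(tree, rates)
        mu0, logdet, Q = _gls_quadratics(V, Y)
    else:
        raise ValueError(f"unknown method {method!r}")
    ll, R = _loglik_from_quadratics(mu0, logdet, Q, n, m)
    k = m * (m + 1) // 2 + m + extra_k
    return BMFit(rate=R if m > 1 else R.ravel(), mu0=mu0, loglik=ll, k=k, n_obs=n * m)


# ------------------------------------------------------------- shift scaling


def build_scaling(tree: Phylogeny, shifts) -> np.ndarray:
    """Per-edge rate multipliers from a list of shifts.

    Each shift is ``(node, kind, r)`` with kind ``"clade"`` (all subtree
    edges including the stem edge leading to the clade) or ``"branch"``
    (the stem edge only).  Where shifts overlap on an edge the innermost
    (smallest-subtree) shift wins; rates are assigned, not multiplied.
    """
    rates = np.ones(tree.n_nodes)
    order = sorted(
        shifts,
        key=lambda s: -len(tree.subtree_tips(int(s[0]))),
    )
    for node, kind, r in order:
        node = int(node)
        if node <= 0 or node >= tree.n_nodes:
            raise PhylogenyError(f"shift node {node} not found")
        if r <= 0:
            raise PhylogenyError("rate multiplier must be > 0")
        if kind == "branch":
            rates[node] = r
        elif kind == "clade":
            rates[tree.subtree_nodes(node)] = r
        else:
            raise ValueError(f"unknown shift kind {kind!r}")
    rates[0] = 1.0
    return rates


def scaled_loglik(tree: Phylogeny, traits, shifts, method: str = "pruning") -> BMFit:
    """BM likelihood under a set of rate shifts; one extra AICc parameter
    per shift (shift locations are not counted, following the stepwise
    search convention)."""
    rates = build_scaling(tree, shifts)
    return bm_loglik(tree, traits, rates, method=method, extra_k=len(list(shifts)))
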