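"""Stepwise rate-shift search (trait-MEDUSA, the "tm2" variant).

Starting from a homogeneous Brownian-motion model, the search iterates
over every eligible node, trying in turn a *clade* shift (one rate scalar
applied to every edge of the subtree, stem edge included) and a *branch*
shift (the scalar applied to the stem edge only).  The scalar that most
improves the likelihood is located by maximum likelihood jointly with the
background parameters; the best shift is accepted when it improves AICc
by at least a calibrated threshold, its location is frozen, and the
search continues up to ``max_shifts``.  Scalars of previously accepted
shifts are re-optimized jointly at each step (locations stay fixed).

Shift scalars add one parameter each to the AICc count; shift locations
are not counted.  Eligibility: internal, non-root nodes whose subtree has
at least ``min_clade`` tips (applied to both clade and branch candidates,
with a flag to lift it for branches).

Profile-likelihood confidence intervals use the chi-square(1)/2 rule:
scalar values where the profile log-likelihood drops 1.92 units below its
maximum; the upper limit is reported as unbounded when there is no finite
crossing below a cap (1e6).

The acceptance threshold itself is calibrated by simulation: traits are
simulated under constant-rate BM on the fitted tree many times, the best
single-shift model is fitted to each replicate, and the 95th percentile
of (AICc_BM - AICc_one_shift) becomes the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, solve_triangular
from scipy.optimize import brentq, minimize, minimize_scalar

from . import bm
from .bm import BMFit, aicc, align_traits, build_scaling
from .tree import Phylogeny, PhylogenyError

__all__ = [
    "Shift",
    "ShiftModel",
    "tm2_search",
    "fit_single_shift",
    "profile_ci",
    "calibrate_threshold",
]

LOG_R_MIN, LOG_R_MAX = np.log(1e-6), np.log(1e6)
PROFILE_DROP = 1.92  # chi-square(1)/2 at the 5% level


@dataclass
class Shift:
    node: int
    kind: str  # "clade" | "branch"
    rate: float
    ci_low: float | None = None
    ci_high: float | None = None  # None after profiling means unbounded


@dataclass
class ShiftModel:
    """Result of the stepwise search."""

    shifts: list[Shift]
    fit: BMFit                  # final model (k includes one scalar per shift)
    single_rate: BMFit          # homogeneous BM baseline
    trace: list[dict] = field(default_factory=list)
    threshold: float = 0.0

    @property
    def aicc(self) -> float:
        return self.fit.aicc

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "single_rate": {
                "loglik": self.single_rate.loglik,
                "k": self.single_rate.k,
                "aicc": self.single_rate.aicc,
            },
            "model": {
                "loglik": self.fit.loglik,
                "k": self.fit.k,
                "aicc": self.fit.aicc,
            },
            "shifts": [
                {
                    "node": s.node,
                    "type": s.kind,
                    "rate": s.rate,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                }
                for s in self.shifts
            ],
            "trace": self.trace,
        }


# ------------------------------------------------------------------ internals


def _candidates(tree: Phylogeny, min_clade: int, min_clade_branch: bool) -> list[tuple[int, str]]:
    out = []
    for node in range(1, tree.n_nodes):
        if not tree.children(node):
            continue
        ntips = len(tree.subtree_tips(node))
        if ntips >= min_clade:
            out.append((node, "clade"))
        if ntips >= (min_clade if min_clade_branch else 2):
            out.append((node, "branch"))
    return out


def _shift_edges(tree: Phylogeny, node: int, kind: str) -> np.ndarray:
    if kind == "branch":
        return np.array([node], dtype=np.int64)
    return tree.subtree_nodes(node)


def _owned_edges(tree: Phylogeny, node: int, kind: str, prev: list[Shift]) -> np.ndarray:
    """Edges the candidate shift would actually control under the
    innermost-wins assignment rule, given previously fixed shifts."""
    edges = set(int(e) for e in _shift_edges(tree, node, kind))
    my_size = len(tree.subtree_tips(node)) if kind == "clade" else 0
    for s in prev:
        s_edges = set(int(e) for e in _shift_edges(tree, s.node, s.kind))
        s_size = len(tree.subtree_tips(s.node)) if s.kind == "clade" else 0
        if s_size < my_size or (s_size == my_size and s.kind == "branch"):
            edges -= s_edges  # the previous shift is innermost there
    return np.array(sorted(edges), dtype=np.int64)


class _Scan:
    """Shared state for scanning single-shift candidates on fixed data.

    Whitens the data by the Cholesky factor of the base covariance once;
    each candidate's shift-contribution matrix is then eigendecomposed in
    the whitened metric, after which every likelihood evaluation during
    the scalar optimization is O(n).
    """

    def __init__(
        self,
        tree: Phylogeny,
        Y: np.ndarray,
        base_rates: np.ndarray | None = None,
        mrca: np.ndarray | None = None,
    ):
        if not tree.is_binary:
            raise PhylogenyError(
                "tree has unresolved polytomies; resolve them before likelihood work"
            )
        self.tree = tree
        self.Y = Y
        self.n, self.m = Y.shape
        self.base_rates = (
            np.ones(tree.n_nodes) if base_rates is None else np.asarray(base_rates, float)
        )
        self.M = bm.mrca_matrix(tree) if mrca is None else mrca
        self.V_base = self._cov(self.base_rates)
        self.L = np.linalg.cholesky(self.V_base)
        self.logdet_base = 2.0 * float(np.sum(np.log(np.diag(self.L))))
        self.Zy = solve_triangular(self.L, Y, lower=True)
        self.z1 = solve_triangular(self.L, np.ones(self.n), lower=True)

    def _cov(self, rates: np.ndarray) -> np.ndarray:
        tree = self.tree
        depth = np.zeros(tree.n_nodes)
        for i in range(1, tree.n_nodes):
            depth[i] = depth[tree.parent[i]] + tree.edge_length[i] * rates[i]
        return depth[self.M]

    def _contribution(self, edges: np.ndarray) -> np.ndarray:
        """Unit-rate covariance contribution of an edge set."""
        tree = self.tree
        ind = np.zeros(tree.n_nodes)
        ind[edges] = 1.0
        depth = np.zeros(tree.n_nodes)
        for i in range(1, tree.n_nodes):
            depth[i] = depth[tree.parent[i]] + tree.edge_length[i] * ind[i]
        return depth[self.M]

    def _loglik_eig(self, d, t1, Ty):
        a = float(np.sum(t1 * t1 / d))
        b = (t1 / d) @ Ty
        Q = Ty.T @ (Ty / d[:, None]) - np.outer(b, b) / a
        logdet = self.logdet_base + float(np.sum(np.log(d)))
        mu0 = b / a
        return bm._loglik_from_quadratics(mu0, logdet, Q, self.n, self.m)

    def optimize_candidate(self, edges: np.ndarray) -> tuple[float, float]:
        """Return (r_hat, loglik) maximizing the likelihood over the shift
        scalar for the given edge set, other rates held at base values.
        Requires base rate to be uniform across ``edges``."""
        c = float(self.base_rates[edges[0]])
        B = self._contribution(edges)
        X = solve_triangular(self.L, B, lower=True)
        Msym = solve_triangular(self.L, X.T, lower=True).T
        Msym = 0.5 * (Msym + Msym.T)
        w, U = eigh(Msym)
        w = np.clip(w, 0.0, None)
        t1 = U.T @ self.z1
        Ty = U.T @ self.Zy

        def nll(logr: float) -> float:
            r = np.exp(logr)
            d = 1.0 + (r - c) * w
            if np.min(d) <= 1e-12:
                return np.inf
            try:
                ll, _ = self._loglik_eig(d, t1, Ty)
            except PhylogenyError:
                return np.inf
            return -ll

        grid = np.linspace(LOG_R_MIN, LOG_R_MAX, 49)
        vals = np.array([nll(g) for g in grid])
        i0 = int(np.argmin(vals))
        lo = grid[max(i0 - 1, 0)]
        hi = grid[min(i0 + 1, len(grid) - 1)]
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        best_log = res.x if res.fun <= vals[i0] else grid[i0]
        return float(np.exp(best_log)), float(-nll(best_log))

    def loglik_at(self, rates: np.ndarray) -> tuple[float, BMFit]:
        """Dense likelihood for an arbitrary full rate vector."""
        V = self._cov(rates)
        mu0, logdet, Q = bm._gls_quadratics(V, self.Y)
        ll, R = bm._loglik_from_quadratics(mu0, logdet, Q, self.n, self.m)
        return ll, (mu0, R)


def _uniform_base(scan: _Scan, edges: np.ndarray) -> bool:
    return bool(np.all(scan.base_rates[edges] == scan.base_rates[edges[0]]))


def _dense_optimize(scan: _Scan, prev: list[Shift], node: int, kind: str) -> tuple[float, float]:
    def nll(logr: float) -> float:
        shifts = [(s.node, s.kind, s.rate) for s in prev] + [(node, kind, np.exp(logr))]
        rates = build_scaling(scan.tree, shifts)
        try:
            return -scan.loglik_at(rates)[0]
        except (PhylogenyError, np.linalg.LinAlgError):
            return np.inf

    grid = np.linspace(LOG_R_MIN, LOG_R_MAX, 25)
    vals = np.array([nll(g) for g in grid])
    i0 = int(np.argmin(vals))
    res = minimize_scalar(
        nll, bounds=(grid[max(i0 - 1, 0)], grid[min(i0 + 1, len(grid) - 1)]),
        method="bounded", options={"xatol": 1e-8},
    )
    best = res.x if res.fun <= vals[i0] else grid[i0]
    return float(np.exp(best)), float(-nll(best))


def _scan_step(
    scan: _Scan,
    prev: list[Shift],
    candidates: list[tuple[int, str]],
) -> tuple[int, str, float, float] | None:
    """Best (node, kind, rate, loglik) over all candidates at this step."""
    best = None
    depth_of = scan.tree.depth_in_edges
    for node, kind in candidates:
        if any(s.node == node and s.kind == kind for s in prev):
            continue
        edges = _owned_edges(scan.tree, node, kind, prev)
        if len(edges) == 0:
            continue
        if _uniform_base(scan, edges):
            r, ll = scan.optimize_candidate(edges)
        else:
            r, ll = _dense_optimize(scan, prev, node, kind)
        if not np.isfinite(ll):
            continue
        key = (ll, -depth_of(node), -node)  # ties: rootward first, then low id
        if best is None or key > best[0]:
            best = (key, node, kind, r, ll)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def _joint_reoptimize(scan: _Scan, shifts: list[Shift]) -> tuple[list[Shift], float]:
    """Re-optimize all shift scalars jointly (locations fixed)."""
    if len(shifts) == 1:
        rates = build_scaling(scan.tree, [(shifts[0].node, shifts[0].kind, shifts[0].rate)])
        return shifts, scan.loglik_at(rates)[0]

    x0 = np.log([s.rate for s in shifts])

    def nll(x: np.ndarray) -> float:
        spec = [(s.node, s.kind, float(np.exp(xi))) for s, xi in zip(shifts, x)]
        try:
            return -scan.loglik_at(build_scaling(scan.tree, spec))[0]
        except (PhylogenyError, np.linalg.LinAlgError):
            return np.inf

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400 * len(shifts)})
    x = res.x if res.fun <= nll(x0) else x0
    out = [
        Shift(s.node, s.kind, float(np.exp(xi))) for s, xi in zip(shifts, x)
    ]
    return out, float(-nll(x))


class SingleShiftScanner:
    """Repeated single-shift fits on one tree (simulation studies).

    The whitening Cholesky and every candidate's eigendecomposition depend
    only on the tree, so they are computed once; per trait replicate only
    the O(n^2) data transform and an O(n)-per-evaluation scalar
    optimization remain.
    """

    def __init__(
        self,
        tree: Phylogeny,
        min_clade: int = 5,
        min_clade_branch: bool = True,
    ):
        if not tree.is_binary:
            raise PhylogenyError(
                "tree has unresolved polytomies; resolve them before likelihood work"
            )
        self.tree = tree
        self.n = tree.n_tips
        self.M = bm.mrca_matrix(tree)
        scan = _Scan(tree, np.zeros((self.n, 1)), mrca=self.M)
        self.logdet_base = scan.logdet_base
        Linv = solve_triangular(scan.L, np.eye(self.n), lower=True)
        self.z1w = Linv @ np.ones(self.n)
        self.candidates = []
        self._depth = {}
        for node, kind in _candidates(tree, min_clade, min_clade_branch):
            B = scan._contribution(_shift_edges(tree, node, kind))
            Msym = Linv @ B @ Linv.T
            w, U = eigh(0.5 * (Msym + Msym.T))
            w = np.clip(w, 0.0, None)
            P = U.T @ Linv
            self.candidates.append((node, kind, w, P @ np.ones(self.n), P))
            self._depth[(node, kind)] = tree.depth_in_edges(node)

    def best_single_shift(self, Y: np.ndarray) -> tuple[float, Shift, float]:
        """Return (bm_loglik, best Shift, one-shift loglik) for traits Y."""
        Y = np.atleast_2d(np.asarray(Y, float).T).T
        n, m = Y.shape
        best = None
        ll0 = None
        for node, kind, w, t1, P in self.candidates:
            Ty = P @ Y

            def nll(logr: float) -> float:
                d = 1.0 + (np.exp(logr) - 1.0) * w
                if np.min(d) <= 1e-12:
                    return np.inf
                a = float(np.sum(t1 * t1 / d))
                b = (t1 / d) @ Ty
                Q = Ty.T @ (Ty / d[:, None]) - np.outer(b, b) / a
                logdet = self.logdet_base + float(np.sum(np.log(d)))
                try:
                    ll, _ = bm._loglik_from_quadratics(b / a, logdet, Q, n, m)
                except PhylogenyError:
                    return np.inf
                return -ll

            if ll0 is None:
                ll0 = -nll(0.0)
            grid = np.linspace(LOG_R_MIN, LOG_R_MAX, 33)
            vals = np.array([nll(g) for g in grid])
            i0 = int(np.argmin(vals))
            res = minimize_scalar(
                nll, bounds=(grid[max(i0 - 1, 0)], grid[min(i0 + 1, len(grid) - 1)]),
                method="bounded", options={"xatol": 1e-7},
            )
            x, fx = (res.x, res.fun) if res.fun <= vals[i0] else (grid[i0], vals[i0])
            key = (-fx, -self._depth[(node, kind)], -node)
            if best is None or key > best[0]:
                best = (key, node, kind, float(np.exp(x)), float(-fx))
        _, node, kind, r, ll1 = best
        return float(ll0), Shift(node, kind, r), ll1


# ------------------------------------------------------------------ frontend


def fit_single_shift(
    tree: Phylogeny,
    traits,
    min_clade: int = 5,
    min_clade_branch: bool = True,
) -> tuple[BMFit, Shift | None, float]:
    """Homogeneous BM fit plus the best single-shift model.

    Returns ``(bm_fit, best_shift, one_shift_aicc)``; the shift is None
    only when no candidate exists.  Used by threshold calibration and the
    bias/power simulation studies.
    """
    Y = align_traits(tree, traits)
    scan = _Scan(tree, Y)
    n, m = Y.shape
    base_k = m * (m + 1) // 2 + m
    ll0, _ = scan.loglik_at(np.ones(tree.n_nodes))
    fit0 = bm.bm_loglik(tree, Y, method="gls")
    best = _scan_step(scan, [], _candidates(tree, min_clade, min_clade_branch))
    if best is None:
        return fit0, None, np.inf
    node, kind, r, ll = best
    a1 = aicc(ll, base_k + 1, n * m)
    return fit0, Shift(node, kind, r), a1


def tm2_search(
    tree: Phylogeny,
    traits,
    max_shifts: int = 5,
    min_clade: int = 5,
    threshold: float = 9.22,
    min_clade_branch: bool = True,
    compute_ci: bool = True,
) -> ShiftModel:
    """Greedy forward search for rate shifts under the AICc threshold.

    The trace records the best candidate at every step, including the
    final sub-threshold one, so shifts detectable at lower cutoffs remain
    inspectable.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    Y = align_traits(tree, traits)
    n, m = Y.shape
    base_k = m * (m + 1) // 2 + m
    M = bm.mrca_matrix(tree)
    scan = _Scan(tree, Y, mrca=M)
    single = bm.bm_loglik(tree, Y, method="gls")
    candidates = _candidates(tree, min_clade, min_clade_branch)

    shifts: list[Shift] = []
    current_aicc = single.aicc
    current_ll = single.loglik
    trace: list[dict] = [
        {"step": 0, "model": "BM", "loglik": single.loglik, "k": single.k,
         "aicc": single.aicc, "accepted": True}
    ]
    while len(shifts) < max_shifts:
        if shifts:
            # the candidate scan whitens against the current model, so the
            # base covariance must carry the already-accepted shifts
            base = build_scaling(tree, [(s.node, s.kind, s.rate) for s in shifts])
            scan = _Scan(tree, Y, base_rates=base, mrca=M)
        best = _scan_step(scan, shifts, candidates)
        if best is None:
            break
        node, kind, r, _ = best
        trial = shifts + [Shift(node, kind, r)]
        trial, ll = _joint_reoptimize(scan, trial)
        k = base_k + len(trial)
        a = aicc(ll, k, n * m)
        delta = current_aicc - a
        accepted = delta >= threshold
        trace.append(
            {"step": len(shifts) + 1, "node": int(node), "type": kind,
             "rate": float(trial[-1].rate), "loglik": float(ll), "k": k,
             "aicc": float(a), "delta_aicc": float(delta), "accepted": bool(accepted)}
        )
        if not accepted:
            break
        shifts = trial
        current_aicc, current_ll = a, ll

    rates = build_scaling(scan.tree, [(s.node, s.kind, s.rate) for s in shifts])
    final = bm.bm_loglik(tree, Y, rates, method="gls", extra_k=len(shifts))
    model = ShiftModel(shifts=shifts, fit=final, single_rate=single,
                       trace=trace, threshold=threshold)
    if compute_ci:
        for i in range(len(shifts)):
            lo, hi = profile_ci(tree, Y, model, i)
            shifts[i].ci_low, shifts[i].ci_high = lo, hi
    return model


def profile_ci(
    tree: Phylogeny,
    traits,
    model: ShiftModel,
    which: int,
    drop: float = PROFILE_DROP,
    cap: float = 1e6,
) -> tuple[float | None, float | None]:
    """Profile-likelihood CI for one shift scalar.

    Other shift scalars are re-optimized at each profiled value.  Returns
    ``(lower, upper)``; ``None`` for a bound means no crossing inside
    ``[1e-6, cap]`` (reported as unbounded).
    """
    Y = align_traits(tree, traits)
    scan = _Scan(tree, Y)
    shifts = model.shifts
    r_ml = shifts[which].rate

    others = [s for i, s in enumerate(shifts) if i != which]

    def pll(logr: float) -> float:
        fixed = Shift(shifts[which].node, shifts[which].kind, float(np.exp(logr)))
        if not others:
            spec = [(fixed.node, fixed.kind, fixed.rate)]
            return scan.loglik_at(build_scaling(tree, spec))[0]
        x0 = np.log([s.rate for s in others])

        def nll(x):
            spec = [(fixed.node, fixed.kind, fixed.rate)] + [
                (s.node, s.kind, float(np.exp(xi))) for s, xi in zip(others, x)
            ]
            try:
                return -scan.loglik_at(build_scaling(tree, spec))[0]
            except (PhylogenyError, np.linalg.LinAlgError):
                return np.inf

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8})
        return float(-min(res.fun, nll(x0)))

    ll_max = pll(np.log(r_ml))
    target = ll_max - drop

    def crossing(side: int) -> float | None:
        # side=-1: search below r_ml; side=+1: above
        limit = np.log(1e-6) if side < 0 else np.log(cap)
        grid = np.linspace(np.log(r_ml), limit, 40)[1:]
        prev = np.log(r_ml)
        for g in grid:
            if pll(g) < target:
                try:
                    return float(np.exp(brentq(lambda x: pll(x) - target, prev, g,
                                               xtol=1e-10)))
                except ValueError:
                    warnings.warn("non-monotone likelihood profile; widening bracket")
                    return float(np.exp(g))
            prev = g
        return None

    return crossing(-1), crossing(+1)


def calibrate_threshold(
    tree: Phylogeny,
    n_sims: int = 1000,
    q: float = 0.95,
    seed: int | None = None,
    m: int = 1,
    min_clade: int = 5,
    min_clade_branch: bool = True,
) -> float:
    """Simulation-calibrated AICc cutoff for accepting one extra shift.

    Simulates constant-rate BM traits on the tree ``n_sims`` times, fits
    the best single-shift model to each, and returns the ``q`` quantile of
    (AICc of BM) - (AICc of the one-shift model).
    """
    from .simulate import simulate_bm  # deferred: simulate also uses this module

    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} is small; the quantile will be noisy")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    base_k = m * (m + 1) // 2 + m
    scanner = SingleShiftScanner(tree, min_clade, min_clade_branch)
    deltas = np.empty(n_sims)
    R = np.eye(m)
    for i in range(n_sims):
        Y = simulate_bm(tree, R, seed=int(rng.integers(2**31 - 1)))
        ll0, _, ll1 = scanner.best_single_shift(Y)
        a0 = aicc(ll0, base_k, n * m)
        a1 = aicc(ll1, base_k + 1, n * m)
        deltas[i] = a0 - a1
    return float(np.quantile(deltas, q))
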