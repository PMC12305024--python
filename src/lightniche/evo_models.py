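"""Single- and multipeak trait-evolution models on regime-painted phylogenies.

Implements the Mk (equal-rates) model with Felsenstein pruning, stochastic
character mapping of discrete regimes, Gaussian likelihoods for BM1 / BMM /
OU1 / OUM / EB, maximum-likelihood fitting with analytic profiling of the
linear parameters, and AICc comparison across an ensemble of sampled maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .phylo_stats import aicc
from .trees import Phylogeny

log = logging.getLogger(__name__)

MODELS = ("BM1", "BMM", "OU1", "OUM", "EB")


class EvoModelError(RuntimeError):
    pass


# -- regime maps ----------------------------------------------------------


@dataclass
class RegimeMap:
    """Piecewise-constant regime history along every branch of a tree.

    ``histories[node]`` lists (duration, regime) segments for the edge above
    ``node``, ordered from the rootward end to the tipward end.
    """

    tree: Phylogeny
    histories: dict[int, list[tuple[float, str]]]
    root_regime: str
    regimes: tuple[str, ...]

    def __post_init__(self):
        for v in range(self.tree.n_nodes):
            if v == self.tree.root:
                continue
            segs = self.histories.get(v)
            if not segs:
                raise EvoModelError(f"edge above node {v} has no history")
            total = sum(d for d, _ in segs)
            if abs(total - self.tree.edge_len[v]) > 1e-9 * max(1.0, self.tree.edge_len[v]):
                raise EvoModelError(f"segments on edge {v} do not sum to branch length")
            if any(d <= 0 for d, _ in segs):
                raise EvoModelError(f"non-positive segment duration on edge {v}")
            for (_, a), (_, b) in zip(segs, segs[1:]):
                if a == b:
                    raise EvoModelError(f"adjacent equal regimes on edge {v}")

    def tip_regimes(self) -> dict[str, str]:
        out = {}
        for tip in self.tree.tips:
            if tip == self.tree.root:
                out[self.tree.labels[tip]] = self.root_regime
            else:
                out[self.tree.labels[tip]] = self.histories[tip][-1][1]
        return out

    def node_entry_regime(self, v: int) -> str:
        """Regime at the rootward end of the edge above ``v``."""
        return self.root_regime if v == self.tree.root else self.histories[v][0][1]

    def regime_times_to_nodes(self) -> dict[int, dict[str, float]]:
        """Per-node accumulated time spent in each regime from the root."""
        prof: dict[int, dict[str, float]] = {self.tree.root: {}}
        for v in self.tree.preorder():
            if v == self.tree.root:
                continue
            acc = dict(prof[self.tree.parent[v]])
            for d, reg in self.histories[v]:
                acc[reg] = acc.get(reg, 0.0) + d
            prof[v] = acc
        return prof

    def regime_share_matrices(self) -> dict[str, np.ndarray]:
        """Per-regime tip x tip matrices of shared-path time in that regime.

        Entry (i, j) is the time spent in the regime on the root-to-MRCA(i,j)
        path (root-to-tip path on the diagonal) — the building blocks of the
        multirate BM covariance.
        """
        if not hasattr(self, "_share_cache"):
            tree = self.tree
            prof = self.regime_times_to_nodes()
            mrca = tree.mrca_nodes()
            n = tree.n_tips
            mats = {r: np.zeros((n, n)) for r in self.regimes}
            for a in range(n):
                for b in range(a, n):
                    node = mrca[a, b] if a != b else tree.tips[a]
                    for reg, t in prof[node].items():
                        mats[reg][a, b] = mats[reg][b, a] = t
            self._share_cache = mats
        return self._share_cache

    def path_segments(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per tip (tree tip order): (t_start, t_end, regime index) arrays for
        every segment on the root-to-tip path, in absolute time from the root."""
        if not hasattr(self, "_path_cache"):
            tree = self.tree
            times = tree.node_times()
            ridx = {r: i for i, r in enumerate(self.regimes)}
            out = []
            for tip in tree.tips:
                t0s, t1s, regs = [], [], []
                v = tip
                while v != tree.root:
                    cursor = times[tree.parent[v]]
                    for d, reg in self.histories[v]:
                        t0s.append(cursor)
                        t1s.append(cursor + d)
                        regs.append(ridx[reg])
                        cursor += d
                    v = tree.parent[v]
                out.append((np.asarray(t0s), np.asarray(t1s), np.asarray(regs, dtype=int)))
            self._path_cache = out
        return self._path_cache


def single_regime_map(tree: Phylogeny, regime: str = "0") -> RegimeMap:
    hist = {
        v: [(float(tree.edge_len[v]), regime)]
        for v in range(tree.n_nodes)
        if v != tree.root and tree.edge_len[v] > 0
    }
    # zero-length edges get a degenerate entry skipped by validation
    for v in range(tree.n_nodes):
        if v != tree.root and tree.edge_len[v] == 0:
            hist[v] = [(1e-300, regime)]
    return RegimeMap(tree, hist, regime, (regime,))


def map_from_tip_clusters(tree: Phylogeny, tip_states: dict[str, str]) -> RegimeMap:
    """Deterministic painting: each edge wears its tipward clade's majority state.

    Only used as a fallback/diagnostic; SIMMAP sampling is the analysis route.
    """
    states = sorted(set(tip_states.values()))
    down: dict[int, str] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            down[v] = tip_states[tree.labels[v]]
        else:
            votes = [down[c] for c in tree.children[v]]
            down[v] = max(states, key=votes.count)
    hist = {
        v: [(max(float(tree.edge_len[v]), 1e-300), down[v])]
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    return RegimeMap(tree, hist, down[tree.root], tuple(states))


# -- Mk model and stochastic mapping --------------------------------------


def _er_transition(q: float, t: float, k: int) -> np.ndarray:
    """Equal-rates transition matrix: P = 1/k + (I - 1/k) exp(-k q t)."""
    e = np.exp(-k * q * t)
    return np.full((k, k), (1.0 - e) / k) + np.eye(k) * e


@dataclass
class MkFit:
    q: float
    loglik: float
    states: tuple[str, ...]
    cond_lik: dict[int, np.ndarray]  # scaled partial likelihoods per node
    tree: Phylogeny
    tip_states: dict[str, str]


def _mk_partials(
    tree: Phylogeny, tip_states: dict[str, str], states: list[str], q: float
) -> tuple[dict[int, np.ndarray], float]:
    """Scaled pruning partial likelihoods and total log-likelihood (uniform root)."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    L: dict[int, np.ndarray] = {}
    logscale = 0.0
    for v in tree.postorder():
        if not tree.children[v]:
            vec = np.zeros(k)
            vec[sidx[tip_states[tree.labels[v]]]] = 1.0
        else:
            vec = np.ones(k)
            for c in tree.children[v]:
                P = _er_transition(q, float(tree.edge_len[c]), k)
                vec = vec * (P @ L[c])
            m = vec.max()
            if m <= 0:
                return L, -np.inf
            vec = vec / m
            logscale += np.log(m)
        L[v] = vec
    loglik = logscale + np.log(L[tree.root].mean())
    return L, float(loglik)


def fit_mk(tree: Phylogeny, tip_states: dict[str, str]) -> MkFit:
    """ML equal-rates transition rate via pruning; uniform root prior."""
    missing = sorted(set(tree.tip_labels) - set(tip_states))
    if missing:
        raise EvoModelError(f"tips without a state: {missing}")
    states = sorted(set(tip_states[lb] for lb in tree.tip_labels))
    T = tree.depth
    if len(states) < 2:
        warnings.warn("single observed state: Mk rate collapses to 0")
        q = 1e-8 / T
        L, ll = _mk_partials(tree, tip_states, states, q)
        return MkFit(q, ll, tuple(states), L, tree, dict(tip_states))

    def nll(logq: float) -> float:
        _, ll = _mk_partials(tree, tip_states, states, np.exp(logq))
        return -ll

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(1e-8 / T), np.log(1e3 / T)), method="bounded"
    )
    q = float(np.exp(res.x))
    L, ll = _mk_partials(tree, tip_states, states, q)
    return MkFit(q, ll, tuple(states), L, tree, dict(tip_states))


def mk_node_marginals(fit: MkFit) -> dict[int, np.ndarray]:
    """Marginal posterior state probabilities per node (re-rooting free form).

    Computed with downward partials and upward ("outside") messages under the
    uniform root prior — the analytic counterpart the SIMMAP sampler is
    checked against.
    """
    tree, q, states = fit.tree, fit.q, list(fit.states)
    k = len(states)
    up: dict[int, np.ndarray] = {tree.root: np.full(k, 1.0 / k)}
    for v in tree.preorder():
        for c in tree.children[v]:
            sib = np.ones(k)
            for c2 in tree.children[v]:
                if c2 != c:
                    P2 = _er_transition(q, float(tree.edge_len[c2]), k)
                    sib = sib * (P2 @ fit.cond_lik[c2])
            msg = up[v] * sib
            P = _er_transition(q, float(tree.edge_len[c]), k)
            out = P.T @ msg
            s = out.sum()
            up[c] = out / s if s > 0 else np.full(k, 1.0 / k)
    marg = {}
    for v in range(tree.n_nodes):
        m = up[v] * fit.cond_lik[v]
        marg[v] = m / m.sum()
    return marg


def _sample_branch_history(
    rng: np.random.Generator,
    i: int,
    j: int,
    t: float,
    q: float,
    k: int,
    max_reject: int = 10_000,
) -> list[tuple[float, int]]:
    """CTMC path from state i to j over duration t, conditional on endpoints.

    Rejection sampling of forward paths, with a uniformization fallback.
    Returns (duration, state) segments (adjacent states distinct).
    """
    rate = (k - 1) * q
    if t <= 0:
        return [(max(t, 1e-300), j)]
    for _ in range(max_reject):
        jumps = []
        clock = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        state = i
        while clock < t:
            others = [s for s in range(k) if s != state]
            state = int(rng.choice(others))
            jumps.append((clock, state))
            clock += rng.exponential(1.0 / rate)
        if state == j:
            return _jumps_to_segments(i, jumps, t)
    return _uniformized_history(rng, i, j, t, q, k)


def _jumps_to_segments(start: int, jumps: list[tuple[float, int]], t: float):
    segs = []
    prev_time, prev_state = 0.0, start
    for tm, st in jumps:
        if tm > prev_time:
            segs.append((tm - prev_time, prev_state))
        prev_time, prev_state = tm, st
    segs.append((t - prev_time, prev_state))
    # merge zero-length or repeated-state artifacts
    merged: list[tuple[float, int]] = []
    for d, s in segs:
        if d <= 0:
            continue
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0] + d, s)
        else:
            merged.append((d, s))
    return merged or [(t, start)]


def _uniformized_history(rng, i: int, j: int, t: float, q: float, k: int):
    """Endpoint-conditioned path via uniformization (ER: R has zero diagonal)."""
    mu = (k - 1) * q
    R = (np.ones((k, k)) - np.eye(k)) / (k - 1)
    p_ij = _er_transition(q, t, k)[i, j]
    if p_ij <= 0:
        raise EvoModelError("zero-probability endpoint pair in uniformization")
    nmax = 200
    Rpow = [np.eye(k)]
    for _ in range(nmax):
        Rpow.append(Rpow[-1] @ R)
    logpois = -mu * t + np.arange(nmax + 1) * np.log(max(mu * t, 1e-300)) - np.array(
        [sum(np.log(m) for m in range(1, n + 1)) for n in range(nmax + 1)]
    )
    weights = np.exp(logpois) * np.array([Rpow[n][i, j] for n in range(nmax + 1)])
    wsum = weights.sum()
    if wsum <= 0:
        raise EvoModelError("uniformization failed: no admissible jump count")
    n = int(rng.choice(nmax + 1, p=weights / wsum))
    times = np.sort(rng.uniform(0.0, t, size=n))
    jumps, state = [], i
    for m, tm in enumerate(times):
        rem = n - m - 1
        probs = R[state] * Rpow[rem][:, j]
        probs = probs / probs.sum()
        state = int(rng.choice(k, p=probs))
        jumps.append((float(tm), state))
    return _jumps_to_segments(i, jumps, t)


def sample_simmap(
    tree: Phylogeny,
    tip_states: dict[str, str],
    q: float | None = None,
    n_maps: int = 500,
    seed: int | None = None,
    mk: MkFit | None = None,
) -> list[RegimeMap]:
    """Stochastic character maps conditional on tip states under the ER model.

    Node states are drawn by stochastic traceback from the pruning partials;
    branch histories are endpoint-conditioned CTMC paths.
    """
    if mk is None:
        mk = fit_mk(tree, tip_states)
    if q is None:
        q = mk.q
    states = list(mk.states)
    k = len(states)
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_maps):
        node_state: dict[int, int] = {}
        root_p = mk.cond_lik[tree.root].copy()
        root_p /= root_p.sum()
        node_state[tree.root] = int(rng.choice(k, p=root_p))
        hist: dict[int, list[tuple[float, str]]] = {}
        for v in tree.preorder():
            for c in tree.children[v]:
                t = float(tree.edge_len[c])
                P = _er_transition(q, t, k)
                pvec = P[node_state[v]] * mk.cond_lik[c]
                pvec = pvec / pvec.sum()
                sc = int(rng.choice(k, p=pvec))
                node_state[c] = sc
                segs = _sample_branch_history(rng, node_state[v], sc, t, q, k)
                hist[c] = [(d, states[s]) for d, s in segs]
        maps.append(RegimeMap(tree, hist, states[node_state[tree.root]], tuple(states)))
    return maps


# -- Gaussian likelihoods --------------------------------------------------


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    n = len(y)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise EvoModelError("non-positive-definite trait covariance") from exc
    r = np.linalg.solve(L, y - mean)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ r))


def _trait_vector(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        return trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    if isinstance(trait, dict):
        return np.array([trait[lb] for lb in tree.tip_labels], dtype=float)
    y = np.asarray(trait, dtype=float)
    if len(y) != tree.n_tips:
        raise EvoModelError("trait length does not match tip count")
    return y


def bm_loglik(tree: Phylogeny, trait, sigma2: float, root_state: float) -> float:
    """BM1: cov = sigma2 * shared path time, mean = root state."""
    y = _trait_vector(tree, trait)
    cov = sigma2 * tree.mrca_times()
    return _mvn_loglik(y, np.full(len(y), root_state), cov)


def _bmm_cov(rmap: RegimeMap, sigma2: dict[str, float]) -> np.ndarray:
    mats = rmap.regime_share_matrices()
    return sum(sigma2[r] * A for r, A in mats.items())


def bmm_loglik(rmap: RegimeMap, trait, sigma2: dict[str, float], root_state: float) -> float:
    """Multirate BM: cov accumulates regime-specific sigma2 over shared paths."""
    y = _trait_vector(rmap.tree, trait)
    cov = _bmm_cov(rmap, sigma2)
    return _mvn_loglik(y, np.full(len(y), root_state), cov)


def _eb_cov(tree: Phylogeny, sigma2_0: float, r: float) -> np.ndarray:
    M = tree.mrca_times()
    if abs(r) < 1e-12:
        return sigma2_0 * M
    return sigma2_0 * np.expm1(r * M) / r


def eb_loglik(tree: Phylogeny, trait, sigma2_0: float, r: float, root_state: float) -> float:
    """Early burst: BM with exponentially time-varying rate sigma2_0 * e^(r t)."""
    y = _trait_vector(tree, trait)
    return _mvn_loglik(y, np.full(len(y), root_state), _eb_cov(tree, sigma2_0, r))


def _ou_corr(tree: Phylogeny, alpha: float) -> np.ndarray:
    """OU tip covariance divided by sigma2 (ultrametric tree)."""
    M = tree.mrca_times()
    tt = np.diag(M)
    D = tt[:, None] + tt[None, :] - 2.0 * M
    return np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * M)) / (2.0 * alpha)


def ou_weight_matrix(rmap: RegimeMap, alpha: float, fixed_root: bool = True) -> np.ndarray:
    """Per-tip regime weights for the OUM mean.

    W[i, k] integrates alpha * e^(-alpha (T_i - t)) over root-to-tip segments
    painted regime k. With ``fixed_root`` the residual root weight e^(-alpha T)
    is folded into the root regime's column.
    """
    tree = rmap.tree
    regimes = list(rmap.regimes)
    times = tree.node_times()
    n = tree.n_tips
    W = np.zeros((n, len(regimes)))
    root_col = regimes.index(rmap.root_regime)
    for a, (t0s, t1s, regs) in enumerate(rmap.path_segments()):
        T = times[tree.tips[a]]
        contrib = np.exp(-alpha * (T - t1s)) - np.exp(-alpha * (T - t0s))
        np.add.at(W[a], regs, contrib)
        if fixed_root:
            W[a, root_col] += np.exp(-alpha * T)
    return W


def ou_loglik(
    rmap: RegimeMap,
    trait,
    alpha: float,
    sigma2: float,
    theta: dict[str, float],
    root_state: float | None = None,
) -> float:
    """Multipeak OU log-likelihood; root fixed at the root regime's optimum
    unless ``root_state`` is given."""
    if alpha < 0:
        raise EvoModelError("alpha must be non-negative")
    tree = rmap.tree
    y = _trait_vector(tree, trait)
    if alpha < 1e-12:
        return bm_loglik(tree, trait, sigma2, root_state
                         if root_state is not None else theta[rmap.root_regime])
    fixed_root = root_state is None
    W = ou_weight_matrix(rmap, alpha, fixed_root=fixed_root)
    th = np.array([theta[r] for r in rmap.regimes])
    mean = W @ th
    if not fixed_root:
        T = tree.node_times()[tree.tips]
        mean = mean + root_state * np.exp(-alpha * T)
    cov = sigma2 * _ou_corr(tree, alpha)
    return _mvn_loglik(y, mean, cov)


# -- fitting ---------------------------------------------------------------


@dataclass
class EvolModelFit:
    model: str
    sigma2: float | dict[str, float]
    loglik: float
    k: int
    n: int
    alpha: float | None = None
    theta: float | dict[str, float] | None = None
    r: float | None = None
    root_state: float | None = None
    converged: bool = True
    at_boundary: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


def _profile_gls(y: np.ndarray, M: np.ndarray, R: np.ndarray):
    """Profile linear coefficients and scale: y ~ N(M b, s2 R)."""
    L = np.linalg.cholesky(R)
    wy = np.linalg.solve(L, y)
    wM = np.linalg.solve(L, M)
    b, *_ = np.linalg.lstsq(wM, wy, rcond=None)
    r = wy - wM @ b
    n = len(y)
    s2 = float(r @ r) / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return b, s2, float(ll)


def _optimize_1d(profile_ll, lo: float, hi: float, n_grid: int = 24):
    """Log-spaced grid then local refinement; returns (x, ll, at_boundary)."""
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    vals = np.array([profile_ll(x) for x in grid])
    best = int(np.nanargmax(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda lx: -profile_ll(np.exp(lx)),
        bounds=(np.log(a), np.log(b)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    x = float(np.exp(res.x))
    ll = float(-res.fun)
    if vals[best] > ll:
        x, ll = float(grid[best]), float(vals[best])
    boundary = best in (0, n_grid - 1)
    return x, ll, boundary


def fit_model(
    model: str,
    tree_or_map: Phylogeny | RegimeMap,
    trait,
    estimate_root: bool = False,
) -> EvolModelFit:
    """Maximum-likelihood fit of one trait-evolution model.

    The linear parameters (optima / root state) and the scale sigma2 are
    profiled analytically by GLS; alpha (OU) or r (EB) is optimized by a
    bounded log-spaced search. ``estimate_root`` frees the OU root state
    instead of pinning it to the root regime's optimum.
    """
    model = model.upper()
    if model not in MODELS:
        raise EvoModelError(f"unknown model {model!r}")
    if isinstance(tree_or_map, RegimeMap):
        rmap, tree = tree_or_map, tree_or_map.tree
    else:
        rmap, tree = None, tree_or_map
    y = _trait_vector(tree, trait)
    n = tree.n_tips
    T = tree.depth
    ones = np.ones((n, 1))

    if model == "BM1":
        b, s2, ll = _profile_gls(y, ones, tree.mrca_times() / T)
        return EvolModelFit("BM1", sigma2=s2 / T, loglik=ll, k=2, n=n,
                            root_state=float(b[0]))

    if model == "EB":
        lo, hi = np.log(1e-5) / T, -1e-8 / T

        def prof_eb(mag: float):
            r = -mag  # search over |r|, r < 0
            _, _, ll = _profile_gls(y, ones, _eb_cov(tree, 1.0, r))
            return ll

        mag, ll, boundary = _optimize_1d(prof_eb, -hi, -lo)
        r = -mag
        b, s2, ll = _profile_gls(y, ones, _eb_cov(tree, 1.0, r))
        return EvolModelFit("EB", sigma2=s2, loglik=ll, k=3, n=n, r=r,
                            root_state=float(b[0]), at_boundary=boundary)

    if model == "OU1":
        def prof_ou1(alpha: float):
            _, _, ll = _profile_gls(y, ones, _ou_corr(tree, alpha))
            return ll

        alpha, ll, boundary = _optimize_1d(prof_ou1, 1e-6 / T, 50.0 / T)
        b, s2, ll = _profile_gls(y, ones, _ou_corr(tree, alpha))
        return EvolModelFit("OU1", sigma2=s2, alpha=alpha, theta=float(b[0]),
                            loglik=ll, k=3, n=n, at_boundary=boundary)

    if rmap is None:
        raise EvoModelError(f"{model} requires a RegimeMap")
    regimes = list(rmap.regimes)
    K = len(regimes)

    if model == "BMM":
        rmap.regime_share_matrices()  # warm the cache before the optimizer loop

        def nll(logs: np.ndarray) -> float:
            s2 = {reg: float(np.exp(v)) for reg, v in zip(regimes, logs)}
            cov = _bmm_cov(rmap, s2)
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                return 1e10  # finite penalty keeps L-BFGS gradients defined
            wy = np.linalg.solve(L, y)
            w1 = np.linalg.solve(L, np.ones(n))
            b = float(w1 @ wy / (w1 @ w1))
            r = wy - b * w1
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            return 0.5 * (n * np.log(2 * np.pi) + logdet + float(r @ r))

        # moment start: BM1 rate
        bm = fit_model("BM1", tree, y)
        x0 = np.full(K, np.log(max(bm.sigma2, 1e-12)))
        best = None
        for s in range(3):
            xs = x0 if s == 0 else x0 + np.random.default_rng(s).normal(0, 1.5, K)
            res = optimize.minimize(nll, xs, method="L-BFGS-B",
                                    bounds=[(-30.0, 30.0)] * K)
            if best is None or res.fun < best.fun:
                best = res
        s2 = {reg: float(np.exp(v)) for reg, v in zip(regimes, best.x)}
        cov = _bmm_cov(rmap, s2)
        L = np.linalg.cholesky(cov)
        wy = np.linalg.solve(L, y)
        w1 = np.linalg.solve(L, np.ones(n))
        root = float(w1 @ wy / (w1 @ w1))
        ll = float(-nll(best.x))
        return EvolModelFit("BMM", sigma2=s2, loglik=ll, k=1 + K, n=n,
                            root_state=root, converged=bool(best.success))

    # OUM
    def prof_oum(alpha: float):
        W = ou_weight_matrix(rmap, alpha, fixed_root=not estimate_root)
        M = W
        if estimate_root:
            T_i = tree.node_times()[tree.tips]
            M = np.column_stack([W, np.exp(-alpha * T_i)])
        _, _, ll = _profile_gls(y, M, _ou_corr(tree, alpha))
        return ll

    alpha, ll, boundary = _optimize_1d(prof_oum, 1e-6 / T, 50.0 / T)
    W = ou_weight_matrix(rmap, alpha, fixed_root=not estimate_root)
    M = W
    if estimate_root:
        T_i = tree.node_times()[tree.tips]
        M = np.column_stack([W, np.exp(-alpha * T_i)])
    b, s2, ll = _profile_gls(y, M, _ou_corr(tree, alpha))
    theta = {reg: float(v) for reg, v in zip(regimes, b[:K])}
    root = float(b[K]) if estimate_root else theta[rmap.root_regime]
    k = 2 + K + (1 if estimate_root else 0)
    return EvolModelFit("OUM", sigma2=s2, alpha=alpha, theta=theta, loglik=ll,
                        k=k, n=n, root_state=root, at_boundary=boundary)


# -- map-ensemble comparison ----------------------------------------------


@dataclass
class MapEnsembleResult:
    per_map: pd.DataFrame  # columns: map, BMM, OUM (AICc)
    fixed_aicc: dict[str, float]
    best_fraction: dict[str, float]
    n_maps: int
    failures: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for m in ("BMM", "OUM"):
            if m in self.per_map:
                rows.append({"model": m, "aicc_mean": self.per_map[m].mean(),
                             "aicc_sd": self.per_map[m].std(),
                             "best_fraction": self.best_fraction.get(m, 0.0)})
        for m, a in self.fixed_aicc.items():
            rows.append({"model": m, "aicc_mean": a, "aicc_sd": 0.0,
                         "best_fraction": self.best_fraction.get(m, 0.0)})
        return pd.DataFrame(rows)


def compare_over_maps(
    tree: Phylogeny,
    tip_regimes: dict[str, str],
    trait,
    n_maps: int = 500,
    seed: int | None = None,
    models: tuple[str, ...] = MODELS,
) -> MapEnsembleResult:
    """Fit BMM/OUM per sampled regime map, BM1/OU1/EB once; AICc ensemble."""
    mk = fit_mk(tree, tip_regimes)
    maps = sample_simmap(tree, tip_regimes, mk=mk, n_maps=n_maps, seed=seed)
    fixed = {}
    for m in ("BM1", "OU1", "EB"):
        if m in models:
            fixed[m] = fit_model(m, tree, trait).aicc
    multi = [m for m in ("BMM", "OUM") if m in models]
    rows, failures = [], []
    for i, rmap in enumerate(maps):
        row = {"map": i}
        try:
            for m in multi:
                row[m] = fit_model(m, rmap, trait).aicc
        except EvoModelError as exc:
            log.warning("map %d failed: %s", i, exc)
            failures.append(i)
            continue
        rows.append(row)
    per_map = pd.DataFrame(rows)
    wins = {m: 0 for m in models}
    for _, row in per_map.iterrows():
        scores = dict(fixed)
        for m in multi:
            scores[m] = row[m]
        wins[min(scores, key=scores.get)] += 1
    total = max(len(per_map), 1)
    best_fraction = {m: wins[m] / total for m in models}
    return MapEnsembleResult(per_map, fixed, best_fraction, n_maps, failures)


# -- ancestral states ------------------------------------------------------


def ancestral_states_bm(tree: Phylogeny, trait) -> dict[int, float]:
    """GLS/ML ancestral value estimates under BM1 (for phenograms)."""
    y = _trait_vector(tree, trait)
    fit = fit_model("BM1", tree, y)
    mu = fit.root_state
    times = tree.node_times()
    paths = tree._ancestor_paths()
    # ancestor sets (with times) for internal nodes too
    anc: dict[int, dict[int, float]] = {}
    for v in tree.preorder():
        if v == tree.root:
            anc[v] = {v: 0.0}
        else:
            anc[v] = dict(anc[tree.parent[v]])
            anc[v][v] = times[v]
    Ctt = tree.mrca_times()
    n = tree.n_tips
    out = {}
    Cinv_r = np.linalg.solve(Ctt, y - mu)
    for v in range(tree.n_nodes):
        if not tree.children[v]:
            out[v] = float(y[tree.tips.index(v)])
            continue
        cvt = np.empty(n)
        for a, tip in enumerate(tree.tips):
            shared = anc[v].keys() & paths[tip].keys()
            cvt[a] = max(times[u] for u in shared)
        out[v] = float(mu + cvt @ Cinv_r)
    return out
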