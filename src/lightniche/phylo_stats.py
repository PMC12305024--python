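"""Phylogenetic regression machinery.

Pagel's-lambda correlation structure, PGLS on species means, Gaussian mixed
models with crossed (optionally phylogenetically correlated) random
intercepts estimated by ML/REML, AICc comparison, and standardized major
axis (SMA) allometric shift tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import Phylogeny, TreeError, read_newick, write_newick  # noqa: F401

log = logging.getLogger(__name__)

LOG_VAR_FLOOR = -20.0  # lower bound on log variance components


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhyloCorrelation:
    """Species x species shared-path correlation with Pagel's lambda applied."""

    C: np.ndarray
    species: tuple[str, ...]
    lam: float = 1.0

    def aligned(self, order: list[str]) -> np.ndarray:
        idx = [self.species.index(s) for s in order]
        return self.C[np.ix_(idx, idx)]


def phylo_correlation(tree: Phylogeny, lam: float = 1.0) -> PhyloCorrelation:
    """C_ij = lambda * (shared path length) / depth off-diagonal, 1 on diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("Pagel's lambda must be in [0, 1]")
    if not tree.is_ultrametric(rtol=1e-6) and lam < 1.0:
        log.warning("non-ultrametric tree: lambda-transformed covariance form used")
    M = tree.mrca_times()
    depth = np.diag(M).mean()
    C = lam * M / depth
    np.fill_diagonal(C, np.diag(M) / depth)
    return PhyloCorrelation(C, tuple(tree.tip_labels), lam)


@dataclass
class MixedFit:
    beta: pd.Series
    se: pd.Series
    tvals: pd.Series
    pvals: pd.Series
    varcomps: dict[str, float]
    loglik_ml: float
    loglik_reml: float
    n: int
    k: int
    method: str = "ML"
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik_ml, self.k, self.n)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _as_design(X, n: int) -> pd.DataFrame:
    if X is None:
        return pd.DataFrame({"(Intercept)": np.ones(n)})
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def pgls_fit(
    y,
    X,
    corr: PhyloCorrelation,
    species: list[str] | None = None,
) -> MixedFit:
    """Phylogenetic GLS: beta = (X' V^-1 X)^-1 X' V^-1 y with V = sigma^2 C.

    ``species`` (or the index of ``y``) aligns the rows to the correlation
    matrix. Returns ML and REML log-likelihoods and t-tests on coefficients.
    """
    if species is None:
        if isinstance(y, pd.Series):
            species = list(y.index)
        else:
            species = list(corr.species)
    missing = sorted(set(species) - set(corr.species))
    if missing:
        raise FitError(f"species not in tree: {missing}")
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    Xd = _as_design(X, n)
    Xv = Xd.to_numpy(dtype=float)
    p = Xv.shape[1]
    if np.linalg.matrix_rank(Xv) < p:
        raise FitError("rank-deficient design matrix")
    C = corr.aligned(species)
    L = np.linalg.cholesky(C)
    logdet_C = 2.0 * np.sum(np.log(np.diag(L)))
    wy = np.linalg.solve(L, yv)
    wX = np.linalg.solve(L, Xv)
    XtX = wX.T @ wX
    beta = np.linalg.solve(XtX, wX.T @ wy)
    resid = wy - wX @ beta
    rss = float(resid @ resid)
    sig2_ml = rss / n
    sig2_reml = rss / (n - p)
    ll_ml = -0.5 * (n * np.log(2 * np.pi * sig2_ml) + logdet_C + n)
    _, logdet_XtX = np.linalg.slogdet(XtX)
    ll_reml = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sig2_reml) + 1.0) + logdet_C + logdet_XtX
    )
    cov_beta = sig2_reml * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tv = beta / se
    pv = 2.0 * stats.t.sf(np.abs(tv), df=n - p)
    cols = list(Xd.columns)
    return MixedFit(
        beta=pd.Series(beta, index=cols),
        se=pd.Series(se, index=cols),
        tvals=pd.Series(tv, index=cols),
        pvals=pd.Series(pv, index=cols),
        varcomps={"residual": sig2_ml},
        loglik_ml=float(ll_ml),
        loglik_reml=float(ll_reml),
        n=n,
        k=p + 1,
        method="GLS",
        extra={"sigma2_reml": sig2_reml, "lambda": corr.lam},
    )


@dataclass(frozen=True)
class RandomTerm:
    """A random intercept: a grouping factor, optionally with level correlation."""

    name: str
    groups: tuple
    corr: np.ndarray | None = None  # aligned to sorted unique levels
    levels: tuple | None = None

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        levels = list(self.levels) if self.levels is not None else sorted(set(self.groups))
        lut = {g: i for i, g in enumerate(levels)}
        Z = np.zeros((len(self.groups), len(levels)))
        for i, g in enumerate(self.groups):
            Z[i, lut[g]] = 1.0
        G = np.eye(len(levels)) if self.corr is None else np.asarray(self.corr, float)
        if G.shape != (len(levels), len(levels)):
            raise FitError(f"correlation for term {self.name!r} misaligned with levels")
        return Z, G


def mixed_fit(
    y,
    X,
    random_terms: list[RandomTerm],
    method: str = "REML",
    include_residual: bool = True,
    n_starts: int = 3,
) -> MixedFit:
    """Gaussian mixed model with crossed random intercepts.

    V = sum_g sigma_g^2 Z_g G_g Z_g' (+ sigma_e^2 I); variance components are
    optimized on the log scale by L-BFGS-B with the fixed effects profiled out
    by GLS. Both ML and REML log-likelihoods are evaluated at the optimum of
    the requested criterion.
    """
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    Xd = _as_design(X, n)
    Xv = Xd.to_numpy(dtype=float)
    p = Xv.shape[1]
    if np.linalg.matrix_rank(Xv) < p:
        raise FitError("rank-deficient design matrix")
    if not random_terms and not include_residual:
        raise FitError("model has no variance component at all")
    parts = [Z @ G @ Z.T for Z, G in (t.design() for t in random_terms)]
    names = [t.name for t in random_terms]
    if include_residual:
        parts.append(np.eye(n))
        names.append("residual")
    nv = len(parts)
    jitter = 0.0 if include_residual else 1e-10

    def build_V(theta: np.ndarray) -> np.ndarray:
        V = sum(np.exp(th) * P for th, P in zip(theta, parts))
        return V + jitter * np.eye(n)

    def loglik(theta: np.ndarray, restricted: bool) -> float:
        V = build_V(theta)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -1e10  # finite penalty keeps L-BFGS gradients defined
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        wy = np.linalg.solve(L, yv)
        wX = np.linalg.solve(L, Xv)
        XtX = wX.T @ wX
        beta = np.linalg.solve(XtX, wX.T @ wy)
        r = wy - wX @ beta
        rss = float(r @ r)
        if restricted:
            _, ld2 = np.linalg.slogdet(XtX)
            return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + ld2 + rss)
        return -0.5 * (n * np.log(2 * np.pi) + logdet + rss)

    restricted = method.upper() == "REML"
    obj = lambda th: -loglik(th, restricted)  # noqa: E731

    var_y = max(np.var(yv), 1e-8)
    rng = np.random.default_rng(0)
    best = None
    for s in range(max(1, n_starts)):
        if s == 0:
            x0 = np.full(nv, np.log(var_y / nv))
        else:
            x0 = np.log(var_y / nv) + rng.normal(0, 2, nv)
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=[(LOG_VAR_FLOOR, None)] * nv
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success and s == 0:
            break
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise FitError("variance-component optimization did not converge")
    theta = best.x
    V = build_V(theta)
    L = np.linalg.cholesky(V)
    wy = np.linalg.solve(L, yv)
    wX = np.linalg.solve(L, Xv)
    XtX = wX.T @ wX
    beta = np.linalg.solve(XtX, wX.T @ wy)
    cov_beta = np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tv = beta / se
    dof = max(n - p, 1)
    pv = 2.0 * stats.t.sf(np.abs(tv), df=dof)
    cols = list(Xd.columns)
    k = p + nv
    return MixedFit(
        beta=pd.Series(beta, index=cols),
        se=pd.Series(se, index=cols),
        tvals=pd.Series(tv, index=cols),
        pvals=pd.Series(pv, index=cols),
        varcomps={nm: float(np.exp(th)) for nm, th in zip(names, theta)},
        loglik_ml=float(loglik(theta, restricted=False)),
        loglik_reml=float(loglik(theta, restricted=True)),
        n=n,
        k=k,
        method=method.upper(),
        converged=bool(best.success),
    )


def lrt(fit_null: MixedFit, fit_alt: MixedFit) -> tuple[float, int, float]:
    """ML likelihood-ratio test between nested fits: (stat, df, p)."""
    if fit_null.n != fit_alt.n:
        raise FitError("fits are on different numbers of observations")
    df = fit_alt.k - fit_null.k
    if df <= 0:
        raise FitError("alternative model must have more parameters")
    stat = max(0.0, 2.0 * (fit_alt.loglik_ml - fit_null.loglik_ml))
    return stat, df, float(stats.chi2.sf(stat, df))


def compare_models(
    fits: dict[str, MixedFit], threshold: float = 2.0
) -> pd.DataFrame:
    """AICc ranking; fits within ``threshold`` of the best flagged equivalent."""
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise FitError(f"fits have mismatched n: {sorted(ns)}")
    rows = [
        {"model": name, "loglik": f.loglik_ml, "k": f.k, "aicc": f.aicc}
        for name, f in fits.items()
    ]
    out = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].iloc[0]
    out["equivalent_to_best"] = out["delta_aicc"] < threshold
    return out


# -- standardized major axis ----------------------------------------------


@dataclass
class SMAGroupFit:
    slope: float
    elevation: float
    r: float
    n: int


@dataclass
class SMAFit:
    groups: dict[str, SMAGroupFit]
    common_slope: float | None = None
    slope_test: tuple[float, int, float] | None = None  # (stat, df, p)
    elevation_test: tuple[float, int, float] | None = None
    shift_test: tuple[float, int, float] | None = None

    @property
    def slope(self) -> float:
        if len(self.groups) == 1:
            return next(iter(self.groups.values())).slope
        return self.common_slope


def _sma_group(x: np.ndarray, y: np.ndarray) -> SMAGroupFit:
    if len(x) < 3:
        raise FitError("SMA needs >= 3 points per group")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise FitError("SMA undefined: zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    return SMAGroupFit(slope, float(np.mean(y) - slope * np.mean(x)), r, len(x))


def _resid_fitted_corr(x, y, b) -> float:
    """Correlation between residual (y - b x) and fitted (y + b x) axis scores."""
    res = y - b * x
    fit = y + b * x
    if np.std(res) == 0 or np.std(fit) == 0:
        return 0.0  # degenerate: perfectly on the axis
    return float(np.corrcoef(res, fit)[0, 1])


def sma_fit(x, y, groups=None) -> SMAFit:
    """Standardized major axis fits with slope / elevation / shift tests.

    Per group: slope = sign(r) * sd_y / sd_x, elevation = mean_y - b * mean_x.
    With >= 2 groups, the common slope is estimated by minimizing the
    Warton-style likelihood-ratio statistic built from residual-vs-fitted
    axis-score correlations; elevation and along-axis shifts are tested by
    Wald statistics on residual and fitted scores at the common slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if groups is None:
        groups = np.zeros(len(x), dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()), key=str)
    data = {g: (x[groups == g], y[groups == g]) for g in labels}
    fits = {str(g): _sma_group(*data[g]) for g in labels}
    result = SMAFit(groups=fits)
    if len(labels) < 2:
        return result

    def lr_stat(b: float) -> float:
        s = 0.0
        for g in labels:
            xg, yg = data[g]
            rho = _resid_fitted_corr(xg, yg, b)
            rho2 = min(rho * rho, 1.0 - 1e-12)
            s += -(len(xg) - 2.5) * np.log1p(-rho2)
        return s

    slopes = [f.slope for f in fits.values()]
    gmean = float(np.sign(slopes[0]) * np.exp(np.mean(np.log(np.abs(slopes)))))
    candidates = sorted(set(slopes + [gmean]))
    b_common = min(candidates, key=lr_stat)
    span = max(abs(b_common) * 0.5, 1e-6)
    br = optimize.minimize_scalar(
        lr_stat, bounds=(b_common - span, b_common + span), method="bounded",
        options={"xatol": 1e-12},
    )
    if br.fun <= lr_stat(b_common):
        b_common = float(br.x)
    df = len(labels) - 1
    stat = float(lr_stat(b_common))
    result.common_slope = b_common
    result.slope_test = (stat, df, float(stats.chi2.sf(stat, df)))

    def wald(scores_fn) -> tuple[float, int, float]:
        means, ws = [], []
        for g in labels:
            xg, yg = data[g]
            z = scores_fn(xg, yg)
            v = np.var(z, ddof=1) / len(z)
            means.append(np.mean(z))
            ws.append(1.0 / max(v, 1e-300))
        means = np.asarray(means)
        ws = np.asarray(ws)
        grand = np.sum(ws * means) / np.sum(ws)
        w = float(np.sum(ws * (means - grand) ** 2))
        return w, df, float(stats.chi2.sf(w, df))

    result.elevation_test = wald(lambda xg, yg: yg - b_common * xg)
    result.shift_test = wald(lambda xg, yg: yg + b_common * xg)
    return result
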