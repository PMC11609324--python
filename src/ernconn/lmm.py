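"""Random-intercept linear mixed model via profiled (RE)ML.

The model is y = X b + u_g + e with one random intercept per group (family),
u_g ~ N(0, tau2), e ~ N(0, sigma2). For a single variance ratio
lam = tau2/sigma2 the GLS solution and the residual quadratic form have
closed forms built from per-group sums, so the profiled deviance is a
one-dimensional function of log(lam) that we minimise with Brent's method.

Per-group sufficient statistics (X'X, X'y, column sums, y sums, sizes) are
precomputed once per dataset; a family-level case-bootstrap replicate is
then just a reweighting of those statistics, making each refit O(groups *
p^2) instead of O(n * p^2). This is what keeps thousands of bootstrap
refits per model grid tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOGLAM_LO, _LOGLAM_HI = -15.0, 10.0


class LmmError(ValueError):
    pass


@dataclass
class GroupStats:
    """Per-group sufficient statistics for a fixed design and outcome."""

    G: np.ndarray   # (c, p, p) per-group X'X
    h: np.ndarray   # (c, p)    per-group X'y
    S: np.ndarray   # (c, p)    per-group column sums of X
    t: np.ndarray   # (c,)      per-group sums of y
    yy: np.ndarray  # (c,)      per-group y'y
    nj: np.ndarray  # (c,)      group sizes

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> "GroupStats":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(X) != len(y) or len(y) != len(groups):
            raise LmmError("X, y and groups must have matching first dimension")
        order = np.argsort(groups, kind="stable")
        Xs, ys, gs = X[order], y[order], groups[order]
        _, starts = np.unique(gs, return_index=True)
        G = np.stack([x.T @ x for x in np.split(Xs, starts[1:])])
        h = np.add.reduceat(Xs * ys[:, None], starts, axis=0)
        S = np.add.reduceat(Xs, starts, axis=0)
        t = np.add.reduceat(ys, starts)
        yy = np.add.reduceat(ys * ys, starts)
        nj = np.diff(np.r_[starts, len(gs)]).astype(float)
        return cls(G=G, h=h, S=S, t=t, yy=yy, nj=nj)

    @property
    def n_groups(self) -> int:
        return len(self.nj)


@dataclass
class LmmFit:
    """Result of a profiled (RE)ML random-intercept fit."""

    params: np.ndarray
    bse: np.ndarray
    sigma2: float      # residual variance
    tau2: float        # random-intercept variance
    llf: float
    reml: bool
    n: int
    n_groups: int
    xnames: list[str]
    cov_params: np.ndarray

    def param(self, name: str) -> float:
        return float(self.params[self.xnames.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.xnames.index(name)])


class _ProfileContext:
    """Count-weighted aggregates, built once per (re)sample."""

    __slots__ = ("XtX", "Xty", "yty", "n", "nj", "cnt", "S", "t", "n_groups")

    def __init__(self, stats: GroupStats, counts: np.ndarray | None):
        cnt = np.ones(stats.n_groups) if counts is None else counts.astype(float)
        self.cnt = cnt
        self.nj = stats.nj
        self.S = stats.S
        self.t = stats.t
        self.XtX = np.einsum("j,jkl->kl", cnt, stats.G)
        self.Xty = cnt @ stats.h
        self.yty = float(cnt @ stats.yy)
        self.n = float(cnt @ stats.nj)
        self.n_groups = int((cnt > 0).sum())

    def pieces(self, lam: float):
        w = lam / (1.0 + lam * self.nj)
        cw = self.cnt * w
        A = self.XtX - self.S.T @ (self.S * cw[:, None])
        b = self.Xty - self.S.T @ (cw * self.t)
        yVy = self.yty - float(cw @ (self.t * self.t))
        beta = np.linalg.solve(A, b)
        q = max(yVy - float(beta @ b), 1e-300)  # GLS residual quadratic form
        logdetV = float(self.cnt @ np.log1p(lam * self.nj))
        return beta, A, q, logdetV

    def neg2ll(self, lam: float, reml: bool) -> float:
        beta, A, q, logdetV = self.pieces(lam)
        p = len(beta)
        if reml:
            df = self.n - p
            sigma2 = q / df
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return df * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV + logdetA
        sigma2 = q / self.n
        return self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV


def fit_from_stats(
    stats: GroupStats,
    xnames: list[str],
    reml: bool = True,
    counts: np.ndarray | None = None,
    xatol: float = 1e-8,
) -> LmmFit:
    """Fit the random-intercept model from per-group statistics.

    ``counts`` reweights groups (bootstrap multiplicities); ``None`` means
    the original sample. ``xatol`` is the Brent tolerance on log(tau2/sigma2);
    bootstrap refits may loosen it.
    """
    ctx = _ProfileContext(stats, counts)
    res = minimize_scalar(
        lambda u: ctx.neg2ll(np.exp(u), reml),
        bounds=(_LOGLAM_LO, _LOGLAM_HI),
        method="bounded",
        options={"xatol": xatol},
    )
    lam = float(np.exp(res.x))
    # boundary check: a pure fixed-effects model may beat any interior lam
    if ctx.neg2ll(0.0, reml) <= res.fun:
        lam = 0.0
    beta, A, q, _ = ctx.pieces(lam)
    p = len(beta)
    n = ctx.n
    sigma2 = q / ((n - p) if reml else n)
    cov = sigma2 * np.linalg.inv(A)
    return LmmFit(
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        sigma2=float(sigma2),
        tau2=float(lam * sigma2),
        llf=-0.5 * ctx.neg2ll(lam, reml),
        reml=reml,
        n=int(round(n)),
        n_groups=ctx.n_groups,
        xnames=list(xnames),
        cov_params=cov,
    )


def beta_from_stats(
    stats: GroupStats,
    counts: np.ndarray | None = None,
    reml: bool = True,
    xatol: float = 3e-2,
    bounds: tuple[float, float] = (_LOGLAM_LO, _LOGLAM_HI),
) -> np.ndarray:
    """Point estimate only (bootstrap fast path): skips SEs and final llf.

    ``bounds`` restricts the log variance-ratio search; bootstrap callers
    warm-start it around the full-sample estimate.
    """
    ctx = _ProfileContext(stats, counts)
    res = minimize_scalar(
        lambda u: ctx.neg2ll(np.exp(u), reml),
        bounds=bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    lam = float(np.exp(res.x))
    if bounds[0] <= _LOGLAM_LO + 1e-9 and ctx.neg2ll(0.0, reml) <= res.fun:
        lam = 0.0
    beta, _, _, _ = ctx.pieces(lam)
    return beta


def fit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    xnames: list[str] | None = None,
    reml: bool = True,
) -> LmmFit:
    """Convenience wrapper: build group statistics and fit."""
    y = np.asarray(y, dtype=float)
    if np.std(y) < 1e-12:
        raise LmmError("outcome has (near-)zero variance")
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    const = np.isclose(X.mean(axis=0), 1.0) & (sd < 1e-12)
    if np.any((sd < 1e-12) & ~const):
        raise LmmError("a non-intercept design column has zero variance")
    if len(np.unique(groups)) < 2:
        raise LmmError("need at least 2 groups (families)")
    stats = GroupStats.from_arrays(X, y, groups)
    if xnames is None:
        xnames = [f"x{i}" for i in range(X.shape[1])]
    return fit_from_stats(stats, xnames, reml=reml)
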