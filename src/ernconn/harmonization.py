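"""Empirical-Bayes location/scale batch harmonization (ComBat-style).

Removes additive and multiplicative site/scanner effects from the
connectivity features while preserving covariate structure. The parametric
variant is implemented: per-feature batch locations are shrunk toward a
normal prior and batch scales toward an inverse-gamma prior, with the
standard iterative conditional moment updates. Hyperpriors are estimated by
the method of moments across features within each batch.

Model per feature i, subject j in batch g:

    y_ijg = alpha_i + x_j' beta_i + gamma_ig + delta_ig * eps_ijg

After fitting, the adjusted value is

    y* = sigma_i * (z_ijg - gamma*_ig) / delta*_ig + alpha_i + x_j' beta_i

with z the standardized residual and starred quantities the EB-shrunk batch
effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EB_TOL = 1e-6
EB_MAX_ITER = 100


class HarmonizationError(ValueError):
    pass


@dataclass
class HarmonizationModel:
    """Fitted ComBat-style model for a feature panel."""

    feature_names: list[str]
    covariate_names: list[str]
    batches: list[str]
    alpha: np.ndarray        # (p,) grand intercepts
    beta: np.ndarray         # (q, p) covariate coefficients
    sigma: np.ndarray        # (p,) pooled residual scales
    gamma_star: np.ndarray   # (n_batch, p) EB-shrunk batch locations
    delta_star: np.ndarray   # (n_batch, p) EB-shrunk batch scales (>0)
    covariate_means: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if np.any(self.delta_star <= 0):
            raise HarmonizationError("EB batch scales must be positive")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "feature_names": self.feature_names,
            "covariate_names": self.covariate_names,
            "batches": self.batches,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "covariate_means": self.covariate_means.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            feature_names=obj["feature_names"],
            covariate_names=obj["covariate_names"],
            batches=obj["batches"],
            alpha=np.array(obj["alpha"]),
            beta=np.array(obj["beta"]),
            sigma=np.array(obj["sigma"]),
            gamma_star=np.array(obj["gamma_star"]),
            delta_star=np.array(obj["delta_star"]),
            covariate_means=np.array(obj["covariate_means"]),
        )


def _design(features, batch, covariates):
    Y = np.asarray(features, dtype=float)
    if Y.ndim != 2:
        raise HarmonizationError("features must be a 2-D (subjects x features) array")
    batch = np.asarray(batch).astype(str)
    levels, codes = np.unique(batch, return_inverse=True)
    counts = np.bincount(codes)
    if np.any(counts < 2):
        bad = levels[counts < 2]
        raise HarmonizationError(f"singleton batch(es): {bad.tolist()}")
    X = np.asarray(covariates, dtype=float) if covariates is not None else np.empty((len(Y), 0))
    if X.ndim == 1:
        X = X[:, None]
    return Y, levels, codes, counts, X


def fit_combat(
    features,
    batch,
    covariates=None,
    feature_names: list[str] | None = None,
    covariate_names: list[str] | None = None,
) -> HarmonizationModel:
    """Fit the parametric EB location/scale model.

    ``features``: (n x p) panel; ``batch``: length-n site labels;
    ``covariates``: (n x q) design WITHOUT intercept or batch indicators
    (biological covariates whose effects must be preserved).
    """
    Y, levels, codes, counts, X = _design(features, batch, covariates)
    n, p = Y.shape
    G = len(levels)
    q = X.shape[1]

    # full-rank check on [batch dummies | covariates]
    B = np.zeros((n, G))
    B[np.arange(n), codes] = 1.0
    D = np.c_[B, X]
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise HarmonizationError("covariate design is rank-deficient given batch indicators")

    # OLS with batch means + covariates; grand intercept = count-weighted
    # average of the per-batch intercepts (standard ComBat convention)
    coefs, *_ = np.linalg.lstsq(D, Y, rcond=None)
    batch_int = coefs[:G]            # (G, p)
    beta = coefs[G:]                 # (q, p)
    alpha = (counts / n) @ batch_int  # (p,)
    resid = Y - D @ coefs
    sigma2 = (resid**2).sum(axis=0) / n
    sigma = np.sqrt(np.maximum(sigma2, 1e-24))

    Z = (Y - alpha - X @ beta) / sigma  # standardized data

    if G == 1:
        gamma_star = np.zeros((1, p))
        delta_star = np.ones((1, p))
    else:
        gamma_hat = np.vstack([Z[codes == g].mean(axis=0) for g in range(G)])
        delta2_hat = np.vstack([Z[codes == g].var(axis=0, ddof=1) for g in range(G)])
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta2_hat)
        for g in range(G):
            gs, d2s = _eb_shrink(gamma_hat[g], delta2_hat[g], Z[codes == g])
            gamma_star[g] = gs
            delta_star[g] = np.sqrt(d2s)

    return HarmonizationModel(
        feature_names=list(feature_names or [f"f{i}" for i in range(p)]),
        covariate_names=list(covariate_names or [f"c{i}" for i in range(q)]),
        batches=levels.tolist(),
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=delta_star,
        covariate_means=X.mean(axis=0) if q else np.empty(0),
    )


def _eb_shrink(gamma_hat, delta2_hat, Zg):
    """Iterative EB updates for one batch (features exchangeable).

    Normal prior on locations (moments gbar, t2 across features) and
    inverse-gamma prior on variances (moments lam, th across features).
    """
    ng = len(Zg)
    gbar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1) if len(gamma_hat) > 1 else 0.0
    v = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1) if len(delta2_hat) > 1 else 0.0
    # inverse-gamma hyperparameters by method of moments
    lam = (2 * s2 + v**2) / s2 if s2 > 0 else 100.0
    th = (v**3 + v * s2) / s2 if s2 > 0 else v * 99.0

    g_old = gamma_hat.copy()
    d2_old = delta2_hat.copy()
    for _ in range(EB_MAX_ITER):
        if t2 > 0:
            g_new = (ng * t2 * gamma_hat + d2_old * gbar) / (ng * t2 + d2_old)
        else:
            g_new = np.full_like(gamma_hat, gbar)
        ssq = ((Zg - g_new) ** 2).sum(axis=0)
        d2_new = (th + 0.5 * ssq) / (ng / 2 + lam - 1)
        change = max(np.abs(g_new - g_old).max(), np.abs(d2_new - d2_old).max())
        g_old, d2_old = g_new, d2_new
        if change < EB_TOL:
            break
    return g_old, np.maximum(d2_old, 1e-12)


def apply_combat(model: HarmonizationModel, features, batch, covariates=None) -> np.ndarray:
    """Adjust a feature panel using a fitted model (deterministic)."""
    Y = np.asarray(features, dtype=float)
    batch = np.asarray(batch).astype(str)
    unseen = set(batch) - set(model.batches)
    if unseen:
        raise HarmonizationError(f"unseen batch label(s): {sorted(unseen)}")
    idx = {b: g for g, b in enumerate(model.batches)}
    codes = np.array([idx[b] for b in batch])
    X = np.asarray(covariates, dtype=float) if covariates is not None else np.empty((len(Y), 0))
    if X.ndim == 1:
        X = X[:, None]
    fitted = model.alpha + X @ model.beta
    Z = (Y - fitted) / model.sigma
    Zadj = (Z - model.gamma_star[codes]) / model.delta_star[codes]
    return Zadj * model.sigma + fitted


def harmonize_features(
    data: pd.DataFrame,
    feature_cols: list[str],
    batch_col: str = "site",
    covariate_cols: tuple[str, ...] = ("age", "sex", "int_p", "ext_p", "tot_p",
                                       "int_y", "ext_y", "tot_y"),
) -> tuple[pd.DataFrame, HarmonizationModel]:
    """Fit-and-apply on a cohort table; returns adjusted copy + model.

    Default covariates follow the study design: youth age and sex plus the
    six parental/youth psychopathology scores are preserved while site
    effects are removed from the connectivity features.
    """
    covs = [c for c in covariate_cols if c in data.columns]
    if len(covs) < len(covariate_cols):
        missing = set(covariate_cols) - set(covs)
        logger.warning("covariates absent from table, dropped: %s", sorted(missing))
    cov_mat = data[covs].to_numpy(dtype=float) if covs else None
    model = fit_combat(
        data[feature_cols].to_numpy(dtype=float),
        data[batch_col].to_numpy(),
        cov_mat,
        feature_names=feature_cols,
        covariate_names=covs,
    )
    adj = apply_combat(model, data[feature_cols].to_numpy(dtype=float),
                       data[batch_col].to_numpy(), cov_mat)
    out = data.copy()
    out[feature_cols] = adj
    return out, model
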