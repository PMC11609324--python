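"""Family-nested association models with cluster bootstrap and FDR.

One linear mixed model per (psychopathology scale x connectivity feature)
cell: the feature is the outcome, the scale score plus youth age and sex are
fixed effects, and family is a random intercept. Coefficients are
standardized (outcome and continuous predictors z-scored on the analysis
sample, sex contrast-coded +/-0.5). Inference is by family-level case
bootstrap: percentile confidence intervals and two-sided bootstrap p-values
with the (1 + count)/(B + 1) correction, followed by Benjamini-Hochberg FDR
across the grid.

The grid runs in two directions: parental scale -> youth connectivity (the
main analysis) and youth follow-up scale -> connectivity (exploratory); in
both the connectivity feature is the dependent variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import GroupStats, LmmError, beta_from_stats, fit_from_stats, fit_random_intercept
from .netdef_atlas import FEATURE_KEYS

logger = logging.getLogger(__name__)

PARENT_SCALES = ("int_p", "ext_p", "tot_p")
YOUTH_SCALES = ("int_y", "ext_y", "tot_y")


@dataclass
class LmmSpec:
    """One cell of the association grid."""

    outcome: str
    scale: str
    covariates: tuple[str, ...] = ("age", "sex")
    group: str = "family"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in FEATURE_KEYS:
            raise ValueError(f"outcome {self.outcome!r} is not one of the 10 feature keys")


def _contrast_code_sex(col: pd.Series) -> np.ndarray:
    vals = sorted(col.unique())
    if len(vals) > 2:
        raise LmmError(f"sex column has {len(vals)} levels; expected at most 2")
    mapping = {v: (-0.5 + i) for i, v in enumerate(vals)}
    return col.map(mapping).to_numpy(dtype=float)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd < 1e-12:
        raise LmmError("zero-variance variable cannot be standardized")
    return (x - x.mean()) / sd


def build_design(spec: LmmSpec, data: pd.DataFrame):
    """Complete-case design matrix, outcome and group labels for one cell."""
    cols = [spec.outcome, spec.scale, *spec.covariates, spec.group]
    d = data[cols].dropna()
    if len(d) < len(data):
        logger.info("%s ~ %s: %d incomplete rows dropped", spec.outcome, spec.scale,
                    len(data) - len(d))
    y = d[spec.outcome].to_numpy(dtype=float)
    xcols, xnames = [np.ones(len(d))], ["const"]
    for name in (spec.scale, *spec.covariates):
        if name == "sex":
            xcols.append(_contrast_code_sex(d[name]))
        else:
            v = d[name].to_numpy(dtype=float)
            xcols.append(_zscore(v) if spec.standardize else v)
        xnames.append(name)
    if spec.standardize:
        y = _zscore(y)
    X = np.column_stack(xcols)
    return X, y, d[spec.group].to_numpy(), xnames


def fit_family_lmm(spec: LmmSpec, data: pd.DataFrame):
    """REML random-intercept fit for one grid cell."""
    X, y, groups, xnames = build_design(spec, data)
    return fit_random_intercept(X, y, groups, xnames, reml=True)


@dataclass
class BootstrapResult:
    beta: float
    se: float
    tvalue: float
    ci_low: float
    ci_high: float
    p_boot: float
    n_failed: int
    flagged: bool
    B: int


def bootstrap_inference(
    spec: LmmSpec,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "case",
    xatol: float = 0.1,
) -> BootstrapResult:
    """Cluster bootstrap of the scale coefficient.

    ``scheme='case'`` (default): families resampled with replacement; each
    replicate reweights the precomputed per-family sufficient statistics,
    so no design rebuild is needed. ``'parametric'``: outcomes redrawn from
    the fitted model (new random intercepts and residuals). ``'residual'``:
    predicted family intercepts and level-1 residuals resampled with
    replacement and re-attached to the fixed fitted values. The
    variance-ratio search is warm-started around the full-sample estimate.
    Replicates whose refit fails are dropped and counted; a cell with more
    than 5% failures is flagged.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for bootstrap inference")
    if scheme not in ("case", "parametric", "residual"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    X, y, groups, xnames = build_design(spec, data)
    stats = GroupStats.from_arrays(X, y, groups)
    full = fit_from_stats(stats, xnames, reml=True)
    k = xnames.index(spec.scale)
    c = stats.n_groups
    lam_full = full.tau2 / full.sigma2
    center = np.log(max(lam_full, 1e-6))
    bounds = (center - 3.0, center + 3.0)
    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    n_failed = 0
    if scheme == "case":
        probs = np.full(c, 1.0 / c)
        for b in range(B):
            cnt = rng.multinomial(c, probs)
            try:
                draws[b] = beta_from_stats(stats, counts=cnt, xatol=xatol, bounds=bounds)[k]
            except (np.linalg.LinAlgError, FloatingPointError, LmmError):
                draws[b] = np.nan
                n_failed += 1
    else:
        codes, nj, fitted, u_hat, resid = _residual_pieces(X, y, groups, full)
        tau, sig = np.sqrt(full.tau2), np.sqrt(full.sigma2)
        for b in range(B):
            if scheme == "parametric":
                ystar = fitted + rng.normal(0, tau, c)[codes] + rng.normal(0, sig, len(y))
            else:
                ustar = rng.choice(u_hat, size=c, replace=True)
                estar = rng.choice(resid, size=len(y), replace=True)
                ystar = fitted + ustar[codes] + estar
            try:
                st = GroupStats.from_arrays(X, ystar, codes)
                draws[b] = beta_from_stats(st, xatol=xatol, bounds=bounds)[k]
            except (np.linalg.LinAlgError, FloatingPointError, LmmError):
                draws[b] = np.nan
                n_failed += 1
    ok = draws[np.isfinite(draws)]
    if len(ok) == 0:
        raise LmmError("all bootstrap refits failed")
    ci_low, ci_high = np.percentile(ok, [2.5, 97.5])
    n_le = int((ok <= 0).sum())
    n_ge = int((ok >= 0).sum())
    nb = len(ok)
    p = 2.0 * min((1 + n_le) / (nb + 1), (1 + n_ge) / (nb + 1))
    return BootstrapResult(
        beta=float(full.params[k]),
        se=float(full.bse[k]),
        tvalue=float(full.params[k] / full.bse[k]),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_boot=float(min(p, 1.0)),
        n_failed=n_failed,
        flagged=n_failed > 0.05 * B,
        B=B,
    )


def _residual_pieces(X, y, groups, full):
    """Fixed fitted values, BLUP family intercepts and level-1 residuals.

    The residual scheme recenters and rescales the predicted intercepts and
    residuals so their empirical variances match the REML components (the
    usual shrinkage correction for LMM residual bootstraps).
    """
    codes = pd.factorize(groups)[0]
    c = codes.max() + 1
    fitted = X @ full.params
    marg = y - fitted
    nj = np.bincount(codes).astype(float)
    fam_mean = np.bincount(codes, weights=marg) / nj
    shrink = full.tau2 / (full.tau2 + full.sigma2 / nj)
    u_hat = shrink * fam_mean
    resid = marg - u_hat[codes]
    for v, target in ((u_hat, full.tau2), (resid, full.sigma2)):
        v -= v.mean()
        sd = v.std()
        if sd > 0 and target > 0:
            v *= np.sqrt(target) / sd
    return codes, nj, fitted, u_hat, resid


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_association_grid(
    data: pd.DataFrame,
    scales: tuple[str, ...] = PARENT_SCALES,
    direction: str = "parent_to_connectivity",
    B: int = 1000,
    seed: int = 0,
    fdr_family: str = "pooled",
    covariates: tuple[str, ...] = ("age", "sex"),
    scheme: str = "case",
) -> pd.DataFrame:
    """The (scales x 10 features) grid of bootstrap mixed models.

    Returns one row per cell with standardized beta, SE, T, bootstrap CI and
    p, and FDR-adjusted p (pooled across the whole grid by default, or
    within each scale with ``fdr_family='per_scale'``).
    """
    if direction not in ("parent_to_connectivity", "connectivity_to_youth"):
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(scales) * len(FEATURE_KEYS))
    i = 0
    for scale in scales:
        for feat in FEATURE_KEYS:
            spec = LmmSpec(outcome=feat, scale=scale, covariates=covariates)
            res = bootstrap_inference(spec, data, B=B, seed=int(seeds[i]), scheme=scheme)
            full = fit_family_lmm(spec, data)
            rows.append({
                "scale": scale,
                "measure": feat,
                "beta": res.beta,
                "se": res.se,
                "tvalue": res.tvalue,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_boot": res.p_boot,
                "re_var": full.tau2,
                "resid_var": full.sigma2,
                "n": full.n,
                "n_boot_failed": res.n_failed,
                "flagged": res.flagged,
            })
            i += 1
    out = pd.DataFrame(rows)
    if fdr_family == "pooled":
        out["p_fdr"] = bh_adjust(out["p_boot"].to_numpy())
    elif fdr_family == "per_scale":
        out["p_fdr"] = np.nan
        for scale in scales:
            m = out["scale"] == scale
            out.loc[m, "p_fdr"] = bh_adjust(out.loc[m, "p_boot"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return out
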