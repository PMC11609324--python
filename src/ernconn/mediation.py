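"""Multilevel mediation with within-/between-family path decomposition.

Tests whether youth emotion-regulation network connectivity (M, child
level) mediates the association between parental psychopathology (X, family
level) and youth psychopathology at follow-up (Y, child level). Children
are level 1 and families level 2; the mediator is split into the observed
family mean (between) and the deviation from it (within), so the M -> Y
path is estimated separately within and between families.

Estimation is by two mixed-model equations, both with a family random
intercept and fitted by maximum likelihood (so the chi-square difference
test of the constrained model, b_within = b_between, is valid):

    M ~ X + age + sex                       (a = coefficient on X)
    Y ~ X + M_between + M_within + age + sex  (c' on X; b paths on M parts)

indirect = a * b_between; total = c' + indirect. All coefficients are
standardized as in the association module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import _contrast_code_sex, _zscore, bh_adjust
from .lmm import LmmError, LmmFit, fit_random_intercept
from .netdef_atlas import FEATURE_KEYS

logger = logging.getLogger(__name__)


class MediationError(ValueError):
    pass


def family_decompose(values: np.ndarray, family_ids: np.ndarray):
    """Split child-level values into family means and deviations.

    Returns ``(between, within)`` aligned with the input: ``between`` is the
    observed mean of the child's own family, ``within`` the deviation from
    it. Within components sum to zero inside each family and
    between + within reconstructs the observation exactly.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    fam = pd.Series(np.asarray(family_ids))
    between = s.groupby(fam.values).transform("mean").to_numpy()
    within = s.to_numpy() - between
    return between, within


def check_family_constant(data: pd.DataFrame, col: str, family_col: str = "family") -> None:
    """Reject tables where a family-level variable varies within families."""
    nun = data.groupby(family_col)[col].nunique(dropna=False)
    bad = nun[nun > 1]
    if len(bad):
        raise MediationError(
            f"{col!r} differs within {len(bad)} families (e.g. {bad.index[:3].tolist()}); "
            "resolve with subsample_discrepant_families() before modelling"
        )


def subsample_discrepant_families(
    data: pd.DataFrame, col: str, family_col: str = "family", seed: int = 0
) -> pd.DataFrame:
    """Keep one random child per family whose ``col`` is inconsistently reported."""
    rng = np.random.default_rng(seed)
    nun = data.groupby(family_col)[col].nunique(dropna=False)
    bad = set(nun[nun > 1].index)
    if not bad:
        return data
    keep_rows = []
    for fam, sub in data.groupby(family_col):
        if fam in bad:
            keep_rows.append(sub.iloc[rng.integers(len(sub))])
        else:
            keep_rows.extend(r for _, r in sub.iterrows())
    out = pd.DataFrame(keep_rows).reset_index(drop=True)
    logger.info("subsampled %d discrepant families (%d rows removed)", len(bad), len(data) - len(out))
    return out


@dataclass
class MediationResult:
    """Paths and model-comparison statistic for one (scale, measure) cell."""

    a: float
    a_se: float
    b_between: float
    b_between_se: float
    b_within: float
    b_within_se: float
    c_prime: float
    c_prime_se: float
    indirect: float
    total: float
    llf_free: float
    llf_constrained: float
    chisq_diff: float
    chisq_df: int
    chisq_p: float
    n: int
    m_fit: LmmFit | None = None
    y_fit: LmmFit | None = None


def fit_mediation(
    data: pd.DataFrame,
    x_col: str,
    m_col: str,
    y_col: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    family_col: str = "family",
) -> MediationResult:
    """Two-equation multilevel mediation fit (ML, standardized).

    Fits both the free model (separate within/between M -> Y coefficients)
    and the constrained model (single coefficient), returning the likelihood
    ratio statistic for their comparison (df = 1).
    """
    cols = [x_col, m_col, y_col, *covariates, family_col]
    d = data[cols].dropna().reset_index(drop=True)
    check_family_constant(d, x_col, family_col)
    fam = d[family_col].to_numpy()

    x = _zscore(d[x_col].to_numpy(dtype=float))
    m = _zscore(d[m_col].to_numpy(dtype=float))
    yv = _zscore(d[y_col].to_numpy(dtype=float))
    covs, cnames = [], []
    for name in covariates:
        if name == "sex":
            covs.append(_contrast_code_sex(d[name]))
        else:
            covs.append(_zscore(d[name].to_numpy(dtype=float)))
        cnames.append(name)
    C = np.column_stack(covs) if covs else np.empty((len(d), 0))
    ones = np.ones(len(d))

    m_between, m_within = family_decompose(m, fam)
    if np.std(m_within) < 1e-12:
        raise MediationError(
            "all families are singletons: the within-family path is inestimable"
        )

    # a path: M on X (ML for consistency; a/c' inference is per-equation)
    Xm = np.column_stack([ones, x, C])
    m_fit = fit_random_intercept(Xm, m, fam, ["const", x_col, *cnames], reml=False)

    # free Y equation: separate between/within mediator coefficients
    Xy = np.column_stack([ones, x, m_between, m_within, C])
    y_fit = fit_random_intercept(
        Xy, yv, fam, ["const", x_col, "m_between", "m_within", *cnames], reml=False
    )

    # constrained: single coefficient on raw M (= forcing the two equal)
    Xc = np.column_stack([ones, x, m, C])
    c_fit = fit_random_intercept(Xc, yv, fam, ["const", x_col, "m", *cnames], reml=False)

    a = m_fit.param(x_col)
    b_b = y_fit.param("m_between")
    b_w = y_fit.param("m_within")
    cp = y_fit.param(x_col)
    stat = max(2.0 * (y_fit.llf - c_fit.llf), 0.0)
    return MediationResult(
        a=a,
        a_se=m_fit.se(x_col),
        b_between=b_b,
        b_between_se=y_fit.se("m_between"),
        b_within=b_w,
        b_within_se=y_fit.se("m_within"),
        c_prime=cp,
        c_prime_se=y_fit.se(x_col),
        indirect=a * b_b,
        total=cp + a * b_b,
        llf_free=y_fit.llf,
        llf_constrained=c_fit.llf,
        chisq_diff=stat,
        chisq_df=1,
        chisq_p=float(sps.chi2.sf(stat, df=1)),
        n=y_fit.n,
        m_fit=m_fit,
        y_fit=y_fit,
    )


def indirect_ci(
    result: MediationResult,
    method: str = "montecarlo",
    B: int = 5000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """CI and two-sided p for the indirect effect a * b_between.

    Monte-Carlo method: draw a and b_between from their (independent,
    per-equation) normal sampling distributions and take percentile bounds
    of the product. Returns (low, high, p).
    """
    if method != "montecarlo":
        raise ValueError("only the montecarlo method is implemented at this level; "
                         "use bootstrap_indirect for family resampling")
    if result.a_se == 0 and result.a == 0:
        return 0.0, 0.0, 1.0
    rng = np.random.default_rng(seed)
    a_draw = rng.normal(result.a, result.a_se, B)
    b_draw = rng.normal(result.b_between, result.b_between_se, B)
    prod = a_draw * b_draw
    lo, hi = np.percentile(prod, [2.5, 97.5])
    p = 2.0 * min((1 + (prod <= 0).sum()) / (B + 1), (1 + (prod >= 0).sum()) / (B + 1))
    return float(lo), float(hi), float(min(p, 1.0))


def bootstrap_indirect(
    data: pd.DataFrame,
    x_col: str,
    m_col: str,
    y_col: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    family_col: str = "family",
    B: int = 500,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Family-level case bootstrap CI for the indirect effect."""
    rng = np.random.default_rng(seed)
    fams = data[family_col].unique()
    groups = {f: sub for f, sub in data.groupby(family_col)}
    draws = []
    for _ in range(B):
        pick = rng.choice(fams, size=len(fams), replace=True)
        parts = []
        for i, f in enumerate(pick):
            sub = groups[f].copy()
            sub[family_col] = i  # resampled families are distinct clusters
            parts.append(sub)
        boot = pd.concat(parts, ignore_index=True)
        try:
            r = fit_mediation(boot, x_col, m_col, y_col, covariates, family_col)
            draws.append(r.indirect)
        except (MediationError, LmmError, np.linalg.LinAlgError):
            continue
    if not draws:
        raise MediationError("all bootstrap mediation refits failed")
    draws = np.array(draws)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    nb = len(draws)
    p = 2.0 * min((1 + (draws <= 0).sum()) / (nb + 1), (1 + (draws >= 0).sum()) / (nb + 1))
    return float(lo), float(hi), float(min(p, 1.0))


def compare_b_paths(free: MediationResult, constrained_llf: float | None = None):
    """Likelihood-ratio comparison of free vs constrained M -> Y paths.

    df is always 1 (one equality constraint). Both fits must come from the
    same data by ML; ``fit_mediation`` guarantees this internally.
    """
    llf_c = free.llf_constrained if constrained_llf is None else constrained_llf
    stat = max(2.0 * (free.llf_free - llf_c), 0.0)
    return stat, 1, float(sps.chi2.sf(stat, df=1))


def run_mediation_grid(
    data: pd.DataFrame,
    scales: tuple[tuple[str, str], ...] = (("int_p", "int_y"), ("ext_p", "ext_y"), ("tot_p", "tot_y")),
    measures: tuple[str, ...] = FEATURE_KEYS,
    adjust_baseline: bool = False,
    baseline_map: dict[str, str] | None = None,
    ci_B: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """One mediation model per (scale pair, connectivity measure).

    ``scales`` pairs a parental predictor with the matching youth outcome.
    With ``adjust_baseline`` the matching parent-reported youth baseline
    score (``baseline_map``, default ``<scale>_y_base``) joins the Y-equation
    covariates. FDR is applied over the grid's indirect-effect p-values.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(scales) * len(measures))
    i = 0
    for x_col, y_col in scales:
        for m_col in measures:
            covs: tuple[str, ...] = ("age", "sex")
            if adjust_baseline:
                base = (baseline_map or {}).get(x_col, f"{x_col[:3]}_y_base")
                if base not in data.columns:
                    raise MediationError(f"baseline column {base!r} not in table")
                covs = covs + (base,)
            res = fit_mediation(data, x_col, m_col, y_col, covariates=covs)
            lo, hi, p_ind = indirect_ci(res, B=ci_B, seed=int(seeds[i]))
            rows.append({
                "scale": x_col,
                "outcome": y_col,
                "measure": m_col,
                "a": res.a,
                "b_between": res.b_between,
                "b_within": res.b_within,
                "c_prime": res.c_prime,
                "indirect": res.indirect,
                "total": res.total,
                "indirect_ci_low": lo,
                "indirect_ci_high": hi,
                "p_indirect": p_ind,
                "chisq_diff": res.chisq_diff,
                "chisq_df": res.chisq_df,
                "chisq_p": res.chisq_p,
                "n": res.n,
            })
            i += 1
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p_indirect"].to_numpy())
    return out
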