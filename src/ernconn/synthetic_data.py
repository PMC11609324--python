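"""Synthetic cohorts, connectivity and toy atlases with the study's structure.

The generators emulate the statistical features the analysis relies on:
families of 1-3 children recruited across ~21 acquisition sites, right-
skewed count-like psychopathology sum scores with a modest parent-youth
correlation, connectivity features whose within-network means exceed the
between-network means, site batch effects (additive and multiplicative),
family random intercepts, and small planted standardized effects of the
scores on individual connectivity features. Every generator is fully
deterministic under its seed.

Scores are drawn from negative-binomial marginals coupled through a
Gaussian copula: parental scores are family-level (shared by siblings),
youth scores child-level with a configurable cross-correlation to the
parental scores of the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity_features import ConnectivityMatrix
from .netdef_atlas import BETWEEN_KEYS, FEATURE_KEYS, NETWORK_IDS, WITHIN_KEYS, LabelVolume, NetworkDefinition, NetworkParcelMap

# family-size distribution observed in the study sample: 3709 / 236 / 7
# families with one, two and three participating children out of 3952
SIBLING_PROBS = (3709 / 3952, 236 / 3952, 7 / 3952)


@dataclass(frozen=True)
class ScoreParams:
    """Negative-binomial marginal for one sum score."""

    mean: float
    dispersion: float  # NB size parameter; smaller = more right-skewed


@dataclass(frozen=True)
class MediationPaths:
    """Planted structural paths for the mediation generator."""

    a: float = 0.0
    b_between: float = 0.0
    b_within: float = 0.0
    c_prime: float = 0.0


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    Defaults mirror the study sample: 3952 families with sibling
    probabilities from the observed 3709/236/7 split, 21 sites, parent-youth
    score correlation 0.15 (inside the reported 0.1-0.2 band), within-network
    connectivity means above between-network means, and planted standardized
    effects of magnitude ~0.04-0.05 when a non-null grid is requested.
    """

    n_families: int = 3952
    sibling_probs: tuple[float, float, float] = SIBLING_PROBS
    n_sites: int = 21
    seed: int = 0

    # scores (sum-score marginals; parental ASR-like, youth BPM-like)
    score_params: dict = field(default_factory=lambda: {
        "int_p": ScoreParams(7.0, 1.2),
        "ext_p": ScoreParams(5.0, 1.2),
        "tot_p": ScoreParams(25.0, 1.5),
        "int_y": ScoreParams(3.0, 1.0),
        "ext_y": ScoreParams(2.5, 1.0),
        "tot_y": ScoreParams(7.0, 1.2),
    })
    parent_youth_r: float = 0.15   # copula cross-correlation, same scale
    scale_block_r: float = 0.6     # correlation among the three scales
    youth_family_share: float = 0.2  # sibling-shared share of youth latent
    baseline_r: float = 0.5        # youth baseline vs follow-up latent corr
    with_baseline: bool = False

    # demographics
    age_mean: float = 10.0
    age_sd: float = 0.6
    p_female: float = 0.509

    # connectivity features (Fisher-z scale)
    within_means: tuple[float, ...] = (0.40, 0.32, 0.28, 0.30)
    between_means: tuple[float, ...] = (0.12, 0.10, 0.11, 0.13, 0.15, 0.10)
    family_intercept_sd: float = 0.05
    feature_noise_sd: float = 0.10
    site_additive_sd: float = 0.10
    site_scale_range: tuple[float, float] = (0.8, 1.25)

    # planted standardized effects: (scale column, feature key) -> beta
    planted_effects: dict = field(default_factory=dict)
    mediation_paths: MediationPaths = field(default_factory=MediationPaths)

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if abs(sum(self.sibling_probs) - 1.0) > 1e-9:
            raise ValueError("sibling probabilities must sum to 1")
        for (s, f), b in self.planted_effects.items():
            if abs(b) >= 1:
                raise ValueError(f"planted |beta| must be < 1, got {b} for ({s}, {f})")
            if f not in FEATURE_KEYS:
                raise ValueError(f"unknown feature key {f!r} in planted effects")

    @property
    def feature_means(self) -> dict[str, float]:
        out = dict(zip(WITHIN_KEYS, self.within_means))
        out.update(zip(BETWEEN_KEYS, self.between_means))
        return out


def reported_effects_config(seed: int = 0) -> SimulationConfig:
    """Defaults plus the reported grid of significant standardized effects."""
    effects = {
        ("int_p", "ERN3"): -0.04,
        ("int_p", "ERN12"): -0.04,
        ("int_p", "ERN24"): 0.04,
        ("ext_p", "ERN4"): -0.05,
        ("tot_p", "ERN3"): -0.04,
        ("tot_p", "ERN4"): -0.04,
        ("tot_p", "ERN12"): -0.05,
        ("tot_p", "ERN24"): 0.04,
    }
    return SimulationConfig(seed=seed, planted_effects=effects,
                            mediation_paths=MediationPaths(c_prime=0.17))


def _block_corr(k: int, r: float) -> np.ndarray:
    return np.full((k, k), r) + (1 - r) * np.eye(k)


def _nb_transform(latent: np.ndarray, params: ScoreParams) -> np.ndarray:
    u = sps.norm.cdf(latent)
    k = params.dispersion
    p = k / (k + params.mean)
    return sps.nbinom.ppf(np.clip(u, 1e-12, 1 - 1e-12), k, p)


def simulate_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Phenotype table: ids, demographics and psychopathology scores.

    Parental scores are constant within family; youth scores carry a
    sibling-shared component and the configured cross-correlation with the
    same-scale parental score.
    """
    rng = np.random.default_rng(cfg.seed)
    nf = cfg.n_families
    sizes = rng.choice([1, 2, 3], size=nf, p=cfg.sibling_probs)
    fam = np.repeat(np.arange(nf), sizes)
    n = len(fam)
    site = rng.integers(0, cfg.n_sites, size=nf)[fam]

    L = np.linalg.cholesky(_block_corr(3, cfg.scale_block_r))
    parent_lat = rng.standard_normal((nf, 3)) @ L.T           # family level
    fam_shared = rng.standard_normal((nf, 3)) @ L.T
    child_noise = rng.standard_normal((n, 3)) @ L.T
    r, phi = cfg.parent_youth_r, cfg.youth_family_share
    eta = np.sqrt(phi) * fam_shared[fam] + np.sqrt(1 - phi) * child_noise
    youth_lat = r * parent_lat[fam] + np.sqrt(1 - r**2) * eta

    data = {
        "subject": [f"S{i:05d}" for i in range(n)],
        "family": fam,
        "site": site,
        "age": rng.normal(cfg.age_mean, cfg.age_sd, size=n),
        "sex": (rng.random(n) < cfg.p_female).astype(int),  # 1 = female
    }
    for j, s in enumerate(("int_p", "ext_p", "tot_p")):
        data[s] = _nb_transform(parent_lat[fam, j], cfg.score_params[s])
    for j, s in enumerate(("int_y", "ext_y", "tot_y")):
        data[s] = _nb_transform(youth_lat[:, j], cfg.score_params[s])
    if cfg.with_baseline:
        base_noise = rng.standard_normal((n, 3)) @ L.T
        rb = cfg.baseline_r
        base_lat = rb * youth_lat + np.sqrt(1 - rb**2) * base_noise
        for j, s in enumerate(("int_y", "ext_y", "tot_y")):
            data[s[:3] + "_y_base"] = _nb_transform(base_lat[:, j], cfg.score_params[s])
    return pd.DataFrame(data)


def _planted_shift(cohort: pd.DataFrame, cfg: SimulationConfig) -> np.ndarray:
    """(n x 10) additive shifts realizing the planted standardized betas."""
    n = len(cohort)
    shift = np.zeros((n, len(FEATURE_KEYS)))
    sigma0 = float(np.hypot(cfg.family_intercept_sd, cfg.feature_noise_sd))
    for (scale, feat), beta in cfg.planted_effects.items():
        x = cohort[scale].to_numpy(dtype=float)
        xz = (x - x.mean()) / x.std()
        slope = beta * sigma0 / np.sqrt(1 - beta**2)
        shift[:, FEATURE_KEYS.index(feat)] += slope * xz
    return shift


def simulate_features(cohort: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Cohort plus the 10 connectivity features (feature-level emission).

    feature = network-pair mean + planted effects + site additive offset
    + site scale factor * (family intercept + subject noise).
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    n = len(cohort)
    fam_codes = pd.factorize(cohort["family"])[0]
    nf = fam_codes.max() + 1
    mu = np.array([cfg.feature_means[k] for k in FEATURE_KEYS])
    u = rng.normal(0.0, cfg.family_intercept_sd, size=(nf, len(FEATURE_KEYS)))
    eps = rng.normal(0.0, cfg.feature_noise_sd, size=(n, len(FEATURE_KEYS)))

    site_codes = pd.factorize(cohort["site"])[0]
    ns = site_codes.max() + 1
    add = rng.normal(0.0, cfg.site_additive_sd, size=(ns, len(FEATURE_KEYS)))
    lo, hi = cfg.site_scale_range
    scale = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(ns, len(FEATURE_KEYS))))

    feats = (mu + _planted_shift(cohort, cfg)
             + add[site_codes]
             + scale[site_codes] * (u[fam_codes] + eps))
    out = cohort.copy()
    out[list(FEATURE_KEYS)] = feats
    return out


def toy_network_parcel_map(parcels_per_network: int = 3) -> NetworkParcelMap:
    """Deterministic parcel map: consecutive ids, k parcels per network."""
    assignment = {}
    pid = 1
    for net in NETWORK_IDS:
        for _ in range(parcels_per_network):
            assignment[pid] = net
            pid += 1
    return NetworkParcelMap(assignment=assignment)


def simulate_connectivity(
    cohort: pd.DataFrame,
    cfg: SimulationConfig,
    pmap: NetworkParcelMap | None = None,
    mode: str = "features",
    pair_jitter_sd: float = 0.05,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, ConnectivityMatrix]]:
    """Emit connectivity at feature level or as full parcel matrices.

    Both modes share the same seeded feature draw; matrix mode expands each
    subject's features into a symmetric parcel matrix whose block means
    equal the features exactly (pair-level jitter is de-meaned per block),
    so feature extraction reproduces the planted values.
    """
    table = simulate_features(cohort, cfg)
    if mode == "features":
        return table
    if mode != "matrices":
        raise ValueError(f"mode must be 'features' or 'matrices', got {mode!r}")
    pmap = pmap or toy_network_parcel_map()
    by_net = pmap.parcels_by_network()
    parcels = sorted(pmap.assignment)
    pos = {p: i for i, p in enumerate(parcels)}
    P = len(parcels)
    blocks = []  # (feature key, index pairs of the block's upper triangle)
    for key in WITHIN_KEYS:
        ids = [pos[p] for p in by_net[key]]
        blocks.append((key, [(i, j) for a, i in enumerate(ids) for j in ids[a + 1:]]))
    for key in BETWEEN_KEYS:
        ia = [pos[p] for p in by_net["ERN" + key[3]]]
        ib = [pos[p] for p in by_net["ERN" + key[4]]]
        blocks.append((key, [(min(i, j), max(i, j)) for i in ia for j in ib]))

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    matrices = {}
    for _, row in table.iterrows():
        m = np.zeros((P, P))
        for key, pairs in blocks:
            vals = rng.normal(0.0, pair_jitter_sd, size=len(pairs))
            vals = vals - vals.mean() + row[key]  # block mean == feature
            for (i, j), v in zip(pairs, vals):
                m[i, j] = m[j, i] = v
        matrices[row["subject"]] = ConnectivityMatrix(values=m, parcel_ids=np.array(parcels))
    return table, matrices


def simulate_mediation_cohort(
    paths: MediationPaths,
    n_families: int = 2000,
    sibling_pair_prob: float = 0.3,
    x_col: str = "int_p",
    m_col: str = "ERN3",
    y_col: str = "int_y",
    n_sites: int = 21,
    family_m_sd: float = 0.55,
    family_y_sd: float = 0.3,
    with_baseline: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort generated from the structural mediation model.

    X is family-level standard normal; the mediator has an explicit family
    component (through which the between path acts) and a child component
    (within path); Y adds the direct effect and a family intercept. All
    structural variables are scaled to unit total variance so the planted
    standardized paths are recovered directly.
    """
    rng = np.random.default_rng(seed)
    sizes = np.where(rng.random(n_families) < sibling_pair_prob, 2, 1)
    fam = np.repeat(np.arange(n_families), sizes)
    n = len(fam)
    x_f = rng.standard_normal(n_families)

    a, bb, bw, cp = paths.a, paths.b_between, paths.b_within, paths.c_prime
    var_mb = a**2 + family_m_sd**2
    if var_mb >= 1.0:
        raise ValueError("a and family_m_sd imply mediator variance > 1")
    sd_mw = np.sqrt(1.0 - var_mb)
    u_m = rng.normal(0.0, family_m_sd, n_families)
    m_between_true = a * x_f + u_m
    m_within_true = rng.normal(0.0, sd_mw, n)
    m = m_between_true[fam] + m_within_true

    struct_var = (cp**2 + bb**2 * var_mb + bw**2 * sd_mw**2
                  + 2 * cp * bb * a + family_y_sd**2)
    if struct_var >= 1.0:
        raise ValueError("planted paths imply outcome variance > 1")
    sd_eps = np.sqrt(1.0 - struct_var)
    v_y = rng.normal(0.0, family_y_sd, n_families)
    y = (cp * x_f[fam] + bb * m_between_true[fam] + bw * m_within_true
         + v_y[fam] + rng.normal(0.0, sd_eps, n))

    out = pd.DataFrame({
        "subject": [f"S{i:05d}" for i in range(n)],
        "family": fam,
        "site": rng.integers(0, n_sites, n_families)[fam],
        "age": rng.normal(10.0, 0.6, n),
        "sex": (rng.random(n) < 0.509).astype(int),
        x_col: x_f[fam],
        m_col: m,
        y_col: y,
    })
    if with_baseline:
        out[x_col[:3] + "_y_base"] = rng.standard_normal(n)
    return out


def simulate_label_volume(
    shape: tuple[int, int, int] = (24, 24, 24),
    n_parcels: int = 8,
    voxel_size_mm: float = 2.0,
    seed: int = 0,
) -> tuple[LabelVolume, NetworkDefinition, dict[int, str]]:
    """Toy parcellation + matching peak table with a known assignment.

    The grid is tiled into ``n_parcels`` contiguous nearest-seed (Voronoi)
    parcels; one ROI peak is placed at each parcel seed and networks are
    assigned round-robin, so the expected overlap table and unique
    assignment are known by construction. Returns (volume, definition,
    planted parcel -> network map).
    """
    if n_parcels > np.prod(shape):
        raise ValueError("more parcels than voxels")
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(shape) - 1) / 2.0

    # distinct seed voxels, then nearest-seed labelling (contiguous cells)
    flat = rng.choice(np.prod(shape), size=n_parcels, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, shape)).astype(float)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    d2 = ((vox[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    grid = (np.argmin(d2, axis=1) + 1).reshape(shape).astype(np.int32)
    vol = LabelVolume(grid=grid, affine=affine)

    planted = {pid: NETWORK_IDS[(pid - 1) % len(NETWORK_IDS)] for pid in range(1, n_parcels + 1)}
    seeds_mm = vol.voxel_to_mm(seeds)
    rows = [{"network": planted[pid], "label": f"peak_{pid}",
             "x": seeds_mm[pid - 1, 0], "y": seeds_mm[pid - 1, 1], "z": seeds_mm[pid - 1, 2]}
            for pid in range(1, n_parcels + 1)]
    nets = NetworkDefinition(table=pd.DataFrame(rows))
    return vol, nets, planted


def simulate_item_scores(
    n_subjects: int = 500,
    n_items: int = 10,
    loading: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordinal 0/1/2 item responses from a one-factor model (for alpha)."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_subjects)
    lat = loading * f[:, None] + np.sqrt(1 - loading**2) * rng.standard_normal((n_subjects, n_items))
    items = np.digitize(lat, [0.5, 1.5])  # right-skewed 0/1/2 responses
    return pd.DataFrame(items, columns=[f"item{j}" for j in range(n_items)])


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Internal consistency: alpha = k/(k-1) * (1 - sum(var_i)/var(total))."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var < 1e-12:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
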