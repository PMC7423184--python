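"""Permutation-calibrated SKAT-O rare-variant gene-set association.

For a gene's rare-variant genotype block ``G`` (samples x variants) and
null-model residuals ``r = y - mu``, the family of statistics indexed by
``rho`` interpolates the variance-component (SKAT) and burden scores:

    Q_skat   = sum_j w_j^2 (G_j' r)^2
    Q_burden = (sum_j w_j G_j' r)^2
    Q_rho    = (1 - rho) Q_skat + rho Q_burden

with Beta(1, 25)-density weights ``w_j`` on each variant's minor allele
frequency.  The optimal test takes, per permutation, the minimum over the
rho grid of the per-rho empirical p-value; the reported p is the
permutation p of that minimum, so the grid search is nulled correctly.
Calibration is purely by permutation -- no Davies/Liu mixture machinery.

Rare variants are defined per contrast by the adaptive threshold
``MAF < 1/sqrt(2n)`` over called alleles; variants with call rate below
the missingness cutoff are dropped and remaining missing dosages are
mean-imputed within the contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

from ._rng import derive_rng
from .datatypes import CohortDesign, GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)

#: rho grid of the original optimal-test formulation: squares of 0, .1, ..., .9 plus 1.
DEFAULT_RHO_GRID: tuple[float, ...] = tuple(np.round((np.arange(10) / 10.0) ** 2, 2)) + (1.0,)

PRIMARY_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("long_survivor", "random"),
    ("stroke", "random"),
    ("stroke", "long_survivor"),
)
CONTROL_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("stroke", "control"),
    ("long_survivor", "control"),
    ("random", "control"),
)


@dataclass(frozen=True)
class SkatConfig:
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    weight_beta: tuple[float, float] = (1.0, 25.0)
    missingness_cutoff: float = 0.9
    n_permutations: int = 100_000
    alpha: float = 0.05
    alpha_adjusted: float = 0.017
    min_rare_variants: int = 2
    permute: str = "phenotype"
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(self.rho_grid)
        if 0.0 not in grid or 1.0 not in grid:
            raise ValueError("rho grid must contain 0 and 1")
        if list(grid) != sorted(grid):
            raise ValueError("rho grid must be ascending")
        if not 0.0 < self.missingness_cutoff <= 1.0:
            raise ValueError("missingness cutoff must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.alpha_adjusted < 1.0:
            raise ValueError("significance levels must lie in (0, 1)")
        if self.permute not in ("phenotype", "residual"):
            raise ValueError("permute must be 'phenotype' or 'residual'")
        if self.min_rare_variants < 1:
            raise ValueError("min_rare_variants must be >= 1")


@dataclass
class SkatResult:
    gene: str
    contrast: str
    n_rare: int
    q_rho: dict[float, float]
    rho_min: float
    p_empirical: float
    n_perm: int


def adaptive_maf_threshold(n: int) -> float:
    """Per-comparison rare-variant cutoff ``1/sqrt(2n)`` for n individuals."""
    if n < 2:
        raise ValueError("need at least 2 individuals")
    return 1.0 / np.sqrt(2.0 * n)


@dataclass
class NullModel:
    """Logistic null fit: fitted means, residuals and variance weights."""

    mu: np.ndarray
    residuals: np.ndarray
    weights: np.ndarray = field(repr=False)
    method: str = "glm"


def fit_null_model(y: np.ndarray, covariates: np.ndarray | None = None) -> NullModel:
    """Logistic regression of the group indicator on intercept + covariates.

    Returns residuals ``y - mu`` and variance weights ``mu (1 - mu)``.
    Under separation (or non-convergence) the fit falls back to a
    ridge-stabilized logistic regression and warns.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((len(y), 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    x = sm.add_constant(covariates, has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank-deficient after adding intercept")
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    method = "glm"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100)
        mu = np.asarray(fit.mu)
        if not fit.converged or np.any(mu < 1e-8) or np.any(mu > 1 - 1e-8):
            raise RuntimeError("separation suspected")
    except Exception:
        from sklearn.linear_model import LogisticRegression

        warnings.warn(
            "logistic null model separated or failed to converge; "
            "using ridge-stabilized fit",
            RuntimeWarning,
            stacklevel=2,
        )
        ridge = LogisticRegression(C=1.0, max_iter=1000)
        ridge.fit(x, y.astype(int))
        mu = ridge.predict_proba(x)[:, 1]
        method = "ridge"
    return NullModel(mu=mu, residuals=y - mu, weights=mu * (1 - mu), method=method)


def genotype_pca(matrix: GenotypeMatrix, k: int,
                 sample_idx: np.ndarray | None = None) -> np.ndarray:
    """Top-k principal-component scores of the standardized genotype matrix.

    Missing dosages are mean-imputed; columns are centered and scaled by
    ``sqrt(2 p (1 - p))``.  Deterministic up to sign, which is fixed by
    making each component's largest-magnitude loading positive.
    """
    d = matrix.dosages if sample_idx is None else matrix.dosages[sample_idx]
    n = d.shape[0]
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return np.empty((n, 0))
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    x = d.astype(float)
    x[x == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    nan_cols = np.isnan(col_mean)
    col_mean[nan_cols] = 0.0
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    p = col_mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0
    if not keep.any():
        raise ValueError("genotype matrix is constant; PCA undefined")
    x = (x[:, keep] - col_mean[keep]) / scale[keep]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _prepare_gene(
    dosages: np.ndarray, config: SkatConfig, maf_threshold: float
):
    """Missingness / rarity filtering plus imputation and minor-allele coding.

    Returns ``(G, maf)`` for the qualifying rare variants, or ``None`` when
    fewer than ``min_rare_variants`` survive.  Zero-variance columns are
    dropped and logged.
    """
    d = dosages.astype(float)
    called = d != MISSING
    call_rate = called.mean(axis=0)
    d = d[:, call_rate >= config.missingness_cutoff]
    called = called[:, call_rate >= config.missingness_cutoff]
    if d.shape[1] == 0:
        return None
    alt = np.where(called, d, 0.0).sum(axis=0)
    denom = 2.0 * called.sum(axis=0)
    p = np.where(denom > 0, alt / np.maximum(denom, 1.0), 0.0)
    maf = np.minimum(p, 1.0 - p)
    rare = (maf > 0) & (maf < maf_threshold)
    d, called, p = d[:, rare], called[:, rare], p[rare]
    if d.shape[1] < config.min_rare_variants:
        return None
    # mean-impute within contrast, flip to minor-allele coding
    col_mean = 2.0 * p
    d = np.where(called, d, col_mean)
    flip = p > 0.5
    d[:, flip] = 2.0 - d[:, flip]
    maf = np.minimum(p, 1.0 - p)
    variance = d.var(axis=0)
    if (variance == 0).any():
        logger.debug("dropping %d zero-variance columns", int((variance == 0).sum()))
        d, maf = d[:, variance > 0], maf[variance > 0]
    if d.shape[1] < config.min_rare_variants:
        return None
    return d, maf


def skat_weights(maf: np.ndarray, weight_beta: tuple[float, float]) -> np.ndarray:
    """Beta-density weights on minor allele frequency (canonical (1, 25))."""
    a1, a2 = weight_beta
    return beta_dist.pdf(np.asarray(maf, dtype=float), a1, a2)


def skat_q(genotypes: np.ndarray, weights: np.ndarray, residuals: np.ndarray):
    """``(Q_skat, Q_burden)`` for one residual vector (or matrix of columns)."""
    s = genotypes.T @ residuals  # (m,) or (m, B)
    q_skat = (weights ** 2) @ (s ** 2) if s.ndim == 2 else float((weights ** 2) @ (s ** 2))
    burden = weights @ s
    q_burden = burden ** 2
    return q_skat, q_burden


def _pooled_min_p(q: np.ndarray) -> np.ndarray:
    """Per-column min over rho of pooled exceedance p-values.

    ``q`` is (n_rho, B+1) with the observed statistic in column 0.  For
    each rho, every column's p is its exceedance fraction among all B+1
    columns (ties counted, each column counting itself), which keeps the
    observed and permuted statistics exchangeable under the null.
    """
    n_cols = q.shape[1]
    p = np.empty_like(q)
    for i in range(q.shape[0]):
        ranks = rankdata(q[i], method="min")  # ascending
        p[i] = (n_cols + 1 - ranks) / n_cols
    return p.min(axis=0)


def skat_o_test(
    dosages: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    config: SkatConfig,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
    perm_residuals: np.ndarray | None = None,
) -> SkatResult | None:
    """SKAT-O with permutation-calibrated min-p over the rho grid.

    ``dosages`` is (contrast samples x variants) raw dosage with
    :data:`MISSING` sentinels; ``y`` the 0/1 phenotype.  Permutations
    shuffle phenotype labels (refitting the null when covariates are
    present) or residuals, per ``config.permute``; ``perm_residuals`` lets
    a caller supply a precomputed (n x B) residual ensemble shared across
    genes, which is how phenotype permutation with covariates is run
    efficiently.  With ``exhaustive``, all distinct label assignments are
    enumerated instead.  Returns ``None`` for genes with fewer than
    ``min_rare_variants`` qualifying rare variants.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    prepared = _prepare_gene(dosages, config, adaptive_maf_threshold(n))
    if prepared is None:
        return None
    g, maf = prepared
    w = skat_weights(maf, config.weight_beta)
    null = fit_null_model(y, covariates)
    r_obs = null.residuals

    if exhaustive:
        n_a = int(y.sum())
        total = comb(n, n_a)
        if total > 20_000:
            raise ValueError(f"{total} assignments exceed the exhaustive limit")

        def _residual(y_vec: np.ndarray) -> np.ndarray:
            if covariates is None:
                return y_vec - y_vec.mean()
            return y_vec - fit_null_model(y_vec, covariates).mu

        columns = []
        for subset in combinations(range(n), n_a):
            y_perm = np.zeros(n)
            y_perm[list(subset)] = 1.0
            columns.append(_residual(y_perm))
        # The observed column goes through the identical code path as the
        # ensemble so knife-edge ties resolve consistently.
        r_matrix = np.column_stack([_residual(y)] + columns)
        n_perm = total
        pooled = False
    else:
        b = config.n_permutations
        if perm_residuals is not None:
            r_matrix = np.column_stack([r_obs, perm_residuals])
        else:
            if rng is None:
                rng = derive_rng(config.seed, "skat")
            if config.permute == "phenotype" and covariates is not None:
                cols = np.empty((n, b))
                for j in range(b):
                    y_perm = rng.permutation(y)
                    cols[:, j] = y_perm - fit_null_model(y_perm, covariates).mu
                r_matrix = np.column_stack([r_obs, cols])
            else:
                # Without covariates, permuting the phenotype and permuting
                # the residuals are the same operation (mu is constant).
                perms = rng.permuted(np.tile(r_obs, (b, 1)), axis=1).T
                r_matrix = np.column_stack([r_obs, perms])
        n_perm = b
        pooled = True

    q_skat, q_burden = skat_q(g, w, r_matrix)
    rho = np.asarray(config.rho_grid)
    q = (1.0 - rho)[:, None] * q_skat[None, :] + rho[:, None] * q_burden[None, :]

    if pooled:
        min_p = _pooled_min_p(q)
        p_emp = float((1 + (min_p[1:] <= min_p[0]).sum()) / (1 + n_perm))
    else:
        # Exhaustive: the assignment ensemble (columns 1..) includes the
        # observed labelling; p is the exact exceedance fraction.
        ensemble = q[:, 1:]
        total = ensemble.shape[1]
        p_rho = np.empty_like(q)
        for i in range(q.shape[0]):
            p_rho[i] = (ensemble[i][None, :] >= q[i][:, None]).sum(axis=1) / total
        min_p = p_rho.min(axis=0)
        p_emp = float((min_p[1:] <= min_p[0]).sum() / total)

    p_obs_per_rho = _per_rho_observed_p(q)
    rho_min = float(rho[int(np.argmin(p_obs_per_rho))])
    return SkatResult(
        gene="", contrast="", n_rare=g.shape[1],
        q_rho={float(r_): float(q_) for r_, q_ in zip(rho, q[:, 0])},
        rho_min=rho_min, p_empirical=p_emp, n_perm=n_perm,
    )


def _per_rho_observed_p(q: np.ndarray) -> np.ndarray:
    """Observed column's exceedance p at each rho (for reporting rho_min)."""
    n_cols = q.shape[1]
    return ((q[:, 1:] >= q[:, [0]]).sum(axis=1) + 1) / n_cols


def phenotype_permutation_residuals(
    y: np.ndarray,
    covariates: np.ndarray | None,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n x B) residual ensemble from permuted phenotypes with null refits."""
    y = np.asarray(y, dtype=float)
    out = np.empty((len(y), n_permutations))
    for j in range(n_permutations):
        y_perm = rng.permutation(y)
        if covariates is None:
            out[:, j] = y_perm - y_perm.mean()
        else:
            out[:, j] = y_perm - fit_null_model(y_perm, covariates).mu
    return out


def run_contrasts(
    matrix: GenotypeMatrix,
    assignments: dict[str, list[int]],
    cohort: CohortDesign,
    config: SkatConfig,
    contrasts: list[tuple[str, str]] | None = None,
    use_age: bool = True,
    n_pcs: int = 0,
) -> pd.DataFrame:
    """SKAT-O across genes for each resolvable contrast; tidy result table.

    Covariates are age and, when ``n_pcs > 0``, genotype principal
    components computed on the full cohort (population-stratification
    adjustment).  Contrasts whose groups are absent are skipped with a
    warning.  Significance flags are at ``alpha`` for all contrasts and
    additionally at the Bonferroni-adjusted level for the three primary
    case-case comparisons.
    """
    if contrasts is None:
        contrasts = list(PRIMARY_CONTRASTS + CONTROL_CONTRASTS)
    pcs = genotype_pca(matrix, n_pcs) if n_pcs > 0 else None

    rows = []
    present = set(cohort.groups)
    for contrast in contrasts:
        group_a, group_b = contrast
        if group_a not in present or group_b not in present:
            warnings.warn(f"skipping contrast {group_a}:{group_b}: group absent",
                          stacklevel=2)
            continue
        idx, y = cohort.contrast(group_a, group_b)
        order = np.argsort(idx)
        idx, y = idx[order], y[order]
        cov_blocks = []
        if use_age:
            cov_blocks.append(cohort.ages[idx][:, None])
        if pcs is not None:
            cov_blocks.append(pcs[idx])
        cov = np.hstack(cov_blocks) if cov_blocks else None

        shared = None
        if config.permute == "phenotype" and cov is not None:
            rng = derive_rng(config.seed, "skat-refits", group_a, group_b)
            shared = phenotype_permutation_residuals(
                y, cov, config.n_permutations, rng
            )
        is_primary = contrast in PRIMARY_CONTRASTS
        for gene in sorted(assignments):
            site_idx = assignments[gene]
            if not site_idx:
                continue
            d = matrix.dosages[np.ix_(idx, np.asarray(site_idx, dtype=int))]
            rng = derive_rng(config.seed, "skat", gene, group_a, group_b)
            res = skat_o_test(
                d, y, cov, config, rng=rng, perm_residuals=shared
            )
            if res is None:
                continue
            rows.append(
                (
                    f"{group_a}:{group_b}", gene, res.n_rare, res.rho_min,
                    res.p_empirical, res.n_perm, config.seed,
                    res.p_empirical <= config.alpha,
                    is_primary and res.p_empirical <= config.alpha_adjusted,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["comparison", "gene", "n_variants", "statistic",
                 "p_empirical", "n_perm", "seed",
                 "significant_alpha", "significant_adjusted"],
    )
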