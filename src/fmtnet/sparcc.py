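"""SparCC: correlation inference for compositional count data.

Sequencing counts only carry relative information, so naive correlations of
fractions are badly biased.  SparCC instead works from the variance of
log-ratios T_ij = Var log(x_i/x_j), which is invariant to per-sample depth.
Under a sparsity assumption (most taxa uncorrelated), the latent per-taxon
"basis" variances ω solve the linear system

    [(p-2)·I + J] ω = t,    t_i = Σ_{j≠i} T_ij,

and basis correlations follow as r_ij = (ω_i + ω_j − T_ij) / (2 √(ω_i ω_j)).
Strongly correlated pairs violate the sparsity assumption, so the estimator
iteratively excludes the single strongest pair above a threshold and
re-solves.  Significance comes from a permutation null that shuffles each
taxon's counts across samples independently, preserving marginals.

Counts are made strictly positive with a pseudocount (the study sets 0.05)
before closure to fractions; an optional Dirichlet inner resampling replaces
the point-estimate fractions with posterior draws (median r over draws).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SparccConfig:
    """Tuning knobs for the basis-correlation estimator.

    pseudocount
        Added to every cell before closure; keeps log-ratios finite (0.05 in
        the study).  ``pseudocount_zeros_only`` restricts it to zero cells.
    exclusion_threshold, max_exclusion_iters
        Strong-pair exclusion: per iteration the single largest |r| above the
        threshold is removed from the sums and ω re-solved, stopping early if
        any involved taxon would drop below 3 partners.
    n_inner
        Dirichlet posterior resamples of the fractions; 0 (default) is the
        deterministic point-estimate mode, 20 a typical resampling setting.
    n_boot
        Permutation-null replicates for p-values.
    """

    pseudocount: float = 0.05
    pseudocount_zeros_only: bool = False
    exclusion_threshold: float = 0.1
    max_exclusion_iters: int = 10
    n_inner: int = 0
    n_boot: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not (0 < self.exclusion_threshold < 1):
            raise ValueError("exclusion_threshold must be in (0,1)")


@dataclass
class CorrelationMatrix:
    """Symmetric basis-correlation estimate with optional companion p-values."""

    asv_ids: list[str]
    r: np.ndarray
    p: np.ndarray | None = None

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.asv_ids, columns=self.asv_ids)

    def p_frame(self) -> pd.DataFrame:
        if self.p is None:
            raise ValueError("no p-values attached")
        return pd.DataFrame(self.p, index=self.asv_ids, columns=self.asv_ids)


def _to_matrix(counts) -> tuple[np.ndarray, list[str]]:
    if hasattr(counts, "counts"):  # AsvTable
        df = counts.counts
        return df.to_numpy(dtype=float), list(df.index)
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index)
    arr = np.asarray(counts, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def _fractions(mat: np.ndarray, config: SparccConfig) -> np.ndarray:
    x = mat.copy()
    if config.pseudocount_zeros_only:
        x[x == 0] = config.pseudocount
    else:
        x = x + config.pseudocount
    return x / x.sum(axis=0, keepdims=True)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """T_ij = sample variance over samples of log(x_i/x_j) (taxa x samples in).

    Fractions must be strictly positive; a zero means the pseudocount step
    was skipped.  T is symmetric with zero diagonal.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[1] < 4:
        raise ValueError("need n >= 4 samples")
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive (apply a pseudocount)")
    logx = np.log(fractions)
    cov = np.cov(logx)  # taxa x taxa, ddof=1
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def _solve_basis(t_mat: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Basis variances ω from the log-ratio variance sums.

    ``excluded`` is a symmetric boolean mask of pairs dropped from the sums;
    the system's row i sums over included partners only.
    """
    p = t_mat.shape[0]
    include = ~excluded
    np.fill_diagonal(include, False)
    m = include.astype(float)
    np.fill_diagonal(m, include.sum(axis=1))
    t_vec = (t_mat * include).sum(axis=1)
    omega = np.linalg.solve(m, t_vec)
    return np.maximum(omega, 1e-12)


def _correlations(t_mat: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    r = (omega[:, None] + omega[None, :] - t_mat) / denom
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _basis_r_from_t(t_mat: np.ndarray, config: SparccConfig) -> np.ndarray:
    p = t_mat.shape[0]
    excluded = np.zeros((p, p), dtype=bool)
    try:
        omega = _solve_basis(t_mat, excluded)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular basis system for p={p} taxa: {err}"
        ) from err
    r = _correlations(t_mat, omega)
    for _ in range(config.max_exclusion_iters):
        cand = np.abs(np.triu(np.where(excluded, 0.0, r), k=1))
        np.fill_diagonal(cand, 0.0)
        if cand.max() <= config.exclusion_threshold:
            break
        # largest |r|; ties broken by lowest (i, j) in row-major order
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        partners = (~excluded).sum(axis=1) - 1
        if partners[i] - 1 < 3 or partners[j] - 1 < 3:
            break
        excluded[i, j] = excluded[j, i] = True
        omega = _solve_basis(t_mat, excluded)
        r = _correlations(t_mat, omega)
    return r


def basis_correlations(counts, config: SparccConfig | None = None) -> CorrelationMatrix:
    """Estimate basis correlations from a taxa-x-samples count matrix.

    Needs p >= 4 taxa (the basis decomposition is under-determined below);
    p < 10 triggers a warning.  In point mode (``n_inner = 0``) the result is
    deterministic; with Dirichlet resampling the element-wise median over
    ``n_inner`` draws is returned.
    """
    config = config or SparccConfig()
    mat, ids = _to_matrix(counts)
    p, n = mat.shape
    if p < 4:
        raise ValueError(f"basis_correlations requires >= 4 taxa, got {p}")
    if p < 10:
        logger.warning("basis_correlations: only %d taxa; estimates are unstable", p)
    if config.n_inner == 0:
        frac = _fractions(mat, config)
        r = _basis_r_from_t(log_ratio_variances(frac), config)
    else:
        rng = np.random.default_rng(config.seed)
        draws = np.empty((config.n_inner, p, p))
        alpha = mat + config.pseudocount
        for k in range(config.n_inner):
            frac = np.column_stack(
                [rng.dirichlet(alpha[:, s]) for s in range(n)]
            )
            draws[k] = _basis_r_from_t(log_ratio_variances(frac), config)
        r = np.median(draws, axis=0)
        np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(ids, r)


def sparcc_pvalues(counts, r_obs: CorrelationMatrix, config: SparccConfig | None = None) -> np.ndarray:
    """Two-sided permutation p-values for an observed correlation matrix.

    Each bootstrap permutes every taxon's counts across samples independently
    (destroying correlation, preserving marginals) and re-estimates r; the
    add-one p makes 1/(n_boot+1) the smallest attainable value.
    """
    config = config or SparccConfig()
    if config.n_boot < 20:
        logger.warning("sparcc_pvalues: n_boot=%d gives coarse p granularity", config.n_boot)
    mat, _ = _to_matrix(counts)
    p, n = mat.shape
    rng = np.random.default_rng(config.seed)
    point_cfg = SparccConfig(
        pseudocount=config.pseudocount,
        pseudocount_zeros_only=config.pseudocount_zeros_only,
        exclusion_threshold=config.exclusion_threshold,
        max_exclusion_iters=config.max_exclusion_iters,
        n_inner=0,
        n_boot=config.n_boot,
    )
    abs_obs = np.abs(r_obs.r)
    exceed = np.zeros((p, p), dtype=int)
    for _ in range(config.n_boot):
        perm = mat.copy()
        for i in range(p):
            perm[i] = perm[i, rng.permutation(n)]
        frac = _fractions(perm, point_cfg)
        r_b = _basis_r_from_t(log_ratio_variances(frac), point_cfg)
        exceed += np.abs(r_b) >= abs_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + config.n_boot)
    np.fill_diagonal(pvals, 1.0 / (1.0 + config.n_boot))
    return pvals


def sparcc(counts, config: SparccConfig | None = None) -> CorrelationMatrix:
    """Basis correlations plus permutation p-values in one call."""
    config = config or SparccConfig()
    cm = basis_correlations(counts, config)
    cm.p = sparcc_pvalues(counts, cm, config)
    return cm
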