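"""Alpha/beta diversity, ordination, group tests, and TMM normalization.

Richness is the observed ASV count on rarefied data, Shannon entropy defaults
to log base 2.  Community dissimilarity uses Bray-Curtis, visualised by
classical principal-coordinate analysis (PCoA); group separation is tested by
PERMANOVA (the ADONIS pseudo-F with label-permutation significance), and
univariate indices by Kruskal-Wallis with pairwise rank-sum follow-ups.
Between-sample scaling factors follow the trimmed mean of M-values (TMM)
scheme: precision-weighted mean of log-fold-changes against a reference
sample after trimming extreme M (30%) and A (5%) values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .tables import AsvTable

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    """Outcome of a group-difference test."""

    statistic: float
    pvalue: float
    n_permutations: int | None = None
    method: str = ""


def richness(sample_counts) -> int:
    """Number of ASVs with count > 0."""
    return int(np.count_nonzero(np.asarray(sample_counts)))


def shannon(sample_counts, base: float = 2.0) -> float:
    """Shannon entropy −Σ p log_base p over nonzero fractions."""
    x = np.asarray(sample_counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("shannon requires a sample with total > 0")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_diversity(table: AsvTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample richness and Shannon index as a DataFrame."""
    rows = {
        s: (richness(table.counts[s]), shannon(table.counts[s], base=base))
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["richness", "shannon"])


def bray_curtis(table: AsvTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples (columns)."""
    df = table.counts if isinstance(table, AsvTable) else table
    totals = df.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    mat = squareform(pdist(df.to_numpy().T, metric="braycurtis"))
    return DistanceMatrix(mat, ids=list(df.columns))


def pcoa(dist: DistanceMatrix) -> OrdinationResults:
    """Classical scaling of a distance matrix.

    Axes are ordered by decreasing eigenvalue; axes with eigenvalue <= 0 are
    dropped from the coordinates while all eigenvalues remain reported.
    """
    if dist.shape[0] < 3:
        raise ValueError("pcoa requires at least 3 samples")
    res = _skbio_pcoa(dist, method="eigh")
    # eigenvalues come out sorted descending; keep only positive axes
    n_pos = int(np.sum(res.eigvals.to_numpy() > 1e-12))
    coords = res.samples.iloc[:, :n_pos]
    return OrdinationResults(
        short_method_name="PCoA",
        long_method_name="Principal Coordinate Analysis",
        eigvals=res.eigvals,
        samples=coords,
        proportion_explained=res.proportion_explained,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _ss_parts(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(ss_total, ss_within, n, g):
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        return 0.0 if abs(ss_between) <= 1e-300 else np.inf
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """Permutational multivariate ANOVA (ADONIS) on a distance matrix.

    ``groups`` is a sequence aligned with the matrix ids, or a mapping /
    pandas Series keyed by sample id.  ``n_perm`` may be ``"exhaustive"`` to
    enumerate every distinct labelling (small n only), in which case the
    p-value is the exact fraction of labellings with F >= F_obs; otherwise p
    uses the add-one convention over seeded shuffles.

    Degenerate all-identical data returns F=0, p=1.
    """
    ids = list(dist.ids)
    if isinstance(groups, (dict, pd.Series)):
        labels = np.asarray([groups[s] for s in ids])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != len(ids):
            raise ValueError("groups length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("permanova requires >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    n, g = len(ids), len(uniq)
    d2 = np.asarray(dist.data, dtype=float) ** 2

    ss_total, ss_within = _ss_parts(d2, labels, uniq)
    f_obs = _pseudo_f(ss_total, ss_within, n, g)
    if f_obs == 0.0 and ss_total <= 1e-300:
        return GroupTestResult(0.0, 1.0, 0, "permanova")

    # one-hot per group over a batch of labelings lets every permutation's
    # SS_within come out of one einsum
    def batch_f(label_matrix: np.ndarray) -> np.ndarray:
        ss_w = np.zeros(label_matrix.shape[0])
        for gi, gname in enumerate(uniq):
            b = (label_matrix == gname).astype(float)
            quad = np.einsum("bi,ij,bj->b", b, d2, b) / 2.0
            ss_w += quad / counts[gi]
        ss_b = ss_total - ss_w
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_b / (g - 1)) / (ss_w / (n - g))
        f = np.where(ss_w <= 1e-300, np.where(np.abs(ss_b) <= 1e-300, 0.0, np.inf), f)
        return f

    if n_perm == "exhaustive":
        if n > 10:
            raise ValueError("exhaustive enumeration limited to n <= 10")
        arrangements = np.array(sorted({p for p in itertools.permutations(labels)}))
        f_all = batch_f(arrangements)
        p = float(np.mean(f_all >= f_obs))
        return GroupTestResult(float(f_obs), p, len(arrangements), "permanova-exhaustive")

    rng = np.random.default_rng(seed)
    perm_labels = np.array([labels[rng.permutation(n)] for _ in range(int(n_perm))])
    f_perm = batch_f(perm_labels)
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + int(n_perm))
    return GroupTestResult(float(f_obs), float(p), int(n_perm), "permanova")


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p.

    All-equal observations return the (H=0, p=1) convention instead of an
    error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    samples = [values[labels == u] for u in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return GroupTestResult(0.0, 1.0, None, "kruskal-wallis")
    h, p = scipy.stats.kruskal(*samples)
    return GroupTestResult(float(h), float(p), None, "kruskal-wallis")


def pairwise_wilcoxon(values, groups) -> dict[tuple[str, str], float]:
    """Two-sided rank-sum (Mann-Whitney) p per group pair."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    uniq = sorted(set(labels.tolist()))
    out = {}
    for a, b in itertools.combinations(uniq, 2):
        va, vb = values[labels == a], values[labels == b]
        if len(va) == 0 or len(vb) == 0:
            raise ValueError("empty group")
        both = np.concatenate([va, vb])
        if np.all(both == both[0]):
            out[(a, b)] = 1.0
            continue
        _, p = scipy.stats.mannwhitneyu(va, vb, alternative="two-sided")
        out[(a, b)] = float(p)
    return out


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    table: AsvTable | pd.DataFrame,
    ref_sample: str | None = None,
    log_ratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those; per sample, log2 fold changes M and average
    log abundances A are computed over ASVs nonzero in both, the top/bottom
    ``log_ratio_trim`` by M and ``abs_trim`` by A are discarded, and the
    factor is 2**(precision-weighted mean M) with inverse asymptotic-variance
    weights.  Factors are rescaled to geometric mean 1.

    A sample sharing no nonzero ASV with the reference gets factor 1 with a
    warning.
    """
    df = table.counts if isinstance(table, AsvTable) else table
    if df.shape[1] < 2:
        raise ValueError("tmm_factors requires >= 2 samples")
    lib = df.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero-total sample")
    frac = df / lib
    if ref_sample is None:
        f75 = frac.quantile(0.75, axis=0)
        ref_sample = (f75 - f75.mean()).abs().idxmin()
    y_r = df[ref_sample].to_numpy(dtype=float)
    n_r = lib[ref_sample]

    raw = {}
    for s in df.columns:
        if s == ref_sample:
            raw[s] = 1.0
            continue
        y = df[s].to_numpy(dtype=float)
        n = lib[s]
        mask = (y > 0) & (y_r > 0)
        if not mask.any():
            logger.warning("tmm_factors: sample %r shares no ASV with reference %r", s, ref_sample)
            raw[s] = 1.0
            continue
        yk, yr = y[mask], y_r[mask]
        m = np.log2((yk / n) / (yr / n_r))
        a = 0.5 * np.log2((yk / n) * (yr / n_r))
        v = (n - yk) / (n * yk) + (n_r - yr) / (n_r * yr)
        if np.max(np.abs(m)) < 1e-6:
            raw[s] = 1.0
            continue
        k = len(m)
        lo_m = np.floor(k * log_ratio_trim) + 1
        hi_m = k + 1 - lo_m
        lo_a = np.floor(k * abs_trim) + 1
        hi_a = k + 1 - lo_a
        rm = scipy.stats.rankdata(m)
        ra = scipy.stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            raw[s] = 1.0
            continue
        w = 1.0 / v[keep]
        raw[s] = float(2 ** (np.sum(w * m[keep]) / np.sum(w)))

    factors = pd.Series(raw).reindex(df.columns)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def tmm_normalized_abundance(table: AsvTable | pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Counts scaled to TMM-effective library size, per-sample fractions.

    Downstream indicator/network stages consume this normalized view.
    """
    df = table.counts if isinstance(table, AsvTable) else table
    factors = tmm_factors(df, **kwargs)
    eff = df.sum(axis=0) * factors
    return df / eff
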