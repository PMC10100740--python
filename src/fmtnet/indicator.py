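"""IndVal indicator-species analysis and the group-ASV bipartite network.

For species i and target group t the indicator value combines specificity
A_it (the share of i's mean abundance that falls in t) with fidelity B_it
(the fraction of t's samples where i occurs): IndVal = A x B.  Following the
dominant ecology-package convention the reported statistic is
sqrt(max_t IndVal_it); significance comes from seeded permutations of the
group labels with the add-one p-value convention.  The optional combination
mode lets targets range over non-trivial subsets of groups (a species may
indicate "donor or single-FMT", say).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables import TaxonomyMap

logger = logging.getLogger(__name__)


@dataclass
class IndicatorResult:
    """Per-ASV best target, IndVal-derived statistic, and permutation p."""

    frame: pd.DataFrame  # index asv; columns: target, indval, stat, p
    n_permutations: int = 999
    targets: tuple = ()

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        return self.frame[self.frame["p"] < alpha]


def _targets(groups: np.ndarray, use_combinations: bool) -> list[tuple[str, ...]]:
    uniq = sorted(set(groups.tolist()))
    if not use_combinations:
        return [(g,) for g in uniq]
    subsets = []
    for k in range(1, len(uniq)):
        subsets.extend(itertools.combinations(uniq, k))
    return subsets


def _indval_stats(x: np.ndarray, labels: np.ndarray, targets, uniq) -> tuple[np.ndarray, np.ndarray]:
    """(max-target IndVal, argmax index) for every species.

    ``x`` is species x samples.  Specificity of a combination is the summed
    per-group mean share; fidelity is occurrence frequency over the pooled
    samples of the combination.
    """
    onehot = np.stack([(labels == g) for g in uniq], axis=1).astype(float)  # samples x G
    sizes = onehot.sum(axis=0)
    group_means = (x @ onehot) / sizes  # species x G
    group_presence = (x > 0).astype(float) @ onehot  # species x G, counts
    denom = group_means.sum(axis=1)
    denom = np.where(denom == 0, np.nan, denom)
    ivs = np.empty((x.shape[0], len(targets)))
    for ti, t in enumerate(targets):
        cols = [uniq.index(g) for g in t]
        a = group_means[:, cols].sum(axis=1) / denom
        b = group_presence[:, cols].sum(axis=1) / sizes[cols].sum()
        ivs[:, ti] = a * b
    ivs = np.nan_to_num(ivs, nan=0.0)
    best = np.argmax(ivs, axis=1)  # ties -> lowest target index
    return ivs[np.arange(len(best)), best], best


def indval(
    table,
    groups,
    use_combinations: bool = False,
    n_perm: int = 999,
    seed: int | None = None,
) -> IndicatorResult:
    """Indicator-value analysis with permutation significance.

    Parameters
    ----------
    table : AsvTable or DataFrame
        Species x samples abundances (normalized abundances or rarefied
        counts both work; the statistic only uses means and presence).
    groups : mapping / Series / sequence of labels aligned with samples.

    Species absent from every sample are excluded with a warning.
    """
    df = table.counts if hasattr(table, "counts") else table
    if isinstance(groups, (dict, pd.Series)):
        labels = np.asarray([groups[s] for s in df.columns])
    else:
        labels = np.asarray(list(groups))
    uniq_arr, counts = np.unique(labels, return_counts=True)
    if len(uniq_arr) < 2:
        raise ValueError("indval requires >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    uniq = sorted(uniq_arr.tolist())

    empty = df.index[(df.to_numpy() > 0).sum(axis=1) == 0]
    if len(empty):
        logger.warning("indval: excluding %d species absent everywhere", len(empty))
        df = df.drop(index=empty)
    x = df.to_numpy(dtype=float)

    targets = _targets(labels, use_combinations)
    obs, best = _indval_stats(x, labels, targets, uniq)
    stat_obs = np.sqrt(obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(df), dtype=int)
    for _ in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        pm, _ = _indval_stats(x, perm, targets, uniq)
        exceed += np.sqrt(pm) >= stat_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    frame = pd.DataFrame(
        {
            "target": ["+".join(targets[b]) for b in best],
            "indval": obs,
            "stat": stat_obs,
            "p": pvals,
        },
        index=df.index,
    )
    return IndicatorResult(frame, n_permutations=n_perm, targets=tuple(targets))


def indicator_set(result: IndicatorResult, alpha: float = 0.01) -> set[str]:
    """ASVs significant at ``alpha`` (the study displays P < 0.01)."""
    return set(result.frame.index[result.frame["p"] < alpha])


def bipartite_network(
    result: IndicatorResult,
    taxonomy: TaxonomyMap | None = None,
    alpha: float = 0.01,
    layout: bool = False,
    layout_iterations: int = 10_000,
    seed: int | None = None,
) -> nx.Graph:
    """Group <-> indicator-ASV bipartite graph for significant associations.

    Each significant ASV is connected to its best target group(s); ASV nodes
    carry a ``phylum`` attribute when taxonomy is given.  The optional
    Fruchterman-Reingold layout is cosmetic, seeded, and stored as a ``pos``
    node attribute.
    """
    g = nx.Graph()
    sig = result.significant(alpha)
    for asv, row in sig.iterrows():
        phylum = taxonomy.phylum(asv) if taxonomy is not None else None
        g.add_node(asv, bipartite="asv", phylum=phylum)
        for target in str(row["target"]).split("+"):
            g.add_node(target, bipartite="group")
            g.add_edge(asv, target, stat=float(row["stat"]), p=float(row["p"]))
    if layout and g.number_of_nodes():
        pos = nx.spring_layout(g, iterations=min(layout_iterations, 1000), seed=seed)
        nx.set_node_attributes(g, {k: tuple(v) for k, v in pos.items()}, "pos")
    return g
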