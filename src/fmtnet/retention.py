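"""Donor-taxon retention: genus-level key-species counts across networks.

For every (group, day) co-occurrence network the key species (module members)
are tallied by genus — distinct ASVs per genus, never abundance.  The genus
panel is the union of the donor and recipient top-10 genera; the resulting
profile matrix is clustered hierarchically (z-scored rows, Euclidean, average
linkage) to ask which transplanted time point most resembles the donor.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .netmod import ModulePartition
from .tables import UNASSIGNED, TaxonomyMap

logger = logging.getLogger(__name__)


def key_genus_counts(partition: ModulePartition, taxonomy: TaxonomyMap) -> dict[str, int]:
    """Distinct key-species ASVs per genus for one network.

    Key ASVs missing from the taxonomy are counted under ``unassigned`` with
    a warning; the ``unassigned`` bucket is retained.
    """
    counts: Counter[str] = Counter()
    missing = 0
    for asv in partition.key_species():
        if asv in taxonomy:
            counts[taxonomy.genus(asv)] += 1
        else:
            missing += 1
            counts[UNASSIGNED] += 1
    if missing:
        logger.warning("key_genus_counts: %d key ASV(s) lack taxonomy", missing)
    return dict(counts)


def top_genera(profile: dict[str, int], k: int = 10, include_unassigned: bool = False) -> list[str]:
    """Top ``k`` genera by descending ASV count, ties lexicographic.

    ``unassigned`` is excluded by default.  Fewer than ``k`` genera returns
    all of them with a warning.
    """
    if not profile:
        raise ValueError("empty genus profile")
    items = [(g, c) for g, c in profile.items() if include_unassigned or g != UNASSIGNED]
    ordered = [g for g, _ in sorted(items, key=lambda gc: (-gc[1], gc[0]))]
    if len(ordered) < k:
        logger.warning("top_genera: only %d genera available (k=%d)", len(ordered), k)
    return ordered[:k]


def retention_matrix(
    profiles: dict[tuple, dict[str, int]],
    genus_panel: list[str],
    panel_provenance: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rows = (group, day) networks, columns = panel genera, values = counts.

    Genera absent from a network are 0.  ``panel_provenance`` (genus ->
    "donor" / "recipient" / "shared") is attached as ``df.attrs["provenance"]``.
    """
    if len(profiles) < 1:
        raise ValueError("no profiles")
    if not genus_panel:
        raise ValueError("empty genus panel")
    data = [[int(prof.get(g, 0)) for g in genus_panel]
            for prof in profiles.values()]
    # tuple row labels stay plain tuples, not a MultiIndex
    idx = pd.Index(list(profiles.keys()), tupleize_cols=False)
    df = pd.DataFrame(data, index=idx, columns=genus_panel)
    if panel_provenance is not None:
        df.attrs["provenance"] = dict(panel_provenance)
    return df


def donor_recipient_panel(
    donor_profile: dict[str, int],
    recipient_profile: dict[str, int],
    k: int = 10,
) -> tuple[list[str], dict[str, str]]:
    """Union of donor and recipient top-``k`` genera with provenance tags."""
    donor_top = top_genera(donor_profile, k=k)
    recip_top = top_genera(recipient_profile, k=k)
    panel = donor_top + [g for g in recip_top if g not in donor_top]
    prov = {}
    for g in panel:
        if g in donor_top and g in recip_top:
            prov[g] = "shared"
        elif g in donor_top:
            prov[g] = "donor"
        else:
            prov[g] = "recipient"
    return panel, prov


@dataclass
class ProfileClustering:
    """Hierarchical clustering of retention profiles."""

    linkage: np.ndarray          # scipy linkage table (idx1, idx2, height, size)
    row_labels: list
    leaf_order: list
    cophenetic: pd.DataFrame = field(repr=False, default=None)

    def flat_clusters(self, n_clusters: int) -> dict:
        flat = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.row_labels, flat)}

    def nearest_row(self, label) -> object:
        """Row label with the smallest cophenetic distance to ``label``."""
        d = self.cophenetic.loc[label].drop(label)
        return d.idxmin()


def cluster_profiles(
    matrix: pd.DataFrame,
    z_score: bool = True,
    metric: str = "euclidean",
    linkage_method: str = "average",
) -> ProfileClustering:
    """Agglomerative clustering of profile rows (heatmap convention).

    Rows are z-scored (σ floored at 1e-12 so constant rows survive) before
    Euclidean/average-linkage clustering; deterministic, emits the linkage
    table, leaf order, and the cophenetic distance matrix.
    """
    if matrix.shape[0] < 3:
        raise ValueError("cluster_profiles requires >= 3 rows")
    x = matrix.to_numpy(dtype=float)
    if z_score:
        mu = x.mean(axis=1, keepdims=True)
        sd = np.maximum(x.std(axis=1, keepdims=True), 1e-12)
        x = (x - mu) / sd
    z = sch.linkage(x, method=linkage_method, metric=metric)
    order = sch.leaves_list(z)
    coph = sch.cophenet(z)
    labels = list(matrix.index)
    coph_df = pd.DataFrame(squareform(coph), index=labels, columns=labels)
    return ProfileClustering(
        linkage=z,
        row_labels=labels,
        leaf_order=[labels[i] for i in order],
        cophenetic=coph_df,
    )
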