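"""Co-occurrence network construction, module detection, and key species.

A correlation matrix is thresholded (|r| >= cutoff and p < cutoff, default
0.3 / 0.05) into an undirected ASV graph.  The cutoff can be chosen by a
random-matrix-theory scan: noise-dominated correlation matrices have
Wigner-Dyson (GOE) nearest-neighbour eigenvalue spacings, while real modular
structure decouples the spectrum toward Poisson spacings; the smallest cutoff
at which Poisson fits the unfolded spacings better is selected.

The network is intersected with the indicator-species set (indicators plus
their direct neighbours), partitioned by greedy modularity maximisation, and
communities containing at least one indicator become modules M1..Mk (by
decreasing size); nodes of indicator-free or undersized communities are
labelled NA.  Module members are the "key species" of the community, NA
members the "peripheral species".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_comm

from .sparcc import CorrelationMatrix

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """node -> module label (M1..Mk or NA), modularity Q, indicator flags."""

    labels: dict[str, str]
    modularity: float
    indicator_set: set[str] = field(default_factory=set)
    communities: list[set[str]] = field(default_factory=list)

    @property
    def module_names(self) -> list[str]:
        names = sorted({l for l in self.labels.values() if l != "NA"},
                       key=lambda m: int(m[1:]))
        return names

    def members(self, label: str) -> set[str]:
        return {n for n, l in self.labels.items() if l == label}

    def key_species(self) -> set[str]:
        return {n for n, l in self.labels.items() if l != "NA"}

    def peripheral_species(self) -> set[str]:
        return {n for n, l in self.labels.items() if l == "NA"}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (n, l, n in self.indicator_set, l != "NA")
            for n, l in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["asv", "module", "is_indicator", "is_key"]
                            ).set_index("asv")


# ---------------------------------------------------------------------------
# RMT-based cutoff selection


def _unfolded_spacings(eigvals: np.ndarray, degree: int = 9) -> np.ndarray | None:
    """Nearest-neighbour spacings after polynomial unfolding.

    The empirical cumulative spectral density is smoothed with a low-order
    polynomial; spacings of the mapped eigenvalues have unit mean by
    construction.  Degenerate eigenvalues keep their zero spacings (level
    clustering is evidence for Poisson, not an artifact to remove).  Returns
    None when the spectrum is too small or fully collapsed.
    """
    vals = np.sort(eigvals)
    if len(vals) < 12 or float(np.ptp(vals)) < 1e-8:
        return None
    n = len(vals)
    cdf = (np.arange(n) + 0.5) / n
    fit = np.polynomial.Polynomial.fit(vals, cdf, min(degree, n - 1))
    unfolded = n * fit(vals)
    spacings = np.maximum(np.diff(unfolded), 0.0)
    if spacings.mean() <= 0:
        return None
    return spacings / spacings.mean()


def _spacing_chi2(eigvals: np.ndarray, n_bins: int = 10) -> tuple[float, float] | None:
    """Chi-square of the unfolded spacing distribution against Poisson and
    Wigner-Dyson (GOE); None if the spectrum supports no statistics."""
    spacings = _unfolded_spacings(eigvals)
    if spacings is None:
        return None
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    obs, _ = np.histogram(np.clip(spacings, 0, 3.0 - 1e-9), bins=edges)
    n = obs.sum()
    # expected bin mass from the two reference densities, renormalised on [0,3]
    def cdf_poisson(s):
        return 1.0 - np.exp(-s)

    def cdf_wigner(s):
        return 1.0 - np.exp(-np.pi * s**2 / 4.0)

    out = []
    for cdf in (cdf_poisson, cdf_wigner):
        mass = np.diff(cdf(edges)) / cdf(edges[-1])
        expected = np.maximum(n * mass, 1e-9)
        out.append(float(np.sum((obs - expected) ** 2 / expected)))
    return out[0], out[1]


def rmt_threshold(
    corr: CorrelationMatrix | np.ndarray,
    candidate_cutoffs=None,
    default: float = 0.3,
) -> float:
    """Smallest cutoff at which the thresholded spectrum's spacings look
    Poisson rather than Wigner-Dyson; ``default`` (0.3) with a warning when
    no transition is found."""
    r = corr.r if isinstance(corr, CorrelationMatrix) else np.asarray(corr, dtype=float)
    if r.shape[0] < 20:
        logger.warning("rmt_threshold: <20 taxa, spectra are uninformative")
    if candidate_cutoffs is None:
        candidate_cutoffs = np.round(np.arange(0.10, 0.91, 0.01), 2)
    for cut in candidate_cutoffs:
        m = np.where(np.abs(r) >= cut, r, 0.0)
        np.fill_diagonal(m, 1.0)
        eig = np.linalg.eigvalsh(m)
        scores = _spacing_chi2(eig)
        if scores is None:
            continue
        chi_poisson, chi_wigner = scores
        if chi_poisson < chi_wigner:
            return float(cut)
    logger.warning("rmt_threshold: no Poisson transition found; using default %.2f", default)
    return float(default)


# ---------------------------------------------------------------------------
# network construction


def build_network(
    corr: CorrelationMatrix,
    pvals: np.ndarray | None = None,
    r_cutoff: float = 0.3,
    p_cutoff: float = 0.05,
    signed: str = "abs",
    drop_isolated: bool = True,
) -> nx.Graph:
    """Threshold correlations into an undirected graph.

    Edge (i, j) exists iff |r_ij| >= ``r_cutoff`` (or r_ij >= cutoff in
    ``signed="positive"`` mode) and p_ij < ``p_cutoff``.  Edges carry ``r``
    and ``p`` attributes; isolated nodes are dropped unless requested.
    """
    r = corr.r
    if pvals is None:
        pvals = corr.p
    if pvals is None:
        raise ValueError("no p-value matrix supplied")
    pvals = np.asarray(pvals)
    if pvals.shape != r.shape:
        raise ValueError("correlation and p matrices have mismatched shapes")
    ids = corr.asv_ids
    if signed == "abs":
        pass_r = np.abs(r) >= r_cutoff
    elif signed == "positive":
        pass_r = r >= r_cutoff
    else:
        raise ValueError("signed must be 'abs' or 'positive'")
    g = nx.Graph()
    if not drop_isolated:
        g.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), 1)
    keep = pass_r[iu, ju] & (pvals[iu, ju] < p_cutoff)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], r=float(r[i, j]), p=float(pvals[i, j]))
    return g


def indicator_subnetwork(net: nx.Graph, indicator_set: set[str]) -> nx.Graph:
    """Induced subgraph on indicators present in ``net`` plus their direct
    neighbours (the intersection network of the study)."""
    present = set(net.nodes) & set(indicator_set)
    if not present:
        logger.warning("indicator_subnetwork: no indicator species in the network")
        return nx.Graph()
    keep = set(present)
    for node in present:
        keep.update(net.neighbors(node))
    return net.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# modules


def greedy_modules(net: nx.Graph) -> tuple[list[set[str]], float]:
    """Agglomerative greedy maximisation of Newman modularity on the
    unweighted edge set; returns (communities, Q)."""
    if net.number_of_edges() == 0:
        raise ValueError("greedy_modules requires a network with >= 1 edge")
    comms = [set(c) for c in nx_comm.greedy_modularity_communities(net, weight=None)]
    q = nx_comm.modularity(net, comms, weight=None)
    return comms, float(q)


def classify_key_peripheral(
    communities: list[set[str]],
    indicator_set: set[str],
    modularity: float = float("nan"),
    min_module_size: int = 3,
) -> ModulePartition:
    """Communities with >= 1 indicator (and >= ``min_module_size`` members)
    become modules M1..Mk by decreasing size (ties by smallest member id);
    everything else is NA.  Module members are key species, NA peripheral."""
    with_ind = [
        c for c in communities
        if (c & set(indicator_set)) and len(c) >= min_module_size
    ]
    ordered = sorted(with_ind, key=lambda c: (-len(c), min(map(str, c))))
    labels: dict[str, str] = {}
    for k, comm in enumerate(ordered, start=1):
        for node in comm:
            labels[node] = f"M{k}"
    for comm in communities:
        for node in comm:
            labels.setdefault(node, "NA")
    return ModulePartition(
        labels=labels,
        modularity=modularity,
        indicator_set=set(indicator_set) & set(labels),
        communities=[set(c) for c in communities],
    )


def modules_from_network(net: nx.Graph, indicator_set: set[str],
                         min_module_size: int = 3) -> ModulePartition:
    """greedy_modules + classify_key_peripheral in one step."""
    comms, q = greedy_modules(net)
    return classify_key_peripheral(comms, indicator_set, modularity=q,
                                   min_module_size=min_module_size)


def brute_force_modularity(net: nx.Graph, communities: list[set[str]]) -> float:
    """Independent Σ_c (e_cc − a_c²) evaluation of Newman modularity; used as
    the oracle against the library computation."""
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    q = 0.0
    for comm in communities:
        within = sum(1 for u, v in net.edges if u in comm and v in comm)
        degree = sum(d for _, d in net.degree(comm))
        q += within / m - (degree / (2.0 * m)) ** 2
    return q


def topology(net: nx.Graph, partition: ModulePartition | None = None) -> dict:
    """Node/edge/module counts and Q, serialisable for cross-run comparison."""
    out = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
    }
    if partition is not None:
        sizes = {m: len(partition.members(m)) for m in partition.module_names}
        out.update(
            n_modules=len(sizes),
            module_sizes=sizes,
            n_key=len(partition.key_species()),
            n_peripheral=len(partition.peripheral_species()),
            modularity=partition.modularity,
        )
    return out


def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tr\tp\n")
        for u, v, d in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('r', '')}\t{d.get('p', '')}\n")
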