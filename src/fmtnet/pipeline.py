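"""End-to-end orchestration: rarefy -> diversity -> differential abundance ->
indicator species -> SparCC -> network/modules -> retention.

The pipeline consumes either on-disk inputs (ASV table, taxonomy, metadata)
or a simulated scenario, executes every stage with explicit seeds, and writes
a plain-text artifact tree (TSV tables, JSON sidecars, a log).  Re-running
with an identical config reproduces byte-identical deterministic artifacts.

Co-occurrence networks are built per sample subset following the study's
figure structure: one per endpoint group (P, CV, AT at day 0) and one per
(transplant group, day) combination.  Indicator species are determined once
across all groups with group-combination targets; the indicator set of a
network is the set of significant ASVs whose best target includes that
network's group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffabund, diversity, indicator, netmod, retention, tables
from .simulate import ScenarioConfig, simulate_fmt_timecourse
from .sparcc import SparccConfig, basis_correlations, sparcc_pvalues
from .tables import AsvTable, SampleMetadata, TaxonomyMap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serialized verbatim into the output."""

    output_dir: str = "fmtnet_out"
    # inputs: either the three paths, or a scenario
    table_path: str | None = None
    table_format: str = "tsv"
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    scenario: dict | None = None  # ScenarioConfig fields; None -> require paths

    rarefaction_depth: int = 14_419
    shannon_base: float = 2.0
    permanova_permutations: int = 999
    lefse_alpha: float = 0.05
    lefse_lda_threshold: float = 4.0
    indicator_alpha: float = 0.01
    indicator_permutations: int = 999
    indicator_combinations: bool = True
    sparcc: dict = field(default_factory=dict)  # SparccConfig overrides
    r_cutoff: float = 0.3
    p_cutoff: float = 0.05
    use_rmt_cutoff: bool = False
    min_prevalence: int = 2  # per-network taxon filter: nonzero in >= this many samples
    min_module_size: int = 3
    top_k_genera: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _network_specs(meta: SampleMetadata) -> list[tuple[str, int | None]]:
    """(group, day) subsets in the figure structure: endpoint groups pooled,
    transplant groups split per day."""
    specs: list[tuple[str, int | None]] = []
    frame = meta.frame
    for g in dict.fromkeys(frame["group"]):
        days = sorted(set(frame.loc[frame["group"] == g, "day"]))
        if len(days) == 1:
            specs.append((g, None))
        else:
            specs.extend((g, d) for d in days)
    return specs


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_path = out / "pipeline.log"
    log_lines: list[str] = []

    def stage(name: str, seed=None, **info):
        entry = {"stage": name, "seed": seed, "status": "ok", **info}
        log_lines.append(json.dumps(entry))
        logger.info("stage %s done (%s)", name, info)

    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(64))

    # ---- inputs ----------------------------------------------------------
    if config.scenario is not None:
        sc = ScenarioConfig(**{**config.scenario, "seed": config.seed})
        table, taxonomy, meta, truth = simulate_fmt_timecourse(sc)
        tables.write_asv_table(table, out / "asv_table.tsv")
        tables.write_taxonomy(taxonomy, out / "taxonomy.tsv")
        tables.write_metadata(meta, out / "metadata.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump({"source": truth.source,
                       "module_labels": truth.module_labels,
                       "indicator_map": truth.indicator_map}, fh, indent=1)
        stage("simulate", seed=config.seed, n_samples=table.shape[1])
    else:
        if not (config.table_path and config.metadata_path):
            raise ValueError("need table_path and metadata_path (or a scenario)")
        table = tables.read_asv_table(config.table_path, config.table_format)
        meta = tables.read_metadata(config.metadata_path)
        taxonomy = (tables.read_taxonomy(config.taxonomy_path)
                    if config.taxonomy_path else None)
        stage("load", n_samples=table.shape[1])
    if taxonomy is None:
        raise ValueError("taxonomy required for the retention stage")

    # ---- rarefaction -----------------------------------------------------
    rarefied = tables.rarefy(table, config.rarefaction_depth, seed=next(seeds))
    tables.write_asv_table(rarefied, out / "rarefied.tsv")
    stage("rarefy", depth=config.rarefaction_depth, kept=rarefied.shape[1])

    # ---- diversity -------------------------------------------------------
    alpha = diversity.alpha_diversity(rarefied, base=config.shannon_base)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    dm = diversity.bray_curtis(rarefied)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out / "bray_curtis.tsv", sep="\t")
    ord_res = diversity.pcoa(dm)
    ord_res.samples.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    perm_seed = next(seeds)
    groups = meta.group_series(rarefied.sample_ids)
    perm = diversity.permanova(dm, groups, n_perm=config.permanova_permutations,
                               seed=perm_seed)
    kw = diversity.kruskal_wallis(alpha["shannon"].to_numpy(), groups)
    with open(out / "group_tests.jsonl", "w") as fh:
        for name, res in (("permanova_braycurtis", perm), ("kruskal_shannon", kw)):
            fh.write(json.dumps({"test": name, "statistic": res.statistic,
                                 "p": res.pvalue, "n_perm": res.n_permutations,
                                 "seed": perm_seed}) + "\n")
    stage("diversity", seed=perm_seed, permanova_p=perm.pvalue)

    # ---- normalization + differential abundance --------------------------
    norm = diversity.tmm_normalized_abundance(rarefied)
    rel = tables.relative_abundance(rarefied)
    genus_rel = tables.collapse_taxa(rel, taxonomy, rank="genus", min_frac=0.01)
    genus_rel.to_csv(out / "genus_relative_abundance.tsv", sep="\t")
    lefse_seed = next(seeds)
    genus_all = tables.collapse_taxa(rel, taxonomy, rank="genus", min_frac=0.0)
    records = diffabund.lefse_scores(
        genus_all, groups, alpha=config.lefse_alpha,
        lda_threshold=config.lefse_lda_threshold, seed=lefse_seed)
    diffabund.lefse_to_frame(records).to_csv(out / "lefse.tsv", sep="\t", index=False)
    stage("diffabund", seed=lefse_seed, n_reported=len(records))

    # ---- indicator species ----------------------------------------------
    ind_seed = next(seeds)
    ind = indicator.indval(norm, groups,
                           use_combinations=config.indicator_combinations,
                           n_perm=config.indicator_permutations, seed=ind_seed)
    ind_frame = ind.frame.copy()
    ind_frame.rename(columns={"stat": "sqrt_indval"}).to_csv(
        out / "indicator_species.tsv", sep="\t")
    sig = ind.significant(config.indicator_alpha)
    group_indicators = {
        g: {a for a, row in sig.iterrows() if g in str(row["target"]).split("+")}
        for g in dict.fromkeys(meta.frame["group"])
    }
    stage("indicator", seed=ind_seed, n_significant=len(sig))

    # ---- per-network SparCC / modules / retention profiles ---------------
    profiles: dict[tuple, dict[str, int]] = {}
    topo_all = {}
    for g, day in _network_specs(meta):
        label = f"{g}" if day is None else f"{g}_d{day}"
        sub_samples = meta.samples(group=g, day=day)
        sub_samples = [s for s in sub_samples if s in rarefied.sample_ids]
        if len(sub_samples) < 4:
            logger.warning("network %s: only %d samples, skipped", label, len(sub_samples))
            continue
        sub = rarefied.subset(samples=sub_samples)
        prev = (sub.counts.to_numpy() > 0).sum(axis=1)
        sub = sub.subset(asvs=sub.counts.index[prev >= config.min_prevalence])
        if sub.shape[0] < 4:
            logger.warning("network %s: <4 prevalent taxa, skipped", label)
            continue
        net_seed = next(seeds)
        scfg = SparccConfig(**{**config.sparcc, "seed": net_seed})
        corr = basis_correlations(sub, scfg)
        pvals = sparcc_pvalues(sub, corr, scfg)
        r_cut = (netmod.rmt_threshold(corr, default=config.r_cutoff)
                 if config.use_rmt_cutoff else config.r_cutoff)
        net = netmod.build_network(corr, pvals, r_cutoff=r_cut,
                                   p_cutoff=config.p_cutoff)
        subnet = netmod.indicator_subnetwork(net, group_indicators.get(g, set()))
        if subnet.number_of_edges() == 0:
            logger.warning("network %s: empty indicator subnetwork", label)
            topo_all[label] = netmod.topology(subnet)
            profiles[(g, day if day is not None else 0)] = {}
            continue
        part = netmod.modules_from_network(subnet, group_indicators.get(g, set()),
                                           min_module_size=config.min_module_size)
        netmod.write_edge_list(subnet, out / f"network_{label}.tsv")
        part.to_frame().to_csv(out / f"modules_{label}.tsv", sep="\t")
        topo_all[label] = netmod.topology(subnet, part)
        profiles[(g, day if day is not None else 0)] = retention.key_genus_counts(
            part, taxonomy)
        stage(f"network_{label}", seed=net_seed, r_cutoff=r_cut,
              **{k: v for k, v in topo_all[label].items()
                 if k in ("n_nodes", "n_edges", "n_modules")})
    with open(out / "topology.json", "w") as fh:
        json.dump(topo_all, fh, indent=1, default=str)

    # ---- retention -------------------------------------------------------
    ret_paths = {}
    if ("P", 0) in profiles and ("CV", 0) in profiles and profiles[("P", 0)]:
        panel, prov = retention.donor_recipient_panel(
            profiles[("P", 0)], profiles[("CV", 0)], k=config.top_k_genera)
        matrix = retention.retention_matrix(profiles, panel, prov)
        matrix.index = [f"{g}_d{d}" for g, d in matrix.index]
        matrix.to_csv(out / "retention_matrix.tsv", sep="\t")
        if matrix.shape[0] >= 3:
            clust = retention.cluster_profiles(matrix)
            pd.DataFrame(clust.linkage,
                         columns=["idx1", "idx2", "height", "size"]).to_csv(
                out / "retention_linkage.tsv", sep="\t", index=False)
            with open(out / "retention_clusters.json", "w") as fh:
                json.dump({"leaf_order": [str(l) for l in clust.leaf_order],
                           "panel_provenance": prov}, fh, indent=1)
        stage("retention", n_profiles=len(profiles))
    else:
        logger.warning("retention skipped: donor or recipient profile missing")

    log_path.write_text("\n".join(log_lines) + "\n")
    return out
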