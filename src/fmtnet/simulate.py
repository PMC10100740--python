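"""Synthetic FMT time-course generator with full ground truth.

The generative model is the one the downstream estimators assume: latent
"basis" abundances are log-normal with a block-structured covariance (planted
co-occurrence modules), closed to fractions, and observed as
Dirichlet-multinomial counts at a negative-binomial sequencing depth.

The scenario mirrors a donor/recipient FMT design: a low-diversity donor
community dominated by a few genera (roughly 49/17/9% for the top three, the
scale reported for giant-panda faeces), a higher-diversity recipient mouse
community, and transplant groups whose composition at day t is a mixture
pi_group(t) * donor + (1 - pi_group(t)) * recipient with per-ASV Bernoulli
engraftment.  Group-exclusive indicator taxa are planted for the endpoint
groups.  Everything random is driven by one seed; the emitted
:class:`FmtTruth` ledger records per-ASV source, the true basis correlation
matrix, planted block (module) labels, and the planted indicator map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvTable, SampleMetadata, TaxonomyMap, UNASSIGNED

# genus/phylum vocabulary for the synthetic taxonomy; donor names follow the
# dominant panda-faeces genera, recipient names the usual mouse gut genera
DONOR_GENERA = [
    ("Escherichia-Shigella", "Proteobacteria"),
    ("Streptococcus", "Firmicutes"),
    ("Clostridium sensu stricto 1", "Firmicutes"),
    ("Klebsiella", "Proteobacteria"),
    ("Enterococcus", "Firmicutes"),
    ("Enterobacter", "Proteobacteria"),
    ("Lactococcus", "Firmicutes"),
    ("Raoultella", "Proteobacteria"),
    ("Serratia", "Proteobacteria"),
    ("Terrisporobacter", "Firmicutes"),
]
RECIPIENT_GENERA = [
    ("Lactobacillus", "Firmicutes"),
    ("Lachnospiraceae NK4A136 group", "Firmicutes"),
    ("Bacteroides", "Bacteroidetes"),
    ("Alistipes", "Bacteroidetes"),
    ("Roseburia", "Firmicutes"),
    ("Ruminococcaceae UCG-014", "Firmicutes"),
    ("Pseudomonas", "Proteobacteria"),
    ("Blautia", "Firmicutes"),
    ("Parabacteroides", "Bacteroidetes"),
    ("Akkermansia", "Verrucomicrobia"),
]


@dataclass
class Basis:
    """Log-normal basis parameters: per-taxon log-mean and covariance."""

    mu: np.ndarray
    cov: np.ndarray

    @property
    def n_taxa(self) -> int:
        return len(self.mu)


@dataclass
class ScenarioConfig:
    """Study-design knobs for the synthetic FMT time course.

    Defaults follow the study layout: group sizes P=10, CV=8, AT=8, AM=8,
    M=6, S=6 (AM/M/S resampled at days 3/7/14/21), depths safely above the
    14,419-read rarefaction depth, donor top-three genus fractions on the
    49/17/9% scale, engraftment starting high (0.9) for germfree groups and
    decaying mildly, and moderate (0.6, decaying to 0.1) for the
    antibiotic-treated transplant group.
    """

    n_taxa_donor: int = 40
    n_taxa_recipient: int = 120
    n_overlap: int = 10
    group_sizes: dict = field(default_factory=lambda: {
        "P": 10, "CV": 8, "AT": 8, "AM": 8, "M": 6, "S": 6})
    timepoints: tuple = (3, 7, 14, 21)
    depth_mean: float = 20_000.0
    depth_dispersion: float = 20.0
    min_depth: int = 15_000  # construction flag: keep every sample rarefiable
    log_sd: float = 1.0
    donor_dominant_fracs: tuple = (0.49, 0.17, 0.09)
    donor_blocks: tuple = (5, 5, 5)
    recipient_blocks: tuple = (5, 5)
    block_corr: float = 0.7
    n_indicators: int = 6
    indicator_groups: tuple = ("P", "CV", "AT")
    indicator_frac: float = 0.01
    # pi_group(day): share of the community drawn from the donor basis
    engraftment: dict = field(default_factory=lambda: {
        "S": {3: 0.95, 7: 0.85, 14: 0.75, 21: 0.65},
        "M": {3: 0.70, 7: 0.80, 14: 0.85, 21: 0.85},
        "AM": {3: 0.60, 7: 0.40, 14: 0.20, 21: 0.10},
    })
    # per-ASV Bernoulli presence dynamics: a donor taxon is retained at day t
    # iff its uniform draw < retention(t) (monotone loss); a recipient-side
    # taxon has colonized by day t iff its draw < colonization(t) (monotone
    # gain).  Germfree groups start donor-dominated and acquire the mouse
    # community slowly; the antibiotic group reverts fast.
    # single-FMT germfree mice start near-identical to the donor and drift;
    # multiple-FMT mice start less donor-like (the repeated dosing window
    # perturbs early assembly) and converge later; antibiotic mice revert to
    # their residual native community fast.  Retention may rise for M because
    # repeated gavages re-seed donor taxa.
    donor_retention: dict = field(default_factory=lambda: {
        "S": {3: 0.92, 7: 0.85, 14: 0.78, 21: 0.70},
        "M": {3: 0.75, 7: 0.85, 14: 0.88, 21: 0.88},
        "AM": {3: 0.80, 7: 0.55, 14: 0.35, 21: 0.20},
    })
    # germfree isolator mice acquire non-donor taxa slowly (richness stays
    # below the conventional group throughout); antibiotic mice re-expand
    # their residual native community quickly
    colonization: dict = field(default_factory=lambda: {
        "S": {3: 0.08, 7: 0.20, 14: 0.30, 21: 0.40},
        "M": {3: 0.12, 7: 0.18, 14: 0.25, 21: 0.30},
        "AM": {3: 0.50, 7: 0.70, 14: 0.85, 21: 0.95},
    })
    at_knockdown_frac: float = 0.6
    at_knockdown_logfc: float = -3.0
    # technical overdispersion only: biological variation lives in the
    # log-normal basis, so theta is the replicate-library scale (count
    # variance inflation ~1 + depth*theta, a few-fold at these depths)
    theta: float = 1e-4
    seed: int | None = 0


@dataclass
class FmtTruth:
    """Ground-truth ledger for a simulated scenario."""

    source: dict[str, str]                  # asv -> donor / recipient / shared
    basis_correlation: pd.DataFrame         # true correlation of the latent basis
    module_labels: dict[str, str | None]    # asv -> planted block label or None
    indicator_map: dict[str, str]           # asv -> group it was planted for

    def block_members(self, label: str) -> list[str]:
        return [a for a, b in self.module_labels.items() if b == label]


# ---------------------------------------------------------------------------
# basis construction


def make_basis(log_means, log_sds=None, blocks=(), block_corr: float = 0.7,
               ) -> Basis:
    """Block-equicorrelated log-normal basis parameters.

    ``blocks`` are consecutive block sizes laid out from taxon 0; taxa within
    a block get pairwise correlation ``block_corr``, across blocks 0.  The
    equicorrelation must satisfy rho >= -1/(k-1) (PSD); violations raise.
    """
    mu = np.asarray(log_means, dtype=float)
    n = len(mu)
    sd = np.full(n, 1.0) if log_sds is None else np.asarray(log_sds, dtype=float)
    if len(sd) != n:
        raise ValueError("log_sds length mismatch")
    corr = np.eye(n)
    start = 0
    for size in blocks:
        if size > n - start:
            raise ValueError("blocks exceed the number of taxa")
        if size > 1 and block_corr < -1.0 / (size - 1):
            raise ValueError(f"equicorrelation {block_corr} not PSD for block of {size}")
        idx = np.arange(start, start + size)
        corr[np.ix_(idx, idx)] = block_corr
        corr[idx, idx] = 1.0
        start += size
    cov = corr * np.outer(sd, sd)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10:
        raise ValueError("requested covariance is not positive semi-definite")
    return Basis(mu=mu, cov=cov)


def block_labels(n_taxa: int, blocks) -> list[str | None]:
    """Planted module label per taxon (B1.., None outside blocks)."""
    labels: list[str | None] = [None] * n_taxa
    start = 0
    for k, size in enumerate(blocks, start=1):
        for i in range(start, start + size):
            labels[i] = f"B{k}"
        start += size
    return labels


# ---------------------------------------------------------------------------
# count sampling


def _draw_fractions(basis: Basis, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """(n_samples x n_taxa) compositions from the log-normal basis."""
    jitter = 1e-10 * np.eye(basis.n_taxa)
    logw = rng.multivariate_normal(basis.mu, basis.cov + jitter, size=n_samples,
                                   method="cholesky")
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def _draw_depth(cfg_mean: float, dispersion: float, min_depth: int | None,
                rng: np.random.Generator) -> int:
    p = dispersion / (dispersion + cfg_mean)
    depth = int(rng.negative_binomial(dispersion, p))
    if min_depth is not None:
        depth = max(depth, int(min_depth))
    return max(depth, 1)


def _dm_counts(frac: np.ndarray, depth: int, theta: float,
               rng: np.random.Generator) -> np.ndarray:
    """Dirichlet-multinomial counts; theta=0 is plain multinomial."""
    frac = np.asarray(frac, dtype=float)
    pos = frac > 0
    p = frac
    if theta > 0:
        conc = (1.0 - theta) / theta
        alpha = frac[pos] * conc
        draw = rng.dirichlet(alpha)
        p = np.zeros_like(frac)
        p[pos] = draw
    counts = np.zeros(len(frac), dtype=np.int64)
    counts[pos] = rng.multinomial(depth, p[pos] / p[pos].sum())
    return counts


def simulate_counts(
    basis: Basis,
    n_samples: int,
    depth_cfg: tuple[float, float] = (20_000.0, 20.0),
    theta: float = 1e-4,
    seed: int | None = None,
    min_depth: int | None = None,
    asv_ids=None,
    sample_ids=None,
) -> AsvTable:
    """Sample an ASV count table from a basis (taxa x samples).

    Per sample: basis abundances are drawn log-normal(mu, cov), closed to
    fractions, and counts drawn Dirichlet-multinomial with overdispersion
    ``theta`` at a negative-binomial depth.  Fully reproducible given seed.
    """
    if depth_cfg[0] <= 0:
        raise ValueError("depth mean must be > 0")
    rng = np.random.default_rng(seed)
    frac = _draw_fractions(basis, n_samples, rng)
    cols = {}
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    for si in range(n_samples):
        depth = _draw_depth(depth_cfg[0], depth_cfg[1], min_depth, rng)
        cols[sample_ids[si]] = _dm_counts(frac[si], depth, theta, rng)
    asv_ids = asv_ids or [f"t{i}" for i in range(basis.n_taxa)]
    return AsvTable(pd.DataFrame(cols, index=asv_ids))


# ---------------------------------------------------------------------------
# the full scenario


def simulate_fmt_timecourse(config: ScenarioConfig | None = None,
                            ) -> tuple[AsvTable, TaxonomyMap, SampleMetadata, FmtTruth]:
    """Generate the full FMT time course plus taxonomy, metadata, and truth."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)

    n_d, n_r, n_o = cfg.n_taxa_donor, cfg.n_taxa_recipient, cfg.n_overlap
    if n_o > min(n_d, n_r):
        raise ValueError("n_overlap exceeds a basis size")
    donor_ids = [f"ASV_d{i:03d}" for i in range(n_d - n_o)]
    shared_ids = [f"ASV_x{i:03d}" for i in range(n_o)]
    recip_ids = [f"ASV_r{i:03d}" for i in range(n_r - n_o)]
    ind_ids = {
        g: [f"ASV_i{g}{i:02d}" for i in range(cfg.n_indicators)]
        for g in cfg.indicator_groups
    }
    universe = donor_ids + shared_ids + recip_ids + sum(ind_ids.values(), [])
    pos = {a: k for k, a in enumerate(universe)}
    n_u = len(universe)

    # donor basis: donor-only taxa first (blocks sit here), then shared
    donor_taxa = donor_ids + shared_ids
    mu_d = np.empty(len(donor_taxa))
    top = np.asarray(cfg.donor_dominant_fracs)
    rest = max(1.0 - top.sum(), 0.05) / max(len(donor_taxa) - len(top), 1)
    mu_d[: len(top)] = np.log(top)
    mu_d[len(top):] = np.log(rest)
    # planted blocks sit away from the dominant taxa so module recovery is
    # not confounded with dominance
    n_block = sum(cfg.donor_blocks)
    block_start = len(top)
    order = np.arange(len(donor_taxa))
    donor_block_idx = order[block_start: block_start + n_block]
    basis_d = _basis_with_blocks(mu_d, cfg.log_sd, donor_block_idx, cfg.donor_blocks,
                                 cfg.block_corr)

    recip_taxa = recip_ids + shared_ids
    mu_r = np.full(len(recip_taxa), np.log(1.0 / len(recip_taxa)))
    recip_block_idx = np.arange(sum(cfg.recipient_blocks))
    basis_r = _basis_with_blocks(mu_r, cfg.log_sd, recip_block_idx,
                                 cfg.recipient_blocks, cfg.block_corr)

    # antibiotic knockdown: a seeded subset of recipient taxa loses abundance
    n_kd = int(round(cfg.at_knockdown_frac * len(recip_taxa)))
    kd_idx = rng.choice(len(recip_taxa), size=n_kd, replace=False)
    mu_at = mu_r.copy()
    mu_at[kd_idx] += cfg.at_knockdown_logfc
    basis_at = Basis(mu=mu_at, cov=basis_r.cov)

    # per-(group, taxon) uniform draws drive monotone presence dynamics:
    # donor taxa drop out as retention decays, recipient taxa appear as
    # colonization grows
    u_donor = {g: rng.random(len(donor_taxa)) for g in cfg.engraftment}
    u_recip = {g: rng.random(len(recip_taxa)) for g in cfg.engraftment}

    def embed(ids, values) -> np.ndarray:
        v = np.zeros(n_u)
        for a, x in zip(ids, values):
            v[pos[a]] = x
        return v

    def with_indicators(frac_u: np.ndarray, group: str) -> np.ndarray:
        if group not in ind_ids:
            return frac_u / frac_u.sum()
        out = frac_u.copy()
        for a in ind_ids[group]:
            out[pos[a]] = cfg.indicator_frac * float(rng.lognormal(0.0, 0.3))
        return out / out.sum()

    samples: dict[str, np.ndarray] = {}
    meta_rows = []

    def add_sample(name: str, group: str, day: int, frac_u: np.ndarray):
        depth = _draw_depth(cfg.depth_mean, cfg.depth_dispersion, cfg.min_depth, rng)
        samples[name] = _dm_counts(frac_u, depth, cfg.theta, rng)
        meta_rows.append((name, group, day))

    for g in ("P", "CV", "AT"):
        n_g = cfg.group_sizes.get(g, 0)
        basis = {"P": basis_d, "CV": basis_r, "AT": basis_at}[g]
        ids = donor_taxa if g == "P" else recip_taxa
        frac = _draw_fractions(basis, n_g, rng)
        for i in range(n_g):
            add_sample(f"{g}{i}", g, 0, with_indicators(embed(ids, frac[i]), g))

    for g, curve in cfg.engraftment.items():
        n_g = cfg.group_sizes.get(g, 0)
        for day in cfg.timepoints:
            pi = float(curve[day])
            retained = u_donor[g] < float(cfg.donor_retention[g][day])
            colonized = u_recip[g] < float(cfg.colonization[g][day])
            fr_d = _draw_fractions(basis_d, n_g, rng)
            fr_r = _draw_fractions(basis_r, n_g, rng)
            for i in range(n_g):
                d_part = fr_d[i] * retained
                r_part = fr_r[i] * colonized
                if d_part.sum() > 0:
                    d_part = d_part / d_part.sum()
                if r_part.sum() > 0:
                    r_part = r_part / r_part.sum()
                mix = pi * embed(donor_taxa, d_part) + (1 - pi) * embed(recip_taxa, r_part)
                add_sample(f"{g}{i}_d{day}", g, day, with_indicators(mix, g))

    table = AsvTable(pd.DataFrame(samples, index=universe))
    meta = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "group", "day"]
                     ).set_index("sample_id")
    )
    taxonomy = _synthetic_taxonomy(donor_ids, shared_ids, recip_ids, ind_ids)
    truth = _build_truth(cfg, universe, pos, donor_ids, shared_ids, recip_ids,
                         ind_ids, donor_taxa, donor_block_idx, recip_taxa,
                         recip_block_idx, basis_d, basis_r)
    return table, taxonomy, meta, truth


def _basis_with_blocks(mu, log_sd, block_positions, block_sizes, rho) -> Basis:
    """Equicorrelated blocks at arbitrary (contiguous-in-list) positions."""
    n = len(mu)
    sd = np.full(n, float(log_sd))
    corr = np.eye(n)
    start = 0
    for size in block_sizes:
        idx = np.asarray(block_positions[start: start + size])
        if size > 1 and rho < -1.0 / (size - 1):
            raise ValueError("equicorrelation not PSD")
        corr[np.ix_(idx, idx)] = rho
        corr[idx, idx] = 1.0
        start += size
    cov = corr * np.outer(sd, sd)
    if np.linalg.eigvalsh(cov).min() < -1e-10:
        raise ValueError("covariance not PSD")
    return Basis(mu=np.asarray(mu, dtype=float), cov=cov)


def _synthetic_taxonomy(donor_ids, shared_ids, recip_ids, ind_ids) -> TaxonomyMap:
    lineages = {}

    def assign(ids, vocab):
        for k, asv in enumerate(ids):
            genus, phylum = vocab[k % len(vocab)]
            lineages[asv] = ("Bacteria", phylum, UNASSIGNED, UNASSIGNED,
                             UNASSIGNED, genus, UNASSIGNED)

    # the dominant donor taxa map to distinct genera (round-robin keeps every
    # genus populated with several ASVs)
    assign(donor_ids, DONOR_GENERA)
    assign(shared_ids, [("Lactobacillus", "Firmicutes"),
                        ("Blautia", "Firmicutes")])
    assign(recip_ids, RECIPIENT_GENERA)
    for g, ids in ind_ids.items():
        vocab = DONOR_GENERA if g == "P" else RECIPIENT_GENERA
        assign(ids, vocab[5:] + vocab[:5])
    return TaxonomyMap(lineages)


def _build_truth(cfg, universe, pos, donor_ids, shared_ids, recip_ids, ind_ids,
                 donor_taxa, donor_block_idx, recip_taxa, recip_block_idx,
                 basis_d, basis_r) -> FmtTruth:
    source = {}
    for a in donor_ids:
        source[a] = "donor"
    for a in shared_ids:
        source[a] = "shared"
    for a in recip_ids:
        source[a] = "recipient"
    indicator_map = {}
    for g, ids in ind_ids.items():
        for a in ids:
            source[a] = "donor" if g == "P" else "recipient"
            indicator_map[a] = g

    n_u = len(universe)
    corr = np.eye(n_u)

    def fill(ids, cov):
        sd = np.sqrt(np.diag(cov))
        c = cov / np.outer(sd, sd)
        idx = [pos[a] for a in ids]
        corr[np.ix_(idx, idx)] = c

    fill(donor_taxa, basis_d.cov)
    fill(recip_taxa, basis_r.cov)

    modules: dict[str, str | None] = {a: None for a in universe}
    labels_d = block_labels(len(donor_taxa), cfg.donor_blocks)
    for local, lab in zip(donor_block_idx, labels_d):
        modules[donor_taxa[local]] = f"donor-{lab}"
    labels_r = block_labels(len(recip_taxa), cfg.recipient_blocks)
    for local, lab in zip(recip_block_idx, labels_r):
        modules[recip_taxa[local]] = f"recipient-{lab}"

    return FmtTruth(
        source=source,
        basis_correlation=pd.DataFrame(corr, index=universe, columns=universe),
        module_labels=modules,
        indicator_map=indicator_map,
    )
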