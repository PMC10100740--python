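# Methods

`fmtnet` analyses fecal-microbiota-transplant (FMT) time courses from an ASV
count table upward: diversity comparison, indicator-species detection, SparCC
co-occurrence network inference, indicator-guided module identification, and
donor-taxon retention tracking. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely open.

## Data model and preprocessing

The central container is the ASV table: non-negative integer counts, rows =
amplicon sequence variants, columns = samples, round-tripping through TSV and
BIOM-JSON v1.0. Taxonomy is a seven-rank lineage per ASV (SILVA-style
semicolon strings; rank prefixes stripped, missing ranks `unassigned`).
Sample metadata carries a group label from the six-group FMT design — donor
(P), conventional mice (CV), antibiotic-treated (AT), antibiotic + multiple
FMT (AM), germfree multiple FMT (M), germfree single FMT (S) — and a sampling
day in {0, 3, 7, 14, 21}.

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a common depth, default 14,419 reads — the study's even
depth. Samples below the depth are dropped with a logged warning rather than
raising; the generated scenarios guarantee depths above it by construction.
Relative-abundance views close each sample to 1; rank-collapsed views pool
taxa whose *mean* relative abundance across the displayed samples falls below
1% into an `Others` bucket (the mean rule keeps display legends stable; the
threshold is a parameter).

## Diversity

* Richness = observed ASV count on rarefied data (deliberately not Chao1;
  swap in any estimator by operating on the rarefied table).
* Shannon entropy H = −Σ p_i log₂ p_i, base 2 by default (a parameter).
* Beta diversity: Bray-Curtis on rarefied counts, ordinated by classical
  PCoA. Axes with non-positive eigenvalues are dropped from coordinates but
  all eigenvalues are reported.
* PERMANOVA partitions the squared-distance matrix: pseudo-F =
  (SS_between/(g−1)) / (SS_within/(n−g)) with SS_total = (1/n)Σ_{i<j} d²_ij
  and SS_within summed per group. The p-value uses seeded label shuffles
  with the add-one convention, or exhaustive enumeration of distinct
  labellings for small n (then the p is exact, identity included).
  All-identical data returns (F=0, p=1) rather than NaN.
* Univariate group tests: tie-corrected Kruskal-Wallis (all-equal data → H=0,
  p=1) and pairwise two-sided rank-sum tests.

TMM normalization provides between-sample scaling for the indicator and
network stages: the reference is the sample whose 75th-percentile count
fraction is closest to the mean of those; per sample, log2 fold changes M
and average log abundances A are computed over ASVs nonzero in both, the
extreme 30% by M and 5% by A are trimmed, and the factor is the
inverse-variance-weighted (precision-weighted) mean of the surviving M,
rescaled so factors have geometric mean 1. This is the edgeR construction;
the implementation agrees with `edgeR::calcNormFactors` to ~1e-6 on shared
fixtures (cross-checked in the test suite via Rscript).

## Differential abundance (LEfSe-style)

Per-taxon Kruskal-Wallis screens at α = 0.05; surviving taxa are rescaled to
per-million and scored one-vs-rest per group over 30 seeded bootstrap
subsamples (2/3 of samples each). Each subsample fits a two-class linear
discriminant from a ridge-regularized pooled within-class covariance
(diagonal loading 1e-3 × mean diagonal; direction normalized to unit length).
The effect size of taxon f is ½(|Δ raw class means| + |w_f · Δ mean_f|) —
the raw difference averaged with the share of the projected difference
attributable to f — and the LDA score is log₁₀ of the bootstrap-mean effect.
Records need score > 4.0 (the study's display cutoff) and are reported for
the group where the taxon is enriched. This scoring is this package's
declared formulation of the idea: it reproduces the qualitative behaviour
(a taxon at 2×10⁵ per-million vs 0 scores ≥ 5; nulls report nothing at
realistic richness) but is not bit-compatible with the original tool, whose
subclass/Wilcoxon stage is also skipped because this design has no
subclasses.

## Indicator species (IndVal)

For species i and target t: specificity A_it = (mean abundance in t) / (Σ of
group means), fidelity B_it = occurrence fraction in t, IndVal = A×B, and the
reported statistic is √(max_t IndVal) (the dominant ecology-package
convention; the raw IndVal is also emitted). Significance comes from 999
seeded permutations of the group labels, add-one p. Targets are single
groups by default; the combination mode ranges over non-trivial group
subsets, with a combination's specificity the summed per-group mean share
and its fidelity the pooled occurrence fraction. The pipeline runs the
combination mode and defines the indicator set of group g as the significant
ASVs whose best target contains g — an engrafted donor taxon can then
indicate "P or S" rather than being split. Inputs are TMM-normalized
abundances by default (rarefied counts work equally; the statistic uses only
means and presence).

## SparCC

Counts carry only relative information; correlations of fractions are
biased. SparCC works from log-ratio variances T_ij = Var log(x_i/x_j)
(depth-invariant) and, under sparsity, solves

    [(p−2)·I + J] ω = t,  t_i = Σ_{j≠i} T_ij

for basis variances ω, giving r_ij = (ω_i + ω_j − T_ij) / (2√(ω_i ω_j)),
clamped to [−1, 1], ω floored at 1e-12. Strong pairs violate sparsity, so up
to 10 exclusion rounds each remove the single largest |r| above 0.1 from the
sums (ties by lowest index pair) and re-solve, stopping early if any taxon
would fall below 3 partners. A pseudocount of 0.05 (the study's value) is
added to every cell before closure; zeros-only placement is available. The
default is deterministic point-estimate fractions; optional Dirichlet inner
resampling (typically 20 draws, element-wise median r) reproduces the
original tool's posterior-sampling behaviour at the cost of Monte-Carlo
noise. Estimation requires ≥ 4 taxa (under-determined below) and warns
under 10.

P-values: each of 100 bootstrap replicates permutes every taxon's counts
across samples independently (destroying correlation, preserving marginals)
and re-estimates r; two-sided add-one p, so 1/101 is the attainable floor.

Accuracy context: at n = 100 samples the sampling noise of *any* pairwise
correlation estimator is ≈ 1/√(n−1) ≈ 0.1 per pair; an oracle Pearson
estimator given the true latent log-abundances reaches an RMSE of ≈ 0.101
over all pairs of the planted-block benchmark (p = 50, three blocks of 5 at
ρ = 0.7). The SparCC point estimate measures ≈ 0.102 — essentially at the
information floor — with planted-edge sensitivity 1.0 at |r| ≥ 0.3.

## Network, threshold, and modules

Edges require |r| ≥ 0.3 and p < 0.05 by default (a signed-positive mode
exists because thresholding conventions differ). The cutoff can instead be
scanned by a random-matrix-theory criterion: for each candidate cutoff the
thresholded matrix's eigenvalue spacings are unfolded with a degree-9
polynomial fit of the empirical spectral CDF and compared by chi-square
against Poisson, e^{−s}, vs Wigner-Dyson (GOE), (πs/2)e^{−πs²/4}; the
smallest cutoff where Poisson fits better is chosen (noise-dominated spectra
show level repulsion, decoupled modular structure shows clustering).
Degenerate eigenvalues keep their zero spacings — level clustering is
Poisson evidence, not an artifact. If no transition is found the configured
default (0.3) is returned with a warning.

The indicator subnetwork keeps indicators present in the network plus their
direct neighbours (induced subgraph). Modules come from agglomerative greedy
maximisation of Newman modularity Q = Σ_c (e_cc − a_c²) on the unweighted
edge set (networkx CNM implementation; Q is verified against a brute-force
evaluation in the tests). Communities containing ≥ 1 indicator ASV and
≥ 3 members (a configurable floor that demotes fragments) become modules
M1..Mk ordered by decreasing size, ties by smallest member id; all other
nodes are labelled NA. Module members are the key species, NA nodes the
peripheral species — NA is read as "community with no indicator species",
which is what makes modules indicator-related.

## Retention tracking

For each (group, day) network the key species are tallied by genus —
distinct ASV counts, never abundance; `unassigned` is its own bucket,
excluded from top-k rankings by default. The genus panel is the union of
the donor and recipient top-10 genera, each column tagged donor / recipient /
shared. Profiles are clustered hierarchically: rows z-scored (σ floored at
1e-12 so constant rows survive), Euclidean distance, average linkage;
"nearest to the donor" means smallest cophenetic distance. Euclidean/average
is a conservative default; raw-count clustering is available.

## Synthetic scenario generator

The generator produces data from exactly the model the estimators assume,
so the tests measure estimator correctness, not model mismatch:

* **Basis**: per-taxon log-normal latent abundances with block-equicorrelated
  covariance (blocks = planted modules; equicorrelation must satisfy
  ρ ≥ −1/(k−1) for PSD). Log-sd 1.0 — the spread typical of amplicon
  log-abundances.
* **Counts**: closure to fractions, then Dirichlet-multinomial at a
  negative-binomial depth (mean 20,000, dispersion 20, floored at 15,000 so
  every sample survives rarefaction to 14,419). The overdispersion θ = 1e-4
  is deliberately *technical-scale only* (count-variance inflation ~3× at
  these depths): biological variation already lives in the log-normal basis,
  and a larger θ would double-count it — an early θ of 2e-3 measurably
  destroyed planted correlations (per-taxon Dirichlet concentrations near 1
  inject log-noise of order ψ₁(1) ≈ 1.6) and was corrected on those grounds.
* **Communities**: the donor (P) basis is low-diversity with three dominant
  genera near 49/17/9% (the giant-panda faeces scale) and donor-typical
  genus names; the recipient (CV) basis is richer with mouse-gut genera; AT
  is the recipient basis with a seeded 60% of taxa knocked down by e⁻³.
* **Transplant groups**: the community of group g at day t mixes
  π_g(t)·donor + (1−π_g(t))·recipient at the abundance level, while
  *presence* follows per-ASV monotone Bernoulli dynamics — a donor taxon is
  retained while its uniform draw is below a decaying retention curve, a
  recipient-side taxon appears once its draw falls below a growing
  colonization curve. Defaults encode the study's qualitative course:
  single-FMT germfree mice start near-identical to the donor
  (π = 0.95, retention 0.92, colonization 0.08 at day 3) and drift mildly;
  multiple-FMT mice start less donor-like (repeated dosing perturbs early
  assembly) and converge later; antibiotic-treated transplant mice revert
  toward their residual native community by day 21 (π down to 0.1,
  colonization up to 0.95).
* **Indicators**: six group-exclusive taxa each are planted for P, CV, and
  AT at ~1% abundance.
* **Truth ledger**: per-ASV source (donor/recipient/shared), the true basis
  correlation matrix, planted block labels, and the planted indicator map.

What the generator does *not* emulate: phylogenetic structure, strain-level
variation, mechanistic ecological dynamics (no Lotka-Volterra), primer or
copy-number bias, and chimeras/contamination. Passing tests therefore
demonstrate that the pipeline recovers structure *when the data match the
model assumptions*; they do not certify performance on real sequencing runs,
where compositional noise is heavier-tailed and correlations are weaker.

## Pipeline

Stages run in order rarefy → diversity → differential abundance → indicator
species → per-network SparCC → thresholding/intersection/modules →
retention, writing plain-text artifacts (TSV/JSON) plus a JSON-lines log
with stage, seed, and status. Networks follow the figure structure of the
design: one per endpoint group (P, CV, AT) and one per (transplant group,
day); per-network taxa need counts in ≥ 2 samples of the subset. All
randomness derives from one master seed through spawned seed sequences, so
identical configs reproduce byte-identical deterministic artifacts (force-
directed layouts are cosmetic and excluded). Networks with fewer than 4
samples or 4 prevalent taxa are skipped with a warning.

Problem sizes used by the shipped verification runs (`scripts/acceptance.py`
and the test suite) are the scenario defaults above — 106 samples, ~170
taxa, 999-permutation tests, 100-replicate bootstraps, 10-seed medians for
recovery statistics and 5-seed majorities for the qualitative end-to-end
check; these sizes make the whole verification run in well under an hour on
one core while keeping every statistical envelope meaningful.

## Known limitations

* The LEfSe-style score is a documented reimplementation, not the original
  tool; absolute scores can differ even where rankings agree.
* SparCC p-values inherit bootstrap granularity (floor 1/(n_boot+1)); with
  few samples per network (6-10 in the scenario) edge sets are noisy, which
  the retention stage absorbs by counting genera rather than edges.
* The RMT cutoff scan needs enough distinct eigenvalues (≥ 12) to say
  anything; tiny networks fall back to the default cutoff.
* Donor-metadata arithmetic (ages, birth years) is intentionally out of
  scope.
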