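# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `infantde`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pseudobulk NB Wald differential expression

The unit of replication is the pseudobulk sample: counts summed over one
individual's nuclei of one cell type. `aggregate_pseudobulk` performs
the summation and drops groups below `min_cells` (default 10, logged).

Counts are modelled as NB2: Var(y) = μ + α·μ². The engine is a minimal
DESeq2-family implementation rather than a wrapper, consisting of:

* **Size factors** — median over genes expressed in every sample of the
  count/geometric-mean ratio, normalized to geometric mean 1. When no
  gene is expressed everywhere the engine falls back to total-count
  ratios with a warning.
* **Dispersion** — per-gene method of moments on normalized counts,
  α̂ = (s² − m·z̄)/m², where s² is the within-group pooled variance with
  df = n − n_groups and z̄ = mean(1/s_j) corrects for the extra Poisson
  noise normalization introduces. Raw estimates are blended (default
  weight 0.5, arithmetic on the α scale so negative raw values shrink
  past the trend no further than the floor) toward a robustly fitted
  trend α(m) = a₀ + a₁/m, then floored at 1e-8. The shrinkage trades a
  little per-gene bias for much lower variance, which is what keeps the
  Wald test near its nominal level at ~10 samples per group; the test
  suite measures the type-I error directly. All-zero genes are flagged
  untestable.
* **Group means** — maximum likelihood at fixed dispersion by the
  fixed-point iteration μ ← Σy / Σ[(y + 1/α)·α·s/(1 + α·s·μ)], which
  reduces to Σy/Σs in the Poisson limit; iterated to relative tolerance
  1e-12 (cap 100 iterations).
* **Wald test** — log2FC = log2(μ_A/μ_B) with each group mean floored
  at `mu_floor` (default 0.5 normalized counts; floored genes are
  flagged, genes zero in both groups get p = 1). The SE comes from the
  expected Fisher information of log μ, I = Σ s·μ/(1 + α·s·μ) per
  group. Two-sided normal p-values; BH-FDR within each cell type ×
  contrast, matching the per-cell-type reporting of DE counts.

Calling uses strict inequalities, |log2FC| > 0.5 and FDR < 0.05, since
these thresholds are stated as bounds. No covariates (sex, batch) are
supported; the design is the two-group species contrast within one cell
type and age group.

## Divergence sets

"Human-specific" is operationalized as significant with concordant sign
in both pairwise contrasts (vs chimpanzee and vs rhesus); a pooled
one-vs-rest alternative is available via `mode="one_vs_rest"`. The
infant-specific set subtracts the adult set of the same cell type and
direction; a gene DE in opposite directions across ages stays
infant-specific. Jaccard of two empty sets is defined as 1 with a
warning. The flag-list confounder tests default their universe to the
genes tested in that cell type's DE run.

## Enrichment statistics

* Hypergeometric upper tails and Fisher point probabilities come from
  `scipy.stats.hypergeom`; the Fisher two-sided rule sums tables with
  point probability ≤ observed × (1 + 1e-7) — the dominant convention,
  with the tolerance absorbing floating-point ties. One-sided values are
  tail sums, and `fisher_exact(greater)` coincides with the
  hypergeometric upper tail by construction. The spec-level invariant
  that holds is p_two ≥ min(p_greater, p_less): the two-sided p can be
  far below the *other* tail's one-sided p.
* Odds ratios are unconditional (a·d)/(b·c) — the convention that
  reproduces printed values exactly — with +inf / 0 / NaN conventions
  for degenerate diagonals. On the TF-level lineage table the one-sided
  (greater) Fisher p (≈ 0.0248) matches the printed value where the
  two-sided p (≈ 0.0496) does not; both are reported.
* BH-FDR delegates to `statsmodels.stats.multitest` (step-up, monotone,
  capped at 1). For risk-gene grids it is applied once across the whole
  (cell type × disease list) grid within each direction; rerunning on a
  subset of lists never changes raw p-values but can change FDRs.
* The combined score ln(OR)·(−ln p) replaces the EnrichR service's
  rank-based formula (which needs their background ranking); it sizes
  dots only and never decides significance. Infinite ORs are clamped at
  1e6 before scoring.
* The chi-square test of independence drops zero-margin rows/columns
  with a warning, flags cells with expected count below 5 (configurable)
  and reports Pearson residuals (O − E)/√E.

## hiDECORE network construction

Retention requires, in fixed attribution order: (node) TF and target are
both hiDE gains in the lineage; (i) the mediating region overlaps at
least one annotated human-specific sequence change; (ii) TF-to-gene
score > 0; (iii) region-to-gene score > 0; (role) the regulon is an
activator. An edge's failure is attributed to the first failing rule, so
provenance counts are reproducible and satisfy retained + Σ failures +
universe-exclusions = input edges. Repressor regulons are excluded
because the positive-correlation rules demand activation; their count is
reported. Disabling any rule (the `rules` argument) can only grow the
network, which the tests exercise.

Interval overlap is the 0-based half-open ≥ 1 bp rule, computed by a
per-chromosome sort-and-sweep with a min-heap of active intervals;
because regions are start-sorted but not end-sorted, each candidate is
re-checked against the region's end before a hit is recorded. The engine
is verified against a quadratic all-pairs oracle.

Capture concordance restricts to network regions present in the assay's
bait set and reports (a) the fraction with at least one captured target
and (b) the fraction of network region→target pairs present among the
capture pairs.

## Trajectories

Module scores per nucleus are mean module expression minus the mean of
control genes: genes are ranked by mean expression into `n_bins` = 25
equal-occupancy bins and each module gene draws `n_ctrl` = 50 controls
from its bin without replacement (with replacement plus a warning when
the bin is too small). A random module therefore scores 0 in
expectation, and a constant matrix scores exactly 0. "Normalized" means
control-subtracted; no further z-scaling is applied. Trend fits are
descriptive lowess over log2(age + 0.1) years (offset configurable to
admit prenatal/0-year samples); age-group bin edges default to (0, 1,
20). Cell-type proportions are computed per individual within a stated
denominator lineage (so they sum to 1 exactly), and the infant-vs-adult
log2FC of group means accepts a configurable pseudo-fraction for zero
groups.

## Synthetic data: what it emulates, and what it does not

The generator simulates directly at the pseudobulk level under the same
NB2 model the engine fits, with planted log2 effects:

* Default study conditions: 3 species × 2 age groups × 4 cell types
  (2 neural, 2 oligodendrocyte-lineage), 10 individuals per species per
  age, 2000 genes, planted |log2FC| = 1 against the 0.5 calling
  threshold. Per cell type, 10% of genes are hiDE (gain/loss split
  evenly), a disjoint 10% are ciDE, 5% are shared infant+adult effects
  and 5% adult-only.
* Baseline means are log-uniform on (10, 1000) and dispersions
  log-uniform on (0.01, 0.1) — the primary data's depth and dispersion
  are not published, so these are chosen for test power, i.e. so that
  planted effects are recoverable but not trivially so at n = 10. Size
  factors are log-normal(0, 0.2) to exercise normalization.
* A 40-gene lineage-shared core is planted as gains in one cell type of
  each lineage; regulon TFs are drawn from it and 80% of designed pass
  edges target it, emulating the observed lack of lineage specificity of
  the core network. Each retention rule gets ≥ 5 edges designed to fail
  exactly that rule, plus 40 background edges per lineage with random
  genes, signed scores and mixed roles (~50% annotated regions).
* Regions live on one synthetic chromosome "chrS", ids are
  coordinate-encoded (`chrS:start-end`), and annotation intervals are
  nested inside their regions with decoys in the gaps, so the emitted
  BED reproduces the annotation truth exactly under the overlap engine.
* Disease truth gives network genes a strong lineage-matched signal
  (ASD in the OL lineage, PD in neural), non-network focal gains a
  weaker signal with a planted down-excess (feeding the directionality
  contingency), and background genes a flat 5% rate. Risk lists hit
  lineage gains at 3× the background rate. Capture pairs bait the
  annotated pass-edge regions with planted edge-level concordance 0.9.
* All randomness flows from `SimConfig.seed` through named child
  streams; adding individuals (the robustness rerun) leaves existing
  columns untouched.

What the generator does **not** emulate: cell-level structure (ambient
RNA, doublets, dropout), clustering or annotation error, batch and sex
covariates, phylogenetic correlation between the two comparison species,
mean–dispersion coupling, and realistic gene-gene correlation. Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under its own model assumptions — not robustness
to the full messiness of real single-nucleus data.

## Problem sizes and determinism

The validation suite runs the full default bundle (2000 genes, 240
pseudobulk samples, 16 DE contrasts), an exhaustive exact-test
enumeration over all 2×2 tables with total ≤ 30, a 1000×1000 interval
comparison against the quadratic oracle, and 100-seed module-score
nulls; these sizes keep the whole suite in well under a minute of
compute while leaving the statistical checks well-powered. Every
simulation, test and pipeline stage is seeded; pipeline reruns with the
same configuration produce byte-identical outputs (checksummed in the
run log).

## Known limitations

* The DE engine implements fixed-dispersion Wald tests without
  Cox–Reid adjustment or apeGLM-style LFC shrinkage; at very small n or
  extreme dispersions it will differ from full DESeq2 fits.
* Gene identifiers are matched exactly as opaque strings; no
  symbol-alias resolution is attempted, and cross-dataset mismatches
  are only logged.
* Patient DE significance is taken as given from the input table (an
  FDR pre-filter is applied by the loader); re-deriving patient DE is
  out of scope.
* The CLI's per-stage subcommands rerun the deterministic pipeline up
  to the requested stage rather than consuming partial outputs; for
  iterative work the library API is the intended surface.
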