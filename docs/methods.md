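# Methods

## Differential expression

Expression values are log2 intensities. Columns are quantile normalized by
rank assignment to the across-sample mean of order statistics; ties are
broken by row order (stable argsort), which makes the transform idempotent.
Probes mapping to the same gene are collapsed by the arithmetic mean;
unmapped probes are dropped with a logged count. No detection-p-value or
platform QC filter is implemented — probe quality control is represented
downstream only as "gene not measured" availability flags.

Each gene is fit by OLS on an intercept, a case/control indicator, and
dummy columns for optional blocking covariates (`batch`, `family_id`). The
log2 fold change is the group coefficient (case − control). Covariate
levels observed in exactly one sample are merged into the reference level:
a singleton level carries no blocking information, and — decisive for
twin-cohort designs in which one group holds all the twin pairs and the
other only unrelated individuals — the union of singleton-level indicators
would otherwise span a whole group and make the group contrast inestimable.
Family structure is thus a fixed blocking effect on genuine twin pairs, a
deliberate, testable approximation to a mixed model with a random family
effect (the fixed-effect fit is slightly conservative when family variance
is small).

Gene-wise residual variances s²_g (df d) are shrunk by empirical Bayes
under a scaled inverse-χ²(d₀, s₀²) prior: s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d),
moderated t = logFC/(s̃_g√v) on d₀+d df, where v is the contrast entry of
(XᵀX)⁻¹. (d₀, s₀²) are estimated by method of moments on z = log s²:
marginally s²/s₀² ~ F(d, d₀), so Var[z] − ψ′(d/2) = ψ′(d₀/2), solved by
Newton inversion of the trigamma function; non-positive excess variance
yields d₀ = 10⁶, the "effectively infinite" cap (all genes pooled to s₀²).
Pinning d₀ = 0 recovers the ordinary two-sample t exactly; d₀ = ∞ gives the
fully pooled limit — both limits are tested to machine precision.

Benjamini–Hochberg adjustment (step-up, adj_p monotone in raw p, capped at
1) controls FDR; the defaults are 5% for discovery-style cohorts and 10%
for validation-style cohorts, both exposed. Restricted-list testing keeps
raw p-values untouched and re-runs BH over a pre-specified candidate subset
(e.g. the hub genes), recording candidates missing from the platform.
Tumor-style comparisons use the same fit with a batch covariate and report
unadjusted p-values.

## Subnetwork significance

The minimal connected network (MCN) of a gene list is computed in two
modes. *direct*: induced subgraph on the mapped list genes, isolated nodes
dropped (all components of size ≥ 2 kept). *one_linker*: a non-list node is
admitted when adjacent to ≥ 2 mapped list genes — a linker adjacent to one
list gene cannot link anything, so the ≥ 2 threshold is the minimal
meaningful interpretation of single-linker augmentation.

Three topology statistics are exposed: retained node count, largest
connected component as a fraction of the mapped list size (default — node
counts are how such networks are conventionally summarized, and the
fraction makes the statistic size-comparable across permutations), and
mean normalized betweenness within the subnetwork. The null is n_perm
uniform random node subsets of the same mapped size drawn from the whole
interactome — no degree matching, matching the "random lists of the same
size" null this procedure descends from. The reported p-value is the
add-one estimator (1 + #{null ≥ obs})/(n_perm + 1), which is never exactly
0 (floor 1/(n_perm+1) ≈ 1e-4 at 10,000 permutations) and never
anti-conservative. Because the statistic is discrete, ties at the null's
upper quantiles can make the test *conservative* on a given graph; the
calibration suite therefore averages the rejection rate over independently
drawn graph instances. The permutation inner loop runs on a plain
adjacency-set representation (no graph objects); a test pins its exact
agreement with the public extraction + statistic path.

## Topology and hub selection

Degree is the incident-edge count; betweenness is exact Brandes
betweenness, normalized by (N−1)(N−2)/2 over the whole graph (not per
component), so values are in [0, 1] and comparable across components.
Distribution summaries use the sample SD (ddof = 1; switchable). Node
classes use strict inequalities — high: degree > μ+3σ; medium:
μ+2σ < degree ≤ μ+3σ; low otherwise; a σ = 0 degenerate distribution labels
everything low with a warning. Hubs are the high-class nodes plus non-high
nodes with betweenness > μ_btw + k·σ_btw (default k = 1.0: in sparse
biological networks the betweenness distribution is strongly right-skewed
and genuine bottlenecks can sit barely one SD above the mean; larger k
rapidly empties the rescue set). `first_neighbors` reports the hub
neighbourhood and its coverage of the network.

## Replication and power

`replicate_hubs` fits the genome-wide contrast on the validation cohort
once; table (A) reads significance off the genome-wide BH adjustment,
table (B) re-adjusts the same raw p-values over the measured hubs only.
Raw p-values are identical between (A) and (B) by construction; only the
multiplicity family differs, which is why a modest, consistent hub effect
can be significant in (B) while invisible in (A). Direction concordance
against the discovery dataset is flagged when discovery directions are
supplied.

Two-sample power is exact: noncentrality ncp = log2(FC)/(sd·√(1/n₁+1/n₂)),
df = n₁+n₂−2, power = P(|T_ncp| > t_{1−α/2,df}) via the noncentral t.
"Adjusted" power uses Bonferroni α/m — a deliberately simple, conservative
stand-in for multiplicity-adjusted power. The per-group SD of log2
expression is a required input; the package makes no claim about any
particular published power figure, whose underlying SD is not recoverable.

## Synthetic data

`simulate_interactome` grows a preferential-attachment (Barabási–Albert,
m = 2 edges per arriving node) or Erdős–Rényi graph over the gene universe
and plants a module: a random gene subset densified with random internal
edges to a target induced density (default 0.15), then bridged until
connected. `simulate_expression` draws gene variances from the scaled
inverse-χ²(d₀ = 4, s₀² = 0.05) prior — exactly the DE model's assumption,
so method-of-moments recovery of (d₀, s₀²) is a meaningful end-to-end
check — and adds a planted log2 fold change (mean 0.5, SD 0.1, random
sign) on the chosen DE genes, optional per-gene batch shifts, family
effects shared within twin pairs, and Gaussian noise. The default cohort
is 14 cases (three twin pairs plus singletons) vs 7 control singletons,
two batches; the default universe is 2,000 genes with a 60-gene planted
module. All generators are bit-reproducible from a single seed, fanned
out to independent streams per generator.

What the generator does **not** emulate: platform probe chemistry,
detection p-values, spatial artifacts, correlated (co-expressed) null
genes, non-Gaussian noise, or degree-biased coverage of the interactome by
the expression platform. Passing tests therefore demonstrate correctness
of the statistical machinery under its own model, not robustness to every
real-data pathology.

## Pipeline

`run_pipeline` executes: load → quantile normalize → moderated-t DE →
direction split → per-direction MCN + permutation test → topology + hub
selection → (optional) replication, writing a manifest of every artifact
and a run log with seed and version. Up- and down-regulated networks are
always built separately and never merged. A single global seed spawns
per-stage child seeds (NumPy `SeedSequence`), so adding or removing a
stage does not perturb the others. Re-running with the same config and
seed produces byte-identical outputs.

## Problem sizes

Default test-suite simulations use 600–2,000-gene universes, 300–10,000
permutations, 5–20 seeds per calibration or recovery check, and 50,000
Monte-Carlo replicates for the power oracle — sizes at which every
quantity checked has comfortably smaller Monte-Carlo error than the
tolerance asserted, while the whole suite runs in well under a minute of
compute for the unit tests plus a few minutes for the calibration suites.

## Known limitations

- Family blocking is fixed-effect; true twin studies are mixed-model
  territory. With all twin pairs inside one group, a random-effect fit
  would gain some power; the fixed-effect fit shown here is conservative.
- The permutation null draws lists uniformly over nodes; hub-rich lists
  are compared against typical lists, not degree-matched ones. A
  degree-matched null would be stricter for lists enriched in hubs.
- Hub-selection thresholds (μ+2σ/μ+3σ, rescue k) treat the degree and
  betweenness distributions as if the normal-theory tail heuristic were
  meaningful; in scale-free networks these are heavy-tailed, so the
  thresholds are best read as conventional cutoffs, not as calibrated
  significance levels.
- Symbol-level matching only: no probe→gene identifier service is bundled;
  the interactome edge list is assumed to use the same gene symbols as the
  expression matrix.
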