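# Methods

## The model

`metameta` pools genome-wide association findings that are available only
as (two-tailed p-value, total sample size) pairs. Each study is entered
on the Fisher-z partial-correlation scale:

    Z   = Phi^-1(1 - p/2)          (nonnegative standard normal deviate)
    z_r = Z / sqrt(n - 3)          (Fisher-z effect)
    SE  = 1 / sqrt(n - 3)

This is the classical variance-stabilized scale for a correlation
estimated from n subjects; entering Z/sqrt(n-3) with that SE makes the
study's Wald statistic reproduce the reported Z exactly. All effects are
entered with positive direction, reflecting the convention that a GWAS
association is reported as a positive signal regardless of which allele
drives it. The folding this implies (effects are magnitudes, not signed
estimates) is a deliberate modelling choice and is visible downstream:
funnels are one-sided and signed recovery of a negative true effect is
out of scope.

An optional `t`-based conversion (p -> t on n-2 df, r = t/sqrt(t^2+n-2),
Fisher transform) is provided for sensitivity analysis; the
normal-deviate form is the default because it reproduces the worked
single-study case (p=2e-8, n=14,754 -> 0.046 [0.030, 0.062]) to the
printed precision.

Study selection is two-phase: records at or above the genome-wide
threshold (default 5e-8) are discarded, then within each study the
single *largest* surviving p-value is kept ("most cautious" selection;
configurable to smallest). Ties break on the lexicographically smallest
rsID for determinism. Zero p-values (file underflow) are clamped to
1e-300 with a warning rather than rejected.

## Pooling

Random-effects pooling uses the DerSimonian-Laird moment estimator:
Q about the fixed-effect mean, C = sum(w) - sum(w^2)/sum(w),
tau^2 = max(0, (Q - (K-1))/C), starred weights 1/(SE^2 + tau^2).
Confidence intervals use the normal quantile (1.96 at 95%), not
Knapp-Hartung, matching the convention of the mainstream commercial
meta-analysis tools this pipeline mirrors. K=1 is handled as Q=0, df=0,
tau^2=0, I^2=0. The engine is verified against an independent
closed-form oracle on a thousand random instances and against R's
`metafor::rma(method="DL")` on the packaged inputs.

The second-level "meta-meta" treats each trait-level meta-analysis as
one pseudo-study. Two constructions are implemented:

* `pseudo_study` (default): each group's pooled two-tailed p-value and
  *total* sample size are re-converted through the same p->z_r mapping
  and pooled with DL. On the packaged three-group inputs this yields
  0.011 [0.004, 0.018], matching the reference summary 0.012
  [0.004, 0.020] within the rounding of its printed inputs (the group
  p-values are printed to 2-3 significant figures).
* `pooled_estimates`: the groups' (pooled z, SE) pairs are pooled
  directly. On the same inputs this yields ~0.031 and is therefore the
  rejected construction; it remains available because it is the more
  orthodox hierarchical choice when exact group-level estimates are
  trusted.

## Publication-bias battery

* **Classic fail-safe N**: max(0, (sum Z_i)^2 / z_alpha^2 - K).
* **Orwin fail-safe N**: max(0, K (mean_obs - criterion)/criterion) with
  the fixed-effect weighted mean as mean_obs; the criterion effect is a
  required user input.
* **Begg-Mazumdar**: Kendall tau between effects and sampling variances
  over all K(K-1)/2 pairs. The continuity correction shrinks |C - D| by
  one (sign preserved, floored at zero): for three concordant pairs this
  gives 2/3 ~ 0.66-0.67. A standardized variant (deviations from the
  fixed-effect mean scaled by their conditional SD) is available by flag.
* **Egger**: OLS of the standardized effect on precision; intercept,
  its SE, t = intercept/SE, df = K-2, computed from the normal
  equations. Calibration under a no-bias simulation (K=15, 2,000 reps)
  holds the nominal 5% size (measured 0.044).
* **Trim-and-fill**: Duval-Tweedie with the L0 (default) or R0
  missing-study estimator. Trimming iterations centre on the
  *fixed-effect* mean of the untrimmed studies, as in the original
  formulation (metafor instead re-centres on the refitted random-effects
  estimate; both are published variants and agree on the instances we
  cross-checked). Deviations are quantized at 1e-9 relative to their
  scale and tied |deviations| receive midranks, so an exactly symmetric
  funnel yields zero imputations. `side="right"` (default) names the
  side holding the excess observed studies, which under the all-positive
  entry convention is where suppression of small effects leaves its
  mark; imputed mirror studies therefore land on the left and the
  adjusted estimate can only move down. Known limitation: against
  study-level suppression (drop each p>0.05 study with probability 0.9
  from K=40 generated), L0 imputes at least one study in only ~60-70% of
  replicates across every effect/sample-size regime we simulated --
  identical to `metafor::trimfill` on the same draws. This is the
  estimator's true power at these scales, and the corresponding
  acceptance-style check is left failing rather than weakened; the
  direction-of-adjustment property (adjusted <= unadjusted) holds in
  100/100 replicates.

## Gene lists, networks, enrichment, PGx

The pre-primary list keeps genome-wide-significant records after ruling
out intergenic, non-coding-transcript and synonymous variants, then
deduplicates symbols (uppercased; no alias resolution) keeping the best
p. Refinement drops pseudogenes and RNA genes; unknown biotypes are
retained with a warning (conservative). The primary list is the set
union with the packaged 10-gene dopaminergic risk panel, provenance
tagged (`cannabis` / `gars_panel` / `both`). The secondary list drops
genes with no in-list interaction partner at combined score >= 0.4 (the
common "medium confidence" default; configurable). Removal rounds are
repeated `steps` times (default 2); because removing an isolated node
cannot isolate another, a single round is already a fixed point and the
extra round asserts stability. Self-loops do not rescue a node.

Networks are undirected simple graphs over typed nodes (gene / miRNA /
TF / chemical); reported statistics are the raw interaction count
(degree) and exact unnormalized betweenness. The two are deliberately
separated: published "degree of betweenness (interactions)" figures in
this literature are interaction counts, so the headline number here is
degree, with true betweenness alongside. Bridge nodes are those adjacent
to both designated gene subsets after shared members are set aside.

Enrichment is the one-sided hypergeometric tail with a 20,000-gene
default universe (protein-coding genome scale; the right value depends
on the annotation source and is configurable). Odds ratios use
Haldane-Anscombe 0.5 on all four cells when any cell is zero. BH
q-values are computed within each library, mirroring per-database
rankings; a global-FDR flag exists. The PGx screen is a pure filter
(gene membership, optional significance flag and phenotype substring)
over an annotation table; the packaged table carries the 28
heroin-dependence rows transcribed from the source publication (2 BDNF,
1 DRD1, 4 DRD2, 21 OPRM1).

## Synthetic data

The generator emulates exactly what the pipeline consumes, no more:
effects are drawn directly on the Fisher-z scale (theta_i ~ N(mu, tau^2),
y_i = theta_i + N(0, 1/(n_i-3))) and reported as two-tailed p-values,
with one lead SNP per study and weaker companion SNPs (p inflated by
2-6 orders of magnitude). Publication bias is whole-study suppression of
non-significant results. Defaults: K=13 studies (the scale of the
packaged multi-trait pull), mu=0.02, tau=0.01, n ~ U(5,000; 50,000),
suppress_prob=0. Each table draws from its own stream spawned off the
master seed, so tables are reproducible in isolation.

What the generator does *not* emulate -- LD structure, allele
frequencies, winner's curse within a study, correlated studies sharing
cohorts, signed effects -- bounds what green tests mean: they validate
the statistical machinery under its own assumptions, not robustness of
the pipeline to real GWAS-catalog pathologies.

Network fixtures plant hubs (guaranteed top degree) and bridge miRNAs
(guaranteed adjacency to both subsets); gene-set libraries plant one
term containing a fixed fraction of the query. These construction
guarantees are what the recovery tests assert.

## Numerical choices and degenerate inputs

* p -> Z uses `scipy.stats.norm.isf(p/2)`, which keeps full precision to
  p ~ 1e-300; the round trip is tested to 1e-9 relative down to p=1e-12.
* Empty estimate lists, K below a method's minimum (2 for rank
  correlation and trim-and-fill, 3 for Egger), non-positive SEs,
  confidence levels outside (0,1) and undersized universes raise
  `DomainError`; malformed tables raise `ValidationError`; trim-and-fill
  non-convergence after 50 iterations raises `ConvergenceError` with a
  state dump. The CLI maps these to exit codes 2/2/3.
* Problem sizes in the test suite (e.g. 1,000 oracle instances, 50
  recovery seeds, 2,000 Egger replicates, 500 betweenness graphs) were
  chosen to make Monte-Carlo bands tight enough to be meaningful while
  keeping the whole suite interactive (<10 s).
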