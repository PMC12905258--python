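# Methods

This note documents the models implemented in `methylink`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was
genuinely open.

## Cohort-level association model

For each CpG *j* in each cohort, methylation β-values (methylated
fraction, bounded in [0, 1]) are regressed by OLS on the natural log of
the circulating exposure:

    DNAm_βij = β0 + β1·ln(IL6)_i + β2·age_i + β3·sexFemale_i
             + β4..β8·cell proportions_i + technical factors_i + ε_ij

The base model adjusts for five predicted immune-cell proportions
(CD8T, CD4T, NK, monocytes, B cells); neutrophils are excluded because
the proportions sum to one, so including every component makes the
design rank deficient (the rank check names the collinear columns).
Sensitivity models swap in eleven extended cell types (the twelve-cell
panel minus neutrophils), add trichotomous smoking, or add the other
inflammatory exposure (ln hsCRP).  Technical factors are arbitrary
categorical covariates (dummy-coded, first level dropped) because which
factors exist is cohort-specific; the model spec accepts any set.

Preprocessing before the fit:

* **LOD censoring.**  Cytokine values below the assay limit of
  detection are removed (default) or capped at the LOD; the removal
  count and percentage are reported.  All values below the LOD is an
  error — there is no usable exposure.
* **3 × IQR outlier rule.**  A value is an outlier when it lies more
  than three interquartile ranges beyond the nearest quartile.
  Quartiles use linear interpolation (numpy default, the type-7
  convention) — the most widespread choice; the documented edge case
  IQR = 0 flags every value different from the quartile constant.  The
  rule is applied once to the exposure cohort-wide and again to each
  CpG's β-values, so *n* varies per CpG and is recorded per record.
* **Missing covariates** cause listwise deletion for that model, with
  the reduced *n* logged, mirroring the usual loss of samples when
  smoking status is incomplete.

p-values come from the t reference with residual degrees of freedom —
exact in small synthetic cohorts, indistinguishable from the normal at
cohort scale.  The IQR rule is applied to the exposure on its measured
(pg/mL) scale, before the log transform used in the model.

## Empirical-null (bias/inflation) correction

EWAS z-scores are modelled as a three-component Gaussian mixture: a
dominant empirical null N(µ, σ²) — µ is the bias, σ the inflation
(reported as λ) — flanked by a negative and a positive signal
component.  Estimation is Gibbs sampling with conjugate updates:
inverse-gamma(α = 1.28, β = 0.36) priors on component variances (the
upstream tool's defaults; the paper-level hyperparameters are exposed
in config), a mildly null-favouring Dirichlet(9, 0.5, 0.5) prior on the
weights, and a near-flat normal prior on the means.  Two numerical
choices matter:

* **Identifiability.**  Signal-component means are truncated to lie at
  least two null-SDs beyond the null mean on their side.  Without this
  the (often empty) signal components drift into the tails of the null
  bulk and siphon mass, biasing σ downward by several percent on
  pure-null input; with it, a N(0, 1) sample of 20k z-scores is
  recovered to |µ| < 0.01, |σ − 1| < 0.01.
* **Point estimates** are per-coordinate posterior medians over the
  post-burn-in trace (5000 iterations, 2000 burn-in by default, seed
  required), weights renormalised; a split-chain R-hat > 1.1 on the µ
  trace attaches a non-convergence warning.

A deterministic EM fit of the same constrained mixture (MAP on the
variances) is available as a cross-check and agrees with the sampler to
within 0.02 on the test fixtures.

Adjustment rescales z′ = (z − µ)/σ and, by default, keeps the effect
size while reconstructing SE = |β/z′| ("effect/SE" mode, matching
downstream meta-analysis input); a z-score-only mode exists because
which quantity the upstream tooling adjusted is ambiguous.  z′ = 0
yields p = 1 and an infinite SE, flagged.  Re-estimating (µ, σ) on
adjusted statistics returns ≈ (0, 1).

## Meta-analysis, filters, regions

Cohort records are pooled per CpG by fixed-effects inverse-variance
weighting (w_i = 1/SE_i²), with Cochran's Q and I² = max(0,
(Q − df)/Q)·100, df = contributing cohorts − 1.  Single-cohort CpGs
pass through with Q = I² = 0 but a flagging direction string
(`+`/`-`/`?` per cohort, in fixed cohort order).  The heterogeneity
filter removes I² **strictly greater than** 90 by default — the
source's own wording differs between its methods (≥) and results (>)
sections, so the comparison is a config flag.  FDR is
Benjamini–Hochberg throughout, applied once per analysis family.  The
attenuation filter drops base-model hits whose adjusted-model q ≥ 0.05
(or that the adjusted model never tested), and reports the
between-model effect-size correlation.

DMRs chain tested probes left to right: a region grows from a DMP while
the next *tested* probe (significant or not) is < 1 kb away and at most
three non-DMPs have been absorbed; emitted regions contain ≥ 3 DMPs and
are trimmed to start and end on DMPs.  Measuring gaps between
consecutive tested probes (not only DMPs) is the reading consistent
with allowing non-DMPs inside a region.  Distinct loci =
#DMPs − #DMPs in DMRs + #DMRs, so isolated DMPs each count once.

## Enrichment

Trait and chromatin-state enrichment is logistic regression of the
hit indicator on the annotation indicator over the full tested
background (hits included) — with a single binary covariate this equals
the 2 × 2 cross-product OR, which is how the implementation is tested;
the fit itself is a frequency-weighted binomial GLM on the aggregated
table (exact and O(1) in the background size).  Validation: the
published counts 51/401 vs 14,767/412,226 reproduce OR = 3.9.  Zero
cells get the Haldane–Anscombe 0.5 correction with a warning; an
annotation covering the whole background is an error.  The EWAS-style
catalog filter keeps studies with a PubMed id, sample size > 500 and
> 100 reported CpGs (both strict), and merges trait synonyms through a
user mapping before taking unions — inclusion thresholds beyond these
are database-specific and stay configurable.  Gene-set and TF-regulon
over-representation is the one-sided hypergeometric tail P(X ≥ k) with
the universe fixed to the library's gene space, FDR per library.

## eQTM and colocalisation

Expression is transformed to log₂CPM with a 0.5 pseudo-count,
log2((c + 0.5)/(libsize + 1)·1e6), then rank-inverse-normal transformed
per gene with the Blom offset (c = 3/8; ties share average ranks).
Cis pairs are genes whose body (BED half-open) intersects the ±100 kb
window around the CpG; distance is 0 inside the gene, else the gap to
the nearest edge; strand is ignored.  CpG coordinates in TSVs are
1-based, intervals 0-based half-open — a CpG at 1-based position p
occupies 0-based coordinate p − 1 for all interval arithmetic.  Each
pair is an OLS of transformed expression on methylation with age, sex,
cell-type and technical covariates; FDR across all tested pairs.

Colocalisation is the single-causal-variant approximate-Bayes-factor
method: per SNP and trait a Wakefield log-ABF with prior effect SD
0.15·sdY (the conventional default for quantitative traits; sdY is
estimable from varbeta, EAF and n by regression through the origin),
combined over the five hypotheses H0–H4 by log-sum-exp with priors
p1 = p2 = 1e-4, p12 = 5e-6, and a PP(H4) > 0.9 decision rule.  The
posterior vector is tested against brute-force enumeration over all
(causal SNP for trait 1, causal SNP for trait 2) configurations and is
invariant to jointly rescaling a trait's betas and SEs.  Multi-signal
(SuSiE-style) colocalisation is deliberately out of scope: the decision
rule and priors are honoured on the dominant signal, but regions with
several independent QTLs will be summarised by their strongest pair —
a known deviation.

## Causal inference

**Triangulation.**  For the consequential direction (DNAm → IL-6) the
observed effect is the top cis-mQTL's association with ln(IL-6); the
predicted effect is β_mQTL/β_EWAS (the instrument's methylation effect
pushed through the inverted EWAS slope).  For the causal direction
(IL-6 → DNAm) the observed effect is the EAF-weighted combination of
the two IL-6 instrument SNPs' trans-mQTL effects on the CpG; the
predicted effect is the same weighting of their IL-6 effects times the
EWAS slope.  "EAF weighting" is under-specified upstream; the default
weights w_k ∝ 2·EAF_k(1 − EAF_k) (per-allele genotype variance, the
standard genetic interpretation), with a plain-EAF mode behind a flag.
Because observed and predicted use identical weights, the choice
cancels for the correlation's sign structure.  Each direction is
summarised by Pearson R and p over CpGs; CpGs without a usable
instrument or with β_EWAS = 0 are excluded and counted.

**Two-sample MR.**  Harmonisation aligns the outcome to the exposure's
effect allele (sign and EAF flips for swapped pairs, incompatible
allele sets dropped, palindromic SNPs dropped when either EAF lies in
[0.42, 0.58]); every action is logged, and harmonising twice equals
once.  Clumping is greedy: keep the lowest-p SNP (ties by larger |β|,
then lexicographic id — determinism), drop r² > 0.001 neighbours,
repeat; SNPs absent from the LD matrix are treated as independent with
a warning.  Single instruments use the Wald ratio β_out/β_exp with
first-order SE |β_out|-side only (se_out/|β_exp|); multiple independent
instruments are combined by fixed-effect IVW — the same pooling rule,
and the same tested oracle, as the meta-analysis.  FDR is applied per
direction across CpGs.

**Mediation.**  For each CpG × trait, three genetically estimated
legs — a (IL-6 → DNAm), b (DNAm → trait), c (total IL-6 → trait), each
a Wald ratio or IVW estimate (IVW when ≥ 2 independent instruments
survive clumping, else Wald) — are decomposed into indirect = a·b with
first-order delta-method (Sobel) SE √(a²se_b² + b²se_a²) and
direct = c − a·b, so indirect + direct = c holds exactly.  The indirect
p is a normal z-test, FDR per trait.  Pleiotropy diagnostics (MR-Egger,
weighted median) are out of scope, as in the source analysis.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the published study conditions: three cohorts of
799/668/2894 participants with the published age, sex, smoking and
IL-6/hsCRP distributions (log-normal parameters solved from the printed
medians and IQRs), twelve-cell Dirichlet immune profiles aggregated to
the six-cell panel for base models, a 1.2% sub-LOD censoring rate
implemented as a quantile of the simulated IL-6 distribution, and
effect sizes of SD 0.01 β-value units per unit ln(IL-6) — the range of
the reported associations.  β-values are generated on the logit scale
and squashed, guaranteeing (0, 1) without rejection sampling; causal
slopes are divided by the logistic derivative at the CpG's baseline so
the planted effect is approximately the β-scale slope an EWAS
estimates.  Cohort heterogeneity is a per-cohort random perturbation of
each causal slope; a few planted CpGs receive 8× the spread (and a
boosted mean effect) so the I² filter has significant CpGs to remove.
Cell-type confounding runs through regulatory T-cell proportions — a
contrast invisible to the six-cell adjustment but captured by the
twelve-cell panel, which is precisely the failure mode the attenuation
filter screens.  Forward CpGs respond to realised ln(IL-6); reverse
CpGs are generated first from a latent (conceptually genetic) driver
and feed back into IL-6.  Some forward CpGs are seeded into sub-kb
probe clusters so DMR calling has regions to find.

The genetic layer is summary-level: every CpG gets 1–5 cis-mQTL SNPs
(EAF ∈ (0.05, 0.95); the planted top effect is drawn |β| ∈ 0.03–0.15 on
the β-value scale), two SNPs instrument IL-6, and effects propagate
along the truth by path products (forward: instrument → IL-6 → DNAm;
reverse: mQTL → DNAm → IL-6), with sampling noise matching study sizes
of 27k (mQTL), 67k (IL-6 GWAS) and 300k (trait GWAS).  LD is
block-diagonal, with an occasional r² = 0.9 tagged pair inside a CpG's
SNP set to exercise clumping.  `simulate_meta_summary` provides the
implied summary-level EWAS directly (forward: the true slope; reverse:
the regression-attenuated t·var(β)/var(ln IL-6)); the causal-layer
calibration tests use it so that twenty replicates stay cheap, while
the pipeline and power tests run the full individual-level chain.

Not emulated: realistic LD (so clumping is exercised, not stressed),
array probe chemistry and bimodal β-value distributions at causal CpGs
(baselines there are kept in (0.25, 0.75) for slope stability), twin
relatedness, batch structure beyond a single plate factor, and
horizontal pleiotropy.  Passing tests therefore demonstrate that the
estimators recover known signal under the stated noise model — not that
real cohort data meet these assumptions.

## Problem sizes and determinism

The demonstration pipeline runs 600 CpGs across cohorts of
250/220/400 with a 1200-iteration sampler warm-started per
cohort-model; it completes in about a minute on one core and its report
(counts at every filter, per-cohort µ/σ/λ, triangulation correlations,
exclusion log) hashes identically across reruns with one seed.  The
recovery tests use 3 × 1000 samples and 400 CpGs (forward-CpG power
≥ 80% at FDR < 0.05), 50k z-scores for the empirical-null fixture, and
150-CpG replicates for the twenty-seed triangulation check.  All
randomness flows from explicit seeds through `numpy.random.default_rng`;
every file format round-trips losslessly through the `io` module.

## Known limitations

* The three-component mixture assumes one dominant null; massively
  polygenic z-score distributions (null weight far below ~0.8) would
  break the constraint that the null is the largest component.
* Single-causal-variant colocalisation, as noted, understates H4 when
  a region carries several shared signals.
* The first-order Wald/Sobel SEs ignore instrument-exposure
  uncertainty; a second-order correction is available behind a flag but
  is not the default, matching the unqualified "delta method"
  convention.
* Mixed models for family structure and robust/sandwich errors are not
  implemented; cohorts with relatedness need pre-adjusted inputs.
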