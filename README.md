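# methylink

**EWAS meta-analysis and causal inference linking DNA methylation to
circulating cytokine levels.**

Chronically elevated interleukin-6 (IL-6) marks, and partly drives,
immunometabolic disease — type 2 diabetes, rheumatoid arthritis,
inflammatory bowel disease.  Blood DNA methylation both responds to and
modulates inflammatory signalling, so an epigenome-wide association
study (EWAS) of circulating IL-6 faces a directionality problem: is a
CpG associated with IL-6 because the cytokine reprograms methylation,
or because methylation regulates cytokine production?

`methylink` implements the full analysis stack needed to ask — and
answer — that question from multi-cohort data, for epidemiologists and
epigeneticists working with cohort EWAS summary statistics:

* **Per-cohort EWAS** (`methylink.ewas`) — OLS of methylation
  β-values on ln(IL-6) (or ln(hsCRP)) adjusted for age, sex, predicted
  immune cell proportions and technical covariates; left-censoring of
  sub-LOD cytokine measurements; a 3 × IQR outlier rule applied to both
  exposure and per-CpG methylation; probe filters (n < 50, sex
  chromosomes, blacklist intervals).
* **Bias/inflation correction** (`methylink.bacon`) — the
  empirical-Bayes three-component Gaussian mixture on z-scores: the
  empirical null N(µ, σ²) is estimated by Gibbs sampling (inverse-gamma
  priors α = 1.28, β = 0.36 on component variances) and divided out,
  z′ = (z − µ)/σ.
* **Fixed-effects meta-analysis** (`methylink.meta`) — inverse-variance
  weights w_i = 1/SE_i², Cochran's Q and I² = max(0, (Q − df)/Q)·100
  with an I² > 90 exclusion rule, Benjamini–Hochberg FDR, a
  sensitivity-attenuation filter (drop hits with p_fdr ≥ 0.05 after
  extended-cell-type or smoking adjustment), and DMR calling (≥ 3 DMPs,
  inter-CpG gaps < 1 kb, ≤ 3 non-DMPs) with the distinct-locus count
  `#DMPs − #DMPs_in_DMRs + #DMRs`.
* **Enrichment** (`methylink.enrichment`) — trait and chromatin-state
  enrichment by logistic regression over the array background (OR with
  Wald 95% CI), and hypergeometric gene-set / TF-regulon
  over-representation from GMT libraries.
* **Integration** (`methylink.integrate`) — cis eQTM regression
  (RIN-transformed log₂CPM expression on β-values, ±100 kb window) and
  single-causal-variant colocalisation via Wakefield approximate Bayes
  factors (priors p1 = p2 = 1e-4, p12 = 5e-6; colocalised when
  PP(H4) > 0.9).
* **Causal inference** (`methylink.causal`) — bidirectional
  triangulation (observed vs predicted instrument effects, Pearson R
  per direction), bidirectional two-sample Mendelian randomisation
  (Wald ratio β_out/β_exp, fixed-effect IVW, allele harmonisation,
  LD clumping), and two-step MR mediation (indirect = a·b with Sobel
  SE √(a²·se_b² + b²·se_a²), direct = c − a·b).
* **Synthetic data** (`methylink.synthetic`) — a generator emulating
  the three-cohort study design (799/668/2894 participants, published
  age/sex/IL-6 distributions, 1.2% sub-LOD censoring, cell-type
  confounding, between-cohort heterogeneity) plus a genetic layer with
  known causal directions, so every stage has a parameter-recovery
  oracle.

## Worked example

Run the full pipeline on synthetic data with known ground truth:

```bash
methylink run --seed 1 --out report.json
```

which prints (seed 1):

```
CpGs tested:                 600
FDR-significant (base):      61
  removed, heterogeneity:    7
  removed, attenuation:      31
Final associated CpGs:       23
DMRs / distinct loci:        1 / 20
Triangulation R (causal):    0.967
Triangulation R (conseq.):   -0.097
Report hash:                 d0a17b18bd76dcc7
```

Reading the output: of 600 simulated CpGs, 61 were associated with
ln(IL-6) after empirical-null correction and FDR (the generator planted
48 causal CpGs plus 25 cell-confounded null CpGs); 7 were excluded for
between-cohort heterogeneity (I² > 90) and 31 more lost significance
when the model was extended with twelve cell types or smoking — the
confounded plants are removed preferentially, which is exactly what the
attenuation filter is for.  The 23 surviving CpGs collapse into 1 DMR
and 20 distinct loci.  Triangulation strongly supports the simulated
forward direction (IL-6 → DNAm): predicted and observed genetic effects
correlate at R = 0.97 through the causal path but not through the
consequential one.  The report hash is identical across reruns with the
same seed.

Individual stages are exposed as subcommands over TSV files
(`simulate`, `ewas`, `bacon`, `meta`, `dmr`, `enrich`, `eqtm`, `coloc`,
`triangulate`, `mr`, `mediate`, `report`) — see `methylink --help`.

As a library:

```python
from methylink.enrichment import logistic_enrichment

hits = {f"hit{i}" for i in range(401)}
background = hits | {f"bg{i}" for i in range(412_226 - 401)}
enhancer = ({f"hit{i}" for i in range(51)}
            | {f"bg{i}" for i in range(14_767 - 51)})
print(round(logistic_enrichment(hits, enhancer, background).odds_ratio, 1))
# 3.9
```

## Layout

```
src/methylink/     synthetic | ewas | bacon | meta | enrichment |
                   integrate | causal | io | config | pipeline | cli
tests/             unit, property and acceptance suites
docs/methods.md    model and design notes
```
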