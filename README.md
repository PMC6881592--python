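# epimetab

Integrative analysis of metabolic-gene expression dysregulation and promoter
DNA methylation in tumor cohorts.

## The problem

Cancer cells rewire metabolism, and some of the rewired genes — notably the
DNA methyltransferase *DNMT3B* — sit directly upstream of epigenetic
regulation. Given matched tumor/normal expression (TPM), CpG-probe methylation
(beta values), clinical follow-up and mutation tables, the question is: which
genes are transcriptionally dysregulated across cancers, which promoter
methylation changes are attributable to the driver's expression, which genes
are silenced (or activated) *by* those methylation changes, and does the
driver carry prognostic weight? `epimetab` packages that screen as a tested,
reusable pipeline for computational biologists, with a synthetic multi-omics
cohort generator (planted, recoverable ground truth) to validate every stage.

## The statistics at the core

* **Differential expression** — an empirical-Bayes unpaired t: per-group gene
  variance shrunk toward a background variance pooled over genes of similar
  expression, `v_g = (v0·bg² + (n−1)s²)/(v0 + n − 1)` with `v0` prior degrees
  of freedom, df `= n_a + n_b − 2 + 2·v0`. Genes called at BH-FDR < 0.05 and
  signed fold change |FC| ≥ 1.5 (microarray profile: |log2FC| > 1), after
  excluding genes with mean TPM < 1; a recurrence filter keeps genes called in
  ≥ 8 cohorts.
* **Differential methylation** — per-probe Δβ (group mean difference of beta
  values) in promoter windows (0–1500 bp upstream of the TSS, strand-aware),
  tested with the same regularized engine; hyper/hypo called at P < 0.05 and
  |Δβ| > 0.2 under two contrasts: tumor vs normal, and top vs bottom decile of
  tumors by driver expression. Probes differential in both contrasts form the
  driver-attributed overlap.
* **Integration** — Spearman correlation r between probe beta and log2 gene
  expression across tumors; *hyper-repressed*: Δβ > 0.2, r < −0.2, FC ≤ −1.5;
  *hypo-activated*: the mirror image.
* **Survival** — median-split Kaplan–Meier with log-rank testing and a
  univariate Cox fit (Newton–Raphson partial likelihood, Breslow ties)
  reporting the hazard ratio of high expression.
* **Mutation stratification** — top-3 most frequently mutated drivers,
  mutated-vs-wild-type DE restricted to a metabolic gene list, with a ≥ 20
  mutated-sample eligibility rule.
* **Enrichment** — hypergeometric over-representation of gene sets from GMT
  collections (EASE variant optional).

## Worked example

```python
import epimetab as em

cohort = em.simulate_cohort(em.SimConfig(seed=7))   # 200 tumor / 40 normal
res = em.IntegrationPipeline(cohort.expression, cohort.methylation,
                             cohort.manifest, cohort.annotation).run()
print(res.de.summary())
print(res.dm.summary())
print(res.summary())
```

prints

```
Differential expression: tumor vs normal
  genes tested: 1997
  up: 101  down: 110  ns: 1786
  thresholds: FDR < 0.05, |FC| >= 1.5
Differential methylation (P < 0.05, |delta-beta| > 0.2)
  tumor vs normal: 30 hyper, 0 hypo
  DNMT3B top vs bottom 10%: 30 hyper, 0 hypo
  overlap probes: 30
Methylation-expression integration (delta-beta > 0.2, r < -0.2)
  candidate probe-gene pairs: 30
  hyper_repressed: 10 genes
  hypo_activated: 0 genes
```

The 30 overlap probes are exactly the 3 promoter probes of each of the 10
planted driver targets (the per-target decoy probe outside the promoter window
is filtered out), and all 10 targets are recovered as hyper-repressed —
hypermethylated, anticorrelated with their promoter, and downregulated. The
first call rows show the table layout (probe, Δβ, gene, FC, P, r, P):

```
    probe  delta_beta      gene  fc_signed            p         r          p_r          class_
cg0000001    0.688097 GENE00001  -3.464659 1.152743e-75 -0.515681 5.534058e-15 hyper_repressed
cg0000002    0.708442 GENE00001  -3.464659 7.380262e-82 -0.567104 2.049154e-18 hyper_repressed
```

The planted prognostic effect of the driver is likewise recovered:

```python
surv = em.SurvivalScreen(cohort.expression, cohort.annotation,
                         genes=["DNMT3B"]).fit()
print(surv.table.to_string(index=False))
```

```
  gene  n_high  n_low  logrank_chi2  logrank_p       hr  hr_ci_low  hr_ci_high    cox_p  significant
DNMT3B     100    100     14.310678   0.000155 1.854334   1.340436    2.565249 0.000192         True
```

High *DNMT3B* expression is significantly associated with shorter survival
(log-rank P = 1.5e-4) with an estimated hazard ratio of 1.85 (the median-split
dichotomization attenuates the planted continuous effect, as expected).

A command-line layer mirrors the library: `epimetab simulate | dex |
recurrence | dmp | integrate | survival | mutassoc | enrich | run-all`, each
with `--config`, `--seed`, `--out-dir`; every run writes its resolved
configuration next to its outputs.

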