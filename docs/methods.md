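# Methods

`epimetab` implements an integrative screen linking metabolic-gene expression
dysregulation to promoter DNA-methylation alteration in tumor cohorts, driven
by the expression of a DNA-methyltransferase driver gene (default *DNMT3B*).
This note documents the statistical model behind each stage, the tunable
parameters with their defaults, what the synthetic cohort generator does and
does not emulate, and the numerical choices made where the design was open.

## Data model

Expression is gene-level TPM (genes x samples, nonnegative, no missing
values). Methylation is CpG-probe beta values in [0, 1] (probes x samples);
missing entries are allowed and propagated pairwise-complete, as masked probes
are common on methylation arrays. A probe manifest assigns each probe a gene
and a signed, strand-aware distance to the transcription start site (positive
= upstream in transcription direction). Sample annotation carries a two-level
group label (normal / tumor), a cancer-type label, optional survival time with
an event flag (the flag is required wherever a time is present), and an
optional binary mutation-status table.

## Regularized differential expression

The test statistic is an empirical-Bayes unpaired t in the Cyber-T family:
each group's per-gene variance is shrunk toward a *background* variance pooled
from genes of similar expression. On log2(TPM + 1) values, genes are ordered
by mean; the background SD of a gene is the root-mean of the per-gene sample
variances inside a `window_size` (default 101) window centred on it. Windows
keep full size at the ends of the ordering (the window slides rather than
shrinks), so a window as large as the gene count pools globally. For group *g*
with *n_g* samples, sample variance *s_g^2* and background SD *bg_g*, the
posterior variance is

    v_g = (prior_df * bg_g^2 + (n_g - 1) * s_g^2) / (prior_df + n_g - 1)

with `prior_df` (default 10) pseudo-observations. The groups are pooled with
weights `prior_df + n_g - 1` and the statistic is referred to Student's t with
`n_a + n_b - 2 + 2 * prior_df` degrees of freedom. The `prior_df + n_g - 1`
denominator is chosen so that `prior_df = 0` reduces *exactly* to the ordinary
pooled-variance unpaired t, which anchors the limit tests; a Welch-style
variant (Satterthwaite df on the posterior variances) is config-exposed.
Degenerate genes (zero pooled variance, equal means) get t = 0, p = 1.

Fold change is the signed ratio of group means (test/reference if >= 1, else
-(reference/test), so |FC| >= 1 always), computed on TPM plus the same
pseudocount used for the log transform. Calling: BH-FDR < 0.05 together with
|FC| >= 1.5 (the fold-change arm is inclusive; the FDR arm strict). The
microarray profile calls on |log2 FC| > 1 (strict) instead of the ratio
threshold, on the same engine. Genes with mean TPM < 1 over all samples are
excluded beforehand (strict "less than": a mean of exactly 1 is retained).
The cross-cohort recurrence filter keeps genes called in at least
`recurrence_min_cancers` (default 8) cohorts, regardless of direction; a
`consistent_direction` flag restricts to same-direction recurrence.

## Dual-contrast differential methylation

Probes are restricted to the promoter window, the closed interval
[0, 1500] bp upstream of the TSS. Per probe, delta-beta is the difference of
group-mean beta values, and a two-sided p comes from the same regularized-t
engine applied directly to beta values (probes ordered by mean beta for the
background window; beta is analyzed on its own scale, not as M-values, because
every calling threshold is a beta-scale quantity). Calling is strict:
hyper if p < 0.05 and delta-beta > 0.2, hypo if p < 0.05 and delta-beta <
-0.2. Two contrasts are run: tumor vs normal, and the *driver split* — the
top versus bottom `extreme_fraction` (default 10%, ceiling-rounded, ties at
the cut broken by sample-id order) of **tumor** samples ranked by driver-gene
expression. Probes differential in both contrasts, with matching direction by
default, form the overlap set attributed to the driver.

## Methylation-expression integration

Overlap probes are joined to differentially expressed genes by the manifest's
probe-to-gene assignment (a gene with several surviving probes contributes one
candidate pair per probe). For each pair, the Spearman rank correlation
(average ranks for ties, pairwise-complete, large-sample t p-value) between
probe beta and log2 gene expression is computed across tumor samples (normals
can be included by config). Classification:

* **hyper_repressed**: delta-beta > 0.2, r < -0.2, FC <= -1.5
* **hypo_activated**: delta-beta < -0.2, r < -0.2, FC >= +1.5

All inequalities strict except the FC arm, which inherits the inclusive DE
rule. The hypo rule is the mirror image of the hyper rule; the shipped
published call table (108 probe-gene rows) is reproduced by this rule with
zero misclassifications, which is what the rule-consistency test asserts.
No multiple-testing correction is applied to the correlation p-values: the
filter is the |r| > 0.2 magnitude cutoff, with raw p reported for
transparency. Pairs with undefined correlation (constant input, fewer than 3
complete pairs) are flagged and excluded.

## Survival screen

Tumor samples with survival data are split at the median expression of each
gene; ties at the median go to the low group (deterministic and
conventional). Groups are compared with the log-rank test (lifelines), and a
univariate Cox proportional-hazards fit on the high/low indicator reports the
hazard ratio of high expression with a Wald 95% CI. The Cox fit is a
single-covariate partial-likelihood Newton-Raphson implemented in-package with
Breslow tie handling by default (Efron optional); lifelines' fitter supports
only Efron ties and serves as the cross-check oracle on tie-free data, where
the two coincide. The covariate is standardized internally for stability and
the coefficient rescaled back. Monotone likelihood (|beta| running away) is
flagged as separation rather than raised. Genes are flagged significant at
log-rank p < 0.05.

## Mutation stratification

The top-k (default 3) most frequently mutated candidates from a user-supplied
pan-cancer driver list (the candidate list itself is external knowledge, not
re-derived) are screened. Samples split by binary mutation status; a driver is
eligible only if the mutated arm has at least 20 samples (inclusive boundary;
a flag extends the rule to both arms). Eligible splits are fed to the DE
engine (mutated = test group), restricted to the metabolic gene list. A
minimal MAF-to-binary converter keyed on gene symbol and sample barcode is
provided; consequence annotations are not parsed.

## Over-representation analysis

Upper-tail hypergeometric test per gene set: with universe size N, set size K,
query size n and overlap k, p = P(X >= k), BH-FDR across sets. The universe
defaults to the genes surviving the expression filter and is config-
overridable. An EASE-style variant (discounting one overlapping gene, as the
modified Fisher score of common annotation servers does) is available behind
a flag. Query genes outside the universe are dropped and reported.

## Synthetic cohort generator

The generator emits matched expression, methylation, manifest, clinical and
mutation tables plus a truth ledger of every planted effect. Defaults are the
package's study conditions: 40 normal / 200 tumor samples, 2000 genes, 10%
planted DE genes at |FC| 3 (half up, half down), biological CV 0.3
(log-normal noise), driver gene *DNMT3B* upregulated 3-fold in tumors, 10
driver-target genes, methylation slope 2.0 on the logit scale, silencing
strength 2.0, survival hazard ratio 2.5 for the high-driver half, 30%
censoring, three mutation drivers at 30% frequency with 20
mutation-responsive genes at FC 2 for the first driver.

Mechanics worth knowing:

* Planted methylation lives on the logit scale:
  beta = expit(logit(0.1) + slope * z + noise), where z is the sample's driver
  expression standardized against the normal-sample mean. Tumor
  overexpression of the driver therefore shifts target promoters hyper
  (tumor-vs-normal contrast) while tumor-to-tumor driver variability spreads
  the decile contrast — both contrasts of the overlap are recoverable from one
  mechanism. The link guarantees beta in [0, 1] at any slope, at the price of
  saturation: beyond slope ~3 under the default driver effect, tumor probes
  pile up near beta = 1 and the realized decile contrast *shrinks* again, so
  the slope-monotonicity property is tested in the non-saturating range.
* Target expression is multiplied by exp(-silencing_strength * promoter beta)
  per sample, producing both the downregulation and the anticorrelation the
  integration stage screens for.
* Each target carries three promoter probes inside the 0-1500 bp window plus
  one decoy probe outside it that carries the same planted signal, to
  exercise the window filter; every other gene carries one promoter probe
  with a two-mode (0.1 / 0.8) baseline.
* Genes carrying planted effects draw their baselines from the clearly
  expressed range (log2 TPM ~ N(5, 1)) so planted signal is not erased by the
  mean-TPM filter; this mirrors the fact that silencing calls in real cohorts
  are only possible for genes expressed well enough to quantify.
* Survival times are exponential with the hazard multiplied for samples above
  the median driver expression, mirroring the pipeline's own grouping so
  recovery is well-posed; censoring is independent exponential with its rate
  set to the target censoring fraction under the baseline hazard.
* Identical seeds give bitwise-identical cohorts. `simulate_null` forces all
  effect parameters neutral and emits an empty truth ledger.

What the generator does **not** emulate: batch effects, tumor purity and
cell-type composition, copy-number confounding, realistic genome coordinates,
probe cross-reactivity, or the correlation structure of real methylomes.
Passing recovery tests therefore demonstrates that the pipeline's logic is
correct and its thresholds behave as printed — not that the pipeline is robust
to the technical artifacts of real array data.

## Problem sizes and numerical choices

The test and acceptance computations use reduced but statistically meaningful
sizes chosen as the package's own study conditions: 2000-gene cohorts with 30
vs 30 samples (200 null replicates) for false-discovery control and
sensitivity; the 200/40 default cohort for end-to-end recovery; 500 null and
100 alternative replicates at n = 200-300 for log-rank calibration and power;
50 replicates at n = 1000 for Cox recovery. Other numerics: BH step-up for all
FDR adjustment; strict inequalities wherever the published thresholds print
"<" or ">", inclusive where they print "not less than"; result tables are
written with repr-precision floats and re-read with round-trip parsing so
write-then-read is bitwise identity; all randomness flows from explicit seeds.

## Known limitations

* The background-variance window couples nearby genes; for very small gene
  counts the window clamps to the whole matrix and the shrinkage becomes
  global.
* The probe-level DM test treats probes as independent; correlated probes in
  one promoter are not modelled.
* Only univariate Cox is offered (no covariate adjustment), matching the
  screening design.
* The recurrence filter counts cohorts, not effect sizes; a gene barely
  significant in eight cohorts outranks one strongly significant in seven.
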