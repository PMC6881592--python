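"""Synthetic matched multi-omics cohort with planted, recoverable effects.

The generator emulates the statistical structure the pipeline assumes: a
tumor/normal expression contrast, a continuous driver-gene (DNMT3B) expression
axis, planted promoter hypermethylation of driver-target genes that suppresses
their expression, a planted prognostic effect of the driver, and binary
driver-mutation status with mutation-responsive genes.

Generative model
----------------
* Expression: per-gene log-normal baseline; per-sample multiplicative
  log-normal noise with coefficient of variation ``biological_cv``. A fraction
  ``fraction_de`` of genes receive a tumor-only fold change (half up, half
  down) of ``de_fold_change``. The driver gene is planted upregulated in tumors
  by ``driver_fold_change``.
* Methylation: promoter beta values live on the logit scale. Each driver
  target carries three promoter probes (tss_distance within the 0-1500 bp
  window) plus one decoy probe outside the window; every other gene carries one
  promoter probe. Baselines are a two-mode mixture (low ~0.1 / high ~0.8; a
  target's promoter starts in the low mode). Target-probe beta is
  inverse-logit(logit(baseline) + methylation_slope * z + noise), where z is
  the sample's driver expression standardized against the normal-sample mean,
  so driver overexpression in tumors shifts target promoters hyper while
  tumor-to-tumor driver variability spreads the top/bottom-decile contrast.
* Silencing: target-gene expression is multiplied by
  exp(-silencing_strength * beta_promoter) per sample.
* Survival (tumor samples only): exponential event times; the hazard is
  multiplied by ``survival_hazard_ratio`` for samples above the median driver
  expression. Censoring is independent exponential with rate set so roughly
  ``censoring_rate`` of baseline samples are censored.
* Mutations: independent Bernoulli status per driver; mutation-responsive
  genes get a fold change of ``mutation_effect_fc`` in mutated tumors.

Identical seeds produce bitwise-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (ExpressionMatrix, MethylationMatrix, ProbeManifest,
                        SampleAnnotation, ValidationError)
from . import io as io_mod


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Cohort-generator parameters (defaults = the package's study conditions)."""

    n_normal: int = 40
    n_tumor: int = 200
    n_genes: int = 2000
    fraction_de: float = 0.10
    de_fold_change: float = 3.0
    biological_cv: float = 0.3
    driver_gene: str = "DNMT3B"
    driver_fold_change: float = 3.0
    n_driver_targets: int = 10
    methylation_slope: float = 2.0
    silencing_strength: float = 2.0
    beta_mode_low: float = 0.1
    beta_mode_high: float = 0.8
    beta_high_fraction: float = 0.3
    logit_noise_sd: float = 0.5
    survival_hazard_ratio: float = 2.5
    baseline_median_survival: float = 50.0
    censoring_rate: float = 0.3
    mutation_drivers: tuple = ("TP53", "KRAS", "PIK3CA")
    mutation_frequency: float = 0.3
    n_mutation_responsive: int = 20
    mutation_effect_fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {"n_normal": self.n_normal, "n_tumor": self.n_tumor,
                  "n_genes": self.n_genes}
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0 <= self.fraction_de <= 1:
            raise ValidationError("fraction_de must be in [0, 1]")
        if self.de_fold_change < 1 or self.driver_fold_change < 1:
            raise ValidationError("fold changes must be >= 1")
        if self.biological_cv <= 0:
            raise ValidationError("biological_cv must be > 0")
        if not 0 < self.beta_mode_low < self.beta_mode_high < 1:
            raise ValidationError("beta modes must satisfy 0 < low < high < 1")
        if self.survival_hazard_ratio <= 0:
            raise ValidationError("survival_hazard_ratio must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        if not 0 <= self.mutation_frequency <= 1:
            raise ValidationError("mutation_frequency must be in [0, 1]")
        if self.n_driver_targets + 1 + self.n_mutation_responsive > self.n_genes:
            raise ValidationError("planted genes exceed n_genes")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ledger of planted effects, for recovery scoring.

    Empty frames under a null configuration.
    """

    de_genes: pd.DataFrame          # gene, true_fc (signed)
    driver_targets: pd.DataFrame    # gene, probes, methylation_slope, silencing_strength
    prognostic_genes: pd.DataFrame  # gene, hazard_ratio
    mutation_responsive: pd.DataFrame  # driver, gene, true_fc

    @property
    def driver_target_genes(self) -> list[str]:
        return sorted(self.driver_targets["gene"].tolist())


@dataclass
class Cohort:
    expression: ExpressionMatrix
    methylation: MethylationMatrix
    manifest: ProbeManifest
    annotation: SampleAnnotation
    mutations: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def simulate_cohort(config: SimConfig = None) -> Cohort:
    """Generate one matched expression/methylation/clinical/mutation cohort."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    n_n, n_t, n_g = cfg.n_normal, cfg.n_tumor, cfg.n_genes
    normals = [f"N{i:04d}" for i in range(n_n)]
    tumors = [f"T{i:04d}" for i in range(n_t)]
    samples = normals + tumors
    is_tumor = np.array([False] * n_n + [True] * n_t)

    genes = [f"GENE{i:05d}" for i in range(n_g)]
    genes[0] = cfg.driver_gene
    driver_idx = 0
    target_idx = np.arange(1, 1 + cfg.n_driver_targets)
    mut_idx = np.arange(1 + cfg.n_driver_targets,
                        1 + cfg.n_driver_targets + cfg.n_mutation_responsive)

    # --- expression baselines (log2 scale) ---------------------------------
    sigma_ln = np.sqrt(np.log1p(cfg.biological_cv**2))
    sigma_log2 = sigma_ln / np.log(2)
    base_log2 = rng.normal(loc=4.0, scale=1.5, size=n_g)

    n_de = int(round(cfg.fraction_de * n_g))
    plantable = np.setdiff1d(np.arange(n_g),
                             np.concatenate([[driver_idx], target_idx, mut_idx]))
    de_idx = rng.choice(plantable, size=min(n_de, plantable.size),
                        replace=False)
    # genes carrying planted effects represent detectably expressed genes:
    # their baselines are drawn from the clearly expressed range so planted
    # signal is not erased by the mean-TPM filter
    planted = np.concatenate([[driver_idx], target_idx, mut_idx, de_idx])
    base_log2[planted] = rng.normal(loc=5.0, scale=1.0, size=planted.size)

    log2_expr = base_log2[:, None] + rng.normal(0.0, sigma_log2,
                                                size=(n_g, len(samples)))

    # --- planted tumor DE genes ---------------------------------------------
    signs = np.where(np.arange(de_idx.size) % 2 == 0, 1.0, -1.0)
    lfc = np.log2(cfg.de_fold_change)
    for i, s in zip(de_idx, signs):
        log2_expr[i, is_tumor] += s * lfc
    de_truth = pd.DataFrame({
        "gene": [genes[i] for i in de_idx],
        "true_fc": [cfg.de_fold_change if s > 0 else -cfg.de_fold_change
                    for s in signs]})

    # --- driver upregulation in tumors -----------------------------------
    if cfg.driver_fold_change > 1:
        log2_expr[driver_idx, is_tumor] += np.log2(cfg.driver_fold_change)
        de_truth = pd.concat(
            [de_truth, pd.DataFrame({"gene": [cfg.driver_gene],
                                     "true_fc": [cfg.driver_fold_change]})],
            ignore_index=True)

    # driver z-score: each sample's driver expression standardized against the
    # normal-sample mean, scaled by the all-sample SD
    drv = log2_expr[driver_idx]
    z_driver = (drv - drv[~is_tumor].mean()) / drv.std()

    # --- probe manifest ----------------------------------------------------
    probe_rows = []
    probe_of_gene: dict[int, list[str]] = {}
    counter = 0

    def _new_probe(gene_i, tss):
        nonlocal counter
        pid = f"cg{counter:07d}"
        counter += 1
        probe_rows.append({"probe_id": pid, "chromosome": "chr1",
                           "position": 10_000 + 2_000 * counter,
                           "strand": "+" if counter % 2 else "-",
                           "gene": genes[gene_i], "tss_distance": tss})
        probe_of_gene.setdefault(gene_i, []).append(pid)
        return pid

    target_promoter_probes = {}
    decoy_probes = {}
    for gi in range(n_g):
        if gi in set(target_idx):
            target_promoter_probes[gi] = [_new_probe(gi, tss)
                                          for tss in (200, 700, 1400)]
            decoy_probes[gi] = _new_probe(gi, 2500)  # outside the window
        else:
            _new_probe(gi, int(rng.integers(0, 1501)))
    manifest_df = pd.DataFrame(probe_rows).set_index("probe_id")
    n_probes = len(manifest_df)

    # --- methylation --------------------------------------------------------
    high_mode = rng.random(n_probes) < cfg.beta_high_fraction
    base_beta = np.where(high_mode, cfg.beta_mode_high, cfg.beta_mode_low)
    logit_base = _logit(base_beta)
    logits = logit_base[:, None] + rng.normal(0.0, cfg.logit_noise_sd,
                                              size=(n_probes, len(samples)))
    probe_pos = {pid: i for i, pid in enumerate(manifest_df.index)}
    planted_probe_idx = []
    for gi in target_idx:
        for pid in target_promoter_probes[gi] + [decoy_probes[gi]]:
            planted_probe_idx.append(probe_pos[pid])
    if planted_probe_idx and cfg.methylation_slope != 0:
        planted_probe_idx = np.array(planted_probe_idx)
        low_logit = _logit(cfg.beta_mode_low)
        logits[planted_probe_idx] = (
            low_logit
            + cfg.methylation_slope * z_driver[None, :]
            + rng.normal(0.0, cfg.logit_noise_sd,
                         size=(len(planted_probe_idx), len(samples))))
    elif planted_probe_idx:
        planted_probe_idx = np.array(planted_probe_idx)
        logits[planted_probe_idx] = (
            _logit(cfg.beta_mode_low)
            + rng.normal(0.0, cfg.logit_noise_sd,
                         size=(len(planted_probe_idx), len(samples))))
    beta = _expit(logits)

    # --- silencing: promoter beta suppresses target expression -------------
    target_truth_rows = []
    for gi in target_idx:
        promoter = [probe_pos[p] for p in target_promoter_probes[gi]]
        mean_beta = beta[promoter].mean(axis=0)
        log2_expr[gi] += -cfg.silencing_strength * mean_beta / np.log(2)
        target_truth_rows.append({
            "gene": genes[gi],
            "probes": ",".join(target_promoter_probes[gi]),
            "methylation_slope": cfg.methylation_slope,
            "silencing_strength": cfg.silencing_strength})
    has_planted_meth = (cfg.methylation_slope != 0
                        or cfg.silencing_strength != 0)
    driver_targets = pd.DataFrame(
        target_truth_rows if has_planted_meth else [],
        columns=["gene", "probes", "methylation_slope", "silencing_strength"])

    # --- mutations and mutation-responsive genes ---------------------------
    mutations = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"),
        columns=list(cfg.mutation_drivers), dtype=int)
    mut_truth_rows = []
    for driver in cfg.mutation_drivers:
        status = (rng.random(n_t) < cfg.mutation_frequency).astype(int)
        mutations.loc[tumors, driver] = status
        mutations.loc[normals, driver] = 0
    if cfg.mutation_effect_fc > 1 and len(cfg.mutation_drivers):
        primary = cfg.mutation_drivers[0]
        mutated_mask = np.zeros(len(samples), dtype=bool)
        mutated_mask[n_n:] = mutations.loc[tumors, primary].to_numpy() == 1
        for gi in mut_idx:
            log2_expr[gi, mutated_mask] += np.log2(cfg.mutation_effect_fc)
            mut_truth_rows.append({"driver": primary, "gene": genes[gi],
                                   "true_fc": cfg.mutation_effect_fc})
    mutation_responsive = pd.DataFrame(
        mut_truth_rows, columns=["driver", "gene", "true_fc"])

    # --- survival (tumors only) --------------------------------------------
    lam0 = np.log(2) / cfg.baseline_median_survival
    drv_tumor = log2_expr[driver_idx, is_tumor]
    high = drv_tumor > np.median(drv_tumor)
    hazard = lam0 * np.where(high, cfg.survival_hazard_ratio, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        lam_c = lam0 * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        censor_t = rng.exponential(1.0 / lam_c, size=n_t)
    else:
        censor_t = np.full(n_t, np.inf)
    obs_t = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    prognostic = pd.DataFrame(
        [{"gene": cfg.driver_gene, "hazard_ratio": cfg.survival_hazard_ratio}]
        if cfg.survival_hazard_ratio != 1 else [],
        columns=["gene", "hazard_ratio"])

    # --- assemble -----------------------------------------------------------
    expr_df = pd.DataFrame(np.exp2(log2_expr), index=pd.Index(genes),
                           columns=samples)
    ann = pd.DataFrame({
        "group": np.where(is_tumor, "tumor", "normal"),
        "cancer_type": "SIM",
        "survival_months": np.nan,
        "event": np.nan,
    }, index=pd.Index(samples, name="sample_id"))
    ann.loc[tumors, "survival_months"] = np.round(obs_t, 4)
    ann.loc[tumors, "event"] = event

    truth = SimTruth(de_genes=de_truth if cfg.fraction_de > 0
                     or cfg.driver_fold_change > 1
                     else pd.DataFrame(columns=["gene", "true_fc"]),
                     driver_targets=driver_targets,
                     prognostic_genes=prognostic,
                     mutation_responsive=mutation_responsive)
    return Cohort(expression=ExpressionMatrix(expr_df),
                  methylation=MethylationMatrix(pd.DataFrame(
                      beta, index=manifest_df.index, columns=samples)),
                  manifest=ProbeManifest(manifest_df),
                  annotation=SampleAnnotation(ann),
                  mutations=mutations,
                  truth=truth,
                  config=cfg)


def simulate_null(config: SimConfig = None) -> Cohort:
    """Cohort with every planted effect forced neutral (type-I-error harness)."""
    cfg = (config or SimConfig()).replace(
        fraction_de=0.0, de_fold_change=1.0, driver_fold_change=1.0,
        methylation_slope=0.0, silencing_strength=0.0,
        survival_hazard_ratio=1.0, mutation_effect_fc=1.0)
    return simulate_cohort(cfg)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write every cohort table to ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "methylation": out / "methylation.tsv",
        "manifest": out / "manifest.tsv",
        "annotation": out / "annotation.tsv",
        "mutations": out / "mutations.tsv",
        "truth_de": out / "truth_de_genes.tsv",
        "truth_targets": out / "truth_driver_targets.tsv",
        "truth_prognostic": out / "truth_prognostic.tsv",
        "truth_mutation": out / "truth_mutation_responsive.tsv",
    }
    io_mod.write_expression(cohort.expression, paths["expression"])
    io_mod.write_methylation(cohort.methylation, paths["methylation"])
    io_mod.write_manifest(cohort.manifest, paths["manifest"])
    io_mod.write_annotation(cohort.annotation, paths["annotation"])
    io_mod.write_mutations(cohort.mutations, paths["mutations"])
    cohort.truth.de_genes.to_csv(paths["truth_de"], sep="\t", index=False)
    cohort.truth.driver_targets.to_csv(paths["truth_targets"], sep="\t",
                                       index=False)
    cohort.truth.prognostic_genes.to_csv(paths["truth_prognostic"], sep="\t",
                                         index=False)
    cohort.truth.mutation_responsive.to_csv(paths["truth_mutation"], sep="\t",
                                            index=False)
    return {k: str(v) for k, v in paths.items()}
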