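"""Methylation-expression integration: the anticorrelation gene calls.

Probes surviving the dual-contrast differential-methylation overlap are joined
to the differentially expressed genes; the Spearman rank correlation between
each probe's beta values and its gene's log2 expression across tumor samples is
computed, and each probe-gene pair is classified:

* hyper_repressed:  delta-beta > 0.2, r < -0.2, fold change <= -1.5
* hypo_activated:   delta-beta < -0.2, r < -0.2, fold change >= +1.5

(all inequalities strict except the fold-change arm, which inherits the
differential-expression "not less than 1.5" rule). These are the genes whose
expression change is attributable to a driver-associated promoter methylation
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .datatypes import (ExpressionMatrix, MethylationMatrix, ProbeManifest,
                        SampleAnnotation, ValidationError)
from .diffexpr import DifferentialExpression, DEResults
from .diffmeth import DifferentialMethylation, DMResults

HYPER_REPRESSED = "hyper_repressed"
HYPO_ACTIVATED = "hypo_activated"
NONE = "none"


def spearman_correlation(x, y):
    """Spearman rank correlation with average ranks for ties, pairwise-complete.

    Returns ``(r, p)``; p is the large-sample t approximation. Fewer than 3
    complete pairs or a constant input yields ``(nan, nan)`` (flagged, excluded
    downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def join_dm_de(overlap: pd.DataFrame, de_table: pd.DataFrame,
               probe_map: pd.Series = None) -> pd.DataFrame:
    """Probe-gene candidate pairs: overlap probes whose assigned gene is a DEG.

    A gene with several surviving probes contributes one pair per probe; genes
    without surviving probes are dropped.
    """
    degs = de_table[de_table["direction"] != "ns"]
    merged = overlap.merge(
        degs[["gene", "fc_signed", "fdr", "direction"]].rename(
            columns={"direction": "de_direction", "fdr": "de_fdr"}),
        on="gene", how="inner")
    return merged.reset_index(drop=True)


def classify_pair(delta_beta: float, fc_signed: float, r: float,
                  config: PipelineConfig = None) -> str:
    """Classify one probe-gene pair (see module docstring for the rule)."""
    cfg = config or PipelineConfig()
    if not (np.isfinite(delta_beta) and np.isfinite(fc_signed) and np.isfinite(r)):
        return NONE
    anticorr = r < cfg.integration_r
    if delta_beta > cfg.integration_delta_beta and anticorr \
            and fc_signed <= -cfg.de_fc:
        return HYPER_REPRESSED
    if delta_beta < -cfg.integration_delta_beta and anticorr \
            and fc_signed >= cfg.de_fc:
        return HYPO_ACTIVATED
    return NONE


@dataclass
class IntegrationResults:
    """Integrated probe-gene calls plus the upstream stage results.

    ``table`` columns: probe, delta_beta, gene, fc_signed, p, r, p_r, class_
    (mirroring the published table layout: Probe, delta-beta, Gene, Fold
    change, P value, r, P value).
    """

    table: pd.DataFrame
    de: DEResults
    dm: DMResults
    config: PipelineConfig

    @property
    def calls(self) -> pd.DataFrame:
        return self.table[self.table["class_"] != NONE]

    @property
    def hyper_repressed_genes(self) -> list[str]:
        return sorted(self.table.loc[self.table["class_"] == HYPER_REPRESSED,
                                     "gene"].unique())

    @property
    def hypo_activated_genes(self) -> list[str]:
        return sorted(self.table.loc[self.table["class_"] == HYPO_ACTIVATED,
                                     "gene"].unique())

    def summary(self) -> str:
        return ("Methylation-expression integration "
                f"(delta-beta > {self.config.integration_delta_beta}, "
                f"r < {self.config.integration_r})\n"
                f"  candidate probe-gene pairs: {len(self.table)}\n"
                f"  hyper_repressed: {len(self.hyper_repressed_genes)} genes\n"
                f"  hypo_activated: {len(self.hypo_activated_genes)} genes")


class IntegrationPipeline:
    """End-to-end cascade: differential expression -> dual-contrast
    differential methylation -> probe overlap -> DEG join -> Spearman
    anticorrelation -> classification.

    Correlation is computed across tumor samples only by default (set
    ``config.include_normals_in_correlation`` to include normals).
    """

    def __init__(self, expr: ExpressionMatrix, meth: MethylationMatrix,
                 manifest: ProbeManifest, annotation: SampleAnnotation,
                 driver_gene: str = "DNMT3B", config: PipelineConfig = None):
        self.config = config or PipelineConfig()
        self.expr = expr
        self.meth = meth
        self.manifest = manifest
        self.annotation = annotation
        self.driver_gene = driver_gene

    def run(self) -> IntegrationResults:
        cfg = self.config
        try:
            de = DifferentialExpression(self.expr, self.annotation,
                                        config=cfg).fit()
        except Exception as exc:  # pragma: no cover - propagation contract
            raise RuntimeError(f"integration failed at stage 'dex': {exc}") from exc
        try:
            dm = DifferentialMethylation(self.meth, self.manifest, self.expr,
                                         self.annotation, self.driver_gene,
                                         config=cfg).fit()
        except Exception as exc:
            raise RuntimeError(f"integration failed at stage 'dmp': {exc}") from exc
        pairs = join_dm_de(dm.overlap, de.table)
        samples = list(self.annotation.tumor_samples)
        if cfg.include_normals_in_correlation:
            samples = list(self.annotation.sample_ids)
        samples = [s for s in samples
                   if s in set(self.meth.sample_ids)
                   and s in set(self.expr.sample_ids)]
        log_expr = self.expr.log2(cfg.expr_pseudocount)
        rows = []
        for rec in pairs.itertuples(index=False):
            beta = self.meth.beta.loc[rec.probe, samples].to_numpy(float)
            ex = log_expr.loc[rec.gene, samples].to_numpy(float)
            r, p_r = spearman_correlation(beta, ex)
            cls = NONE if np.isnan(r) else classify_pair(
                rec.delta_beta, rec.fc_signed, r, cfg)
            rows.append({"probe": rec.probe, "delta_beta": rec.delta_beta,
                         "gene": rec.gene, "fc_signed": rec.fc_signed,
                         "p": rec.p, "r": r, "p_r": p_r, "class_": cls})
        columns = ["probe", "delta_beta", "gene", "fc_signed", "p", "r",
                   "p_r", "class_"]
        table = pd.DataFrame(rows, columns=columns)
        return IntegrationResults(table=table, de=de, dm=dm, config=cfg)
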