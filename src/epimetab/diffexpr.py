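"""Regularized differential expression between two sample groups.

The test statistic is an empirical-Bayes (Cyber-T-style) unpaired t: each
group's sample variance is shrunk toward a background variance pooled from
genes of similar mean expression, weighted by ``prior_df`` pseudo-observations.
With ``prior_df = 0`` the statistic reduces exactly to the ordinary
pooled-variance unpaired t.

Per group g with n_g observations, sample variance s_g^2 and background
standard deviation bg_g:

    v_g = (prior_df * bg_g^2 + (n_g - 1) * s_g^2) / (prior_df + n_g - 1)

The groups are pooled with weights (prior_df + n_g - 1) and the statistic is
referred to a t distribution with df = n_a + n_b - 2 + 2 * prior_df.

Genes are called differentially expressed at FDR < ``de_fdr`` together with
|signed fold change| >= ``de_fc`` (signed FC is the ratio of group means,
reported as -(reference/test) when the test group is lower, so |FC| >= 1
always). The microarray profile calls on |log2 FC| > ``geo_logfc`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import ExpressionMatrix, SampleAnnotation, ValidationError


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def filter_low_expression(expr: ExpressionMatrix,
                          min_mean_tpm: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose mean TPM over all samples is below ``min_mean_tpm``.

    The exclusion is strict ("mean TPM of less than 1"), so a gene at exactly
    the threshold is retained. Requires a non-log matrix.
    """
    if expr.log_transformed:
        raise ValidationError("filter_low_expression needs non-log TPM")
    keep = expr.values.mean(axis=1) >= min_mean_tpm
    return ExpressionMatrix(expr.values.loc[keep], log_transformed=False)


def signed_fold_change(mean_a, mean_b, pseudocount: float = 0.0):
    """Signed ratio fold change: a/b if >= 1 else -(b/a); |FC| >= 1 always.

    Vectorized; both means zero (after pseudocount) is an error.
    """
    a = np.asarray(mean_a, dtype=float) + pseudocount
    b = np.asarray(mean_b, dtype=float) + pseudocount
    if np.any((a == 0) & (b == 0)):
        raise ValidationError("signed_fold_change: both group means are zero")
    with np.errstate(divide="ignore"):
        ratio = np.where(a >= b, a / np.where(b == 0, np.nan, b),
                         -b / np.where(a == 0, np.nan, a))
    ratio = np.where((a >= b) & (b == 0), np.inf, ratio)
    ratio = np.where((a < b) & (a == 0), -np.inf, ratio)
    return ratio if ratio.ndim else float(ratio)


def estimate_background_sd(log_expr: pd.DataFrame,
                           window_size: int = 101) -> pd.Series:
    """Per-gene background SD pooled over a window of similarly expressed genes.

    Genes are ordered by mean; for each gene the per-gene sample variances of
    the ``window_size`` genes in a full-size window centred on it (clamped at
    the ends of the ordering) are averaged and the square root returned, in the
    original gene order.
    """
    n = log_expr.shape[0]
    if n < 3:
        raise ValidationError("background SD needs at least 3 genes")
    if window_size < 3 or window_size % 2 == 0:
        raise ValidationError("window_size must be odd and >= 3")
    w = min(window_size, n)
    means = log_expr.mean(axis=1).to_numpy()
    variances = log_expr.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(means, kind="stable")
    sorted_var = variances[order]
    csum = np.concatenate([[0.0], np.cumsum(sorted_var)])
    idx = np.arange(n)
    start = np.clip(idx - w // 2, 0, n - w)
    pooled_var = (csum[start + w] - csum[start]) / w
    bg = np.empty(n)
    bg[order] = np.sqrt(pooled_var)
    return pd.Series(bg, index=log_expr.index, name="background_sd")


def regularized_t(group_a, group_b, background_sd_a, background_sd_b,
                  prior_df: float = 10.0, welch: bool = False):
    """Bayes-regularized unpaired t; vectorized over genes (rows).

    Returns ``(t_stat, df, p)``. With ``prior_df = 0`` this is the ordinary
    pooled-variance (or Welch) unpaired t. Degenerate genes (zero pooled
    variance, equal means) get t = 0, p = 1.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    scalar_in = np.asarray(group_a).ndim == 1
    na, nb = a.shape[1], b.shape[1]
    if prior_df == 0 and (na < 2 or nb < 2):
        raise ValidationError("need >= 2 observations per group when prior_df=0")
    if na < 1 or nb < 1:
        raise ValidationError("empty group")
    bg_a = np.broadcast_to(np.asarray(background_sd_a, dtype=float),
                           (a.shape[0],)).astype(float)
    bg_b = np.broadcast_to(np.asarray(background_sd_b, dtype=float),
                           (b.shape[0],)).astype(float)
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa2 = a.var(axis=1, ddof=1) if na > 1 else np.zeros(a.shape[0])
    sb2 = b.var(axis=1, ddof=1) if nb > 1 else np.zeros(b.shape[0])
    wa, wb = prior_df + na - 1, prior_df + nb - 1
    va = (prior_df * bg_a**2 + (na - 1) * sa2) / wa
    vb = (prior_df * bg_b**2 + (nb - 1) * sb2) / wb
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (np.where(wa > 0, (va / na)**2 / wa, 0)
                           + np.where(wb > 0, (vb / nb)**2 / wb, 0))
        df = np.where(np.isfinite(df), df, 1.0)
    else:
        pooled = (wa * va + wb * vb) / (wa + wb)
        se2 = pooled * (1.0 / na + 1.0 / nb)
        df = np.full(a.shape[0], na + nb - 2 + 2 * prior_df, dtype=float)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where((se2 == 0) & (diff == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where((se2 == 0) & (diff == 0), 1.0, p)
    if scalar_in:
        return float(t[0]), float(df[0]), float(p[0])
    return t, df, p


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_degs(results: pd.DataFrame, de_fdr: float = 0.05,
              de_fc: float = 1.5) -> pd.DataFrame:
    """Assign direction: up iff fdr < de_fdr and fc_signed >= de_fc; down iff
    fdr < de_fdr and fc_signed <= -de_fc; otherwise ns. The fold-change arm is
    inclusive ("not less than 1.5")."""
    out = results.copy()
    sig = out["fdr"] < de_fdr
    out["direction"] = "ns"
    out.loc[sig & (out["fc_signed"] >= de_fc), "direction"] = "up"
    out.loc[sig & (out["fc_signed"] <= -de_fc), "direction"] = "down"
    return out


def call_degs_geo(results: pd.DataFrame, de_fdr: float = 0.05,
                  geo_logfc: float = 1.0) -> pd.DataFrame:
    """Microarray-profile calling: FDR < de_fdr and |log2 FC| > geo_logfc
    (strict, matching the published '|logFC| > 1' cutoff)."""
    out = results.copy()
    logfc = np.sign(out["fc_signed"]) * np.log2(np.abs(out["fc_signed"]))
    sig = (out["fdr"] < de_fdr) & (np.abs(logfc) > geo_logfc)
    out["direction"] = "ns"
    out.loc[sig & (logfc > 0), "direction"] = "up"
    out.loc[sig & (logfc < 0), "direction"] = "down"
    return out


def recurrence_filter(per_cohort_calls: dict, min_cohorts: int = 8,
                      consistent_direction: bool = False) -> list[str]:
    """Genes differentially expressed (direction != ns) in >= ``min_cohorts``
    cohorts. Direction consistency across cohorts is optional (default off:
    recurrence counts significance regardless of direction)."""
    if min_cohorts > len(per_cohort_calls):
        raise ValidationError(
            f"min_cohorts={min_cohorts} exceeds number of cohorts "
            f"({len(per_cohort_calls)})")
    counts: dict[str, dict[str, int]] = {}
    for table in per_cohort_calls.values():
        called = table[table["direction"] != "ns"]
        for gene, direction in zip(called["gene"], called["direction"]):
            d = counts.setdefault(gene, {"up": 0, "down": 0})
            d[direction] += 1
    kept = []
    for gene, d in counts.items():
        total = d["up"] + d["down"]
        if consistent_direction:
            if max(d["up"], d["down"]) >= min_cohorts:
                kept.append(gene)
        elif total >= min_cohorts:
            kept.append(gene)
    return sorted(kept)


def restrict_to_metabolic(results: pd.DataFrame, metabolic_genes) -> pd.DataFrame:
    """Subset a result table to a curated gene list by exact symbol match.

    Returns the subset; list entries absent from the table are tolerated (the
    ``unmatched`` attribute on the returned frame records them). An empty list
    is an error.
    """
    genes = list(metabolic_genes)
    if not genes:
        raise ValidationError("metabolic gene list is empty")
    present = set(results["gene"])
    unmatched = sorted(set(genes) - present)
    out = results[results["gene"].isin(set(genes))].copy()
    out.attrs["unmatched"] = unmatched
    return out


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

@dataclass
class DEResults:
    """Differential-expression results.

    ``table`` has one row per gene: gene, mean_a, mean_b, fc_signed, t_stat,
    df, p, fdr, direction. Group a is the test group (tumor / mutated), group b
    the reference (normal / wild-type).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    config: PipelineConfig

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]

    @property
    def deg_genes(self) -> list[str]:
        return sorted(self.degs["gene"].tolist())

    def summary(self) -> str:
        n = len(self.table)
        up = int((self.table["direction"] == "up").sum())
        down = int((self.table["direction"] == "down").sum())
        return (f"Differential expression: {self.group_a} vs {self.group_b}\n"
                f"  genes tested: {n}\n"
                f"  up: {up}  down: {down}  ns: {n - up - down}\n"
                f"  thresholds: FDR < {self.config.de_fdr}, "
                f"|FC| >= {self.config.de_fc}")


class DifferentialExpression:
    """Two-group regularized differential expression model.

    Parameters
    ----------
    expr : ExpressionMatrix
        Non-log TPM matrix.
    annotation : SampleAnnotation
        Sample metadata; ``group_a``/``group_b`` name annotation groups, or
        pass explicit sample id lists via ``samples_a``/``samples_b``.
    profile : {"tcga", "geo"}
        Calling profile: ratio-FC thresholds (default) or |log2FC| cutoff.
    """

    def __init__(self, expr: ExpressionMatrix, annotation: SampleAnnotation = None,
                 group_a: str = "tumor", group_b: str = "normal",
                 samples_a=None, samples_b=None,
                 config: PipelineConfig = None, profile: str = "tcga",
                 apply_expression_filter: bool = True):
        self.config = config or PipelineConfig()
        if profile not in ("tcga", "geo"):
            raise ValidationError("profile must be 'tcga' or 'geo'")
        self.profile = profile
        if samples_a is None or samples_b is None:
            if annotation is None:
                raise ValidationError("need annotation or explicit sample lists")
            samples_a = [s for s in expr.sample_ids
                         if s in set(annotation.samples_in_group(group_a))]
            samples_b = [s for s in expr.sample_ids
                         if s in set(annotation.samples_in_group(group_b))]
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValidationError("each group needs >= 2 samples")
        self.samples_a, self.samples_b = list(samples_a), list(samples_b)
        self.group_a, self.group_b = group_a, group_b
        self.expr = (filter_low_expression(expr, self.config.min_mean_tpm)
                     if apply_expression_filter else expr)

    def fit(self) -> DEResults:
        cfg = self.config
        log_all = self.expr.log2(cfg.expr_pseudocount)
        log_a = log_all[self.samples_a]
        log_b = log_all[self.samples_b]
        bg_a = estimate_background_sd(log_a, cfg.window_size)
        bg_b = estimate_background_sd(log_b, cfg.window_size)
        t, df, p = regularized_t(log_a.to_numpy(), log_b.to_numpy(),
                                 bg_a.to_numpy(), bg_b.to_numpy(),
                                 prior_df=cfg.prior_df, welch=cfg.welch)
        raw_a = self.expr.values[self.samples_a].mean(axis=1).to_numpy()
        raw_b = self.expr.values[self.samples_b].mean(axis=1).to_numpy()
        fc = signed_fold_change(raw_a, raw_b, pseudocount=cfg.expr_pseudocount)
        table = pd.DataFrame({
            "gene": self.expr.gene_ids,
            "mean_a": raw_a,
            "mean_b": raw_b,
            "fc_signed": fc,
            "t_stat": t,
            "df": df,
            "p": p,
            "fdr": bh_fdr(p),
        })
        if self.profile == "geo":
            table = call_degs_geo(table, cfg.de_fdr, cfg.geo_logfc)
        else:
            table = call_degs(table, cfg.de_fdr, cfg.de_fc)
        return DEResults(table=table, group_a=self.group_a,
                         group_b=self.group_b, config=cfg)
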