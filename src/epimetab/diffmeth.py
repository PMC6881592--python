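"""Promoter differential methylation under two contrasts.

Probes are restricted to the promoter window (0-1500 bp upstream of the TSS,
strand-aware, closed interval). Per-probe delta-beta (group mean difference)
and a two-sided p-value from the shared regularized-t engine applied directly
to beta values are computed under two contrasts:

* tumor vs normal, and
* top vs bottom decile of tumor samples ranked by a driver gene's expression
  (the "driver split", default driver DNMT3B).

A probe is hypermethylated when p < 0.05 and delta-beta > 0.2, hypomethylated
when p < 0.05 and delta-beta < -0.2 (both strict). The probes differential in
both contrasts ("overlap probes") are the methylation changes attributable to
the driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import (ExpressionMatrix, MethylationMatrix, ProbeManifest,
                        SampleAnnotation, ValidationError)
from .diffexpr import estimate_background_sd, regularized_t

TUMOR_VS_NORMAL = "tumor_vs_normal"
DRIVER_HIGH_VS_LOW = "driver_high_vs_low"


def promoter_probes(manifest: ProbeManifest,
                    window_bp: int = 1500) -> pd.Series:
    """Probe -> gene map for probes with 0 <= tss_distance <= window_bp.

    The window is the closed interval [0, window_bp] upstream of the TSS;
    downstream probes (negative tss_distance) are excluded.
    """
    t = manifest.table
    keep = (t["tss_distance"] >= 0) & (t["tss_distance"] <= window_bp)
    return t.loc[keep, "gene"]


def promoter_mean_beta(meth: MethylationMatrix, probe_map: pd.Series,
                       gene: str) -> pd.Series:
    """Per-sample arithmetic mean beta over a gene's promoter probes,
    ignoring missing entries."""
    probes = probe_map.index[probe_map == gene]
    probes = [p for p in probes if p in meth.beta.index]
    if not probes:
        raise ValidationError(f"gene {gene!r} has no promoter probes")
    return meth.beta.loc[probes].mean(axis=0, skipna=True)


def delta_beta(meth: MethylationMatrix, probes, group_a_samples,
               group_b_samples) -> pd.Series:
    """Per-probe mean beta(group A) - mean beta(group B); missing entries are
    ignored pairwise. A probe missing in every sample of a group yields NaN."""
    if not len(group_a_samples) or not len(group_b_samples):
        raise ValidationError("both groups must be nonempty")
    block = meth.beta.loc[list(probes)]
    return (block[list(group_a_samples)].mean(axis=1, skipna=True)
            - block[list(group_b_samples)].mean(axis=1, skipna=True))


def dm_test(meth: MethylationMatrix, probes, group_a_samples, group_b_samples,
            prior_df: float = 10.0, window_size: int = 101) -> pd.Series:
    """Two-sided p per probe from the regularized-t engine on beta values.

    Background SDs are pooled over probes of similar mean beta, per group.
    Degenerate probes (zero variance in both groups, equal means) get p = 1.
    """
    block = meth.beta.loc[list(probes)]
    a = block[list(group_a_samples)]
    b = block[list(group_b_samples)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need >= 2 samples per group")
    if block.shape[0] >= 3 and prior_df > 0:
        bg_a = estimate_background_sd(a, window_size).to_numpy()
        bg_b = estimate_background_sd(b, window_size).to_numpy()
    else:
        bg_a = np.zeros(block.shape[0])
        bg_b = np.zeros(block.shape[0])
        prior_df = 0.0 if block.shape[0] < 3 else prior_df
    _, _, p = regularized_t(a.to_numpy(), b.to_numpy(), bg_a, bg_b,
                            prior_df=prior_df)
    return pd.Series(p, index=block.index, name="p")


def extreme_group_split(expr: ExpressionMatrix, driver_gene: str,
                        fraction: float = 0.10, samples=None):
    """Top and bottom ``fraction`` of samples ranked by driver-gene expression.

    Group size is ceil(fraction * n); ties at the cut are broken by sample-id
    lexical order, deterministically. Returns ``(high, low)`` sample-id lists.
    """
    if driver_gene not in expr.values.index:
        raise ValidationError(f"driver gene {driver_gene!r} not in matrix")
    values = expr.values.loc[driver_gene]
    if samples is not None:
        values = values[list(samples)]
    n = len(values)
    k = int(np.ceil(fraction * n))
    if k < 2:
        raise ValidationError(
            f"extreme groups would have {k} < 2 samples (n={n})")
    if 2 * k > n:
        raise ValidationError("extreme groups would overlap")
    ordered = sorted(values.index, key=lambda s: (values[s], s))
    low = sorted(ordered[:k])
    high = sorted(ordered[-k:], key=lambda s: (-values[s], s))
    high = sorted(high)
    return high, low


def call_dm(dm_results: pd.DataFrame, dm_p: float = 0.05,
            dm_delta_beta: float = 0.2) -> pd.DataFrame:
    """Direction per probe: hyper iff p < dm_p and delta_beta > dm_delta_beta;
    hypo iff p < dm_p and delta_beta < -dm_delta_beta; else ns (strict
    inequalities)."""
    out = dm_results.copy()
    sig = out["p"] < dm_p
    out["direction"] = "ns"
    out.loc[sig & (out["delta_beta"] > dm_delta_beta), "direction"] = "hyper"
    out.loc[sig & (out["delta_beta"] < -dm_delta_beta), "direction"] = "hypo"
    return out


def overlap_probes(calls_tumor_vs_normal: pd.DataFrame,
                   calls_driver_split: pd.DataFrame,
                   require_same_direction: bool = True) -> pd.DataFrame:
    """Probes differential in both contrasts, intersected by probe id.

    With ``require_same_direction`` (default) the direction must agree across
    contrasts (hyper in both or hypo in both). Returns the tumor-vs-normal rows
    of the surviving probes with the driver-split direction attached.
    """
    a = calls_tumor_vs_normal[calls_tumor_vs_normal["direction"] != "ns"]
    b = calls_driver_split[calls_driver_split["direction"] != "ns"]
    merged = a.merge(b[["probe", "direction", "delta_beta"]], on="probe",
                     suffixes=("", "_driver"))
    if require_same_direction:
        merged = merged[merged["direction"] == merged["direction_driver"]]
    return merged.reset_index(drop=True)


@dataclass
class DMResults:
    """Per-contrast differential-methylation tables and their overlap.

    Each table has columns probe, gene, delta_beta, p, direction, contrast.
    """

    tumor_vs_normal: pd.DataFrame
    driver_split: pd.DataFrame
    overlap: pd.DataFrame
    config: PipelineConfig
    driver_gene: str

    def summary(self) -> str:
        def _counts(t):
            return (int((t["direction"] == "hyper").sum()),
                    int((t["direction"] == "hypo").sum()))
        h1, l1 = _counts(self.tumor_vs_normal)
        h2, l2 = _counts(self.driver_split)
        return (f"Differential methylation (P < {self.config.dm_p}, "
                f"|delta-beta| > {self.config.dm_delta_beta})\n"
                f"  tumor vs normal: {h1} hyper, {l1} hypo\n"
                f"  {self.driver_gene} top vs bottom "
                f"{self.config.extreme_fraction:.0%}: {h2} hyper, {l2} hypo\n"
                f"  overlap probes: {len(self.overlap)}")


class DifferentialMethylation:
    """Dual-contrast promoter differential-methylation model.

    Runs the tumor-vs-normal and driver-split contrasts on promoter-window
    probes and intersects the calls. The driver split is computed on tumor
    samples only (the cohort whose methylation disorder is being attributed).
    """

    def __init__(self, meth: MethylationMatrix, manifest: ProbeManifest,
                 expr: ExpressionMatrix, annotation: SampleAnnotation,
                 driver_gene: str = "DNMT3B", config: PipelineConfig = None):
        self.config = config or PipelineConfig()
        self.meth = meth
        self.manifest = manifest
        self.expr = expr
        self.annotation = annotation
        self.driver_gene = driver_gene

    def _contrast(self, probes, probe_map, samples_a, samples_b, label):
        cfg = self.config
        db = delta_beta(self.meth, probes, samples_a, samples_b)
        p = dm_test(self.meth, probes, samples_a, samples_b,
                    prior_df=cfg.prior_df, window_size=cfg.window_size)
        table = pd.DataFrame({
            "probe": list(probes),
            "gene": [probe_map[pr] for pr in probes],
            "delta_beta": db.to_numpy(),
            "p": p.to_numpy(),
            "contrast": label,
        })
        return call_dm(table, cfg.dm_p, cfg.dm_delta_beta)

    def fit(self) -> DMResults:
        cfg = self.config
        probe_map = promoter_probes(self.manifest, cfg.promoter_window_bp)
        probes = [p for p in probe_map.index if p in self.meth.beta.index]
        probe_map = probe_map.loc[probes]
        tumor = [s for s in self.meth.sample_ids
                 if s in set(self.annotation.tumor_samples)]
        normal = [s for s in self.meth.sample_ids
                  if s in set(self.annotation.normal_samples)]
        tn = self._contrast(probes, probe_map, tumor, normal, TUMOR_VS_NORMAL)
        high, low = extreme_group_split(self.expr, self.driver_gene,
                                        cfg.extreme_fraction, samples=tumor)
        ds = self._contrast(probes, probe_map, high, low, DRIVER_HIGH_VS_LOW)
        ov = overlap_probes(tn, ds, cfg.require_same_direction)
        return DMResults(tumor_vs_normal=tn, driver_split=ds, overlap=ov,
                         config=cfg, driver_gene=self.driver_gene)
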