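"""Mutation-stratified differential expression of metabolic genes.

Samples are split by the binary mutation status of a driver gene (oncogene or
tumor suppressor); cohorts where the mutated arm has fewer than 20 samples are
excluded. The differential-expression engine then compares mutated vs
wild-type tumors, restricted to the metabolic gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .datatypes import ExpressionMatrix, ValidationError
from .diffexpr import DifferentialExpression, DEResults, restrict_to_metabolic


def select_top_drivers(mutation_table: pd.DataFrame, candidates, k: int = 3):
    """The ``k`` candidate drivers with the highest mutated-sample frequency.

    Frequencies are computed in this cohort over non-missing statuses; ties are
    broken by candidate-list order (deterministic). Candidates absent from the
    table count as frequency 0.
    """
    candidates = list(candidates)
    if k > len(candidates):
        raise ValidationError(f"k={k} exceeds {len(candidates)} candidates")
    freqs = {}
    for gene in candidates:
        if gene in mutation_table.columns:
            col = mutation_table[gene].dropna()
            freqs[gene] = float(col.mean()) if len(col) else 0.0
        else:
            freqs[gene] = 0.0
    rank = {g: i for i, g in enumerate(candidates)}
    ordered = sorted(candidates, key=lambda g: (-freqs[g], rank[g]))
    return ordered[:k]


@dataclass
class MutationGrouping:
    """Mutated / wild-type sample split for one driver gene."""

    driver_gene: str
    mutated_samples: list
    wildtype_samples: list
    eligible: bool
    n_missing: int = 0

    def __post_init__(self) -> None:
        if set(self.mutated_samples) & set(self.wildtype_samples):
            raise ValidationError("mutated and wild-type groups overlap")


def group_by_mutation(mutation_table: pd.DataFrame, driver_gene: str,
                      min_group: int = 20,
                      both_arms: bool = False) -> MutationGrouping:
    """Split samples by the driver's binary mutation status.

    Eligibility requires >= ``min_group`` mutated samples (inclusive at the
    boundary); with ``both_arms`` the wild-type arm must satisfy it too.
    Samples with missing status are excluded from both arms and counted.
    """
    if driver_gene not in mutation_table.columns:
        raise ValidationError(f"driver {driver_gene!r} absent from mutation table")
    status = mutation_table[driver_gene]
    missing = int(status.isna().sum())
    mutated = sorted(status.index[status == 1].tolist())
    wildtype = sorted(status.index[status == 0].tolist())
    eligible = len(mutated) >= min_group
    if both_arms:
        eligible = eligible and len(wildtype) >= min_group
    return MutationGrouping(driver_gene=driver_gene, mutated_samples=mutated,
                            wildtype_samples=wildtype, eligible=eligible,
                            n_missing=missing)


def mutation_de(expr: ExpressionMatrix, grouping: MutationGrouping,
                metabolic_genes=None, config: PipelineConfig = None) -> DEResults:
    """DE engine applied with mutated samples as the test group and wild-type
    as reference, restricted to the metabolic gene list when given. Refuses
    ineligible groupings."""
    cfg = config or PipelineConfig()
    if not grouping.eligible:
        raise ValidationError(
            f"grouping for {grouping.driver_gene} is ineligible "
            f"({len(grouping.mutated_samples)} mutated samples "
            f"< {cfg.mutation_min_group})")
    present = set(expr.sample_ids)
    samples_a = [s for s in grouping.mutated_samples if s in present]
    samples_b = [s for s in grouping.wildtype_samples if s in present]
    model = DifferentialExpression(expr, samples_a=samples_a,
                                   samples_b=samples_b, group_a="mutated",
                                   group_b="wildtype", config=cfg)
    res = model.fit()
    if metabolic_genes is not None:
        res.table = restrict_to_metabolic(res.table, metabolic_genes)
    return res


@dataclass
class MutationAssociationResults:
    """Per-driver DE tables plus the groupings (including ineligible ones)."""

    per_driver: dict
    groupings: dict
    config: PipelineConfig
    excluded: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Mutation-stratified DE (mutated arm >= "
                 f"{self.config.mutation_min_group} samples)"]
        for driver, res in self.per_driver.items():
            g = self.groupings[driver]
            lines.append(f"  {driver}: {len(g.mutated_samples)} mutated vs "
                         f"{len(g.wildtype_samples)} wild-type, "
                         f"{len(res.degs)} DEGs")
        for driver, reason in self.excluded.items():
            lines.append(f"  {driver}: excluded ({reason})")
        return "\n".join(lines)


class MutationAssociation:
    """Screen the top-k most frequently mutated drivers against the metabolic
    expression profile of tumor samples."""

    def __init__(self, expr: ExpressionMatrix, mutation_table: pd.DataFrame,
                 candidate_drivers, k: int = 3, metabolic_genes=None,
                 config: PipelineConfig = None):
        self.config = config or PipelineConfig()
        self.expr = expr
        self.mutation_table = mutation_table
        self.candidates = list(candidate_drivers)
        self.k = k
        self.metabolic_genes = metabolic_genes

    def fit(self) -> MutationAssociationResults:
        cfg = self.config
        drivers = select_top_drivers(self.mutation_table, self.candidates,
                                     self.k)
        per_driver, groupings, excluded = {}, {}, {}
        for driver in drivers:
            grouping = group_by_mutation(self.mutation_table, driver,
                                         cfg.mutation_min_group,
                                         cfg.min_group_both_arms)
            groupings[driver] = grouping
            if not grouping.eligible:
                excluded[driver] = (
                    f"mutated arm has {len(grouping.mutated_samples)} "
                    f"< {cfg.mutation_min_group} samples")
                continue
            per_driver[driver] = mutation_de(self.expr, grouping,
                                             self.metabolic_genes, cfg)
        return MutationAssociationResults(per_driver=per_driver,
                                          groupings=groupings, config=cfg,
                                          excluded=excluded)
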