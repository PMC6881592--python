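"""Shared in-memory data model for the pipeline.

All containers are thin, validating wrappers around :class:`pandas.DataFrame`.
Matrices are oriented features x samples (genes x samples for expression,
probes x samples for methylation); sample metadata is indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
GROUPS = (NORMAL, TUMOR)


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene-level expression (TPM unless ``log_transformed``), genes x samples.

    Invariants: unique gene and sample ids; values nonnegative and non-missing
    on the TPM scale.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if not self.log_transformed and (self.values.to_numpy() < 0).any():
            rows, cols = np.where(self.values.to_numpy() < 0)
            g, s = self.values.index[rows[0]], self.values.columns[cols[0]]
            raise ValidationError(f"negative TPM at gene {g!r}, sample {s!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)],
                                log_transformed=self.log_transformed)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)],
                                log_transformed=self.log_transformed)

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(TPM + pseudocount); raises if already log-transformed."""
        if self.log_transformed:
            raise ValidationError("matrix is already log-transformed")
        return np.log2(self.values + pseudocount)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: group, cancer type, survival, event flag.

    ``table`` is indexed by sample id with columns ``group`` (normal/tumor),
    ``cancer_type``, ``survival_months`` and ``event`` (both may be missing,
    but the event flag must be present wherever survival time is).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        required = {"group", "cancer_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        bad = set(self.table["group"].unique()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if "survival_months" in self.table.columns:
            t = self.table["survival_months"]
            e = self.table.get("event")
            if e is None:
                raise ValidationError("survival_months present without event column")
            orphan = t.notna() & e.isna()
            if orphan.any():
                raise ValidationError(
                    f"samples with survival time but no event flag: "
                    f"{sorted(self.table.index[orphan])[:5]}")
            if (t.dropna() < 0).any():
                raise ValidationError("negative survival_months")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_in_group(TUMOR)

    @property
    def normal_samples(self) -> list[str]:
        return self.samples_in_group(NORMAL)


@dataclass
class MethylationMatrix:
    """CpG probe beta values in [0, 1], probes x samples; NaN = masked probe.

    ``unannotated`` records probes present in the matrix but absent from the
    companion manifest (retained, flagged).
    """

    beta: pd.DataFrame
    unannotated: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe ids")
        _check_unique(self.beta.columns, "sample ids")
        arr = self.beta.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            rows, cols = np.where(bad & ~np.isnan(arr))
            p, s = self.beta.index[rows[0]], self.beta.columns[cols[0]]
            raise ValidationError(
                f"beta value outside [0, 1] at probe {p!r}, sample {s!r}: "
                f"{arr[rows[0], cols[0]]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.beta.loc[:, list(sample_ids)],
                                 unannotated=self.unannotated)


MANIFEST_COLUMNS = ["probe_id", "chromosome", "position", "strand", "gene",
                    "tss_distance"]


@dataclass
class ProbeManifest:
    """Probe -> gene/TSS assignment.

    ``table`` indexed by probe id, columns chromosome, position (1-based),
    strand (+/-), gene symbol, tss_distance (signed bp; positive = upstream of
    the TSS in transcription direction).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe ids")
        required = {"chromosome", "position", "strand", "gene", "tss_distance"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        bad_strand = set(self.table["strand"].unique()) - {"+", "-"}
        if bad_strand:
            raise ValidationError(f"malformed strand values: {sorted(bad_strand)}")
        if self.table["tss_distance"].isna().any() or \
                not np.isfinite(self.table["tss_distance"].to_numpy(float)).all():
            raise ValidationError("non-finite tss_distance in manifest")
        empty = self.table["gene"].isna() | (self.table["gene"].astype(str) == "")
        if empty.any():
            raise ValidationError(
                f"empty gene for probes: {sorted(self.table.index[empty])[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def gene_of(self, probe_id: str) -> str:
        return self.table.at[probe_id, "gene"]


def harmonize_samples(matrix_samples, annotation: SampleAnnotation):
    """Check every matrix sample resolves in the annotation; return the matrix
    sample order restricted to annotated samples (order preserved)."""
    missing = [s for s in matrix_samples if s not in annotation.table.index]
    if missing:
        raise ValidationError(
            f"samples in matrix missing from annotation: {missing[:5]}")
    return list(matrix_samples)
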