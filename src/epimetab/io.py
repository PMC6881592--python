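"""Readers and writers for every on-disk format the pipeline touches.

All tables are TSV. Matrices carry the feature id in the first column and
sample ids in the header row. Result tables round-trip at full floating
precision (written with repr-level precision, reread bitwise-identical).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (ExpressionMatrix, MethylationMatrix, ProbeManifest,
                        SampleAnnotation, ValidationError, harmonize_samples,
                        MANIFEST_COLUMNS)

ANNOTATION_COLUMNS = ["sample_id", "group", "cancer_type", "survival_months",
                      "event"]


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("annotation must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_expression(path, annotation_path):
    """Read a TPM matrix and its sample annotation, harmonized.

    Raises on duplicate gene/sample ids, negative TPM, or matrix samples
    missing from the annotation.
    """
    values = _read_matrix(path)
    annotation = read_annotation(annotation_path)
    expr = ExpressionMatrix(values)
    harmonize_samples(expr.sample_ids, annotation)
    return expr, annotation


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str,
                                            "strand": str, "chromosome": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    return ProbeManifest(df.set_index("probe_id"))


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.rename_axis("probe_id").to_csv(path, sep="\t")


def read_methylation(path, manifest_path):
    """Read a beta matrix plus probe manifest.

    Beta values outside [0, 1] are rejected (not clipped). Probes present in
    the matrix but absent from the manifest are retained and flagged in
    ``MethylationMatrix.unannotated``.
    """
    beta = _read_matrix(path)
    manifest = read_manifest(manifest_path)
    unannotated = frozenset(beta.index) - frozenset(manifest.table.index)
    meth = MethylationMatrix(beta, unannotated=frozenset(unannotated))
    return meth, manifest


def write_methylation(meth: MethylationMatrix, path) -> None:
    meth.beta.rename_axis("probe_id").to_csv(path, sep="\t")


def read_mutations(path) -> pd.DataFrame:
    """Sample x driver-gene binary mutation table (0/1; blank = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 0) | (vals == 1)
    if not ok.all():
        raise ValidationError("mutation table entries must be 0, 1 or missing")
    return df


def write_mutations(mutations: pd.DataFrame, path) -> None:
    mutations.rename_axis("sample_id").to_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks and '#' lines skipped."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_result_table(records, path, columns=None) -> None:
    """Write a result table (DataFrame or list of dicts/dataclasses) as TSV.

    Column order is preserved; floats are written with full (repr) precision so
    a reread yields bitwise-identical values. An empty record list produces a
    header-only file (pass ``columns`` to name the header when the list carries
    no column information).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                import dataclasses
                rows.append(dataclasses.asdict(r))
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows, columns=columns) if columns is not None \
            else pd.DataFrame(rows)
    # repr round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", index=False,
              float_format=lambda v: repr(float(v)))


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def maf_to_binary(maf: pd.DataFrame, samples, drivers) -> pd.DataFrame:
    """Minimal MAF-to-binary converter keyed on Hugo symbol + sample barcode.

    ``maf`` needs columns Hugo_Symbol and Tumor_Sample_Barcode; any record for
    (sample, driver) marks that sample mutated. Consequence annotations are not
    parsed: the pipeline treats mutation as binary.
    """
    needed = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
    if not needed <= set(maf.columns):
        raise ValidationError(f"MAF table needs columns {sorted(needed)}")
    out = pd.DataFrame(0, index=pd.Index(list(samples), name="sample_id"),
                       columns=list(drivers), dtype=int)
    hits = maf[maf["Hugo_Symbol"].isin(drivers)
               & maf["Tumor_Sample_Barcode"].isin(out.index)]
    for gene, sample in zip(hits["Hugo_Symbol"], hits["Tumor_Sample_Barcode"]):
        out.at[sample, gene] = 1
    return out
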