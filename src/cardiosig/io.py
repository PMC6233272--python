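"""Readers/writers and validation for expression matrices, sample metadata and gene annotation.

All tabular artifacts are plain TSV/CSV. An expression matrix is a pandas
DataFrame with gene identifiers as the index and sample identifiers as
columns; values are nonnegative finite abundances (RPKM in RNA-seq mode,
probe/gene intensities in microarray mode). A sample table is a DataFrame
indexed by sample id with at least a ``phenotype`` column (DCM, ICM or NF)
and, when available, ``age`` (years) and ``sex`` (male/female) plus optional
binary clinical fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PHENOTYPES = ("DCM", "ICM", "NF")
SEXES = ("male", "female")
#: chromosome names treated as mitochondrial (annotation dialects differ)
MITO_CHROMOSOMES = frozenset({"MT", "chrM", "M"})


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


def _infer_sep(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("tsv", "csv"):
            raise ValidationError(f"unknown format {format!r}; expected 'tsv' or 'csv'")
        return "\t" if format == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_unique(values: pd.Index, what: str) -> None:
    if values.has_duplicates:
        dups = sorted(values[values.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dups}")


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression matrix in place and return it.

    Checks: unique gene and sample ids, numeric dtype, no NaN (reported with
    coordinates), no negative or non-finite values.
    """
    _check_unique(matrix.index, "gene ids")
    _check_unique(matrix.columns, "sample ids")
    try:
        values = matrix.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression values: {exc}") from exc
    nan_rows, nan_cols = np.nonzero(np.isnan(values))
    if nan_rows.size:
        coords = [
            (matrix.index[r], matrix.columns[c])
            for r, c in zip(nan_rows[:10], nan_cols[:10])
        ]
        raise ValidationError(f"NaN expression values at (gene, sample): {coords}")
    if not np.isfinite(values).all():
        raise ValidationError("non-finite expression values present")
    if (values < 0).any():
        bad = matrix.index[(values < 0).any(axis=1)][:10].tolist()
        raise ValidationError(f"negative expression values in genes: {bad}")
    return matrix


def read_expression(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a gene-by-sample matrix (first column gene ids, header sample ids)."""
    path = Path(path)
    sep = _infer_sep(path, format)
    matrix = pd.read_csv(path, sep=sep, index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return validate_expression(matrix)


def write_expression(matrix: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    matrix.to_csv(path, sep=_infer_sep(path, format), index_label="gene_id")


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    _check_unique(table.index, "sample ids")
    if "phenotype" not in table.columns:
        raise ValidationError("sample table must have a 'phenotype' column")
    bad = set(table["phenotype"].unique()) - set(PHENOTYPES)
    if bad:
        raise ValidationError(f"unknown phenotypes {sorted(bad)}; expected {PHENOTYPES}")
    if "age" in table.columns:
        ages = table["age"].dropna()
        if (ages <= 0).any():
            raise ValidationError("ages must be > 0")
    if "sex" in table.columns:
        bad = set(table["sex"].dropna().unique()) - set(SEXES)
        if bad:
            raise ValidationError(f"unknown sex values {sorted(bad)}; expected {SEXES}")
    return table


def read_sample_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_infer_sep(path, format), index_col=0)
    table.index = table.index.astype(str)
    return validate_sample_table(table)


def write_sample_table(table: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    table.to_csv(path, sep=_infer_sep(path, format), index_label="sample_id")


def check_samples_covered(matrix: pd.DataFrame, table: pd.DataFrame) -> None:
    """Every matrix sample must be described in the sample table."""
    missing = matrix.columns.difference(table.index)
    if len(missing):
        raise ValidationError(f"samples missing from sample table: {missing.tolist()}")


def read_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a gene annotation table with columns gene_id, symbol, chromosome."""
    path = Path(path)
    ann = pd.read_csv(path, sep=_infer_sep(path, format))
    required = {"gene_id", "symbol", "chromosome"}
    missing = required - set(ann.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    ann["gene_id"] = ann["gene_id"].astype(str)
    _check_unique(pd.Index(ann["gene_id"]), "annotation gene ids")
    return ann.set_index("gene_id")


def annotation_from_gtf(path: str | Path) -> pd.DataFrame:
    """Derive a gene annotation table from a GTF file (thin importer).

    Uses pyranges' GTF reader; keeps ``gene`` features and extracts gene_id,
    gene_name (symbol) and chromosome.
    """
    import pyranges  # deferred: optional heavyweight import

    gr = pyranges.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else gr
    genes = df[df["Feature"] == "gene"]
    symbol = genes["gene_name"] if "gene_name" in genes.columns else genes["gene_id"]
    ann = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].astype(str).to_numpy(),
            "symbol": symbol.astype(str).to_numpy(),
            "chromosome": genes["Chromosome"].astype(str).to_numpy(),
        }
    ).drop_duplicates("gene_id")
    return ann.set_index("gene_id")
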