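"""Reading, validating and writing expression matrices and result tables.

Supported inputs are plain TSV/CSV tables (first column gene identifiers,
header row of sample identifiers) and GCT version 1.2 files as produced by
common microarray preprocessing pipelines.  RNA-seq input must be raw
counts: normalized quantities (TPM, RPKM, FPKM) break both the scale-factor
normalization and the count models downstream, so they are rejected at
validation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MICROARRAY = "microarray"
RNASEQ = "rnaseq"

#: log2 microarray intensities essentially never exceed this; a larger
#: maximum suggests the matrix was not log-transformed.
UNLOGGED_MAX = 50.0


class ParseError(ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """An expression matrix violates the requirements of its platform."""


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression matrix.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as columns.  Raw
        counts for ``platform="rnaseq"``; background-corrected, normalized
        log2 intensities for ``platform="microarray"``.
    platform
        ``"rnaseq"`` or ``"microarray"``.
    gene_annotation
        Optional per-gene description (e.g. the GCT Description column).
    """

    values: pd.DataFrame
    platform: str
    gene_annotation: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.platform not in (MICROARRAY, RNASEQ):
            raise ValidationError(
                f"unknown platform {self.platform!r}; expected "
                f"{MICROARRAY!r} or {RNASEQ!r}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample identifiers: {list(dups)[:5]}")

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

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return replace(self, values=self.values[sample_ids])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        ann = self.gene_annotation
        return replace(
            self,
            values=self.values.loc[gene_ids],
            gene_annotation=None if ann is None else ann.loc[gene_ids],
        )


def _read_gct(path) -> tuple[pd.DataFrame, pd.Series]:
    with open(path, "rt", encoding="utf-8") as fh:
        version = fh.readline().rstrip("\n")
        if version.strip() != "#1.2":
            raise ParseError(
                f"unsupported GCT version line {version!r}; expected '#1.2'"
            )
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) < 2:
            raise ParseError(f"malformed GCT dimensions line {dims!r}")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise ParseError(f"malformed GCT dimensions line {dims!r}") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
            raise ParseError(
                f"malformed GCT header {header[:3]!r}; expected "
                "'Name', 'Description', then sample ids"
            )
        samples = header[2:]
        if len(samples) != n_samples:
            raise ParseError(
                f"GCT dimensions line declares {n_samples} samples but the "
                f"header has {len(samples)}"
            )
        body = pd.read_csv(fh, sep="\t", header=None, dtype={0: str, 1: str})
    if body.shape[0] != n_genes:
        raise ParseError(
            f"GCT dimensions line declares {n_genes} genes but the body has "
            f"{body.shape[0]} rows"
        )
    if body.shape[1] != n_samples + 2:
        raise ParseError(
            f"GCT row width {body.shape[1]} does not match 2 + {n_samples} samples"
        )
    values = body.iloc[:, 2:].copy()
    values.index = pd.Index(body.iloc[:, 0].astype(str), name="gene")
    values.columns = samples
    annotation = pd.Series(
        body.iloc[:, 1].values, index=values.index, name="description"
    )
    return values.apply(pd.to_numeric), annotation


def read_expression_table(path, format: str | None = None, platform: str = RNASEQ) -> ExpressionMatrix:
    """Read an expression matrix from a TSV, CSV or GCT 1.2 file.

    ``format=None`` infers the format from the file extension.  The matrix
    is oriented genes x samples; the GCT Description column is kept as
    ``gene_annotation`` and removed from the values.
    """
    if format is None:
        suffix = str(path).lower().rsplit(".", 1)[-1]
        format = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "gct": "gct"}.get(suffix)
        if format is None:
            raise ParseError(f"cannot infer format from path {path!r}")
    if format == "gct":
        values, annotation = _read_gct(path)
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        values = pd.read_csv(path, sep=sep, index_col=0)
        values.index = values.index.astype(str)
        annotation = None
    else:
        raise ParseError(f"unknown format {format!r}")
    return ExpressionMatrix(values=values, platform=platform, gene_annotation=annotation)


def validate_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Check that a matrix satisfies its platform's requirements.

    RNA-seq matrices must be raw counts: finite, non-negative and
    integer-valued.  Microarray matrices must be finite; a maximum above
    ``UNLOGGED_MAX`` triggers a warning that the data look un-logged (use
    :func:`log2_transform` to fix explicitly — nothing is transformed
    silently).  Validation is idempotent and returns the matrix unchanged.
    """
    vals = matrix.values.to_numpy(dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        genes = matrix.values.index[bad.any(axis=1)]
        raise ValidationError(
            f"non-finite values (NaN/Inf) in genes: {list(genes[:10])}"
        )
    if matrix.platform == RNASEQ:
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            offending = matrix.values.index[
                ((vals < 0) | ~np.isclose(vals, np.round(vals))).any(axis=1)
            ]
            raise ValidationError(
                "RNA-seq input must be a raw counts matrix (non-negative "
                "integers); TPM, RPKM or FPKM normalized values cannot be "
                f"handled. Offending genes: {list(offending[:10])}"
            )
    else:
        if vals.size and vals.max() > UNLOGGED_MAX:
            warnings.warn(
                f"microarray matrix maximum {vals.max():.1f} exceeds "
                f"{UNLOGGED_MAX:g}; the data look un-logged. Apply "
                "log2_transform() if intensities are on the raw scale.",
                UserWarning,
                stacklevel=2,
            )
    return matrix


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy with values replaced by log2(x + 1) (explicit opt-in)."""
    return replace(matrix, values=np.log2(matrix.values + 1.0))


def write_results_table(result: pd.DataFrame, path) -> None:
    """Write a per-gene result table as tab-delimited UTF-8 text.

    The gene identifier (index) becomes the first column; values survive a
    write-then-read round trip to 6 significant digits.
    """
    out = result.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", float_format="%.6g", encoding="utf-8",
               lineterminator="\n")
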