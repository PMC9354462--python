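"""Expression-matrix and sample-metadata containers and file formats.

Expression values are TPM (transcripts per million): non-negative,
library-size-normalised compositional data. Matrices live in memory as
samples x genes (`pandas.DataFrame` with sample ids as the index), while
the GCT-like dialect on disk stores genes in rows, following the
convention of the consortium files this pipeline targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "split_by_sex",
    "ValidationError",
]

METADATA_COLUMNS = ["sample_id", "sex", "age", "bmi", "rin", "ischemic_time"]


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """A samples x genes TPM table.

    Attributes
    ----------
    data
        DataFrame indexed by sample id with gene symbols as columns;
        values are TPM (>= 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at sample {df.index[r]!r}, "
                f"gene {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative TPM {values[r, c]} at sample {df.index[r]!r}, "
                f"gene {df.columns[c]!r}"
            )
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(genes)].copy())

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(sample_ids)].copy())


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` — samples in rows, header row of gene symbols, first
        column sample ids. ``"gct"`` — GCT-like: two header lines
        (version tag, then ``n_genes<TAB>n_samples``) followed by a
        genes x samples table whose first column is the gene symbol;
        transposed to samples x genes on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        df.index = df.index.astype(str)
        return ExpressionMatrix(df)
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            dims = fh.readline().split()
            df = pd.read_csv(fh, sep="\t", index_col=0,
                             float_precision="round_trip")
        if len(dims) >= 2:
            n_genes, n_samples = int(dims[0]), int(dims[1])
            if df.shape != (n_genes, n_samples):
                raise ValidationError(
                    f"GCT header declares {n_genes} genes x {n_samples} "
                    f"samples but table is {df.shape[0]} x {df.shape[1]} "
                    f"(version line {version!r})"
                )
        df.index = df.index.astype(str)
        return ExpressionMatrix(df.T)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_expression(
    expr: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write an expression matrix; inverse of :func:`read_expression`.

    Values are serialised with ``repr`` round-trip precision so that a
    write/read cycle is bit-identical.
    """
    path = Path(path)
    if dialect == "tsv":
        expr.data.to_csv(path, sep="\t", index_label="sample_id",
                         float_format="%.17g")
        return
    if dialect == "gct":
        t = expr.data.T
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{t.shape[0]}\t{t.shape[1]}\n")
            t.to_csv(fh, sep="\t", index_label="gene_id",
                     float_format="%.17g")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-attribute table (TSV).

    Expected columns: ``sample_id``, ``sex`` (female/male), ``age``
    (years), ``bmi`` (kg/m2), ``rin``, ``ischemic_time`` (minutes).
    All but ``sample_id`` and ``sex`` may contain missing values.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = {"sample_id", "sex"} - set(meta.columns)
    if missing_cols:
        raise ValidationError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    bad_sex = ~meta["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValidationError(
            "sex must be 'female' or 'male'; offending sample ids: "
            f"{meta.loc[bad_sex, 'sample_id'].tolist()}"
        )
    if "ischemic_time" in meta.columns:
        neg = meta["ischemic_time"] < 0
        if neg.any():
            raise ValidationError(
                "negative ischemic_time for samples: "
                f"{meta.loc[neg, 'sample_id'].tolist()}"
            )
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in meta.columns]
    meta.loc[:, cols].to_csv(path, sep="\t", index=False)


def split_by_sex(
    expr: ExpressionMatrix, meta: pd.DataFrame
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition samples into (female, male) sub-matrices.

    Sample order within each part follows the input matrix. Every sample
    must carry a sex annotation; an empty part triggers a warning only.
    """
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id", drop=False)
    missing = [s for s in expr.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"samples lacking sex annotation: {missing}")
    sex = meta.loc[expr.sample_ids, "sex"]
    if sex.isna().any():
        raise ValidationError(
            f"samples lacking sex annotation: {sex.index[sex.isna()].tolist()}"
        )
    female_ids = [s for s in expr.sample_ids if sex[s] == "female"]
    male_ids = [s for s in expr.sample_ids if sex[s] == "male"]
    for label, ids in (("female", female_ids), ("male", male_ids)):
        if not ids:
            warnings.warn(f"no {label} samples in input", stacklevel=2)
    return (
        ExpressionMatrix(expr.data.loc[female_ids].copy()),
        ExpressionMatrix(expr.data.loc[male_ids].copy()),
    )
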