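"""Reading and writing the pipeline's file formats.

Expression matrices are TSV/CSV with a header row and an ID column
(genes x subjects by default); labels are two-column tables
(subject_id, label with values healthy/tumor). Score, goodness-of-fit,
PI, GSS, and CI tables are written as TSV. Graphs go through the Mapper
module's GraphML/JSON writers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "write_table",
    "read_scores",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path, orientation: str = "genes_by_subjects"
) -> pd.DataFrame:
    """Read an expression matrix, returned as genes x subjects.

    The first column is the ID column. Duplicate IDs and non-numeric
    cells are rejected with the offending location named.
    """
    if orientation not in ("genes_by_subjects", "subjects_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row ID {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column ID {dup!r} in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = df[col][coerced.isna()].index[0]
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row!r} of {path}"
            )
        df[col] = coerced
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError(f"missing or non-finite values in {path}")
    if orientation == "subjects_by_genes":
        df = df.T
    df.index.name = "gene_id"
    df.columns.name = "subject_id"
    return df


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_labels(path) -> pd.Series:
    """Read a subject-label table (subject_id, label)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} needs >= 2 columns")
    s = pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(),
        index=pd.Index(df.iloc[:, 0].astype(str), name="subject_id"),
        name="label",
    )
    bad = set(s.unique()) - {"healthy", "tumor"}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)} in {path}")
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"duplicate subject ID {dup!r} in {path}")
    return s


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, sep=_sep_for(path),
                                  index_label="subject_id")


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep=_sep_for(path), index=index_label is not None,
              index_label=index_label)


def read_scores(path) -> pd.DataFrame:
    """Read a subjects x genes score matrix written by the pipeline."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index.name = "subject_id"
    return df
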