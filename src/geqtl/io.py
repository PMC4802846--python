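"""Reading and writing labeled matrices as TSV.

Matrices are stored dense: one header row of sample identifiers, one
leading column of feature identifiers (SNPs or genes), tab-separated
numeric body.  Values are written with 10 significant digits so files
diff stably across runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "read_genotypes", "read_expression"]


def read_matrix(path) -> Tuple[np.ndarray, list, list]:
    """Read a labeled TSV matrix; returns ``(values, row_ids, sample_ids)``.

    Validation is strict: duplicate identifiers, missing values and
    non-numeric cells are all rejected with the offending row/column
    named.
    """
    path = Path(path)
    # keep_default_na=False so literal "NA" cells surface in error messages
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row identifier {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample identifier {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        cell = df.iloc[i, j]
        raise ValueError(
            f"{path}: non-numeric or missing value {cell!r} at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return numeric.values.astype(float), list(df.index), list(df.columns)


def write_matrix(path, values: np.ndarray, row_ids: Sequence, sample_ids: Sequence) -> None:
    """Write a labeled matrix as TSV with 10-significant-digit floats."""
    df = pd.DataFrame(np.asarray(values, float), index=list(row_ids), columns=list(sample_ids))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_genotypes(path):
    """Read a genotype TSV into a :class:`~geqtl.core.GenotypeMatrix`."""
    from .core import GenotypeMatrix

    values, row_ids, sample_ids = read_matrix(path)
    standardized = not np.isin(values, (0.0, 1.0, 2.0)).all()
    return GenotypeMatrix(values, row_ids, sample_ids, standardized=standardized)


def read_expression(path):
    """Read an expression TSV into an :class:`~geqtl.core.ExpressionMatrix`."""
    from .core import ExpressionMatrix

    values, row_ids, sample_ids = read_matrix(path)
    return ExpressionMatrix(values, row_ids, sample_ids, standardized=False)
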