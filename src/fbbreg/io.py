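"""Reading tabular count-regression datasets.

A dataset is delimited text with named columns: a response count, a trial
count, and covariates.  A :class:`DatasetSchema` names the columns and
optionally requests covariate standardization, factor expansion into
dummies (lexicographic levels, first level as baseline unless
configured), and extra polynomial columns such as a squared term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .regression import RegressionData

__all__ = [
    "DatasetSchema",
    "MissingColumnError",
    "CountError",
    "read_dataset",
    "build_design",
]


class MissingColumnError(KeyError):
    """A column named by the schema is absent from the file."""


class CountError(ValueError):
    """Counts are non-integer or violate 0 <= y <= n (the row is named)."""


@dataclass
class DatasetSchema:
    """Column mapping for :func:`read_dataset`.

    ``powers`` maps a covariate name to the highest power included, e.g.
    ``{"x": 2}`` adds ``x^2`` alongside ``x`` (a column-transform spec in
    place of a formula language).  ``baselines`` overrides the baseline
    level of a factor; by default the lexicographically first level is
    the baseline.
    """

    y: str
    n: str
    covariates: Sequence[str] = ()
    factors: Sequence[str] = ()
    standardize: Sequence[str] = ()
    powers: Dict[str, int] = field(default_factory=dict)
    baselines: Dict[str, str] = field(default_factory=dict)


def build_design(df: pd.DataFrame, schema: DatasetSchema) -> tuple[np.ndarray, list[str]]:
    """Intercept-led design matrix from a data frame per the schema."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for c in schema.covariates:
        if c not in df.columns:
            raise MissingColumnError(c)
        x = df[c].to_numpy(dtype=float)
        if c in schema.standardize:
            x = (x - x.mean()) / x.std(ddof=1)
        cols.append(x)
        names.append(c)
        for power in range(2, schema.powers.get(c, 1) + 1):
            cols.append(x**power)
            names.append(f"{c}^{power}")
    for f in schema.factors:
        if f not in df.columns:
            raise MissingColumnError(f)
        levels = sorted(df[f].astype(str).unique())
        baseline = schema.baselines.get(f, levels[0])
        if baseline not in levels:
            raise ValueError(f"baseline {baseline!r} is not a level of factor {f!r}")
        for lev in levels:
            if lev == baseline:
                continue
            cols.append((df[f].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names


def read_dataset(path, schema: DatasetSchema, sep: str = ",") -> RegressionData:
    """Read and validate a delimited dataset into :class:`RegressionData`.

    Distinct errors are raised for a missing column, a non-integer count,
    and a count exceeding its trial total (naming the offending row).
    """
    df = pd.read_csv(path, sep=sep)
    for col in (schema.y, schema.n):
        if col not in df.columns:
            raise MissingColumnError(col)
    for col in (schema.y, schema.n):
        vals = df[col].to_numpy()
        if not np.all(np.equal(np.mod(vals, 1), 0)):
            bad = int(np.flatnonzero(~np.equal(np.mod(vals, 1), 0))[0])
            raise CountError(f"column {col!r}, row {bad}: counts must be integers")
    y = df[schema.y].to_numpy(dtype=np.int64)
    n = df[schema.n].to_numpy(dtype=np.int64)
    if np.any(y < 0):
        raise CountError(f"row {int(np.flatnonzero(y < 0)[0])}: negative response count")
    if np.any(y > n):
        raise CountError(f"row {int(np.flatnonzero(y > n)[0])}: y exceeds the trial count n")
    X, names = build_design(df, schema)
    return RegressionData(y=y, n=n, X=X, column_names=names)
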