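"""Data model and delimited-text I/O for metabolomics feature tables.

A feature table holds non-negative intensities with samples in rows and
metabolites in columns.  Missingness is carried as an explicit boolean mask
next to the numeric values; masked entries are stored as NaN and must never
be interpreted as data.  Readers do not transpose or transform: the
samples-in-rows orientation is fixed, and intensities are kept on their
original (linear) scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import TableParseError, TableValidationError

#: Tokens recognised as missing values on input, besides optional 0/1 markers.
DEFAULT_NA_TOKENS = frozenset({"", "NA", "NaN", "N/A"})


@dataclass
class IntensityMatrix:
    """A samples x metabolites intensity table with an explicit missingness mask.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_samples, n_metabolites)``.  Entries under
        the mask are stored as NaN and carry no information.
    mask
        Boolean matrix of the same shape; ``True`` marks a missing cell.
    sample_ids, metabolite_ids
        Row and column labels, unique within each axis.
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    metabolite_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise TableValidationError("values must be a 2-D matrix")
        if self.values.shape != self.mask.shape:
            raise TableValidationError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i + 1}" for i in range(n)]
        if not self.metabolite_ids:
            self.metabolite_ids = [f"met_{j + 1}" for j in range(m)]
        if len(self.sample_ids) != n:
            raise TableValidationError("sample_ids length does not match row count")
        if len(self.metabolite_ids) != m:
            raise TableValidationError("metabolite_ids length does not match column count")
        for name, ids in (("sample", self.sample_ids), ("metabolite", self.metabolite_ids)):
            if len(set(ids)) != len(ids):
                raise TableValidationError(f"duplicate {name} ids")
        # masked cells carry no data
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.mask.copy(), list(self.sample_ids), list(self.metabolite_ids)
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Return the table as a DataFrame with NaN in masked cells."""
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.metabolite_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IntensityMatrix":
        """Build a matrix from a DataFrame, treating NaN as missing."""
        values = df.to_numpy(dtype=float)
        return cls(values, np.isnan(values), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: offending cells and missingness counts."""

    ok: bool
    n_missing: int
    missing_fraction_per_metabolite: np.ndarray
    offending_cells: list[tuple[str, str, str]]


@dataclass
class MissingnessSummary:
    """Per-metabolite, per-sample and total missing fractions."""

    per_metabolite: pd.Series
    per_sample: pd.Series
    total_fraction: float


def read_table(
    path,
    delimiter: str = ",",
    zero_as_missing: bool = False,
    one_as_missing: bool = False,
    na_tokens=DEFAULT_NA_TOKENS,
) -> IntensityMatrix:
    """Read a delimited intensity table (header row = metabolite ids, first
    column = sample ids).

    ``zero_as_missing`` / ``one_as_missing`` opt into the metabolomics
    convention of encoding missing values as literal 0 or 1; both default to
    off because 0 and 1 can be legitimate intensities.
    """
    # check the raw header first: pandas silently renames duplicate columns
    with open(path, encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=delimiter), None)
    if header and len(set(header[1:])) != len(header[1:]):
        raise TableValidationError(f"duplicate metabolite ids in {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise TableValidationError(f"empty table: {path}")
    sample_ids = [str(i) for i in df.index]
    metabolite_ids = [str(c) for c in df.columns]
    for name, ids in (("sample", sample_ids), ("metabolite", metabolite_ids)):
        if len(set(ids)) != len(ids):
            raise TableValidationError(f"duplicate {name} ids in {path}")

    na_tokens = frozenset(na_tokens)
    values = np.empty(df.shape, dtype=float)
    mask = np.zeros(df.shape, dtype=bool)
    raw = df.to_numpy(dtype=object)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            token = str(raw[i, j]).strip()
            if token in na_tokens:
                mask[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                x = float(token)
            except ValueError:
                raise TableParseError(
                    f"cell ({sample_ids[i]}, {metabolite_ids[j]}): "
                    f"cannot parse {token!r} as a number"
                ) from None
            if (zero_as_missing and x == 0.0) or (one_as_missing and x == 1.0):
                mask[i, j] = True
                values[i, j] = np.nan
            else:
                values[i, j] = x
    return IntensityMatrix(values, mask, sample_ids, metabolite_ids)


def write_table(
    matrix: IntensityMatrix, path, delimiter: str = ",", na_token: str = "NA"
):
    """Write a matrix as delimited text; masked cells become ``na_token``."""
    df = matrix.to_dataframe()
    df.to_csv(path, sep=delimiter, na_rep=na_token, index_label="sample_id")
    return path


def validate(matrix: IntensityMatrix) -> ValidationReport:
    """Check that all observed entries are finite and non-negative.

    Problems are reported, not raised: each offending cell is listed with its
    sample id, metabolite id and a reason (``"negative"`` or ``"non-finite"``).
    """
    offending: list[tuple[str, str, str]] = []
    vals, mask = matrix.values, matrix.mask
    obs = ~mask
    bad_neg = obs & (vals < 0)
    bad_fin = obs & ~np.isfinite(vals)
    for i, j in zip(*np.nonzero(bad_fin)):
        offending.append((matrix.sample_ids[i], matrix.metabolite_ids[j], "non-finite"))
    for i, j in zip(*np.nonzero(bad_neg & ~bad_fin)):
        offending.append((matrix.sample_ids[i], matrix.metabolite_ids[j], "negative"))
    frac = mask.mean(axis=0)
    return ValidationReport(
        ok=not offending,
        n_missing=int(mask.sum()),
        missing_fraction_per_metabolite=frac,
        offending_cells=offending,
    )


def missingness_summary(matrix: IntensityMatrix) -> MissingnessSummary:
    """Numeric missingness overview: fractions per metabolite, per sample, total."""
    mask = matrix.mask
    return MissingnessSummary(
        per_metabolite=pd.Series(mask.mean(axis=0), index=list(matrix.metabolite_ids)),
        per_sample=pd.Series(mask.mean(axis=1), index=list(matrix.sample_ids)),
        total_fraction=float(mask.mean()),
    )
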