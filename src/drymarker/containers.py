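"""Tabular containers shared across the pipeline.

Two lightweight wrappers around :class:`pandas.DataFrame` carry the data
through every stage:

* :class:`FeatureMatrix` — samples x features of real-valued measurements
  (log metabolite intensities, normalized transcript expression) plus a
  per-sample metadata table (cultivar, trial, treatment, batch, run order,
  trial type).
* :class:`ExpressionMatrix` — genes x samples of expression values in a
  declared unit (FPKM, CPM or raw qPCR Ct) plus per-sample metadata, used
  by the marker-candidate screening steps.

Yield tables and long-format qPCR tables are plain DataFrames with a
documented schema (see :data:`YIELD_COLUMNS`, :data:`QPCR_COLUMNS`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Required columns of a long-format yield table.
YIELD_COLUMNS = ("cultivar", "trial", "treatment", "replicate", "starch_yield")

#: Required columns of a long-format qPCR table.
QPCR_COLUMNS = ("sample", "gene", "ct", "is_reference")

#: Reserved metadata columns that precede feature columns in TSV files.
META_COLUMNS = ("cultivar", "trial", "treatment", "batch", "sequence", "trial_type")

TREATMENTS = ("control", "drought")
TRIAL_TYPES = ("experimental", "agronomic")


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def validate_yield_table(yields: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a long-format yield table.

    Every trial must contain both treatment arms and starch yields must be
    non-negative. Returns the table unchanged.
    """
    _require_columns(yields, YIELD_COLUMNS, "yield table")
    bad = set(yields["treatment"].unique()) - set(TREATMENTS)
    if bad:
        raise SchemaError(f"unknown treatment label(s): {sorted(bad)}")
    if (yields["starch_yield"] < 0).any():
        rows = yields.index[yields["starch_yield"] < 0][:5].tolist()
        raise SchemaError(f"negative starch_yield at rows {rows}")
    arms = yields.groupby("trial")["treatment"].nunique()
    one_armed = arms.index[arms < 2].tolist()
    if one_armed:
        raise SchemaError(f"trial(s) missing a treatment arm: {one_armed}")
    return yields


@dataclasses.dataclass
class FeatureMatrix:
    """Samples x features measurement table with per-sample metadata.

    Parameters
    ----------
    values
        Real-valued matrix, samples as rows (index = sample ids), features
        as columns. ``NaN`` marks missing cells.
    meta
        Per-sample metadata indexed like ``values``. The pipeline relies on
        the reserved columns in :data:`META_COLUMNS` where a stage needs
        them; extra columns pass through untouched.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise SchemaError("values and meta must share the same sample index")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate feature ids: {dups}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")

    # -- basic properties -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        """Fraction of missing cells in the matrix."""
        if self.values.size == 0:
            return 0.0
        return float(self.values.isna().to_numpy().mean())

    def is_complete(self) -> bool:
        return not self.values.isna().to_numpy().any()

    # -- manipulation -----------------------------------------------------
    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.meta.copy())

    def subset(self, samples=None, features=None) -> "FeatureMatrix":
        """Row/column subset preserving metadata alignment."""
        values = self.values
        meta = self.meta
        if samples is not None:
            values = values.loc[samples]
            meta = meta.loc[samples]
        if features is not None:
            values = values.loc[:, features]
        return FeatureMatrix(values, meta)

    def with_values(self, values: pd.DataFrame) -> "FeatureMatrix":
        """Same metadata, new value matrix (same sample index)."""
        return FeatureMatrix(values, self.meta.copy())

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write a single TSV with reserved metadata columns leading."""
        meta_cols = [c for c in self.meta.columns]
        out = pd.concat([self.meta, self.values], axis=1)
        out.index.name = "sample"
        out.to_csv(path, sep="\t", na_rep="NA")
        # remember which leading columns are metadata on read via META_COLUMNS
        del meta_cols

    @classmethod
    def from_tsv(cls, path, meta_columns=None) -> "FeatureMatrix":
        """Read a TSV written by :meth:`to_tsv`.

        ``meta_columns`` defaults to the intersection of the file's columns
        with :data:`META_COLUMNS` (plus any column named ``response``).
        """
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        if meta_columns is None:
            reserved = set(META_COLUMNS) | {"response", "tolerance_class"}
            meta_columns = [c for c in df.columns if c in reserved]
        meta = df[meta_columns]
        values = df.drop(columns=meta_columns).astype(float)
        return cls(values, meta)


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples expression table in one declared unit.

    ``unit`` is one of ``"FPKM"``, ``"CPM"`` or ``"Ct"``. ``sample_meta``
    is indexed by sample id and carries the columns the screening filters
    need: ``cultivar``, ``tolerance_group`` (tolerant / sensitive /
    unknown), ``treatment`` and ``cultivation`` (field / glasshouse).
    """

    values: pd.DataFrame
    unit: str
    sample_meta: pd.DataFrame

    VALID_UNITS = ("FPKM", "CPM", "Ct")

    def __post_init__(self) -> None:
        if self.unit not in self.VALID_UNITS:
            raise SchemaError(f"unit must be one of {self.VALID_UNITS}, got {self.unit!r}")
        if not self.values.columns.equals(self.sample_meta.index):
            # allow same set in different order; align
            if set(self.values.columns) != set(self.sample_meta.index):
                raise SchemaError("expression columns and sample_meta index disagree")
            self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path, meta_path=None) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")
        if meta_path is not None:
            self.sample_meta.to_csv(meta_path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, meta_path, unit: str) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, unit, meta)


def read_yield_table(path) -> pd.DataFrame:
    """Read and validate a long-format yield TSV/CSV (sniffs the delimiter)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return validate_yield_table(df)


def read_qpcr_table(path) -> pd.DataFrame:
    """Read a long-format qPCR table (sample, gene, ct, is_reference)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, QPCR_COLUMNS, "qPCR table")
    df["is_reference"] = df["is_reference"].astype(bool)
    return df
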