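"""Expression-table input/output and per-gene time-course slicing.

The on-disk dialect is tab-separated UTF-8 with ``#``-prefixed comment
lines.  An expression matrix has a ``gene_id`` first column and one column
per sample; sample metadata is a four-column table mapping every sample id
to its condition, replicate and hours elapsed in continuous light (LL).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("low_salt", "high_salt")

META_COLUMNS = ("sample_id", "condition", "replicate", "time_ll_h")


class ExpressionIOError(ValueError):
    """Raised for malformed expression matrices or metadata."""


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample.

    Parameters
    ----------
    sample_id : str
        Column name in the expression matrix.
    condition : str
        One of ``low_salt`` (0.5 M NaCl) or ``high_salt`` (2.5 M NaCl).
    replicate : int
        Biological replicate index (1-based; the study design uses 1 and 2,
        arbitrary counts are accepted).
    time_ll_h : float
        Hours elapsed in continuous light at harvest.
    """

    sample_id: str
    condition: str
    replicate: int
    time_ll_h: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: condition {self.condition!r} "
                f"is not one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: replicate must be a positive "
                f"integer, got {self.replicate}"
            )
        if self.time_ll_h < 0:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: time_ll_h must be non-negative, "
                f"got {self.time_ll_h}"
            )


@dataclasses.dataclass
class ExpressionMatrix:
    """A gene x sample table of TPM values with per-sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample id, in the same order as ``samples``.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ExpressionIOError(
                "matrix columns do not match sample metadata order"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ExpressionIOError(f"duplicate gene id {dup!r}")
        if self.values.index.isna().any():
            raise ExpressionIOError("missing gene id in matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionIOError("non-numeric values in expression matrix")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ExpressionIOError(
                f"non-numeric or missing value at gene "
                f"{self.values.index[g]!r}, sample {ids[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ExpressionIOError(
                f"negative value {arr[g, s]} at gene "
                f"{self.values.index[g]!r}, sample {ids[s]!r}"
            )
        triples = [(s.condition, s.replicate, s.time_ll_h) for s in self.samples]
        if len(set(triples)) != len(triples):
            seen: set = set()
            for t in triples:
                if t in seen:
                    raise ExpressionIOError(
                        f"duplicate (condition, replicate, time) triple {t}"
                    )
                seen.add(t)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def meta(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame in matrix column order."""
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples], columns=META_COLUMNS
        )

    def samples_for(
        self, condition: str, replicate: int | None = None
    ) -> list[SampleMeta]:
        """Samples of one condition (optionally one replicate), unordered."""
        out = [s for s in self.samples if s.condition == condition]
        if replicate is not None:
            out = [s for s in out if s.replicate == replicate]
        return out

    def replicates_for(self, condition: str) -> list[int]:
        return sorted({s.replicate for s in self.samples_for(condition)})


@dataclasses.dataclass(frozen=True)
class TimeCourse:
    """One gene's TPM values for one condition/replicate, ordered in time."""

    gene_id: str
    condition: str
    replicate: int
    times_h: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "values", values)
        if times.size < 2:
            raise ExpressionIOError("time course needs at least 2 points")
        if times.size != values.size:
            raise ExpressionIOError("times and values differ in length")
        if not np.all(np.diff(times) > 0):
            raise ExpressionIOError("times must be strictly increasing")
        if np.any(values < 0):
            raise ExpressionIOError(
                f"gene {self.gene_id!r}: negative TPM value in time course"
            )


def read_expression_table(matrix_path, meta_path) -> ExpressionMatrix:
    """Read and validate a TSV expression matrix plus sample metadata.

    The matrix file has ``gene_id`` as its first column and one column per
    sample; every matrix sample must be described in the metadata file
    (columns ``sample_id``, ``condition``, ``replicate``, ``time_ll_h``).
    Sample order follows the matrix header.
    """
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"sample_id": str})
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ExpressionIOError(
            f"metadata file {meta_path} lacks columns {missing_cols}"
        )
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ExpressionIOError(f"duplicate sample id {dup!r} in metadata")
    meta = meta.set_index("sample_id")

    raw = pd.read_csv(matrix_path, sep="\t", comment="#", dtype={0: str})
    if raw.shape[1] < 2:
        raise ExpressionIOError(f"matrix file {matrix_path} has no sample columns")
    gene_col = raw.columns[0]
    raw = raw.set_index(gene_col)
    raw.index.name = "gene_id"

    samples = []
    for sid in raw.columns:
        if sid not in meta.index:
            raise ExpressionIOError(
                f"sample {sid!r} in matrix is missing from metadata"
            )
        row = meta.loc[sid]
        samples.append(
            SampleMeta(
                sample_id=sid,
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                time_ll_h=float(row["time_ll_h"]),
            )
        )

    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ExpressionIOError(
            f"non-numeric value {raw.iloc[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    return ExpressionMatrix(values=values.astype(float), samples=samples)


def write_expression_table(matrix: ExpressionMatrix, matrix_path, meta_path) -> None:
    """Write a matrix and its metadata in the dialect ``read_expression_table`` reads."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.9g")
    matrix.meta.to_csv(meta_path, sep="\t", index=False, float_format="%.9g")


def extract_time_course(
    matrix: ExpressionMatrix, gene_id: str, condition: str, replicate: int
) -> TimeCourse:
    """Slice one gene's time course, ordered by ascending LL time."""
    if gene_id not in matrix.values.index:
        raise ExpressionIOError(f"unknown gene {gene_id!r}")
    picked = matrix.samples_for(condition, replicate)
    if not picked:
        raise ExpressionIOError(
            f"no samples for condition {condition!r}, replicate {replicate}"
        )
    times = np.array([s.time_ll_h for s in picked])
    if len(set(times.tolist())) != len(picked):
        raise ExpressionIOError(
            f"duplicate sample times for condition {condition!r}, "
            f"replicate {replicate}"
        )
    order = np.argsort(times)
    sids = [picked[i].sample_id for i in order]
    return TimeCourse(
        gene_id=gene_id,
        condition=condition,
        replicate=replicate,
        times_h=times[order],
        values=matrix.values.loc[gene_id, sids].to_numpy(dtype=float),
    )


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV with >= 6 significant digits on floats."""
    if records.columns.empty:
        raise ExpressionIOError("refusing to write a table with no columns")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
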