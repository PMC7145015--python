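"""Containers and tab-delimited I/O for expression matrices and annotations.

Orientation is genes-in-rows, samples-in-columns everywhere (an m x n
matrix for m probes and n samples). Expression values are assumed to be
already log2-transformed and normalized; nothing in this package
re-normalizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_REQUIRED_COLUMNS = ("sample_id", "sample_type", "collection")


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression intensities.

    Parameters
    ----------
    probe_ids
        Ordered, unique probe (gene) identifiers; length m.
    sample_ids
        Ordered, unique sample identifiers; length n.
    values
        m x n array of finite floats, log2 scale.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        m, n = self.values.shape
        if len(self.probe_ids) != m or len(self.sample_ids) != n:
            raise ValueError(
                f"shape mismatch: values is {m}x{n} but there are "
                f"{len(self.probe_ids)} probes and {len(self.sample_ids)} samples"
            )
        if m < 2:
            raise ValueError(f"need at least 2 probes, got {m}")
        if n < 1:
            raise ValueError("need at least 1 sample")
        dup_p = _find_duplicates(self.probe_ids)
        if dup_p:
            raise ValueError(f"duplicate probe ids: {dup_p}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite expression value at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=list(self.sample_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            probe_ids=df.index.to_numpy(dtype=object),
            sample_ids=df.columns.to_numpy(dtype=object),
            values=df.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            self.probe_ids.copy(),
            np.asarray(list(sample_ids), dtype=object),
            self.values[:, cols].copy(),
        )

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        rows = [idx[p] for p in probe_ids]
        return ExpressionMatrix(
            np.asarray(list(probe_ids), dtype=object),
            self.sample_ids.copy(),
            self.values[rows, :].copy(),
        )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First column holds probe ids, the header row holds sample ids. Raises
    on duplicate identifiers, missing values and non-numeric cells, naming
    the offending location.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    probe_ids = df.index.to_numpy(dtype=object)
    # pandas mangles duplicate headers to "x", "x.1"; detect via the raw header
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_s = _find_duplicates(header)
    if dup_s:
        raise ValueError(f"duplicate sample ids in header of {path}: {dup_s}")
    dup_p = _find_duplicates(probe_ids)
    if dup_p:
        raise ValueError(f"duplicate probe ids in {path}: {dup_p}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (df[col].str.strip() == "")
        if bad.any():
            probe = df.index[bad.to_numpy()][0]
            raw = df.loc[probe, col]
            raise ValueError(
                f"non-numeric or missing value {raw!r} at probe {probe!r}, "
                f"sample {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(probe_ids, np.asarray(header, dtype=object), values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a tab-delimited matrix (probe_id first column, '.' decimal)."""
    df = expr.to_frame()
    df.to_csv(Path(path), sep="\t", float_format="%.6g")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table.

    Requires columns sample_id, sample_type and collection; an optional
    batch column defaults to the collection label when absent (collections
    are the batch unit throughout).
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} missing required columns: {missing}")
    return validate_annotation(df)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an annotation table (adds batch if absent)."""
    ann = ann.copy()
    missing = [c for c in ANNOTATION_REQUIRED_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing required columns: {missing}")
    dup = _find_duplicates(ann["sample_id"].tolist())
    if dup:
        raise ValueError(f"duplicate sample ids in annotation: {dup}")
    for col in ("sample_type", "collection"):
        empty = ann[col].astype(str).str.strip() == ""
        if empty.any():
            bad = ann.loc[empty, "sample_id"].tolist()
            raise ValueError(f"empty {col} label for samples: {bad}")
    if "batch" not in ann.columns:
        logger.info("no batch column in annotation; defaulting batch = collection")
        ann["batch"] = ann["collection"]
    return ann.reset_index(drop=True)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(Path(path), sep="\t", index=False)


def align(
    expr: ExpressionMatrix, ann: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Restrict and reorder an annotation table to the matrix's samples.

    Annotation rows come back in the matrix's column order; annotated
    samples absent from the matrix are dropped (count logged). A matrix
    sample with no annotation is an error.
    """
    ann = validate_annotation(ann)
    by_id = ann.set_index("sample_id", drop=False)
    missing = [s for s in expr.sample_ids if s not in by_id.index]
    if missing:
        raise ValueError(f"samples in matrix but not annotation: {missing}")
    n_dropped = len(ann) - expr.n_samples
    if n_dropped > 0:
        logger.info("align: dropped %d annotated samples not in matrix", n_dropped)
    out = by_id.loc[list(expr.sample_ids)].reset_index(drop=True)
    return expr, out


def intersect_probes(
    a: ExpressionMatrix, b: Sequence[str]
) -> tuple[ExpressionMatrix, float]:
    """Restrict a matrix to the probes of a target list, in the list's order.

    Returns the restricted matrix and the coverage fraction
    |intersection| / |target list|. Empty intersection is an error.
    """
    have = set(a.probe_ids)
    common = [p for p in b if p in have]
    if not common:
        raise ValueError("no probes in common with the target probe list")
    coverage = len(common) / len(b)
    return a.subset_probes(common), coverage
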