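"""Reading, validation and writing of count matrices, annotations and results.

The count matrix convention is miRNAs in rows, samples in columns.  Tabular
formats (TSV/CSV) carry miRNA identifiers in the first column and sample
identifiers in the header row.  The MatrixMarket triplet format is accompanied
by two sidecar text files holding the row and column identifiers, one per
line: for a matrix at ``<base>.mtx`` they are ``<base>_rows.txt`` and
``<base>_cols.txt``.

Raw integer read counts are required everywhere: a table containing
fractional values (e.g. an already-normalized CPM matrix) is rejected,
because the downstream negative-binomial testing assumes counts.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    AnnotationParseError,
    DuplicateIdError,
    EmptyInputError,
    MalformedCountError,
    MissingAnnotationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleAnnotation",
    "Dataset",
    "read_counts",
    "write_counts",
    "read_annotations",
    "write_annotations",
    "bind_dataset",
    "write_results",
]


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer miRNA x sample read-count table.

    Parameters
    ----------
    counts
        DataFrame with miRNA ids as the index and sample ids as columns;
        values are validated to be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise EmptyInputError(
                f"count matrix needs >=1 miRNA and >=2 samples, got {df.shape}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate miRNA ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise MalformedCountError("count matrix contains non-numeric cells")
        if not np.isfinite(values).all():
            raise MalformedCountError("count matrix contains NaN/inf cells")
        if (values < 0).any():
            raise MalformedCountError("count matrix contains negative cells")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.array_equal(values, np.round(values)):
                raise MalformedCountError(
                    "count matrix contains non-integer cells; raw read "
                    "counts are required (normalized matrices are rejected)"
                )
            object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def mirna_ids(self) -> list[str]:
        return [str(i) for i in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    @property
    def values(self) -> np.ndarray:
        """Counts as an int64 array, shape (n_mirnas, n_samples)."""
        return self.counts.to_numpy(dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_mirnas(self, mirna_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(mirna_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)])


@dataclass(frozen=True)
class SampleAnnotation:
    """Clinical labels of one sample: node status and optional Gleason score."""

    sample_id: str
    node_status: str  # "N0" or "N1"
    gleason: int | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.node_status not in ("N0", "N1"):
            raise AnnotationParseError(
                f"node_status must be N0 or N1, got {self.node_status!r}"
            )
        if self.gleason is not None and not 6 <= self.gleason <= 10:
            raise AnnotationParseError(
                f"Gleason score must lie in [6, 10], got {self.gleason}"
            )


@dataclass(frozen=True)
class Dataset:
    """A count matrix bound to per-sample annotations in matching order."""

    counts: CountMatrix
    annotations: tuple[SampleAnnotation, ...]

    def __post_init__(self) -> None:
        ann_ids = [a.sample_id for a in self.annotations]
        if ann_ids != self.counts.sample_ids:
            raise MissingAnnotationError(
                "annotations are not aligned to count-matrix samples"
            )

    @property
    def node_status(self) -> np.ndarray:
        """Node labels aligned to samples, as an array of 'N0'/'N1' strings."""
        return np.array([a.node_status for a in self.annotations])

    @property
    def gleason(self) -> np.ndarray:
        """Gleason scores aligned to samples (NaN where absent)."""
        return np.array(
            [np.nan if a.gleason is None else float(a.gleason) for a in self.annotations]
        )


def _sep_for(path: Path, format: str) -> str:
    if format == "csv":
        return ","
    if format == "tsv":
        return "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def _triplet_sidecars(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix == ".mtx" else path
    return (
        base.parent / (base.name + "_rows.txt"),
        base.parent / (base.name + "_cols.txt"),
    )


def read_counts(path: str | Path, format: str = "auto") -> CountMatrix:
    """Read a miRNA x sample count matrix.

    ``format`` is one of ``tsv``, ``csv``, ``mtx_triplet`` or ``auto``
    (inferred from the file suffix).  Cells must be non-negative integers;
    a fractional cell raises :class:`MalformedCountError` rather than being
    silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto" and path.suffix == ".mtx":
        format = "mtx_triplet"

    if format == "mtx_triplet":
        rows_path, cols_path = _triplet_sidecars(path)
        for p in (rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"missing triplet sidecar id file: {p}")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mirna_ids = rows_path.read_text().split()
        sample_ids = cols_path.read_text().split()
        if mat.shape != (len(mirna_ids), len(sample_ids)):
            raise MalformedCountError(
                f"triplet matrix shape {mat.shape} does not match id files "
                f"({len(mirna_ids)} rows, {len(sample_ids)} cols)"
            )
        df = pd.DataFrame(mat, index=mirna_ids, columns=sample_ids)
        return CountMatrix(df)

    sep = _sep_for(path, format)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None or len(header) < 2:
        raise EmptyInputError(f"no usable header in {path}")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise DuplicateIdError(f"duplicate sample ids in header of {path}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty count table: {path}") from exc
    if df.shape[0] == 0:
        raise EmptyInputError(f"count table has no data rows: {path}")
    df.columns = sample_ids
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise MalformedCountError(
                f"non-numeric entries in sample column {col!r} of {path}"
            )
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path, format: str = "auto") -> None:
    """Write a count matrix as TSV/CSV or MatrixMarket triplet + id sidecars."""
    path = Path(path)
    if format == "auto" and path.suffix == ".mtx":
        format = "mtx_triplet"
    if format == "mtx_triplet":
        rows_path, cols_path = _triplet_sidecars(path)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.values))
        rows_path.write_text("\n".join(cm.mirna_ids) + "\n")
        cols_path.write_text("\n".join(cm.sample_ids) + "\n")
        return
    sep = _sep_for(path, format)
    cm.counts.to_csv(path, sep=sep, index_label="mirna_id")


def _parse_annotation_row(row: Mapping[str, object], extra_cols: Sequence[str]) -> SampleAnnotation:
    sid = str(row["sample_id"]).strip()
    raw_status = str(row["node_status"]).strip().upper()
    if raw_status not in ("N0", "N1"):
        raise AnnotationParseError(
            f"sample {sid!r}: unknown node_status token {row['node_status']!r}"
        )
    gleason: int | None = None
    if "gleason" in row and row["gleason"] is not None:
        g = row["gleason"]
        if not (isinstance(g, float) and np.isnan(g)) and str(g).strip() != "":
            gf = float(g)
            if gf != int(gf):
                raise AnnotationParseError(
                    f"sample {sid!r}: Gleason score must be an integer, got {g!r}"
                )
            gleason = int(gf)
    covariates = {
        c: row[c]
        for c in extra_cols
        if not (isinstance(row[c], float) and np.isnan(row[c]))
    }
    return SampleAnnotation(sid, raw_status, gleason, covariates)


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation table (TSV/CSV).

    Requires columns ``sample_id`` and ``node_status``; ``gleason`` and any
    further columns (age, PSA, ...) are optional.  Node status is parsed
    case-insensitively from {N0, N1}.
    """
    path = Path(path)
    sep = _sep_for(path, "auto")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty annotation table: {path}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    for required in ("sample_id", "node_status"):
        if required not in df.columns:
            raise AnnotationParseError(f"missing required column {required!r} in {path}")
    if df["sample_id"].duplicated().any():
        raise DuplicateIdError(f"duplicate sample ids in {path}")
    extra = [c for c in df.columns if c not in ("sample_id", "node_status", "gleason")]
    try:
        g_int = df["gleason"].astype(float) if "gleason" in df.columns else None
    except (TypeError, ValueError) as exc:
        raise AnnotationParseError(f"non-numeric Gleason score in {path}") from exc
    records = []
    for _, row in df.iterrows():
        records.append(_parse_annotation_row(row.to_dict(), extra))
    return records


def write_annotations(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    """Write annotations as a TSV with sample_id, node_status, gleason columns."""
    rows = [
        {
            "sample_id": a.sample_id,
            "node_status": a.node_status,
            "gleason": "" if a.gleason is None else a.gleason,
            **dict(a.covariates),
        }
        for a in annotations
    ]
    if not rows:
        raise EmptyInputError("no annotations to write")
    pd.DataFrame(rows).to_csv(Path(path), sep=_sep_for(Path(path), "auto"), index=False)


def bind_dataset(counts: CountMatrix, annotations: Sequence[SampleAnnotation]) -> Dataset:
    """Align annotations to the count-matrix sample order and bind them.

    The count matrix defines the analysis set: every count column must have
    exactly one annotation (else :class:`MissingAnnotationError`), while
    annotated samples absent from the matrix are dropped with a warning.
    """
    by_id: dict[str, SampleAnnotation] = {}
    for a in annotations:
        if a.sample_id in by_id:
            raise DuplicateIdError(f"duplicate annotation for sample {a.sample_id!r}")
        by_id[a.sample_id] = a
    missing = [s for s in counts.sample_ids if s not in by_id]
    if missing:
        raise MissingAnnotationError(f"samples without annotation: {missing}")
    extra = [s for s in by_id if s not in set(counts.sample_ids)]
    if extra:
        logger.warning(
            "dropping %d annotation rows without count columns: %s", len(extra), extra
        )
    ordered = tuple(by_id[s] for s in counts.sample_ids)
    return Dataset(counts, ordered)


def write_results(records, path: str | Path) -> None:
    """Serialize a list of result dataclasses (e.g. DERecord) to TSV.

    Column order follows the dataclass field order; floats carry six
    significant digits so a write/read round trip preserves values at that
    precision.
    """
    if records is None:
        raise EmptyInputError("no records to write")
    if dataclasses.is_dataclass(records) and not isinstance(records, type):
        records = [records]
    records = list(records)
    if not records:
        raise EmptyInputError("no records to write")
    if not dataclasses.is_dataclass(records[0]):
        raise TypeError("write_results expects dataclass records")
    columns = [f.name for f in dataclasses.fields(records[0])]
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")
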