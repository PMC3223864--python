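"""Reading and writing expression matrices and fitted state lines.

Expression matrices are delimited text, genes in rows and samples in
columns, with a header row of sample IDs and the first column holding gene
(or probe) identifiers.  GEO Series Matrix flat files are supported through
:func:`read_geo_series_matrix`, which extracts the table block between the
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.

Gene matching across datasets is exact string match on identifiers after
stripping surrounding quotes and whitespace; no probe-to-gene mapping is
attempted.  Cross-platform use requires the caller to pre-map IDs.

No normalization is applied at read time: the projection arithmetic is
faithful to whatever units the caller supplies, and any transform is an
explicit opt-in (see :mod:`devstate.normalize`).
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    GeneMismatchError,
    OverlapError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

STATE_LINE_SCHEMA_VERSION = 1

GEO_TABLE_BEGIN = "!series_matrix_table_begin"
GEO_TABLE_END = "!series_matrix_table_end"


def _clean_id(raw: str) -> str:
    """Strip surrounding whitespace and matching quotes from an identifier."""
    s = str(raw).strip()
    if len(s) >= 2 and s[0] == s[-1] and s[0] in "\"'":
        s = s[1:-1].strip()
    return s


@dataclass
class ExpressionTable:
    """A genes x samples real-valued expression matrix.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers, in row order.
    sample_ids : list of str
        Unique column identifiers, in column order.
    values : ndarray, shape (n_genes, n_samples)
        Finite expression values, units as supplied.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [_clean_id(g) for g in self.gene_ids]
        self.sample_ids = [_clean_id(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.gene_ids):
            raise ValidationError(
                f"{len(self.gene_ids)} gene_ids but {n} value rows"
            )
        if m != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample_ids but {m} value columns"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValidationError(f"duplicate gene IDs: {sorted(dupes)}")
        if _duplicates(self.sample_ids):
            raise ValidationError(
                f"duplicate sample IDs: {sorted(_duplicates(self.sample_ids))}"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionTable":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionTable":
        """Restrict to `gene_ids`, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise GeneMismatchError(
                f"{len(missing)} requested genes absent from table "
                f"(first few: {missing[:5]})"
            )
        rows = [index[g] for g in gene_ids]
        return ExpressionTable(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionTable(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
        )


def _float_or_none(cell: str):
    # python float() is round-trip exact for %.17g output; pandas'
    # fast parser is not
    try:
        return float(cell)
    except ValueError:
        return None


def _parse_numeric_frame(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    numeric = frame.map(_float_or_none)
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = frame.iat[i, j]
        what = "missing cell" if cell == "" else f"non-numeric cell {cell!r}"
        raise ParseError(
            f"{path}: {what} at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    return numeric.astype(float)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression_table(
    path: str | Path,
    delimiter: str = "\t",
    transpose: bool = False,
) -> ExpressionTable:
    """Read a delimited genes x samples matrix.

    The first row is the sample header, the first column gene IDs.  With
    ``transpose=True`` the file is interpreted as samples x genes (header row
    of gene IDs, first column sample IDs) and transposed after reading, so
    the returned table is always genes x samples.

    Raises
    ------
    ParseError
        On ragged rows, non-numeric or missing cells (with the offending
        gene/sample named), or duplicate identifiers.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            header=0,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed rows ({exc})") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ParseError(f"{path}: empty table")
    if transpose:
        frame = frame.T
    frame.index = [_clean_id(g) for g in frame.index]
    frame.columns = [_clean_id(s) for s in frame.columns]
    dupes = _duplicates(list(frame.index))
    if dupes:
        raise ParseError(f"{path}: duplicate gene IDs: {sorted(dupes)}")
    return ExpressionTable.from_frame(_parse_numeric_frame(frame, path))


def write_expression_table(
    table: ExpressionTable, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a table so that read(write(x)) reproduces values exactly."""
    frame = table.to_frame()
    frame.index.name = "gene_id"
    # %.17g round-trips any IEEE double exactly
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def read_geo_series_matrix(path: str | Path) -> ExpressionTable:
    """Read the expression block of a GEO Series Matrix flat file.

    Metadata lines (prefixed ``!``) outside the table block are ignored.
    GSM accessions become sample IDs, probe IDs (quotes stripped) become
    gene IDs.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        begin = next(
            i for i, ln in enumerate(lines) if ln.startswith(GEO_TABLE_BEGIN)
        )
    except StopIteration:
        raise ParseError(f"{path}: missing {GEO_TABLE_BEGIN!r} marker") from None
    try:
        end = next(
            i
            for i, ln in enumerate(lines[begin + 1 :], start=begin + 1)
            if ln.startswith(GEO_TABLE_END)
        )
    except StopIteration:
        raise ParseError(f"{path}: missing {GEO_TABLE_END!r} marker") from None
    block = [ln for ln in lines[begin + 1 : end] if ln.strip()]
    if len(block) < 2:
        raise ParseError(f"{path}: empty series matrix table")
    frame = pd.read_csv(
        _io.StringIO("\n".join(block)),
        sep="\t",
        index_col=0,
        header=0,
        dtype=str,
        keep_default_na=False,
    )
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: series matrix table has no sample columns")
    frame.index = [_clean_id(g) for g in frame.index]
    frame.columns = [_clean_id(s) for s in frame.columns]
    return ExpressionTable.from_frame(_parse_numeric_frame(frame, path))


def harmonize_genes(
    a: ExpressionTable,
    b: ExpressionTable,
    min_overlap_fraction: float = 0.5,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Restrict two tables to their shared genes, identically ordered.

    Rows are sorted lexicographically by gene ID in both outputs so a line
    fitted on one dataset can score another.  The overlap fraction is
    measured relative to the smaller table; below ``min_overlap_fraction``
    an :class:`OverlapError` is raised (default 0.5 — guards against an
    accidental platform mismatch while tolerating probe-set attrition).

    Idempotent: harmonizing an already-harmonized pair is the identity.
    """
    if not (0 < min_overlap_fraction <= 1):
        raise ValidationError("min_overlap_fraction must be in (0, 1]")
    if a.n_genes == 0 or b.n_genes == 0:
        raise ValidationError("cannot harmonize an empty table")
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise OverlapError("no genes shared between the two tables")
    fraction = len(common) / min(a.n_genes, b.n_genes)
    logger.info(
        "harmonize_genes: %d shared genes, overlap fraction %.3f",
        len(common),
        fraction,
    )
    if fraction < min_overlap_fraction:
        raise OverlapError(
            f"gene overlap fraction {fraction:.3g} is below the required "
            f"{min_overlap_fraction:.3g}"
        )
    return a.subset_genes(common), b.subset_genes(common)


def write_state_line(line, path: str | Path) -> None:
    """Serialize a fitted state line as a single JSON document."""
    doc = {
        "schema_version": STATE_LINE_SCHEMA_VERSION,
        "gene_ids": list(line.gene_ids),
        "vector": [float(x) for x in line.direction],
        "coefficients": [float(x) for x in line.coefficients],
        "cos_theta": float(line.cos_theta),
        "time_labels": list(line.time_labels),
        "training_projections": [float(x) for x in line.training_projections],
        "metadata": dict(line.metadata),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_state_line(path: str | Path):
    """Read a state line written by :func:`write_state_line`.

    Raises :class:`SchemaError` on a version mismatch or a vector whose
    length disagrees with the gene count — never a silent misparse.
    """
    from .model import StateLine  # local import to avoid a cycle

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    version = doc.get("schema_version")
    if version != STATE_LINE_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema_version {version!r} not supported "
            f"(this build reads version {STATE_LINE_SCHEMA_VERSION})"
        )
    required = {
        "gene_ids",
        "vector",
        "coefficients",
        "cos_theta",
        "time_labels",
        "training_projections",
    }
    missing = required - doc.keys()
    if missing:
        raise SchemaError(f"{path}: missing fields {sorted(missing)}")
    if len(doc["vector"]) != len(doc["gene_ids"]):
        raise SchemaError(
            f"{path}: vector has {len(doc['vector'])} entries for "
            f"{len(doc['gene_ids'])} genes"
        )
    return StateLine(
        gene_ids=[str(g) for g in doc["gene_ids"]],
        direction=np.asarray(doc["vector"], dtype=float),
        coefficients=np.asarray(doc["coefficients"], dtype=float),
        cos_theta=float(doc["cos_theta"]),
        time_labels=[str(t) for t in doc["time_labels"]],
        training_projections=np.asarray(
            doc["training_projections"], dtype=float
        ),
        metadata=dict(doc.get("metadata", {})),
    )
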