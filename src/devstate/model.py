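"""The time-ordered linear model.

An ordered expression time course traces a piecewise-linear trajectory in
gene ("microarray") space: time-point centroids X_1 .. X_t joined head to
tail by segment vectors v_i = X_{i+1} - X_i.  The *cell developmental state
line* is the unique unit vector e in the span of the segments that makes an
equal angle theta with every segment while maximizing the common cosine.
Projecting samples onto e yields a scalar developmental-state coordinate
that (a) preserves the temporal order of the training centroids and (b)
preserves the ratio of consecutive inter-centroid distances, because each
projection gap equals ||v_i|| * cos(theta).

Closed form.  With u_i = v_i/||v_i|| as columns of U and the Gram matrix
G = U'U, solve G c = 1 (the vector of ones).  Then

    e = Uc / ||Uc||,     cos(theta) = 1 / sqrt(1' G^{-1} 1).

Equal angles hold because (G c)_i = 1 for every i, so u_i . e is the same
constant; maximality over the segment span follows from the Cauchy-Schwarz
argument on the constraint set.  For t = 2 the line is the single
normalized segment and cos(theta) = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateSegmentError,
    GeneMismatchError,
    LinearDependenceError,
    ValidationError,
)
from .io import ExpressionTable

logger = logging.getLogger(__name__)

#: |u_i . u_j - 1| below this counts as "same direction" (collinear reduction)
_COLLINEAR_TOL = 1e-12
#: relative eigenvalue threshold for declaring the Gram matrix singular
_RANK_TOL = 1e-10


@dataclass
class TimeCourse:
    """Ordered per-time-point centroid expression profiles.

    ``centroids`` is genes x time points; column j is the centroid of all
    replicates assigned to ``time_labels[j]``.  Column order *is* the
    declared temporal order.
    """

    gene_ids: list[str]
    time_labels: list[str]
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2:
            raise ValidationError("centroids must be a 2-D matrix")
        n, t = self.centroids.shape
        if t < 2:
            raise ValidationError("a time course needs at least 2 time points")
        if n != len(self.gene_ids):
            raise ValidationError(
                f"{len(self.gene_ids)} gene_ids but {n} centroid rows"
            )
        if t != len(self.time_labels):
            raise ValidationError(
                f"{len(self.time_labels)} time_labels but {t} centroid columns"
            )
        if len(set(self.time_labels)) != t:
            raise ValidationError("time_labels must be unique")
        if not np.all(np.isfinite(self.centroids)):
            raise ValidationError("centroids contain non-finite values")

    @property
    def n_genes(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_times(self) -> int:
        return self.centroids.shape[1]

    def drop_times(self, labels: Sequence[str]) -> "TimeCourse":
        """Return a reduced time course without the given time points."""
        drop = set(labels)
        unknown = drop - set(self.time_labels)
        if unknown:
            raise ValidationError(f"unknown time labels: {sorted(unknown)}")
        keep = [i for i, lb in enumerate(self.time_labels) if lb not in drop]
        if len(keep) < 2:
            raise ValidationError(
                "removal would leave fewer than 2 time points"
            )
        return TimeCourse(
            gene_ids=list(self.gene_ids),
            time_labels=[self.time_labels[i] for i in keep],
            centroids=self.centroids[:, keep],
        )


@dataclass
class SegmentSet:
    """Consecutive centroid differences v_i = X_{i+1} - X_i and their norms."""

    vectors: np.ndarray  # genes x (t-1)
    lengths: np.ndarray  # (t-1,)
    pair_labels: list[str]  # "11d->12d", ...
    time_labels: list[str]  # the t surviving time labels, in order

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths <= 0):
            raise DegenerateSegmentError("segment lengths must all be positive")


@dataclass
class StateLine:
    """A fitted cell developmental state line.

    ``direction`` is the unit co-bisector e; ``coefficients`` a_i express it
    on the raw segment vectors (e = sum_i a_i v_i); ``cos_theta`` is the
    common cosine shared by every segment; ``training_projections`` are the
    raw dot products of the training centroids with e, strictly increasing
    in time.
    """

    gene_ids: list[str]
    direction: np.ndarray
    coefficients: np.ndarray
    cos_theta: float
    time_labels: list[str]
    training_projections: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.training_projections = np.asarray(
            self.training_projections, dtype=float
        )
        if self.direction.shape != (len(self.gene_ids),):
            raise ValidationError("direction length must equal gene count")
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-10:
            raise ValidationError(f"direction norm {norm!r} is not 1")
        if not (0 < self.cos_theta <= 1 + 1e-12):
            raise ValidationError(f"cos_theta {self.cos_theta!r} not in (0, 1]")
        if len(self.training_projections) != len(self.time_labels):
            raise ValidationError(
                "one training projection per time label required"
            )
        if np.any(np.diff(self.training_projections) <= 0):
            raise ValidationError(
                "training projections must be strictly increasing"
            )

    @property
    def origin(self) -> float:
        """Raw projection of the first training centroid (display origin)."""
        return float(self.training_projections[0])


@dataclass
class ProjectionResult:
    """Scalar positions of samples on a state line.

    ``positions_raw`` are plain dot products with the line direction;
    ``positions_centered`` subtract the raw position of the line's first
    training centroid, which therefore sits exactly at 0.
    """

    sample_ids: list[str]
    positions_raw: np.ndarray
    positions_centered: np.ndarray
    line_metadata: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "position_raw": self.positions_raw,
                "position_centered": self.positions_centered,
            }
        )


@dataclass
class DifferentiationCoordinates:
    """2-D embedding: centered projections onto two state lines."""

    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, 2)
    axis_labels: tuple[str, str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.coords, index=self.sample_ids, columns=list(self.axis_labels)
        )


def collapse_replicates(
    table: ExpressionTable,
    assignment: Mapping[str, str],
    time_order: Sequence[str],
    method: str = "mean",
) -> TimeCourse:
    """Average replicate columns into per-time-point centroids.

    ``assignment`` maps sample IDs to time labels; ``time_order`` fixes the
    temporal order of the labels.  The canonical centroid is the arithmetic
    mean of the replicates; ``method="median"`` is offered as a non-canonical
    alternative.  Samples present in the table but absent from the
    assignment are ignored with a warning.
    """
    if method not in ("mean", "median"):
        raise ValidationError(f"unknown collapse method {method!r}")
    time_order = list(time_order)
    if len(set(time_order)) != len(time_order):
        raise ValidationError("time_order labels must be unique")
    known = set(time_order)
    col_of = {s: i for i, s in enumerate(table.sample_ids)}
    for sample, label in assignment.items():
        if label not in known:
            raise ValidationError(
                f"sample {sample!r} assigned to unknown time label {label!r}"
            )
        if sample not in col_of:
            raise ValidationError(
                f"assigned sample {sample!r} not present in the table"
            )
    unassigned = [s for s in table.sample_ids if s not in assignment]
    if unassigned:
        logger.warning(
            "collapse_replicates: ignoring %d unassigned samples (%s%s)",
            len(unassigned),
            ", ".join(unassigned[:3]),
            "..." if len(unassigned) > 3 else "",
        )
    reducer = np.mean if method == "mean" else np.median
    centroids = np.empty((table.n_genes, len(time_order)))
    for j, label in enumerate(time_order):
        cols = [col_of[s] for s, lb in assignment.items() if lb == label]
        if not cols:
            raise ValidationError(f"no samples assigned to time label {label!r}")
        centroids[:, j] = reducer(table.values[:, cols], axis=1)
    return TimeCourse(
        gene_ids=list(table.gene_ids),
        time_labels=time_order,
        centroids=centroids,
    )


def compute_segments(
    tc: TimeCourse,
    zero_tolerance: float = 0.0,
    degenerate_policy: str = "error",
) -> SegmentSet:
    """Head-to-tail difference vectors between consecutive centroids.

    A segment whose norm is <= ``zero_tolerance`` means two consecutive
    centroids coincide.  Under the default policy this is an error naming
    the time pair; ``degenerate_policy="merge"`` instead drops the later
    duplicate time point with a warning and recomputes (changing t, hence
    the coefficient indexing — which is why silent removal is not the
    default).
    """
    if zero_tolerance < 0:
        raise ValidationError("zero_tolerance must be >= 0")
    if degenerate_policy not in ("error", "merge"):
        raise ValidationError(f"unknown degenerate policy {degenerate_policy!r}")
    vectors = np.diff(tc.centroids, axis=1)
    lengths = np.linalg.norm(vectors, axis=0)
    bad = np.nonzero(lengths <= zero_tolerance)[0]
    if bad.size:
        pairs = [
            f"{tc.time_labels[i]}->{tc.time_labels[i + 1]}" for i in bad
        ]
        if degenerate_policy == "error":
            raise DegenerateSegmentError(
                f"zero-length segment(s) between consecutive time points: "
                f"{', '.join(pairs)}"
            )
        drop = [tc.time_labels[i + 1] for i in bad]
        logger.warning(
            "compute_segments: merging duplicate time point(s) %s", drop
        )
        return compute_segments(
            tc.drop_times(drop), zero_tolerance, degenerate_policy="error"
        )
    labels = [
        f"{tc.time_labels[i]}->{tc.time_labels[i + 1]}"
        for i in range(tc.n_times - 1)
    ]
    return SegmentSet(
        vectors=vectors,
        lengths=lengths,
        pair_labels=labels,
        time_labels=list(tc.time_labels),
    )


def fit_state_line(
    tc: TimeCourse,
    zero_tolerance: float = 0.0,
    degenerate_policy: str = "error",
    metadata: Mapping[str, object] | None = None,
) -> StateLine:
    """Fit the maximal co-bisector state line to an ordered time course.

    Solves G c = 1 on the normalized segment directions and normalizes
    U c (see module docstring).  The solution always points "forward in
    time" because cos_theta > 0 by construction; this is asserted, not
    assumed.

    Raises
    ------
    LinearDependenceError
        If the segment directions are linearly dependent with rank < t-1
        (the co-bisector is ill-defined) — unless all segments point
        exactly the same way, which reduces to the t = 2 single-segment
        case and is handled explicitly.
    """
    seg = compute_segments(tc, zero_tolerance, degenerate_policy)
    labels = seg.time_labels  # merging may have dropped time points
    keep = [tc.time_labels.index(lb) for lb in labels]
    centroids = tc.centroids[:, keep]

    U = seg.vectors / seg.lengths  # unit segment directions, n x m
    m = U.shape[1]
    if m == 1:
        direction = U[:, 0]
        cos_theta = 1.0
        coefficients = np.array([1.0 / seg.lengths[0]])
    else:
        G = U.T @ U
        eigvals = np.linalg.eigvalsh(G)
        if eigvals[0] < _RANK_TOL * eigvals[-1]:
            if np.max(np.abs(G - 1.0)) < _COLLINEAR_TOL * max(1.0, eigvals[-1]):
                # all segments exactly collinear, same orientation: the
                # trajectory is a straight line; reduce to the t=2 case
                total = seg.vectors.sum(axis=1)
                direction = total / np.linalg.norm(total)
                cos_theta = 1.0
                coefficients = np.full(m, 1.0 / np.linalg.norm(total))
            else:
                rank = int(np.sum(eigvals >= _RANK_TOL * eigvals[-1]))
                raise LinearDependenceError(
                    f"segment directions are linearly dependent (rank {rank} "
                    f"< {m}); the co-bisector is ill-defined — remove "
                    f"redundant time points"
                )
        else:
            ones = np.ones(m)
            c = np.linalg.solve(G, ones)
            quad = float(ones @ c)  # = 1' G^{-1} 1 = ||Uc||^2 > 0 for PD G
            if quad <= 0:
                raise LinearDependenceError(
                    "Gram system produced a non-positive norm; segment "
                    "geometry is numerically degenerate"
                )
            norm_uc = np.sqrt(quad)
            direction = (U @ c) / norm_uc
            cos_theta = 1.0 / norm_uc
            coefficients = c / (norm_uc * seg.lengths)

    assert cos_theta > 0, "co-bisector cosine must be positive by construction"
    direction = direction / np.linalg.norm(direction)  # tighten rounding
    projections = centroids.T @ direction
    meta = dict(metadata or {})
    meta.setdefault("n_genes", centroids.shape[0])
    meta.setdefault("n_times", len(labels))
    logger.info(
        "fit_state_line: t=%d, n=%d, cos_theta=%.6f",
        len(labels),
        centroids.shape[0],
        cos_theta,
    )
    return StateLine(
        gene_ids=list(tc.gene_ids),
        direction=direction,
        coefficients=coefficients,
        cos_theta=float(cos_theta),
        time_labels=labels,
        training_projections=projections,
        metadata=meta,
    )


def project_samples(line: StateLine, table: ExpressionTable) -> ProjectionResult:
    """Project sample expression profiles onto a state line.

    The raw position of sample s is the plain dot product of its column
    with the line direction — no centering term.  Centered positions
    subtract the stored raw position of the first training centroid, the
    display convention in which the earliest training time point is the
    origin.
    """
    if list(table.gene_ids) != list(line.gene_ids):
        raise GeneMismatchError(
            "table gene_ids differ from the line's gene_ids in content or "
            "order; run harmonize_genes (or subset_genes) first"
        )
    raw = table.values.T @ line.direction
    return ProjectionResult(
        sample_ids=list(table.sample_ids),
        positions_raw=raw,
        positions_centered=raw - line.origin,
        line_metadata=dict(line.metadata),
    )


def angle_between(a: StateLine, b: StateLine) -> float:
    """Angle in degrees between two state-line directions, in [0, 180].

    Antiparallel directions give 180; the angle is *not* folded into
    [0, 90], so opposing developmental directions are distinguishable.
    Both lines must have been fitted on the same ordered gene set.
    """
    if list(a.gene_ids) != list(b.gene_ids):
        raise GeneMismatchError(
            "state lines were fitted on different gene sets/orders; "
            "harmonize the training tables before fitting"
        )
    dot = float(np.clip(a.direction @ b.direction, -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def differentiation_coordinates(
    line_a: StateLine,
    line_b: StateLine,
    table: ExpressionTable,
    axis_labels: tuple[str, str] | None = None,
) -> DifferentiationCoordinates:
    """Position samples in the 2-D differentiation-index coordinate system.

    Each axis is the centered projection onto one state line, computed on
    the table restricted to that line's own gene set (the two lines may
    have different gene sets, e.g. two differentiation directions measured
    on overlapping platforms).
    """
    pa = project_samples(line_a, table.subset_genes(line_a.gene_ids))
    pb = project_samples(line_b, table.subset_genes(line_b.gene_ids))
    if axis_labels is None:
        axis_labels = (
            str(line_a.metadata.get("name", "line_a")),
            str(line_b.metadata.get("name", "line_b")),
        )
    coords = np.column_stack([pa.positions_centered, pb.positions_centered])
    return DifferentiationCoordinates(
        sample_ids=list(table.sample_ids),
        coords=coords,
        axis_labels=axis_labels,
    )
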