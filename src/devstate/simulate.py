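"""Ground-truth synthetic trajectories for testing the model end to end.

A trajectory is built as a piecewise-linear path in gene space: unit
segment directions with prescribed pairwise turn angles are constructed by
Gram-Schmidt in a canonical frame, the whole frame is randomly rotated (so
nothing downstream can rely on axis-aligned coordinates), and centroids
follow by cumulative sums of length-scaled directions from a baseline
expression point.  Replicates add isotropic Gaussian noise around each
centroid; "tumor-like" external samples are displaced along the fitted
line direction and/or into the orthogonal complement of the segment span.

All randomness flows from the single integer seed in the config through
one ``numpy.random.default_rng`` generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .errors import ValidationError
from .io import ExpressionTable, write_expression_table
from .model import StateLine, TimeCourse, fit_state_line

#: baseline per-gene expression is drawn N(BASELINE_MEAN, BASELINE_SD) —
#: the scale of log2 microarray intensities
BASELINE_MEAN = 8.0
BASELINE_SD = 1.0


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic developmental trajectory.

    ``segment_lengths`` (t-1 positive reals) are Euclidean step sizes
    between consecutive time-point centroids; ``turn_angles_deg`` (t-2
    reals in [0, 180)) are the angles between consecutive segment
    directions — 0 keeps going straight, 90 turns perpendicular, exact
    reversal (180) is rejected because the co-bisector degenerates.
    ``noise_sd`` is the isotropic per-gene replicate noise SD.
    """

    n_genes: int
    time_labels: list[str]
    segment_lengths: Sequence[float]
    turn_angles_deg: Sequence[float] = ()
    replicates_per_point: int = 3
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.time_labels)
        if t < 2:
            raise ValidationError("need at least 2 time labels")
        if len(set(self.time_labels)) != t:
            raise ValidationError("time labels must be unique")
        if len(self.segment_lengths) != t - 1:
            raise ValidationError(
                f"expected {t - 1} segment lengths, got {len(self.segment_lengths)}"
            )
        if any(l <= 0 for l in self.segment_lengths):
            raise ValidationError("segment lengths must all be positive")
        if len(self.turn_angles_deg) != max(t - 2, 0):
            raise ValidationError(
                f"expected {max(t - 2, 0)} turn angles, got {len(self.turn_angles_deg)}"
            )
        for a in self.turn_angles_deg:
            if not (0 <= a < 180):
                raise ValidationError(
                    f"turn angle {a} out of [0, 180); exact reversal is degenerate"
                )
        if self.n_genes < t:
            raise ValidationError(
                "n_genes must be >= number of time points so segments can be "
                "linearly independent"
            )
        if self.replicates_per_point < 1:
            raise ValidationError("replicates_per_point must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SimulationTruth:
    """Exact generating geometry of a simulated trajectory."""

    centroids: np.ndarray  # n_genes x t, noiseless
    time_labels: list[str]
    gene_ids: list[str]
    true_line: StateLine  # fitted on the noiseless centroids
    segment_directions: np.ndarray  # n_genes x (t-1), exact unit vectors

    def time_course(self) -> TimeCourse:
        return TimeCourse(
            gene_ids=list(self.gene_ids),
            time_labels=list(self.time_labels),
            centroids=self.centroids,
        )

    def anchor_position(self, label: str) -> float:
        """Centered position of a time-point centroid on the true line."""
        j = self.time_labels.index(label)
        return float(self.true_line.training_projections[j] - self.true_line.origin)


def random_rotation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-distributed orthogonal matrix via QR with sign fixing."""
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def _segment_directions(
    n: int, turn_angles_deg: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Unit directions with prescribed consecutive turn angles, randomly rotated.

    In the canonical frame d_1 = e_1 and d_{i+1} = cos(a_i) d_i +
    sin(a_i) e_{i+1}; e_{i+1} is orthogonal to span(e_1..e_i) which
    contains d_i, so the realized turn angle is exact.  A random rotation
    then scrambles the frame.
    """
    m = len(turn_angles_deg) + 1
    dirs = np.zeros((n, m))
    dirs[0, 0] = 1.0
    for i, a in enumerate(turn_angles_deg):
        rad = np.radians(a)
        d = np.cos(rad) * dirs[:, i]
        d[i + 1] += np.sin(rad)
        dirs[:, i + 1] = d / np.linalg.norm(d)
    return random_rotation(n, rng) @ dirs


def simulate_trajectory(
    config: SimulationConfig,
) -> tuple[ExpressionTable, dict[str, str], SimulationTruth]:
    """Simulate an ordered time course with replicate noise.

    Returns ``(table, assignment, truth)``: the replicate-level expression
    table, the sample -> time-label assignment, and the exact generating
    geometry (noiseless centroids, the line fitted on them, and the exact
    segment directions).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    t = len(config.time_labels)
    dirs = _segment_directions(n, config.turn_angles_deg, rng)
    base = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n)
    steps = dirs * np.asarray(config.segment_lengths)
    centroids = np.empty((n, t))
    centroids[:, 0] = base
    centroids[:, 1:] = base[:, None] + np.cumsum(steps, axis=1)

    gene_ids = [f"g{i:05d}" for i in range(n)]
    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    columns = []
    for j, label in enumerate(config.time_labels):
        for r in range(config.replicates_per_point):
            sid = f"{label}_r{r + 1}"
            sample_ids.append(sid)
            assignment[sid] = label
            noise = (
                rng.normal(0.0, config.noise_sd, size=n)
                if config.noise_sd > 0
                else 0.0
            )
            columns.append(centroids[:, j] + noise)
    table = ExpressionTable(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.column_stack(columns),
    )
    truth = SimulationTruth(
        centroids=centroids,
        time_labels=list(config.time_labels),
        gene_ids=gene_ids,
        true_line=fit_state_line(
            TimeCourse(gene_ids, list(config.time_labels), centroids)
        ),
        segment_directions=dirs,
    )
    return table, assignment, truth


def simulate_displaced_samples(
    truth: SimulationTruth,
    along: float,
    orthogonal: float,
    anchor_label: str,
    count: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionTable:
    """External ("tumor-like") samples displaced from an anchor centroid.

    Each sample is the anchor centroid plus ``along`` times the true line
    direction, plus ``orthogonal`` times a per-sample random unit vector in
    the orthogonal complement of the segment span, plus optional isotropic
    noise.  Along-displacements shift the projected position one-for-one;
    orthogonal displacements are invisible to the line.
    """
    if anchor_label not in truth.time_labels:
        raise ValidationError(f"unknown anchor label {anchor_label!r}")
    if count < 1:
        raise ValidationError("count must be >= 1")
    rng = np.random.default_rng(seed)
    n = truth.centroids.shape[0]
    anchor = truth.centroids[:, truth.time_labels.index(anchor_label)]
    span = truth.segment_directions  # n x m
    m = span.shape[1]
    if orthogonal != 0.0 and n <= m:
        raise ValidationError(
            "orthogonal complement of the segment span is empty "
            f"(n_genes={n}, span rank {m})"
        )
    # orthonormal basis of the span for projecting out
    q, _ = np.linalg.qr(span)
    columns = []
    for _k in range(count):
        x = anchor + along * truth.true_line.direction
        if orthogonal != 0.0:
            w = rng.normal(size=n)
            w -= q @ (q.T @ w)
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                raise ValidationError(
                    "failed to draw a vector orthogonal to the segment span"
                )
            x = x + orthogonal * (w / nw)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=n)
        columns.append(x)
    sample_ids = [f"disp{k + 1:03d}" for k in range(count)]
    return ExpressionTable(
        gene_ids=list(truth.gene_ids),
        sample_ids=sample_ids,
        values=np.column_stack(columns),
    )


def rotation_between(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Orthogonal matrix rotating unit vector x onto unit vector y.

    Rotates only in the plane spanned by x and y, leaving the orthogonal
    complement fixed.  Antiparallel inputs are rejected (the plane is
    undetermined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = float(np.clip(x @ y, -1.0, 1.0))
    if c > 1 - 1e-14:
        return np.eye(len(x))
    if c < -1 + 1e-12:
        raise ValidationError("cannot rotate between antiparallel vectors")
    yp = y - c * x
    yp /= np.linalg.norm(yp)
    s = np.sqrt(1.0 - c * c)
    outer = np.outer
    return (
        np.eye(len(x))
        + (c - 1.0) * (outer(x, x) + outer(yp, yp))
        + s * (outer(yp, x) - outer(x, yp))
    )


def simulate_pair_with_angle(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    angle_deg: float,
) -> tuple[SimulationTruth, SimulationTruth]:
    """Two trajectories whose fitted co-bisectors meet at a prescribed angle.

    Trajectory B is simulated independently, then rigidly rotated so that
    its co-bisector makes exactly ``angle_deg`` with A's, with the residual
    orientation drawn from B's generator.  Gene counts must match so the
    two lines live in the same space.
    """
    if config_a.n_genes != config_b.n_genes:
        raise ValidationError("both trajectories must share n_genes")
    if not (0 <= angle_deg < 180):
        raise ValidationError("angle_deg must be in [0, 180)")
    _, _, truth_a = simulate_trajectory(config_a)
    _, _, truth_b = simulate_trajectory(config_b)
    rng = np.random.default_rng(config_b.seed + 1)
    n = config_a.n_genes
    da = truth_a.true_line.direction
    # target direction: rotate da by angle_deg within a random plane
    w = rng.normal(size=n)
    w -= (w @ da) * da
    w /= np.linalg.norm(w)
    rad = np.radians(angle_deg)
    target = np.cos(rad) * da + np.sin(rad) * w
    rot = rotation_between(truth_b.true_line.direction, target)
    centroids_b = rot @ truth_b.centroids
    tc_b = TimeCourse(truth_b.gene_ids, list(truth_b.time_labels), centroids_b)
    truth_b_rot = SimulationTruth(
        centroids=centroids_b,
        time_labels=list(truth_b.time_labels),
        gene_ids=list(truth_b.gene_ids),
        true_line=fit_state_line(tc_b),
        segment_directions=rot @ truth_b.segment_directions,
    )
    return truth_a, truth_b_rot


def directions_with_pairwise_angles(
    angles_deg: np.ndarray, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit vectors (columns) realizing a prescribed matrix of pairwise angles.

    ``angles_deg`` is a symmetric k x k matrix (zero diagonal); the cosine
    Gram matrix it implies must be positive definite, i.e. the angles must
    be jointly realizable.  The vectors are embedded in ``n_genes``
    dimensions in a random orthonormal frame, so nothing downstream can
    rely on the construction axes.  Useful for building trajectories whose
    co-bisectors meet at known angles (tissue-comparison scenarios).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    k = angles_deg.shape[0]
    if angles_deg.shape != (k, k) or not np.allclose(angles_deg, angles_deg.T):
        raise ValidationError("angles_deg must be a symmetric square matrix")
    if n_genes < k:
        raise ValidationError("n_genes must be >= the number of directions")
    gram = np.cos(np.radians(angles_deg))
    np.fill_diagonal(gram, 1.0)
    try:
        chol = np.linalg.cholesky(gram)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "the prescribed pairwise angles are not jointly realizable "
            "(cosine Gram matrix is not positive definite)"
        ) from None
    frame = random_rotation(n_genes, rng)[:, :k]  # random orthonormal n x k
    return frame @ chol.T


def straight_trajectory_along(
    direction: np.ndarray,
    time_labels: Sequence[str],
    segment_lengths: Sequence[float],
    base: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TimeCourse:
    """A straight (collinear) time course marching along a given unit vector.

    Its fitted state line is exactly ``direction`` with cos_theta = 1, so
    this is the natural training input when the line direction itself is
    the quantity under study.
    """
    direction = np.asarray(direction, dtype=float)
    n = direction.shape[0]
    t = len(time_labels)
    if len(segment_lengths) != t - 1:
        raise ValidationError(f"expected {t - 1} segment lengths")
    if base is None:
        base = (
            rng.normal(BASELINE_MEAN, BASELINE_SD, size=n)
            if rng is not None
            else np.full(n, BASELINE_MEAN)
        )
    positions = np.concatenate([[0.0], np.cumsum(segment_lengths)])
    centroids = base[:, None] + direction[:, None] * positions
    gene_ids = [f"g{i:05d}" for i in range(n)]
    return TimeCourse(gene_ids, list(time_labels), centroids)


def write_truth(truth: SimulationTruth, path) -> None:
    """Truth sidecar (JSON): centroids, labels, and the true line geometry."""
    doc = {
        "time_labels": list(truth.time_labels),
        "gene_ids": list(truth.gene_ids),
        "centroids": truth.centroids.tolist(),
        "segment_directions": truth.segment_directions.tolist(),
        "true_direction": truth.true_line.direction.tolist(),
        "true_cos_theta": truth.true_line.cos_theta,
        "true_training_projections": truth.true_line.training_projections.tolist(),
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def write_simulation(
    out_dir,
    table: ExpressionTable,
    assignment: dict[str, str],
    truth: SimulationTruth,
) -> None:
    """Write a simulated dataset as expression TSV + assignment TSV + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_expression_table(table, out_dir / "expression.tsv")
    with open(out_dir / "assignment.tsv", "w") as fh:
        fh.write("sample_id\ttime_label\n")
        for sid in table.sample_ids:
            fh.write(f"{sid}\t{assignment[sid]}\n")
    write_truth(truth, out_dir / "truth.json")
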