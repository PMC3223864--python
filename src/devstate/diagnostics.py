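"""Evaluation machinery for fitted state lines.

Three instruments:

* :func:`distance_table` — per-gap distances and consecutive-gap ratios in
  full gene space, on the state line, and on PCA components.  The state
  line preserves the distance ratios exactly (each projection gap is
  ||v_i|| * cos_theta, so the common factor cancels); PCA components in
  general do not, which is the model's point of difference from a
  variance-maximizing projection.
* :func:`order_concordance` — Kendall rank correlation between projected
  positions and a known sample order.
* :func:`leave_out_robustness` — refit the line with time points removed
  and track how the projections of a fixed test set move.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import ExpressionTable
from .model import (
    ProjectionResult,
    StateLine,
    TimeCourse,
    compute_segments,
    fit_state_line,
    project_samples,
)

logger = logging.getLogger(__name__)

#: a ratio denominator below this fraction of the trajectory length is
#: flagged as numerically unreliable (a near-zero gap blows the ratio up)
RATIO_GUARD_FRACTION = 1e-12


@dataclass
class DistanceTable:
    """Distances and consecutive-gap ratios in space, on the line, on PCs.

    ``pc_distances[k]`` holds *signed* displacements along component k+1
    between consecutive centroids (a PC gap can be negative); ratio arrays
    have one fewer entry than distance arrays (gap i over gap i+1).
    ``pc_ratio_guard[k]`` flags ratios whose denominator gap is smaller
    than ``RATIO_GUARD_FRACTION`` of the total trajectory length.
    """

    gap_labels: list[str]
    space_distances: np.ndarray
    line_distances: np.ndarray
    space_ratios: np.ndarray
    line_ratios: np.ndarray
    pc_distances: dict[int, np.ndarray] = field(default_factory=dict)
    pc_ratios: dict[int, np.ndarray] = field(default_factory=dict)
    pc_ratio_guard: dict[int, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per gap, fixed column order.

        Columns: gap, space_distance, line_distance, pc<k>_distance...,
        space_ratio, line_ratio, pc<k>_ratio... — ratio columns are NaN on
        the final row (a ratio pairs gap i with gap i+1).
        """
        m = len(self.gap_labels)

        def pad(r: np.ndarray) -> np.ndarray:
            return np.append(r, np.nan)

        data: dict[str, object] = {"gap": self.gap_labels}
        data["space_distance"] = self.space_distances
        data["line_distance"] = self.line_distances
        for k in sorted(self.pc_distances):
            data[f"pc{k}_distance"] = self.pc_distances[k]
        data["space_ratio"] = pad(self.space_ratios)
        data["line_ratio"] = pad(self.line_ratios)
        for k in sorted(self.pc_ratios):
            data[f"pc{k}_ratio"] = pad(self.pc_ratios[k])
        return pd.DataFrame(data)

    def to_csv(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def distance_table(
    tc: TimeCourse, line: StateLine, pca_components: int = 2
) -> DistanceTable:
    """Build the space/line/PC distance-and-ratio comparison table.

    PCA is computed on the time-point centroids (one point per time point,
    mean-centered SVD); each component's sign is fixed so its
    largest-magnitude gene loading is positive, making the table
    reproducible even though PC signs are arbitrary.
    """
    if list(tc.time_labels) != list(line.time_labels):
        raise ValidationError(
            "distance_table requires a line fitted on this time course"
        )
    max_comp = min(tc.n_genes, tc.n_times)
    if not (0 <= pca_components <= max_comp):
        raise ValidationError(
            f"pca_components must be in [0, {max_comp}] for this time course"
        )
    seg = compute_segments(tc)
    space_d = seg.lengths
    line_d = np.diff(line.training_projections)
    traj_len = float(space_d.sum())

    def ratios(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        guard = np.abs(d[1:]) < RATIO_GUARD_FRACTION * traj_len
        denom = np.where(guard, np.nan, d[1:])
        return d[:-1] / denom, guard

    space_r, _ = ratios(space_d)
    line_r, _ = ratios(line_d)

    pc_d: dict[int, np.ndarray] = {}
    pc_r: dict[int, np.ndarray] = {}
    pc_g: dict[int, np.ndarray] = {}
    if pca_components > 0:
        pca = PCA(n_components=pca_components)
        scores = pca.fit_transform(tc.centroids.T)  # t x k
        # reproducible sign: largest-|loading| gene positive per component
        for k in range(pca_components):
            loading = pca.components_[k]
            if loading[np.argmax(np.abs(loading))] < 0:
                scores[:, k] = -scores[:, k]
        for k in range(pca_components):
            d = np.diff(scores[:, k])
            r, g = ratios(d)
            pc_d[k + 1] = d
            pc_r[k + 1] = r
            pc_g[k + 1] = g
    return DistanceTable(
        gap_labels=list(seg.pair_labels),
        space_distances=space_d,
        line_distances=line_d,
        space_ratios=space_r,
        line_ratios=line_r,
        pc_distances=pc_d,
        pc_ratios=pc_r,
        pc_ratio_guard=pc_g,
    )


def order_concordance(
    result: ProjectionResult, expected_order: Sequence[str]
) -> tuple[float, bool]:
    """Kendall tau between projected positions and a known sample order.

    Returns ``(tau, is_perfect)`` where ``is_perfect`` is True iff the
    positions are strictly increasing along ``expected_order``.  Ties in
    position are handled by the tau-b convention.
    """
    expected_order = list(expected_order)
    if len(expected_order) < 2:
        raise ValidationError("order concordance needs at least 2 samples")
    pos_of = dict(zip(result.sample_ids, result.positions_raw))
    missing = [s for s in expected_order if s not in pos_of]
    if missing:
        raise ValidationError(f"samples not in projection result: {missing[:5]}")
    positions = np.array([pos_of[s] for s in expected_order])
    tau, _ = kendalltau(np.arange(len(positions)), positions)
    is_perfect = bool(np.all(np.diff(positions) > 0))
    return float(tau), is_perfect


@dataclass
class RobustnessReport:
    """Projections of a fixed test set across leave-time-points-out refits.

    ``positions`` is runs x samples, each run on its own line's centered
    scale (origin = that line's first surviving training centroid).  A run's
    ``order_violations`` entry counts adjacent pairs, in the test table's
    declared sample order, whose projected positions do not increase.
    """

    removed_labels: list[tuple[str, ...]]
    sample_ids: list[str]
    positions: np.ndarray  # runs x samples, centered per-run
    per_sample_mean: np.ndarray
    per_sample_variance: np.ndarray
    order_violations: np.ndarray  # per run

    def to_frame(self) -> pd.DataFrame:
        """One row per run: removed labels, violations, then per-sample positions."""
        frame = pd.DataFrame(self.positions, columns=self.sample_ids)
        frame.insert(
            0, "removed", ["+".join(r) if r else "(none)" for r in self.removed_labels]
        )
        frame.insert(1, "order_violations", self.order_violations)
        return frame

    def to_csv(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def default_removal_sets(
    time_labels: Sequence[str], max_removed: int = 3
) -> list[tuple[str, ...]]:
    """All singletons, pairs, ... of *interior* time points, plus the empty set.

    Mirrors the protocol of removing 1, 2 and 3 points while keeping both
    endpoints, so every reduced course still brackets the full time range.
    """
    interior = list(time_labels)[1:-1]
    sets: list[tuple[str, ...]] = [()]
    for k in range(1, max_removed + 1):
        sets.extend(itertools.combinations(interior, k))
    return sets


def leave_out_robustness(
    tc: TimeCourse,
    test: ExpressionTable,
    removals: Sequence[Sequence[str]] | None = None,
    keep_endpoints: bool = False,
) -> RobustnessReport:
    """Refit the line under time-point removals and re-project a test set.

    For each removal set the line is refitted on the reduced time course
    and the test samples projected on that line's own centered scale.  The
    empty removal set reproduces the full-line positions exactly.

    ``keep_endpoints=True`` rejects removal sets touching the first or last
    time point (removing an endpoint both shortens the modeled time range
    and moves the origin, so such runs measure a different thing).
    """
    if removals is None:
        removals = default_removal_sets(tc.time_labels)
    test = test.subset_genes(tc.gene_ids)
    endpoints = {tc.time_labels[0], tc.time_labels[-1]}
    rows = []
    violations = []
    removed_out: list[tuple[str, ...]] = []
    for removal in removals:
        removal = tuple(removal)
        if keep_endpoints and (set(removal) & endpoints):
            raise ValidationError(
                f"removal {removal} touches an endpoint but keep_endpoints is set"
            )
        reduced = tc.drop_times(removal) if removal else tc
        line = fit_state_line(reduced)
        proj = project_samples(line, test)
        rows.append(proj.positions_centered)
        violations.append(int(np.sum(np.diff(proj.positions_centered) <= 0)))
        removed_out.append(removal)
    positions = np.vstack(rows)
    logger.info(
        "leave_out_robustness: %d runs, %d test samples",
        positions.shape[0],
        positions.shape[1],
    )
    return RobustnessReport(
        removed_labels=removed_out,
        sample_ids=list(test.sample_ids),
        positions=positions,
        per_sample_mean=positions.mean(axis=0),
        per_sample_variance=positions.var(axis=0),
        order_violations=np.array(violations),
    )
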