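import numpy as np
import pytest

from devstate import (
    DegenerateSegmentError,
    ExpressionTable,
    GeneMismatchError,
    LinearDependenceError,
    StateLine,
    TimeCourse,
    ValidationError,
    angle_between,
    collapse_replicates,
    compute_segments,
    differentiation_coordinates,
    fit_state_line,
    project_samples,
)

from conftest import cobisector_oracle, random_time_course

SQRT2 = np.sqrt(2.0)


def tc_from_columns(*columns, labels=None):
    cols = np.array(columns, dtype=float).T
    n, t = cols.shape
    labels = labels or [f"d{j + 1}" for j in range(t)]
    return TimeCourse([f"g{i + 1}" for i in range(n)], labels, cols)


class TestCollapseReplicates:
    def test_identical_replicates_give_the_value(self):
        table = ExpressionTable(["g1"], ["a1", "a2", "b1", "b2"],
                                [[5.0, 5.0, 7.0, 7.0]])
        assign = {"a1": "d1", "a2": "d1", "b1": "d2", "b2": "d2"}
        tc = collapse_replicates(table, assign, ["d1", "d2"])
        np.testing.assert_array_equal(tc.centroids, [[5.0, 7.0]])

    def test_arithmetic_mean(self):
        table = ExpressionTable(["g1"], ["a1", "a2", "b1", "b2"],
                                [[1.0, 3.0, 2.0, 6.0]])
        assign = {"a1": "d1", "a2": "d1", "b1": "d2", "b2": "d2"}
        tc = collapse_replicates(table, assign, ["d1", "d2"])
        np.testing.assert_array_equal(tc.centroids, [[2.0, 4.0]])

    def test_median_alternative(self):
        table = ExpressionTable(["g1"], ["a1", "a2", "a3", "b1"],
                                [[1.0, 2.0, 100.0, 5.0]])
        assign = {"a1": "d1", "a2": "d1", "a3": "d1", "b1": "d2"}
        tc = collapse_replicates(table, assign, ["d1", "d2"], method="median")
        np.testing.assert_array_equal(tc.centroids, [[2.0, 5.0]])

    def test_empty_time_label_rejected(self):
        table = ExpressionTable(["g1"], ["a1"], [[1.0]])
        with pytest.raises(ValidationError, match="d12"):
            collapse_replicates(table, {"a1": "d1"}, ["d1", "d12"])

    def test_unknown_label_rejected(self):
        table = ExpressionTable(["g1"], ["a1", "b1"], [[1.0, 2.0]])
        with pytest.raises(ValidationError, match="dX"):
            collapse_replicates(table, {"a1": "d1", "b1": "dX"}, ["d1", "d2"])

    def test_unassigned_samples_ignored_with_warning(self, caplog):
        table = ExpressionTable(["g1"], ["a1", "b1", "stray"],
                                [[1.0, 2.0, 99.0]])
        with caplog.at_level("WARNING"):
            tc = collapse_replicates(table, {"a1": "d1", "b1": "d2"},
                                     ["d1", "d2"])
        np.testing.assert_array_equal(tc.centroids, [[1.0, 2.0]])
        assert "stray" in caplog.text


class TestComputeSegments:
    def test_direct_subtraction(self):
        tc = tc_from_columns([0, 0], [1, 0], [1, 1])
        seg = compute_segments(tc)
        np.testing.assert_array_equal(seg.vectors, [[1, 0], [0, 1]])
        np.testing.assert_array_equal(seg.lengths, [1, 1])
        assert seg.pair_labels == ["d1->d2", "d2->d3"]

    def test_lengths(self):
        tc = tc_from_columns([0, 0], [2, 0], [2, 1])
        np.testing.assert_array_equal(compute_segments(tc).lengths, [2, 1])

    def test_duplicate_consecutive_centroids_error_names_pair(self):
        tc = tc_from_columns([0, 0], [1, 0], [1, 0], labels=["a", "b", "c"])
        with pytest.raises(DegenerateSegmentError, match="b->c"):
            compute_segments(tc)

    def test_merge_policy_drops_later_duplicate(self):
        tc = tc_from_columns([0, 0], [1, 0], [1, 0], [1, 1],
                             labels=["a", "b", "c", "d"])
        seg = compute_segments(tc, degenerate_policy="merge")
        assert seg.time_labels == ["a", "b", "d"]
        np.testing.assert_array_equal(seg.lengths, [1, 1])


class TestFitStateLine:
    def test_perpendicular_unit_segments_bisector(self):
        line = fit_state_line(tc_from_columns([0, 0], [1, 0], [1, 1]))
        np.testing.assert_allclose(line.direction, [1 / SQRT2, 1 / SQRT2],
                                   atol=1e-12)
        assert line.cos_theta == pytest.approx(1 / SQRT2, abs=1e-12)
        np.testing.assert_allclose(line.training_projections,
                                   [0, 1 / SQRT2, SQRT2], atol=1e-12)

    def test_hand_derived_gram_solution(self, worked_line):
        assert worked_line.cos_theta == pytest.approx(0.92388, abs=5e-6)
        np.testing.assert_allclose(worked_line.direction, [0.92388, 0.38268],
                                   atol=5e-6)
        np.testing.assert_allclose(worked_line.training_projections,
                                   [0.0, 0.92388, 2.23044], atol=5e-6)
        # gap ratio on the line equals the segment length ratio
        gaps = np.diff(worked_line.training_projections)
        assert gaps[0] / gaps[1] == pytest.approx(1 / SQRT2, abs=1e-9)

    def test_coefficients_reconstruct_direction(self, worked_tc, worked_line):
        seg = compute_segments(worked_tc)
        rebuilt = seg.vectors @ worked_line.coefficients
        np.testing.assert_allclose(rebuilt, worked_line.direction, atol=1e-12)

    def test_two_time_points_cos_exactly_one(self):
        line = fit_state_line(tc_from_columns([0, 0], [3, 4]))
        assert line.cos_theta == 1.0
        np.testing.assert_allclose(line.direction, [0.6, 0.8], atol=1e-15)

    def test_collinear_same_direction_reduces_to_straight_line(self):
        tc = tc_from_columns([0, 0], [1, 0], [3, 0], [6, 0])
        line = fit_state_line(tc)
        assert line.cos_theta == 1.0
        np.testing.assert_allclose(line.direction, [1, 0], atol=1e-15)
        np.testing.assert_allclose(line.training_projections, [0, 1, 3, 6],
                                   atol=1e-15)

    def test_linearly_dependent_segments_rejected(self):
        # 3 segments confined to a 2-D gene space: rank 2 < 3
        tc = tc_from_columns([0, 0], [1, 0], [1, 1], [0, 1])
        with pytest.raises(LinearDependenceError, match="rank 2"):
            fit_state_line(tc)

    def test_equal_angle_with_every_segment(self):
        rng = np.random.default_rng(11)
        tc = random_time_course(rng, n_genes=8, n_times=5)
        line = fit_state_line(tc)
        seg = compute_segments(tc)
        cosines = (seg.vectors / seg.lengths).T @ line.direction
        np.testing.assert_allclose(cosines, line.cos_theta, atol=1e-8)
        assert np.linalg.norm(line.direction) == pytest.approx(1.0, abs=1e-10)

    def test_matches_numerical_optimizer(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(3, 21))
            t = int(rng.integers(3, min(n, 6) + 1))
            tc = random_time_course(rng, n, t)
            line = fit_state_line(tc)
            seg = compute_segments(tc)
            oracle = cobisector_oracle(seg.vectors / seg.lengths)
            assert abs(oracle @ line.direction) > 1 - 1e-6


class TestProjectSamples:
    def test_first_training_centroid_is_origin(self, worked_tc, worked_line):
        table = ExpressionTable(worked_tc.gene_ids, ["first"],
                                worked_tc.centroids[:, :1])
        result = project_samples(worked_line, table)
        assert result.positions_centered[0] == 0.0

    def test_hand_dot_product(self, worked_line):
        table = ExpressionTable(["g1", "g2"], ["s"], [[1.0], [1.0]])
        result = project_samples(worked_line, table)
        assert result.positions_raw[0] == pytest.approx(1.30656, abs=5e-6)

    def test_training_centroids_strictly_increasing(self):
        rng = np.random.default_rng(3)
        tc = random_time_course(rng, 10, 5)
        line = fit_state_line(tc)
        table = ExpressionTable(tc.gene_ids, tc.time_labels, tc.centroids)
        result = project_samples(line, table)
        assert np.all(np.diff(result.positions_raw) > 0)
        np.testing.assert_allclose(result.positions_raw,
                                   line.training_projections, atol=1e-12)

    def test_gene_mismatch_instructs_harmonization(self, worked_line):
        table = ExpressionTable(["g2", "g1"], ["s"], [[1.0], [1.0]])
        with pytest.raises(GeneMismatchError, match="harmonize_genes"):
            project_samples(worked_line, table)


def line_along(direction, gene_ids=None):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = len(direction)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n)]
    return StateLine(
        gene_ids=gene_ids,
        direction=direction,
        coefficients=np.array([1.0]),
        cos_theta=1.0,
        time_labels=["t0", "t1"],
        training_projections=np.array([0.0, 1.0]),
    )


class TestAngleBetween:
    def test_self_angle_zero(self, worked_line):
        assert angle_between(worked_line, worked_line) == 0.0

    def test_orthogonal_ninety(self):
        assert angle_between(line_along([1, 0]), line_along([0, 1])) == \
            pytest.approx(90.0, abs=1e-10)

    def test_antiparallel_is_180_not_folded(self):
        assert angle_between(line_along([1, 0]), line_along([-1, 0])) == \
            pytest.approx(180.0, abs=1e-10)

    def test_gene_mismatch_rejected(self):
        a = line_along([1, 0], gene_ids=["g1", "g2"])
        b = line_along([1, 0], gene_ids=["g2", "g1"])
        with pytest.raises(GeneMismatchError):
            angle_between(a, b)


class TestDifferentiationCoordinates:
    def test_shared_origin_maps_to_zero_zero(self, worked_tc, worked_line):
        table = ExpressionTable(worked_tc.gene_ids, ["origin"],
                                worked_tc.centroids[:, :1])
        dc = differentiation_coordinates(worked_line, worked_line, table)
        np.testing.assert_allclose(dc.coords, [[0.0, 0.0]], atol=1e-12)

    def test_same_line_on_both_axes_gives_equal_coords(self, worked_line):
        table = ExpressionTable(["g1", "g2"], ["s"], [[1.0], [1.0]])
        dc = differentiation_coordinates(worked_line, worked_line, table)
        assert dc.coords[0, 0] == dc.coords[0, 1]

    def test_displacement_along_one_axis_leaves_other_constant(self):
        # orthogonal axes in a 3-gene space; samples slide along axis A only
        la = line_along([1, 0, 0])
        lb = line_along([0, 1, 0])
        values = np.array([[0.0, 1.0, 2.5], [0.7, 0.7, 0.7], [5.0, -1.0, 2.0]])
        table = ExpressionTable(["g1", "g2", "g3"], ["s1", "s2", "s3"], values)
        dc = differentiation_coordinates(la, lb, table)
        np.testing.assert_allclose(dc.coords[:, 0], [0.0, 1.0, 2.5], atol=1e-12)
        assert np.ptp(dc.coords[:, 1]) == pytest.approx(0.0, abs=1e-8)

    def test_axis_labels_from_metadata(self, worked_line):
        worked_line.metadata["name"] = "liver"
        table = ExpressionTable(["g1", "g2"], ["s"], [[1.0], [1.0]])
        dc = differentiation_coordinates(worked_line, worked_line, table)
        assert dc.axis_labels == ("liver", "liver")
        assert list(dc.to_frame().columns) == ["liver", "liver"]
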