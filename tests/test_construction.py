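"""Correlation matrices and density thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covnet import (
    BinaryNetwork,
    CohortTable,
    CorrelationMatrix,
    DensityGrid,
    binarize_over_grid,
    correlation_matrix,
    threshold_at_density,
)


def cohort_with_columns(cols: dict[str, list[float]]) -> CohortTable:
    """Group A carries the given columns; a random group B pads validity."""
    n = len(next(iter(cols.values())))
    rng = np.random.default_rng(99)
    a_vals = np.column_stack([np.asarray(v, float) for v in cols.values()])
    b_vals = rng.normal(size=(3, len(cols)))
    return CohortTable(
        subject_ids=[f"a{i}" for i in range(n)] + ["b0", "b1", "b2"],
        group_labels=["A"] * n + ["B"] * 3,
        regions=list(cols),
        values=np.vstack([a_vals, b_vals]),
    )


def random_correlation(rng, n=68) -> CorrelationMatrix:
    x = rng.normal(size=(50, n))
    r = np.corrcoef(x, rowvar=False)
    return CorrelationMatrix(regions=[f"r{i}" for i in range(n)], r=r,
                             n_subjects=50)


class TestCorrelationMatrix:
    def test_identical_columns_r_one(self):
        c = cohort_with_columns({"x": [1, 2, 3, 4], "y": [1, 2, 3, 4]})
        R = correlation_matrix(c, "A")
        assert R.r[0, 1] == pytest.approx(1.0)

    def test_negated_column_r_minus_one(self):
        c = cohort_with_columns({"x": [1, 2, 3, 4], "y": [-1, -2, -3, -4]})
        R = correlation_matrix(c, "A")
        assert R.r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # definitional formula on x=(1,2,3,4), y=(1,3,2,4) gives 0.8
        c = cohort_with_columns({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        R = correlation_matrix(c, "A")
        assert R.r[0, 1] == pytest.approx(0.8)
        assert R.n_subjects == 4

    def test_unknown_group_and_small_group_rejected(self):
        c = cohort_with_columns({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        with pytest.raises(KeyError):
            correlation_matrix(c, "nope")
        c2 = CohortTable(
            subject_ids=["a0", "a1", "b0", "b1", "b2"],
            group_labels=["A", "A", "B", "B", "B"],
            regions=["x", "y"],
            values=np.random.default_rng(0).normal(size=(5, 2)),
        )
        with pytest.raises(ValueError, match=">= 3"):
            correlation_matrix(c2, "A")

    def test_within_group_zero_variance_named(self):
        vals = np.random.default_rng(1).normal(size=(7, 2))
        vals[:4, 0] = 2.0  # constant within group A only
        c = CohortTable(
            subject_ids=[f"s{i}" for i in range(7)],
            group_labels=["A"] * 4 + ["B"] * 3,
            regions=["flat", "ok"],
            values=vals,
        )
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(c, "A")


class TestThresholdAtDensity:
    def test_keeps_strongest_positive_half(self):
        r = np.array(
            [
                [1.0, 0.9, 0.2, 0.5],
                [0.9, 1.0, 0.6, 0.1],
                [0.2, 0.6, 1.0, 0.7],
                [0.5, 0.1, 0.7, 1.0],
            ]
        )
        R = CorrelationMatrix(regions=list("abcd"), r=r, n_subjects=10)
        net = threshold_at_density(R, 0.5)  # E = round(0.5*4*3/2) = 3
        assert net.n_edges == 3
        assert net.k_nonzero == 6
        kept = {tuple(e) for e in net.edges()}
        assert kept == {(0, 1), (2, 3), (1, 2)}  # r = .9, .7, .6

    def test_zero_edge_density(self):
        rng = np.random.default_rng(0)
        R = random_correlation(rng, n=4)
        net = threshold_at_density(R, 0.01)  # E = round(0.06) = 0
        assert net.k_nonzero == 0
        assert net.density == 0.0

    def test_68_region_density_19_gives_433_edges(self):
        R = random_correlation(np.random.default_rng(3))
        net = threshold_at_density(R, 0.19)
        assert net.n_edges == 433  # round(0.19 * 68 * 67 / 2)
        assert net.k_nonzero == 866
        assert net.density == pytest.approx(866 / (68 * 67))

    def test_negative_correlations_never_retained(self):
        r = -0.5 * np.ones((5, 5))
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = 0.4
        R = CorrelationMatrix(regions=list("abcde"), r=r, n_subjects=10)
        with pytest.warns(UserWarning, match="positive correlations"):
            net = threshold_at_density(R, 0.5)
        assert net.n_edges == 1
        assert net.density_warning

    def test_symmetry_zero_diagonal_and_density_field(self):
        R = random_correlation(np.random.default_rng(5), n=30)
        for d in (0.05, 0.19, 0.4):
            net = threshold_at_density(R, d)
            np.testing.assert_array_equal(net.adjacency, net.adjacency.T)
            assert np.diag(net.adjacency).sum() == 0
            assert net.density == pytest.approx(
                net.k_nonzero / (30 * 29)
            )
            # achieved density within one edge of requested
            assert abs(net.density - d) <= 1 / (30 * 29 / 2)

    def test_tie_break_is_deterministic(self):
        r = np.zeros((4, 4))
        np.fill_diagonal(r, 1.0)
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            r[i, j] = r[j, i] = 0.5  # four-way tie
        R = CorrelationMatrix(regions=list("abcd"), r=r, n_subjects=10)
        net = threshold_at_density(R, 1 / 6)  # E = 1
        assert [tuple(e) for e in net.edges()] == [(0, 1)]

    def test_invalid_density_rejected(self):
        R = random_correlation(np.random.default_rng(0), n=5)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_at_density(R, bad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_transform_of_positive_r(self, seed):
        rng = np.random.default_rng(seed)
        R = random_correlation(rng, n=12)
        transformed = np.sign(R.r) * np.abs(R.r) ** 3  # strictly monotone on r>0
        np.fill_diagonal(transformed, 1.0)
        R2 = CorrelationMatrix(regions=R.regions, r=transformed, n_subjects=50)
        for d in (0.1, 0.3):
            e1 = threshold_at_density(R, d).edges()
            e2 = threshold_at_density(R2, d).edges()
            np.testing.assert_array_equal(e1, e2)


class TestDensityGrid:
    def test_default_grid_has_36_points(self):
        grid = DensityGrid()
        assert len(grid) == 36
        assert grid.values[0] == pytest.approx(0.05)
        assert grid.values[-1] == pytest.approx(0.40)
        assert np.all(np.diff(grid.values) > 0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            DensityGrid(0.4, 0.05, 0.01)
        with pytest.raises(ValueError):
            DensityGrid(0.05, 0.4, -0.01)


class TestBinarizeOverGrid:
    def test_nested_edge_sets_and_agreement(self):
        R = random_correlation(np.random.default_rng(8))
        grid = DensityGrid(0.05, 0.40, 0.05)
        nets = binarize_over_grid(R, grid)
        assert len(nets) == len(grid)
        prev = None
        for net, d in zip(nets, grid.values):
            single = threshold_at_density(R, d)
            np.testing.assert_array_equal(net.adjacency, single.adjacency)
            edges = {tuple(e) for e in net.edges()}
            if prev is not None:
                assert prev <= edges
            prev = edges
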