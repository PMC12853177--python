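"""Diversity indices, Bray-Curtis/PCoA, correlations, horizon transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanomon.stats import (
    DistanceMatrix,
    bray_curtis,
    beta_diversity_matrix,
    correlate,
    horizon_series,
    pcoa,
    shannon,
    simpson,
    taxon_metadata_correlations,
)
from nanomon.store import TimeSeriesTable


def _table(counts, columns=None, sample_ids=None):
    counts = np.asarray(counts, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(counts.shape[0])]
    columns = columns or [f"t{j}" for j in range(counts.shape[1])]
    data = pd.DataFrame(counts, index=sample_ids, columns=columns)
    ts = pd.Series(
        pd.date_range("2024-01-01", periods=len(sample_ids), tz="UTC"), index=sample_ids
    )
    return TimeSeriesTable(data=data, timestamps=ts)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "p,expected",
        [([1.0], 0.0), ([0.25] * 4, 2.0), ([0.5, 0.25, 0.25], 1.5)],
    )
    def test_shannon_closed_forms(self, p, expected):
        assert shannon(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "p,expected", [([1.0], 0.0), ([0.25] * 4, 0.75), ([0.5, 0.5], 0.5)]
    )
    def test_simpson_closed_forms(self, p, expected):
        assert simpson(p) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_vector_errors(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])
        with pytest.raises(ValueError):
            simpson([0.0, 0.0])

    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=20).filter(lambda v: sum(v) > 0))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_uniform_maximum(self, values):
        s = sum(1 for v in values if v > 0)
        h = shannon(values)
        d = simpson(values)
        assert -1e-9 <= h <= np.log2(s) + 1e-9
        assert -1e-9 <= d <= 1 - 1 / s + 1e-9

    def test_uniform_attains_maximum(self):
        assert shannon([1 / 8] * 8) == pytest.approx(3.0, abs=1e-12)
        assert simpson([1 / 8] * 8) == pytest.approx(1 - 1 / 8, abs=1e-12)


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([2.0, 2.0], [1.0, 3.0]) == pytest.approx(0.25, abs=1e-12)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])

    @given(
        st.lists(st.floats(0.0, 50.0), min_size=2, max_size=10),
        st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, u, data):
        v = data.draw(
            st.lists(st.floats(0.0, 50.0), min_size=len(u), max_size=len(u))
        )
        if sum(u) + sum(v) == 0:
            return
        d = bray_curtis(u, v)
        assert d == bray_curtis(v, u)
        assert -1e-12 <= d <= 1 + 1e-12

    def test_matrix_matches_pairwise_calls(self):
        table = _table([[5.0, 1.0, 0.0], [2.0, 2.0, 2.0], [0.0, 1.0, 5.0]])
        matrix = beta_diversity_matrix(table)
        X = table.data.to_numpy()
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else bray_curtis(X[i], X[j])
                assert matrix.values[i, j] == pytest.approx(expected)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 0.0)

    def test_duplicate_samples_distance_zero(self):
        table = _table([[5.0, 1.0], [5.0, 1.0]])
        assert beta_diversity_matrix(table).values[0, 1] == 0.0

    def test_agrees_with_scipy(self):
        from scipy.spatial.distance import braycurtis as scipy_bc

        rng = np.random.default_rng(3)
        for _ in range(20):
            u, v = rng.uniform(0, 10, size=(2, 6))
            assert bray_curtis(u, v) == pytest.approx(scipy_bc(u, v), abs=1e-12)


class TestPCoA:
    def test_two_points(self):
        D = DistanceMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]), ["a", "b"])
        result = pcoa(D)
        coords = result.coordinates["PC1"].to_numpy()
        assert sorted(coords) == pytest.approx([-2.0, 2.0])
        assert result.eigenvalues[0] == pytest.approx(8.0)

    def test_equilateral_triangle(self):
        D = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ["a", "b", "c"])
        result = pcoa(D)
        assert result.eigenvalues[0] == pytest.approx(result.eigenvalues[1], abs=1e-9)
        coords = result.coordinates.to_numpy()[:, :2]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)

    def test_coincident_points(self):
        D = DistanceMatrix(np.zeros((2, 2)), ["a", "b"])
        result = pcoa(D)
        assert np.allclose(result.coordinates.to_numpy(), 0.0)

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(42)
        points = rng.normal(size=(6, 3))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        result = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(6)]))
        coords = result.coordinates.to_numpy()
        reconstructed = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(reconstructed, D, atol=1e-6)

    def test_eigenvalues_nonincreasing_and_nonnegative(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(5, 2))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        result = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(5)]))
        assert (np.diff(result.eigenvalues) <= 1e-12).all()
        assert (result.eigenvalues >= 0).all()

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(11)
        X = rng.uniform(0, 5, size=(5, 4))
        n = 5
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    D[i, j] = bray_curtis(X[i], X[j])
        ours = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(n)]))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        pos = theirs.eigvals.to_numpy() > 1e-9
        assert ours.eigenvalues[: pos.sum()] == pytest.approx(
            theirs.eigvals.to_numpy()[pos], abs=1e-9
        )


def _brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = sum((a - mx) ** 2 for a in x) ** 0.5
    sy = sum((b - my) ** 2 for b in y) ** 0.5
    return cov / (sx * sy)


def _brute_ranks(x):
    out = []
    for a in x:
        less = sum(1 for b in x if b < a)
        equal = sum(1 for b in x if b == a)
        out.append(less + (equal + 1) / 2)
    return out


def _brute_kendall_tau_b(x, y):
    c = d = tx = ty = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    return (c - d) / ((c + d + tx) * (c + d + ty)) ** 0.5


class TestCorrelate:
    def test_perfect_linear(self):
        res = correlate([1, 2, 3, 4], [2, 4, 6, 8], "pearson")
        assert res.coefficient == pytest.approx(1.0)

    def test_full_reversal(self):
        assert correlate([1, 2, 3], [3, 2, 1], "kendall").coefficient == pytest.approx(-1.0)
        assert correlate([1, 2, 3], [3, 2, 1], "spearman").coefficient == pytest.approx(-1.0)

    def test_kendall_pair_counts(self):
        res = correlate([1, 2, 3], [1, 3, 2], "kendall")
        assert (res.concordant, res.discordant) == (2, 1)
        assert res.coefficient == pytest.approx(1 / 3, abs=1e-12)

    def test_kendall_printed_mode_excludes_ties(self):
        x, y = [1, 2, 3, 4], [1, 1, 2, 3]
        res = correlate(x, y, "kendall", kendall_tie_mode="printed")
        # pair (1,2) tied in y is excluded: C=5, D=0
        assert (res.concordant, res.discordant) == (5, 0)
        assert res.coefficient == pytest.approx(1.0)
        assert res.tie_mode == "printed"

    def test_zero_variance_flagged_missing(self):
        res = correlate([1, 1, 1], [1, 2, 3], "pearson")
        assert res.missing

    def test_paired_missing_values_dropped(self):
        res = correlate([1, 2, np.nan, 4], [2, 4, 5, 8], "pearson")
        assert res.n == 3 and res.coefficient == pytest.approx(1.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [2, 1], "pearson")

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 10, size=20).astype(float)  # ties likely
        y = rng.integers(0, 10, size=20).astype(float)
        res = correlate(x, y, "spearman")
        via_ranks = correlate(res.ranks_x, res.ranks_y, "pearson")
        assert res.coefficient == pytest.approx(via_ranks.coefficient, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            x = rng.integers(0, 8, size=n).astype(float)
            y = rng.integers(0, 8, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert correlate(x, y, "pearson").coefficient == pytest.approx(
                _brute_pearson(x, y), abs=1e-9
            )
            assert correlate(x, y, "spearman").coefficient == pytest.approx(
                _brute_pearson(_brute_ranks(x), _brute_ranks(y)), abs=1e-9
            )
            assert correlate(x, y, "kendall").coefficient == pytest.approx(
                _brute_kendall_tau_b(x, y), abs=1e-9
            )

    def test_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(77)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        assert correlate(x, y, "pearson").coefficient == pytest.approx(
            sps.pearsonr(x, y).statistic, abs=1e-12
        )
        assert correlate(x, y, "spearman").coefficient == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12
        )
        assert correlate(x, y, "kendall").coefficient == pytest.approx(
            sps.kendalltau(x, y).statistic, abs=1e-12
        )


class TestTaxonMetadataCorrelations:
    def _setup(self):
        rng = np.random.default_rng(4)
        counts = rng.uniform(1, 100, size=(8, 3))
        table = _table(counts, columns=["A", "B", "C"])
        meta = pd.DataFrame(
            {
                "self": counts[:, 0],  # identical to taxon A's series
                "temp": rng.normal(20, 2, size=8),
                "constant": np.full(8, 3.0),
            },
            index=table.sample_ids,
        )
        return table, meta

    def test_self_correlation_is_one(self):
        table, meta = self._setup()
        result = taxon_metadata_correlations(table, meta, "pearson")
        assert result.coefficients.loc["A", "self"] == pytest.approx(1.0)

    def test_constant_variable_flagged_missing(self):
        table, meta = self._setup()
        result = taxon_metadata_correlations(table, meta, "pearson")
        assert np.isnan(result.coefficients["constant"]).all()

    def test_injected_positive_link_detected(self):
        rng = np.random.default_rng(15)
        counts = rng.uniform(1, 100, size=(12, 4))
        table = _table(counts)
        meta = pd.DataFrame(
            {"driver": 2.0 * counts[:, 2] + rng.normal(0, 1, size=12)},
            index=table.sample_ids,
        )
        result = taxon_metadata_correlations(table, meta, "pearson")
        assert result.coefficients.loc["t2", "driver"] > 0.9

    def test_shuffled_pairing_decorrelates(self):
        rng = np.random.default_rng(16)
        counts = rng.uniform(1, 100, size=(40, 20))
        table = _table(counts)
        meta = pd.DataFrame(
            {"noise": rng.permutation(counts[:, 0])}, index=table.sample_ids
        )
        result = taxon_metadata_correlations(table, meta, "pearson")
        assert np.abs(result.coefficients["noise"]).mean() < 0.25

    def test_no_shared_samples_errors(self):
        table, _ = self._setup()
        meta = pd.DataFrame({"x": [1.0]}, index=["elsewhere"])
        with pytest.raises(ValueError):
            taxon_metadata_correlations(table, meta)


class TestHorizonSeries:
    def test_constant_series_all_zero(self):
        for mode in ("vs_mean", "vs_previous"):
            series = horizon_series([5.0, 5.0, 5.0], mode=mode)
            assert np.allclose(series.deviations, 0.0)
            assert (series.band_index == 0).all()

    def test_vs_mean_worked_example(self):
        series = horizon_series([1.0, 2.0, 3.0], mode="vs_mean")
        assert series.deviations.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_vs_previous_worked_example(self):
        series = horizon_series([1.0, 2.0, 3.0], mode="vs_previous")
        assert series.deviations.tolist() == pytest.approx([0.0, 1.0, 1.0])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_vs_mean_deviations_sum_to_zero(self, values):
        series = horizon_series(values, mode="vs_mean")
        assert abs(series.deviations.sum()) < 1e-9 * max(1.0, np.abs(values).sum())

    def test_band_boundaries_slice_peak(self):
        series = horizon_series([0.0, 8.0, 0.0, -4.0], mode="vs_mean", n_bands=4)
        peak = np.abs(series.deviations).max()
        assert series.band_boundaries.tolist() == pytest.approx(
            [peak / 4, peak / 2, 3 * peak / 4, peak]
        )
        assert series.band_index.max() <= 4 and series.band_index.min() >= -4

    def test_tidy_frame(self):
        frame = horizon_series([1.0, 2.0], mode="vs_mean").to_frame(taxon="A")
        assert list(frame.columns) == ["taxon", "timestamp", "deviation", "band"]
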