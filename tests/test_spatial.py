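"""Spatial statistics, the permutation engine, and the correlation matrix."""

import numpy as np
import pytest

from tespatial import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    PermutationConfig,
    absolute_distance_statistic,
    build_correlation_matrix,
    jaccard_statistic,
    permutation_test,
    permute_queries,
    relative_distance_statistic,
    relative_distance_values,
    run_spatial_tests,
)
from tespatial.spatial import summarize_test


def iset(layout, *triples):
    return IntervalSet(layout, [GenomicInterval(c, s, e) for c, s, e in triples])


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 100_000})


class TestJaccard:
    def test_partial_overlap(self, layout):
        a = iset(layout, ("chr1", 0, 100)).merge()
        b = iset(layout, ("chr1", 50, 150)).merge()
        assert jaccard_statistic(a, b) == pytest.approx(50 / 150)

    def test_identity_is_one_disjoint_is_zero(self, layout):
        a = iset(layout, ("chr1", 0, 100)).merge()
        b = iset(layout, ("chr1", 200, 300)).merge()
        assert jaccard_statistic(a, a) == 1.0
        assert jaccard_statistic(a, b) == 0.0
        assert jaccard_statistic(a, b) == jaccard_statistic(b, a)

    def test_both_empty_raises(self, layout):
        empty = IntervalSet(layout)
        with pytest.raises(ValueError, match="empty"):
            jaccard_statistic(empty, empty)


class TestAbsoluteDistance:
    def test_all_overlapping_gives_zero(self, layout):
        q = iset(layout, ("chr1", 10, 20), ("chr1", 50, 60))
        r = iset(layout, ("chr1", 0, 1000)).merge()
        assert absolute_distance_statistic(q, r) == 0.0

    def test_mean_of_per_query_gaps(self, layout):
        q = iset(layout, ("chr1", 100, 200), ("chr1", 400, 500))
        r = iset(layout, ("chr1", 250, 300)).merge()  # gaps 50 and 100
        assert absolute_distance_statistic(q, r) == pytest.approx(75.0)

    def test_no_shared_chromosome_raises(self):
        lay = GenomeLayout({"chr1": 1_000, "chr2": 1_000})
        q = iset(lay, ("chr2", 0, 10))
        r = iset(lay, ("chr1", 0, 10)).merge()
        with pytest.raises(ValueError, match="chromosome"):
            absolute_distance_statistic(q, r)


class TestRelativeDistance:
    def test_coincident_midpoint_gives_zero(self, layout):
        q = iset(layout, ("chr1", 90, 110))  # midpoint 100
        r = iset(layout, ("chr1", 95, 105), ("chr1", 495, 505)).merge()
        assert relative_distance_values(q, r)[0] == 0.0

    def test_halfway_midpoint_gives_half(self, layout):
        q = iset(layout, ("chr1", 290, 310))  # midpoint 300
        r = iset(layout, ("chr1", 95, 105), ("chr1", 495, 505)).merge()
        assert relative_distance_values(q, r)[0] == 0.5

    def test_queries_outside_reference_span_skipped(self, layout):
        q = iset(layout, ("chr1", 0, 10), ("chr1", 290, 310))
        r = iset(layout, ("chr1", 95, 105), ("chr1", 495, 505)).merge()
        assert relative_distance_values(q, r).size == 1

    def test_statistic_is_mean_and_empty_raises(self):
        assert relative_distance_statistic(np.array([0.0, 0.5])) == 0.25
        assert relative_distance_statistic(np.zeros(5)) == 0.0
        with pytest.raises(ValueError):
            relative_distance_statistic(np.array([]))

    def test_uniform_queries_mean_quarter_monte_carlo(self):
        """Under uniform placement the mean converges to 0.25 (within 3 SE)."""
        lay = GenomeLayout({"chr1": 1_000_000})
        rng = np.random.default_rng(11)
        refs = iset(lay, *((("chr1",) + (s, s + 100)) for s in range(0, 1_000_000, 50_000))).merge()
        n = 100_000
        starts = rng.integers(0, lay["chr1"] - 10, size=n)
        q = IntervalSet.from_arrays(lay, {"chr1": (starts, starts + 10)}, validate=False)
        vals = relative_distance_values(q, refs)
        assert np.all((vals >= 0) & (vals <= 0.5))
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 0.25) < 3 * se


class TestPermuteQueries:
    def test_lengths_and_counts_preserved_within_bounds(self):
        lay = GenomeLayout({"chr1": 10_000, "chr2": 600})
        q = iset(lay, ("chr1", 0, 500), ("chr1", 900, 950), ("chr2", 0, 550))
        p = permute_queries(q, np.random.default_rng(0))
        for chrom in ("chr1", "chr2"):
            qs, qe = q.arrays(chrom)
            ps, pe = p.arrays(chrom)
            assert sorted((qe - qs).tolist()) == sorted((pe - ps).tolist())
            assert np.all(ps >= 0) and np.all(pe <= lay[chrom])

    def test_reproducible_from_seed(self, layout):
        q = iset(layout, ("chr1", 0, 500), ("chr1", 900, 950))
        p1 = permute_queries(q, np.random.default_rng(42))
        p2 = permute_queries(q, np.random.default_rng(42))
        assert p1 == p2

    def test_interval_longer_than_chromosome_raises(self):
        lay = GenomeLayout({"chr1": 100})
        exact = IntervalSet.from_arrays(lay, {"chr1": (np.array([0]), np.array([100]))})
        permute_queries(exact, np.random.default_rng(0))  # exactly fits: fine
        bad = IntervalSet.from_arrays(
            GenomeLayout({"chr1": 50}), {"chr1": (np.array([0]), np.array([51]))}, validate=False
        )
        with pytest.raises(ValueError, match="longer"):
            permute_queries(bad, np.random.default_rng(0))


class TestPValueAndDirection:
    def test_observed_beyond_all_nulls_is_extreme_tail(self):
        null = np.arange(100, dtype=float)
        res = summarize_test("jaccard", 1e6, null, alpha=0.05, larger_is_attraction=True)
        assert res.p_value == pytest.approx(2 / 101)
        assert res.direction == "attraction"
        res = summarize_test("jaccard", -1e6, null, alpha=0.05, larger_is_attraction=True)
        assert res.direction == "repulsion"

    def test_distance_sign_convention_flipped(self):
        null = np.arange(100, dtype=float)
        res = summarize_test("absolute_distance", -1e6, null, alpha=0.05, larger_is_attraction=False)
        assert res.direction == "attraction"

    def test_observed_at_null_median_not_significant(self):
        null = np.arange(101, dtype=float)
        res = summarize_test("jaccard", 50.0, null, alpha=0.05, larger_is_attraction=True)
        assert res.direction == "not_significant"
        assert res.p_value == 1.0


class TestPermutationTest:
    def test_results_bit_reproducible(self, layout):
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 99_000, size=300)
        q = IntervalSet.from_arrays(layout, {"chr1": (starts, starts + 200)}, validate=False)
        r = iset(layout, ("chr1", 10_000, 20_000), ("chr1", 60_000, 70_000)).merge()
        cfg = PermutationConfig(n_permutations=30, seed=5)
        r1 = permutation_test(q, r, "jaccard", cfg)
        r2 = permutation_test(q, r, "jaccard", cfg)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.p_value == r2.p_value

    def test_shared_permutations_match_single_test(self, layout):
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 99_000, size=200)
        q = IntervalSet.from_arrays(layout, {"chr1": (starts, starts + 150)}, validate=False)
        r = iset(layout, ("chr1", 30_000, 45_000), ("chr1", 70_000, 80_000)).merge()
        cfg = PermutationConfig(n_permutations=20, seed=9)
        combined = run_spatial_tests(q, r, cfg)
        single = permutation_test(q, r, "jaccard", cfg)
        assert np.array_equal(combined["jaccard"].null_values, single.null_values)

    def test_custom_statistic_requires_sign(self, layout):
        q = iset(layout, ("chr1", 0, 100))
        r = iset(layout, ("chr1", 50, 150)).merge()
        with pytest.raises(ValueError, match="larger_is_attraction"):
            permutation_test(q, r, lambda a, b: 0.0, PermutationConfig(n_permutations=5))


class TestCorrelationMatrix:
    def _groups_and_features(self, n_per_group=50):
        lay = GenomeLayout({"chr1": 200_000})
        rng = np.random.default_rng(3)
        groups = {}
        for te_class in ("SINE", "LINE"):
            for age_bin in ("young", "old"):
                starts = rng.integers(0, 199_000, size=n_per_group)
                groups[(te_class, age_bin)] = IntervalSet.from_arrays(
                    lay, {"chr1": (starts, starts + 200)}, validate=False)
        feats = {
            "transcript": iset(lay, ("chr1", 10_000, 30_000), ("chr1", 100_000, 120_000)).merge(),
            "cgi": IntervalSet(lay),
        }
        return groups, feats

    def test_small_groups_and_empty_features_not_tested(self):
        groups, feats = self._groups_and_features()
        with pytest.warns(UserWarning, match="empty"):
            m = build_correlation_matrix(
                groups, feats, PermutationConfig(n_permutations=10, seed=1),
                min_group_size=51, species="sp")
        df = m.to_dataframe()
        assert set(df["direction"]) == {"not_tested"}
        assert len(df) == len(groups) * len(feats) * 3

    def test_cell_count_and_tsv_determinism(self, tmp_path):
        groups, feats = self._groups_and_features()
        cfg = PermutationConfig(n_permutations=10, seed=1)
        with pytest.warns(UserWarning):
            m1 = build_correlation_matrix(groups, feats, cfg, min_group_size=10, species="sp")
            m2 = build_correlation_matrix(groups, feats, cfg, min_group_size=10, species="sp")
        assert len(m1.to_dataframe()) == 2 * 2 * 2 * 3
        p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        m1.to_tsv(p1)
        m2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
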