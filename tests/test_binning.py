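import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from orthobin.binning import (
    BINS,
    Cutoffs,
    GeneSummary,
    assign_bins,
    average_replicates,
    bin_dataset,
    collapse_probes,
    percentile_rank,
    quantile_normalize,
)
from orthobin.errors import FormatError

from conftest import make_annotation, make_matrix


def oracle_percentiles(values):
    """Brute-force pairwise strict-lower-count percentile."""
    values = list(values)
    n = len(values)
    return [100.0 * sum(1 for w in values if w < v) / n for v in values]


def oracle_bin(p, cutoffs=(10.0, 50.0, 90.0)):
    low, mid, high = cutoffs
    if p >= high:
        return "H"
    if p >= mid:
        return "M"
    if p >= low:
        return "L"
    return "VL"


class TestQuantileNormalize:
    def test_hand_oracle_two_columns(self):
        m = make_matrix(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        expected = np.array([[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]])
        np.testing.assert_allclose(out.values, expected)

    def test_identical_columns_fixed_point(self):
        m = make_matrix(np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_single_sample_identity(self):
        m = make_matrix(np.array([[4.0], [2.0], [9.0]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_ties_get_mean_of_target_values(self):
        # column 1 has a 2-way tie at the bottom; they share the mean of the
        # two lowest reference values
        m = make_matrix(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
        out = quantile_normalize(m)
        ref = (np.sort(m.values[:, 0]) + np.sort(m.values[:, 1])) / 2
        assert out.values[0, 0] == out.values[1, 0] == pytest.approx(ref[:2].mean())
        assert out.values[2, 0] == pytest.approx(ref[2])

    def test_missing_entries_stay_missing(self, rng):
        X = rng.normal(8, 2, size=(50, 4))
        X[rng.random(X.shape) < 0.1] = np.nan
        # keep at least one finite value per row
        X[np.isnan(X).all(axis=1), 0] = 1.0
        m = make_matrix(X)
        out = quantile_normalize(m)
        np.testing.assert_array_equal(np.isnan(out.values), np.isnan(X))

    def test_all_missing_sample_errors(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(FormatError, match="S1"):
            quantile_normalize(make_matrix(X))

    def test_identical_sorted_vectors_property(self, rng):
        X = rng.normal(8, 2, size=(200, 5))
        out = quantile_normalize(make_matrix(X)).values
        first = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), first, atol=1e-9)

    def test_within_sample_rank_order_preserved(self, rng):
        X = rng.normal(0, 3, size=(150, 6))
        out = quantile_normalize(make_matrix(X)).values
        for j in range(6):
            rho = stats.spearmanr(X[:, j], out[:, j]).statistic
            assert rho == pytest.approx(1.0)


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        m = make_matrix(np.array([[4.0, 6.0]]))
        assert average_replicates(m).iloc[0] == 5.0

    def test_missing_excluded(self):
        m = make_matrix(np.array([[4.0, np.nan]]))
        assert average_replicates(m).iloc[0] == 4.0

    def test_single_sample_identity(self):
        m = make_matrix(np.array([[4.0], [7.0]]))
        pd.testing.assert_series_equal(
            average_replicates(m),
            pd.Series([4.0, 7.0], index=["P0", "P1"]),
        )


class TestPercentileRank:
    def test_ten_distinct_values(self):
        p = percentile_rank(np.arange(10.0))
        assert p[0] == 0.0
        assert p[-1] == 90.0

    def test_ties_share_strict_lower_percentile(self):
        p = percentile_rank(np.array([1.0, 1.0, 2.0]))
        np.testing.assert_allclose(p, [0.0, 0.0, 200.0 / 3.0])

    def test_top_decile_count_n100(self):
        p = percentile_rank(np.arange(100.0))
        assert int((p >= 90).sum()) == 10

    def test_empty_errors(self):
        with pytest.raises(FormatError):
            percentile_rank(np.array([]))

    def test_nonfinite_errors(self):
        with pytest.raises(FormatError):
            percentile_rank(np.array([1.0, np.inf]))

    def test_small_input_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            percentile_rank(np.arange(20.0))

    @given(
        st.lists(
            st.integers(min_value=-50, max_value=50).map(float),
            min_size=1,
            max_size=200,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle(self, values):
        np.testing.assert_allclose(
            percentile_rank(np.array(values)), oracle_percentiles(values)
        )

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_range_invariant(self, values):
        p = percentile_rank(np.array(values))
        assert ((p >= 0) & (p < 100)).all()


class TestAssignBins:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (95.0, "H"),
            (50.0, "M"),
            (9.9, "VL"),
            (90.0, "H"),  # boundary: closed at lower edge
            (10.0, "L"),
            (0.0, "VL"),
            (89.999, "M"),
            (49.999, "L"),
        ],
    )
    def test_cutoff_boundaries(self, p, expected):
        assert assign_bins(np.array([p]))[0] == expected

    def test_thousand_distinct_means_bin_sizes(self):
        p = percentile_rank(np.arange(1000.0))
        bins = assign_bins(p)
        counts = {b: int((bins == b).sum()) for b in BINS}
        assert counts == {"VL": 100, "L": 400, "M": 400, "H": 100}

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            assign_bins(np.array([100.0]))

    @given(st.lists(st.floats(0, 99.999), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_ifchain_oracle(self, percentiles):
        got = assign_bins(np.array(percentiles))
        assert list(got) == [oracle_bin(p) for p in percentiles]

    def test_custom_cutoffs(self):
        cut = Cutoffs(5, 50, 95)
        assert assign_bins(np.array([94.0]), cut)[0] == "M"
        assert assign_bins(np.array([95.0]), cut)[0] == "H"

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(FormatError):
            Cutoffs(50, 10, 90)


def grid_means(n):
    """n distinct probe means spread over a tie-free grid."""
    return np.linspace(0.0, 10.0, n)


class TestCollapseProbes:
    def setup_probes(self, extra):
        """100 background single-probe genes plus extra probes near chosen bins."""
        means = {f"BG{i}": v for i, v in enumerate(grid_means(100))}
        means.update(extra)
        series = pd.Series(means)
        entries = [(f"BG{i}", f"BGGENE{i}", f"NM_{i}") for i in range(100)]
        return series, entries

    def quantile_value(self, pct):
        # a value whose strict-lower percentile among the background grid is pct
        return np.quantile(grid_means(100), pct / 100.0) + 1e-6

    def test_adjacent_bins_retained(self):
        # probes at ~95th and ~70th percentile: provisional H and M, span 1
        series, entries = self.setup_probes(
            {"X1": self.quantile_value(95), "X2": self.quantile_value(70)}
        )
        entries += [("X1", "DUPGENE", "NM_900"), ("X2", "DUPGENE", "NM_901")]
        frame, dropped = collapse_probes(series, make_annotation(entries))
        assert "DUPGENE" in frame.index
        assert dropped == set()
        expected = (series["X1"] + series["X2"]) / 2
        assert frame.loc["DUPGENE", "mean_log2"] == pytest.approx(expected)
        assert frame.loc["DUPGENE", "n_probes"] == 2

    def test_nonadjacent_bins_dropped(self):
        # provisional H together with L: span 2 -> inconsistent
        series, entries = self.setup_probes(
            {"X1": self.quantile_value(95), "X2": self.quantile_value(30)}
        )
        entries += [("X1", "DUPGENE", "NM_900"), ("X2", "DUPGENE", "NM_901")]
        frame, dropped = collapse_probes(series, make_annotation(entries))
        assert dropped == {"DUPGENE"}
        assert "DUPGENE" not in frame.index

    def test_all_adjacent_pairs_enumerated(self):
        """Enumerate every bin pair; only adjacent (or equal) pairs survive."""
        centers = {"VL": 5, "L": 30, "M": 70, "H": 95}
        for (ba, pa), (bb, pb) in itertools.product(centers.items(), repeat=2):
            series, entries = self.setup_probes(
                {"X1": self.quantile_value(pa), "X2": self.quantile_value(pb)}
            )
            entries += [("X1", "G", "NM_900"), ("X2", "G", "NM_901")]
            _, dropped = collapse_probes(series, make_annotation(entries))
            span = abs(BINS.index(ba) - BINS.index(bb))
            assert (dropped == {"G"}) == (span > 1), (ba, bb)

    def test_single_probe_identity(self):
        series, entries = self.setup_probes({})
        frame, dropped = collapse_probes(series, make_annotation(entries))
        assert len(frame) == 100 and not dropped
        assert frame.loc["BGGENE7", "mean_log2"] == series["BG7"]
        assert (frame["n_probes"] == 1).all()

    def test_controls_and_unannotated_excluded(self):
        series, entries = self.setup_probes({"C1": 5.0, "E1": 5.0})
        entries += [("C1", "", "", True), ("E1", "", "NM_999")]
        frame, _ = collapse_probes(series, make_annotation(entries))
        assert len(frame) == 100

    def test_missing_probe_annotation_errors(self):
        series = pd.Series({"P1": 1.0})
        with pytest.raises(FormatError, match="P1"):
            collapse_probes(series, make_annotation([]))

    def test_curated_flag_any_probe(self):
        series, entries = self.setup_probes(
            {"X1": self.quantile_value(70), "X2": self.quantile_value(72)}
        )
        entries += [("X1", "G", "XR_900"), ("X2", "G", "NM_901")]
        frame, _ = collapse_probes(series, make_annotation(entries))
        assert bool(frame.loc["G", "has_curated_accession"])

    def test_permutation_invariance(self, rng):
        series, entries = self.setup_probes(
            {"X1": self.quantile_value(70), "X2": self.quantile_value(95)}
        )
        entries += [("X1", "G", "NM_900"), ("X2", "G", "NM_901")]
        ann = make_annotation(entries)
        frame1, dropped1 = collapse_probes(series, ann)
        shuffled = series.sample(frac=1.0, random_state=7)
        frame2, dropped2 = collapse_probes(shuffled, ann)
        pd.testing.assert_frame_equal(frame1.sort_index(), frame2.sort_index())
        assert dropped1 == dropped2

    def test_case_insensitive_symbol_collapse(self):
        series, entries = self.setup_probes(
            {"X1": self.quantile_value(70), "X2": self.quantile_value(72)}
        )
        entries += [("X1", "Ace", "NM_900"), ("X2", "ACE", "NM_901")]
        frame, _ = collapse_probes(series, make_annotation(entries))
        assert frame.loc["ACE", "n_probes"] == 2


class TestBinDataset:
    def test_pipeline_on_tie_free_grid(self, rng):
        n = 1000
        means = grid_means(n)
        X = np.column_stack([1.1 * means + 0.3, 0.9 * means - 0.2])
        probes = [f"P{i}" for i in range(n)]
        m = make_matrix(X, probes=probes)
        ann = make_annotation([(f"P{i}", f"G{i}", f"NM_{i}") for i in range(n)])
        binned = bin_dataset(m, ann)
        assert binned.bin_counts() == {"VL": 100, "L": 400, "M": 400, "H": 100}

    def test_inconsistent_duplicate_routed_to_dropped(self):
        n = 100
        means = grid_means(n)
        probes = [f"P{i}" for i in range(n)] + ["PD"]
        X = np.append(means, means[95])[:, None]  # duplicate of a high gene
        m = make_matrix(X, probes=probes)
        entries = [(f"P{i}", f"G{i}", f"NM_{i}") for i in range(n)]
        entries += [("PD", "G20", "NM_777")]  # G20 sits near the 20th pct: L vs H
        binned = bin_dataset(m, make_annotation(entries))
        assert "G20" in binned.dropped_inconsistent
        assert "G20" not in binned.genes

    def test_rerank_of_own_gene_means_is_idempotent(self):
        n = 200
        means = grid_means(n)
        probes = [f"P{i}" for i in range(n)]
        m = make_matrix(means[:, None], probes=probes)
        ann = make_annotation([(f"P{i}", f"G{i}", f"NM_{i}") for i in range(n)])
        first = bin_dataset(m, ann)
        gene_means = np.array([first.genes[f"G{i}"].mean_log2 for i in range(n)])
        m2 = make_matrix(gene_means[:, None], probes=probes)
        second = bin_dataset(m2, ann)
        for i in range(n):
            assert second.genes[f"G{i}"].bin == first.genes[f"G{i}"].bin

    def test_monotonicity_raising_one_mean_never_lowers_bin(self, rng):
        n = 120
        base = np.sort(rng.normal(8, 2, n))
        probes = [f"P{i}" for i in range(n)]
        ann = make_annotation([(f"P{i}", f"G{i}", f"NM_{i}") for i in range(n)])
        target = 30
        before = bin_dataset(make_matrix(base[:, None], probes=probes), ann)
        for bump in (0.5, 2.0, 8.0):
            raised = base.copy()
            raised[target] += bump
            after = bin_dataset(make_matrix(raised[:, None], probes=probes), ann)
            assert BINS.index(after.genes[f"G{target}"].bin) >= BINS.index(
                before.genes[f"G{target}"].bin
            )


def test_gene_summary_bin_percentile_consistency_enforced():
    with pytest.raises(FormatError, match="inconsistent"):
        GeneSummary("G", 1.0, percentile=95.0, bin="M")
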