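import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakalign import (AlignmentParams, SimConfig, ValidationFailure, align,
                       best_shift, full_align, generate, merge_rows,
                       partial_align, remove_blanks, remove_singletons,
                       score_shift, select_reference, to_matrix)

from conftest import make_dataset, make_matrix


class TestParams:
    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(max_diff_peak2mean=-0.01)

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(shift_step=0.0)

    def test_warns_when_a_not_below_b(self):
        with pytest.warns(UserWarning, match="min_diff_peak2peak"):
            AlignmentParams(max_diff_peak2mean=0.08, min_diff_peak2peak=0.08)


class TestSelectReference:
    def test_identical_samples_tie_break_lexicographic(self):
        ds = make_dataset({"B": [1.0, 2.0], "A": [1.0, 2.0],
                           "C": [1.0, 2.0]})
        assert select_reference(ds) == "A"

    def test_central_sample_beats_sparse_outlier(self):
        # A,B identical; C holds a single off-grid peak.  Per-pair mean
        # deviations: A->B 0, A->C 0.5 (median 0.25); C->A = C->B = 0.5.
        ds = make_dataset({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [1.5]})
        assert select_reference(ds) == "A"

    def test_blanks_excluded_from_candidacy(self):
        ds = make_dataset({"A": [1.0, 2.0], "B": [1.0, 2.0],
                           "C2": [1.0, 2.0]}, blanks=["C2"])
        assert select_reference(ds) in {"A", "B"}

    def test_needs_two_eligible_samples(self):
        ds = make_dataset({"A": [1.0], "C2": [1.0]}, blanks=["C2"])
        with pytest.raises(ValueError):
            select_reference(ds)


class TestScoreShift:
    @pytest.mark.parametrize("ref,query,shift,expected", [
        ([1.00, 2.00], [1.10, 2.10], -0.10, 0.0),
        ([1.00, 2.00], [1.10, 2.10], 0.0, 0.20),
        ([1.00], [1.00, 5.00], 0.0, 0.0),  # unique query peak is ignored
    ])
    def test_hand_computed_scores(self, ref, query, shift, expected):
        assert score_shift(np.array(ref), np.array(query),
                           shift) == pytest.approx(expected, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            score_shift(np.array([]), np.array([1.0]), 0.0)


class TestBestShift:
    def test_recovers_injected_offset(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert best_shift(ref, ref + 0.03, 0.05, 0.01) == pytest.approx(-0.03)

    def test_identical_lists_prefer_zero_shift(self):
        ref = np.array([1.0, 2.0])
        assert best_shift(ref, ref, 0.05, 0.01) == 0.0

    def test_result_bounded_by_window(self):
        ref = np.array([1.0, 2.0])
        s = best_shift(ref, ref + 0.20, 0.05, 0.01)
        assert abs(s) <= 0.05 + 1e-12


class TestFullAlign:
    def test_pure_drift_recovered_to_grid(self):
        ds, truth = generate(SimConfig(n_samples=6, jitter_sd=0.0,
                                       presence_prob=1.0,
                                       n_unique_per_sample=0, seed=5))
        ref = ds.sample_ids[0]
        shifted, shifts = full_align(ds, ref, window=0.08, step=0.01)
        for s in ds.sample_ids:
            relative_drift = truth.drifts[s] - truth.drifts[ref]
            assert shifts[s] == pytest.approx(-relative_drift, abs=0.005)

    def test_identical_samples_all_shifts_zero(self):
        ds = make_dataset({"A": [1.0, 2.0], "B": [1.0, 2.0]})
        _, shifts = full_align(ds, "A")
        assert shifts == {"A": 0.0, "B": 0.0}

    def test_preserves_counts_and_order(self, clean_sim):
        ds, _ = clean_sim
        shifted, _ = full_align(ds, select_reference(ds))
        for s in ds.sample_ids:
            assert shifted.n_peaks(s) == ds.n_peaks(s)
            rts = shifted.retention_times(s)
            assert np.all(np.diff(rts) > 0)

    def test_unknown_reference_rejected(self):
        ds = make_dataset({"A": [1.0]})
        with pytest.raises(ValueError):
            full_align(ds, "nope")


class TestPartialAlign:
    def test_late_peak_demoted_to_next_row(self):
        m = partial_align(make_matrix([[2.00, 2.01, 2.05]]), a=0.02)
        assert m.rt.tolist() == [[2.00, 2.01, 0.0], [0.0, 0.0, 2.05]]

    def test_early_peak_demotes_predecessors(self):
        m = partial_align(make_matrix([[2.05, 2.05, 2.00]]), a=0.02)
        assert m.rt.tolist() == [[0.0, 0.0, 2.00], [2.05, 2.05, 0.0]]

    def test_row_within_threshold_unchanged(self):
        m = partial_align(make_matrix([[2.00, 2.01, 2.02]]), a=0.02)
        assert m.rt.tolist() == [[2.00, 2.01, 2.02]]

    def test_measures_travel_with_their_peaks(self):
        m0 = make_matrix([[2.00, 2.01, 2.05]],
                         measures={"area": [[10.0, 20.0, 30.0]]})
        m = partial_align(m0, a=0.02)
        assert m.measures["area"].tolist() == [[10.0, 20.0, 0.0],
                                               [0.0, 0.0, 30.0]]

    def test_demotion_pushes_column_tail(self):
        # demoting 2.05 must push 3.00 (below it, same column) down too
        m = partial_align(make_matrix([[2.00, 2.01, 2.05],
                                       [3.00, 3.00, 3.00]]), a=0.02)
        assert m.rt.tolist() == [[2.00, 2.01, 0.0],
                                 [0.0, 0.0, 2.05],
                                 [3.00, 3.00, 3.00]]

    @given(st.lists(
        st.lists(st.floats(min_value=1.0, max_value=5.0,
                           allow_nan=False, width=32),
                 min_size=0, max_size=6),
        min_size=1, max_size=5),
        st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_conservation_and_column_order(self, columns, a):
        columns = [sorted(set(c)) for c in columns]
        ds = make_dataset({f"s{j}": col for j, col in enumerate(columns)})
        m = partial_align(to_matrix(ds), a=a)
        assert m.total_peaks() == sum(len(c) for c in columns)
        for j, col in enumerate(columns):
            nonzero = m.rt[:, j][m.rt[:, j] > 0]
            assert list(nonzero) == col  # order and values conserved


class TestMergeRows:
    def test_complementary_rows_merge(self):
        m = merge_rows(make_matrix([[2.00, 2.01, 0.0],
                                    [0.0, 0.0, 2.03]]), b=0.08)
        assert m.rt.tolist() == [[2.00, 2.01, 2.03]]

    def test_sample_in_both_rows_blocks_merge(self):
        m = merge_rows(make_matrix([[2.00, 2.01, 0.0],
                                    [2.02, 0.0, 2.03]]), b=0.08)
        assert m.n_rows == 2

    def test_b_zero_merges_nothing(self):
        m = merge_rows(make_matrix([[2.00, 2.01, 0.0],
                                    [0.0, 0.0, 2.00]]), b=0.0)
        assert m.n_rows == 2

    def test_merges_iterate_to_fixed_point(self):
        m = merge_rows(make_matrix([[2.00, 0.0, 0.0],
                                    [0.0, 2.01, 0.0],
                                    [0.0, 0.0, 2.02]]), b=0.08)
        assert m.n_rows == 1

    def test_all_zero_rows_deleted(self):
        m = merge_rows(make_matrix([[2.00, 2.01, 2.30],
                                    [0.0, 0.0, 0.0]]), b=0.0)
        assert m.n_rows == 1

    def test_merged_measures_combined(self):
        m0 = make_matrix([[2.00, 0.0], [0.0, 2.01]],
                         measures={"area": [[10.0, 0.0], [0.0, 20.0]]})
        m = merge_rows(m0, b=0.08)
        assert m.measures["area"].tolist() == [[10.0, 20.0]]


class TestFilters:
    def test_blank_shared_rows_and_columns_removed(self):
        m = make_matrix([[1.0, 1.0, 1.0],
                         [2.0, 2.0, 0.0],
                         [3.0, 0.0, 3.0]],
                        sample_ids=["A", "B", "C2"])
        kept, removed = remove_blanks(m, ["C2"])
        assert kept.sample_ids == ["A", "B"]
        assert kept.rt.tolist() == [[2.0, 2.0]]
        assert removed.n_rows == 2

    def test_empty_blank_removes_nothing(self):
        m = make_matrix([[1.0, 0.0], [2.0, 0.0]], sample_ids=["A", "C2"])
        kept, removed = remove_blanks(m, ["C2"])
        assert kept.n_rows == 2
        assert removed.n_rows == 0

    def test_all_rows_shared_gives_valid_empty_matrix(self):
        m = make_matrix([[1.0, 1.0]], sample_ids=["A", "C2"])
        kept, removed = remove_blanks(m, ["C2"])
        assert kept.n_rows == 0
        assert removed.n_rows == 1

    def test_unknown_blank_rejected(self):
        m = make_matrix([[1.0]])
        with pytest.raises(ValueError):
            remove_blanks(m, ["nope"])

    def test_singletons_removed_and_logged(self):
        m = make_matrix([[1.0, 0.0], [2.0, 2.0], [0.0, 3.0]])
        kept, removed = remove_singletons(m)
        assert kept.rt.tolist() == [[2.0, 2.0]]
        assert removed.n_rows == 2


class TestAlignPipeline:
    def test_single_sample_one_row_per_peak(self):
        ds = make_dataset({"A": [1.0, 2.0, 3.0]})
        result = align(ds)
        assert result.matrix.rt.tolist() == [[1.0], [2.0], [3.0]]

    def test_refuses_invalid_input(self):
        ds = make_dataset({"S1": [1.0]})
        ds.sample_ids = ["S1", "S1"]
        with pytest.raises(ValidationFailure):
            align(ds)

    def test_deterministic(self, clean_sim):
        ds, _ = clean_sim
        r1 = align(ds)
        r2 = align(ds)
        assert r1.reference == r2.reference
        assert r1.shifts == r2.shifts
        np.testing.assert_array_equal(r1.matrix.rt, r2.matrix.rt)

    def test_conservation_without_filters(self, clean_sim):
        ds, _ = clean_sim
        result = align(ds)
        assert result.matrix.total_peaks() == ds.total_peaks()

    def test_shift_invariants(self, clean_sim):
        ds, _ = clean_sim
        result = align(ds)
        assert result.shifts[result.reference] == 0.0
        assert all(abs(s) <= result.params.max_linear_shift + 1e-12
                   for s in result.shifts.values())

    def test_column_and_row_monotonicity(self, clean_sim):
        ds, _ = clean_sim
        m = align(ds).matrix
        for j in range(m.n_samples):
            col = m.rt[:, j][m.rt[:, j] > 0]
            assert np.all(np.diff(col) > 0)
        means = m.row_means()
        assert np.all(np.diff(means) > 0)

    def test_no_row_holds_two_peaks_of_one_sample(self, clean_sim):
        # at-most-one is structural: every cell holds at most one peak and
        # conservation guarantees none were dropped or doubled up
        ds, _ = clean_sim
        m = align(ds).matrix
        assert m.total_peaks() == ds.total_peaks()

    def test_sample_order_permutation_only_permutes_columns(self):
        ds, _ = generate(SimConfig(n_samples=5, n_unique_per_sample=1,
                                   seed=9))
        permuted = ds.copy()
        permuted.sample_ids = list(reversed(ds.sample_ids))
        params = AlignmentParams(reference=ds.sample_ids[0])
        m1 = align(ds, params).matrix
        m2 = align(permuted, params).matrix
        cols = [m2.sample_ids.index(s) for s in m1.sample_ids]
        np.testing.assert_allclose(m1.rt, m2.rt[:, cols])
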