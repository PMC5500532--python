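"""Domain types, table I/O, rescaling, age resampling, diversity counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbdiv import (
    CovariateTrajectory,
    EpochGrid,
    FossilOccurrence,
    LineageRecord,
    diversity_trajectory,
    lineages_from_occurrence_ages,
    read_covariate_table,
    read_epoch_grid,
    read_lineage_table,
    read_occurrence_table,
    resample_occurrence_ages,
    rescale_covariate,
    write_lineage_table,
    write_occurrence_table,
)
from mbdiv.errors import (
    DegenerateCovariateError,
    FormatError,
    ValidationError,
)


class TestLineageTable:
    def test_parse_extant_and_extinct(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("taxon\tts\tte\nA\t10\t0\nB\t6\t2\n")
        recs = read_lineage_table(p)
        assert [r.taxon for r in recs] == ["A", "B"]
        assert recs[0].extant and not recs[1].extant

    def test_header_only_gives_empty_collection(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("taxon\tts\tte\n")
        assert read_lineage_table(p) == []

    def test_inverted_times_name_the_taxon(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("taxon\tts\tte\nC\t3\t5\n")
        with pytest.raises(ValidationError, match="C"):
            read_lineage_table(p)

    def test_missing_column_is_a_format_error(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("taxon\tts\nA\t10\n")
        with pytest.raises(FormatError):
            read_lineage_table(p)

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("taxon\tts\tte\nA\t10\t0\nA\t6\t2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_lineage_table(p)

    def test_round_trip(self, tmp_path, two_lineages):
        p = tmp_path / "l.tsv"
        write_lineage_table(two_lineages, p)
        assert read_lineage_table(p) == two_lineages


class TestCovariateTable:
    def test_rows_normalized_oldest_first(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("time\tvalue\n0\t5\n100\t7\n")
        tr = read_covariate_table(p, "x")
        assert tr.times.tolist() == [100.0, 0.0]
        assert tr.values.tolist() == [7.0, 5.0]

    def test_decreasing_rows_unchanged(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("time\tvalue\n100\t7\n0\t5\n")
        tr = read_covariate_table(p)
        assert tr.times.tolist() == [100.0, 0.0]

    def test_duplicate_times_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("time\tvalue\n50\t1\n50\t2\n")
        with pytest.raises(ValidationError):
            read_covariate_table(p)

    def test_single_row_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("time\tvalue\n50\t1\n")
        with pytest.raises(FormatError):
            read_covariate_table(p)

    def test_interpolation_and_constant_extrapolation(self):
        tr = CovariateTrajectory("x", np.array([10.0, 0.0]), np.array([2.0, 0.0]))
        assert tr.at(5.0) == pytest.approx(1.0)
        assert tr.at(50.0) == pytest.approx(2.0)  # beyond the oldest point


class TestRescaling:
    def test_minmax_identity(self):
        tr = CovariateTrajectory(
            "x", np.array([2.0, 1.0, 0.0]), np.array([10.0, 20.0, 30.0])
        )
        out = rescale_covariate(tr)
        assert out.values.tolist() == [0.0, 0.5, 1.0]
        assert out.rescaled

    def test_already_01_unchanged(self):
        tr = CovariateTrajectory("x", np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        out = rescale_covariate(tr)
        assert out.values.tolist() == [0.0, 1.0]

    def test_constant_trajectory_is_degenerate(self):
        tr = CovariateTrajectory(
            "x", np.array([2.0, 1.0, 0.0]), np.array([7.0, 7.0, 7.0])
        )
        with pytest.raises(DegenerateCovariateError):
            rescale_covariate(tr)

    def test_window_restricted_rescaling_clips(self):
        tr = CovariateTrajectory(
            "x", np.array([3.0, 2.0, 1.0, 0.0]), np.array([9.0, 4.0, 2.0, 0.0])
        )
        out = rescale_covariate(tr, window=(0.0, 2.0))
        assert out.values.max() == 1.0  # out-of-window peak clipped to 1
        assert out.values.tolist()[1:] == [1.0, 0.5, 0.0]


class TestAgeResampling:
    def test_degenerate_interval_is_deterministic(self):
        occ = [FossilOccurrence("A", 10.0, 10.0)]
        ages = resample_occurrence_ages(occ, 100, seed=3)
        assert np.all(ages == 10.0)

    def test_uniform_mean_within_standard_error(self):
        occ = [FossilOccurrence("A", 5.0, 15.0)]
        ages = resample_occurrence_ages(occ, 10_000, seed=5)
        se = np.sqrt(100.0 / 12.0 / 10_000)
        assert abs(ages.mean() - 10.0) < 5 * se

    def test_same_seed_bit_identical(self):
        occ = [FossilOccurrence("A", 5.0, 15.0), FossilOccurrence("B", 0.0, 3.0)]
        a = resample_occurrence_ages(occ, 10, seed=9)
        b = resample_occurrence_ages(occ, 10, seed=9)
        assert np.array_equal(a, b)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValidationError):
            resample_occurrence_ages([FossilOccurrence("A", 1.0, 2.0)], 0, seed=0)

    @settings(deadline=None, max_examples=30)
    @given(
        bounds=st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 50, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        ),
        seed=st.integers(0, 2**20),
    )
    def test_samples_stay_inside_ranges(self, bounds, seed):
        occs = [
            FossilOccurrence(f"t{i}", lo, lo + width)
            for i, (lo, width) in enumerate(bounds)
        ]
        ages = resample_occurrence_ages(occs, 5, seed=seed)
        lo = np.array([o.age_min for o in occs])
        hi = np.array([o.age_max for o in occs])
        assert np.all(ages >= lo) and np.all(ages <= hi)

    def test_range_proxy_lineages(self):
        occs = [
            FossilOccurrence("A", 2.0, 2.0),
            FossilOccurrence("A", 8.0, 8.0),
            FossilOccurrence("B", 5.0, 5.0, extant=True),
        ]
        lins = lineages_from_occurrence_ages(occs, np.array([2.0, 8.0, 5.0]))
        assert lins == [LineageRecord("A", 8.0, 2.0), LineageRecord("B", 5.0, 0.0)]

    def test_degenerate_range_dropped_with_warning(self):
        occs = [FossilOccurrence("A", 4.0, 4.0)]
        with pytest.warns(UserWarning, match="degenerate"):
            lins = lineages_from_occurrence_ages(occs, np.array([4.0]))
        assert lins == []


class TestDiversityTrajectory:
    def test_hand_counts(self, two_lineages):
        tr = diversity_trajectory(two_lineages, np.array([12.0, 5.0, 4.0, 1.0]))
        # ts=12 predates both; B extinct at 2 is not alive at t=1
        assert tr.values.tolist() == [0.0, 2.0, 2.0, 1.0]

    def test_summed_occupancy_matches_total_duration(self, two_lineages):
        h = 0.01
        grid = np.arange(11.0, -h / 2, -h)
        tr = diversity_trajectory(two_lineages, grid)
        total = tr.values.sum() * h
        expected = sum(l.duration for l in two_lineages)
        assert abs(total - expected) < 3 * h * len(two_lineages)

    def test_empty_lineage_set_gives_zeros(self):
        tr = diversity_trajectory([], np.array([5.0, 1.0]))
        assert tr.values.tolist() == [0.0, 0.0]


class TestEpochGrid:
    def test_boundary_time_maps_to_younger_epoch(self, epoch_grid):
        assert epoch_grid.index_of(5.0) == 1
        assert epoch_grid.index_of(7.0) == 0
        assert epoch_grid.index_of(0.0) == 1

    def test_read_with_and_without_header(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("boundary\n10\n5\n0\n")
        assert read_epoch_grid(p).boundaries.tolist() == [10.0, 5.0, 0.0]
        p.write_text("10\n5\n0\n")
        assert read_epoch_grid(p).k == 2

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            EpochGrid(np.array([10.0, 5.0]))  # must end at 0
        with pytest.raises(ValidationError):
            EpochGrid(np.array([5.0, 10.0, 0.0]))  # must decrease


def test_occurrence_round_trip(tmp_path):
    occs = [
        FossilOccurrence("A", 1.5, 3.5),
        FossilOccurrence("B", 0.0, 0.5, extant=True),
    ]
    p = tmp_path / "o.tsv"
    write_occurrence_table(occs, p)
    assert read_occurrence_table(p) == occs
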