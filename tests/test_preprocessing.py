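"""Filtering, lineage progeny closure, dilution compensation, truncation."""

import numpy as np
import pytest

from conftest import make_cell
from gal1kinetics.preprocessing import (
    CompensatedTrace,
    Phase,
    TraceTable,
    build_progeny_set,
    compensate_dilution,
    compute_total_fluorescence,
    filter_cells,
    normalize_population,
    read_compensated_traces,
    read_trace_table,
    truncate_and_rescale,
    write_compensated_traces,
    write_trace_table,
)


class TestTotalFluorescence:
    @pytest.mark.parametrize("mean,area,expected", [
        (2.5, 4.0, 10.0),
        (0.0, 100.0, 0.0),
        (3.0, 333.0, 999.0),
    ])
    def test_product(self, mean, area, expected):
        assert compute_total_fluorescence(mean, area) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_total_fluorescence(1.0, 0.0)
        with pytest.raises(ValueError):
            compute_total_fluorescence(np.nan, 1.0)
        with pytest.raises(ValueError):
            compute_total_fluorescence(1.0, -2.0)


class TestFilterCells:
    def test_not_imaged_to_end_discarded(self):
        cells = [make_cell("A", None, 0, 5), make_cell("B", None, 0, 4)]
        table = TraceTable(records=cells,
                           phases=[Phase("r1", "glucose", 0, 5)])
        out = filter_cells(table)
        assert [r.cell_id for r in out.records] == ["A"]

    def test_missing_values_discarded(self):
        bad = make_cell("A", None, 0, 3, [1.0, np.nan, 1.0, 1.0])
        good = make_cell("B", None, 0, 3)
        table = TraceTable(records=[bad, good],
                           phases=[Phase("r1", "glucose", 0, 3)])
        out = filter_cells(table)
        assert [r.cell_id for r in out.records] == ["B"]

    def test_detected_before_mother_discarded(self):
        mother = make_cell("M", None, 2, 5)
        daughter = make_cell("D", "M", 1, 5)   # segmentation error
        ok = make_cell("K", "M", 3, 5)
        table = TraceTable(records=[mother, daughter, ok],
                           phases=[Phase("r1", "glucose", 0, 5)])
        out = filter_cells(table)
        assert {r.cell_id for r in out.records} == {"M", "K"}

    def test_all_pass_is_identity_and_idempotent(self, small_lineage):
        once = filter_cells(small_lineage)
        assert len(once) == len(small_lineage)
        twice = filter_cells(once)
        assert [r.cell_id for r in twice.records] == \
            [r.cell_id for r in once.records]


class TestProgenySet:
    def test_no_divisions_empty(self):
        table = TraceTable(records=[make_cell("M", None, 0, 5)],
                           phases=[Phase("r1", "glucose", 0, 5)])
        assert build_progeny_set(table, "M", (0, 5)) == set()

    def test_transitive_closure_includes_granddaughters(self, small_lineage):
        assert build_progeny_set(small_lineage, "M", (0, 5)) == {"D", "E"}

    def test_bud_at_window_start_included(self):
        mother = make_cell("M", None, 0, 10)
        bud = make_cell("B", "M", 4, 10)       # born just before window
        table = TraceTable(records=[mother, bud],
                           phases=[Phase("r1", "glucose", 5, 10)])
        assert build_progeny_set(table, "M", (5, 10)) == {"B"}

    def test_old_daughter_not_a_bud(self):
        mother = make_cell("M", None, 0, 30)
        old = make_cell("O", "M", 2, 30)       # born long before window
        table = TraceTable(records=[mother, old],
                           phases=[Phase("r1", "glucose", 20, 30)])
        assert build_progeny_set(table, "M", (20, 30)) == set()

    def test_unknown_mother_raises(self, small_lineage):
        with pytest.raises(KeyError):
            build_progeny_set(small_lineage, "nope", (0, 5))


class TestCompensation:
    def test_division_conserves_total(self):
        # mother loses 1 unit/frame to its growing daughter
        mother = make_cell("M", None, 0, 2, [10.0, 9.0, 8.0])
        daughter = make_cell("D", "M", 1, 2, [1.0, 2.0])
        table = TraceTable(records=[mother, daughter],
                           phases=[Phase("r1", "glucose", 0, 2)])
        traces = compensate_dilution(table, "r1")
        assert len(traces) == 1
        np.testing.assert_allclose(traces[0].total_gfp, [10.0, 10.0, 10.0])
        assert traces[0].n_descendants == 1

    def test_no_progeny_identity(self):
        mother = make_cell("M", None, 0, 2, [5.0, 4.0, 3.0], area=2.0)
        table = TraceTable(records=[mother],
                           phases=[Phase("r1", "glucose", 0, 2)])
        traces = compensate_dilution(table, "r1")
        np.testing.assert_allclose(traces[0].total_gfp, [10.0, 8.0, 6.0])

    def test_bud_merged_not_separate_mother(self):
        mother = make_cell("M", None, 0, 10, np.full(11, 4.0))
        bud = make_cell("B", "M", 4, 10, np.full(7, 1.0))
        table = TraceTable(records=[mother, bud],
                           phases=[Phase("r1", "glucose", 5, 10)])
        traces = compensate_dilution(table, "r1")
        assert [t.mother_id for t in traces] == ["M"]
        assert traces[0].had_bud_at_start
        np.testing.assert_allclose(traces[0].total_gfp, np.full(6, 5.0))

    def test_times_start_at_zero_on_common_grid(self, small_lineage):
        traces = compensate_dilution(small_lineage, "r1")
        for tr in traces:
            assert tr.times[0] == 0.0
            np.testing.assert_allclose(np.diff(tr.times), 0.05)


class TestTruncateRescale:
    def test_two_hour_window_keeps_41_points(self):
        times = np.round(np.arange(0, 4.0001, 0.05), 10)
        tr = CompensatedTrace("M", "r1", times, np.ones(len(times)) * 2e7)
        out = truncate_and_rescale(tr)
        assert len(out.times) == 41
        assert out.times[-1] == pytest.approx(2.0)
        np.testing.assert_allclose(out.total_gfp, 2.0)

    def test_rescaling_value(self):
        times = np.round(np.arange(0, 2.0001, 0.05), 10)
        tr = CompensatedTrace("M", "r1", times,
                              np.full(len(times), 5.9e6))
        out = truncate_and_rescale(tr)
        assert out.total_gfp[0] == pytest.approx(0.59)

    def test_truncate_then_rescale_commutes(self):
        times = np.round(np.arange(0, 3.0001, 0.05), 10)
        vals = np.linspace(1e7, 3e7, len(times))
        tr = CompensatedTrace("M", "r1", times, vals)
        a = truncate_and_rescale(tr, window_h=2.0, scale=1e7)
        b = truncate_and_rescale(
            truncate_and_rescale(tr, window_h=times[-1], scale=1e7),
            window_h=2.0, scale=1.0)
        np.testing.assert_allclose(a.total_gfp, b.total_gfp)
        np.testing.assert_allclose(a.times, b.times)

    def test_short_trace_rejected(self):
        times = np.round(np.arange(0, 1.0001, 0.05), 10)
        tr = CompensatedTrace("M", "r1", times, np.ones(len(times)))
        with pytest.raises(ValueError):
            truncate_and_rescale(tr)


class TestNormalize:
    def test_max_becomes_one(self, flat_trace):
        tr = CompensatedTrace("M", "r1", flat_trace.times,
                              flat_trace.total_gfp * 2.0)
        out = normalize_population([tr])
        assert np.max(out[0].total_gfp) == pytest.approx(1.0)

    def test_constant_trace_becomes_unit(self, flat_trace):
        out = normalize_population([flat_trace])
        np.testing.assert_allclose(out[0].total_gfp, 1.0)

    def test_all_zero_trace_rejected(self, flat_trace):
        zero = CompensatedTrace("Z", "r1", flat_trace.times,
                                np.zeros(len(flat_trace.times)))
        with pytest.raises(ValueError):
            normalize_population([zero])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            normalize_population([])


class TestRoundTrip:
    def test_trace_table_round_trips_losslessly(self, small_lineage,
                                                tmp_path):
        cells, meas = tmp_path / "cells.csv", tmp_path / "meas.csv"
        write_trace_table(small_lineage, cells, meas)
        back = read_trace_table(cells, meas,
                                frame_interval=small_lineage.frame_interval,
                                phases=small_lineage.phases)
        assert len(back) == len(small_lineage)
        for orig, new in zip(small_lineage.records, back.records):
            assert orig.cell_id == new.cell_id
            assert orig.mother_id == new.mother_id
            assert (orig.first_frame, orig.last_frame) == \
                (new.first_frame, new.last_frame)
            np.testing.assert_allclose(orig.mean_fluorescence,
                                       new.mean_fluorescence)
            np.testing.assert_allclose(orig.area, new.area)

    def test_compensated_traces_round_trip(self, flat_trace, tmp_path):
        path = tmp_path / "traces.csv"
        write_compensated_traces([flat_trace], path)
        back = read_compensated_traces(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].times, flat_trace.times)
        np.testing.assert_allclose(back[0].total_gfp, flat_trace.total_gfp)
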