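"""Shared fixtures: tiny hand-built lineage tables and synthetic traces."""

import numpy as np
import pytest

from gal1kinetics.preprocessing import (
    CellRecord,
    CompensatedTrace,
    Phase,
    TraceTable,
)


def make_cell(cell_id, mother_id, first, last, values=None, area=1.0):
    """CellRecord with constant area and given per-frame mean fluorescence."""
    n = last - first + 1
    vals = np.full(n, 1.0) if values is None else np.asarray(values, float)
    return CellRecord(cell_id=cell_id, mother_id=mother_id,
                      first_frame=first, last_frame=last,
                      mean_fluorescence=vals,
                      area=np.full(n, float(area)))


@pytest.fixture
def small_lineage():
    """Mother + daughter + granddaughter over 6 frames, single phase.

    Total fluorescence is conserved across the two divisions: the mother
    hands 1/3 of its signal to D at frame 2, D hands 1/3 of its share to E
    at frame 4.
    """
    mother = make_cell("M", None, 0, 5, [9.0, 9.0, 6.0, 6.0, 6.0, 6.0])
    daughter = make_cell("D", "M", 2, 5, [3.0, 3.0, 2.0, 2.0])
    grand = make_cell("E", "D", 4, 5, [1.0, 1.0])
    return TraceTable(records=[mother, daughter, grand],
                      frame_interval=0.05,
                      phases=[Phase("r1", "glucose", 0, 5)])


@pytest.fixture
def flat_trace():
    times = np.round(np.arange(0, 2.0001, 0.05), 10)
    return CompensatedTrace(mother_id="flat", repression_label="r1",
                            times=times, total_gfp=np.full(len(times), 2.0))
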