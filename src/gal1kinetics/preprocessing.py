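"""Raw lineage-tracking tables to dilution-compensated total-GFP traces.

Input is the tracking output of a mother-machine / microfluidics yeast
experiment: one row per cell (id, mother id, first/last detection frame)
plus per-frame mean GFP fluorescence and segmented area at a fixed frame
interval (3 min by default). During budding, cytoplasmic GFP is split
between mother and daughter, which lowers the mother's total signal without
any degradation. To deconvolve this dilution from repression kinetics, each
mother cell present at the start of a repression phase is turned into an
"artificial non-dividing cell": at every frame the total fluorescence
(mean fluorescence x area) of the mother and of all its progeny born during
the repression window is summed. Traces are then truncated to the first
2 h of repression and rescaled by 1e7 for fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gal1kinetics.preprocessing")

__all__ = [
    "CellRecord",
    "Phase",
    "TraceTable",
    "CompensatedTrace",
    "compute_total_fluorescence",
    "filter_cells",
    "build_progeny_set",
    "compensate_dilution",
    "truncate_and_rescale",
    "normalize_population",
    "read_trace_table",
    "write_trace_table",
    "write_compensated_traces",
    "read_compensated_traces",
]

#: Frame interval of the imaging experiment in hours (3 min).
DEFAULT_FRAME_INTERVAL_H = 0.05

#: Analysis window after repression start, hours.
DEFAULT_WINDOW_H = 2.0

#: Fluorescence rescaling factor applied before fitting.
DEFAULT_SCALE = 1e7

#: A daughter first detected at most this many frames before the repression
#: start (and still present at the start) is treated as a bud of its mother:
#: its fluorescence is added to the mother's compensated trace and it does
#: not seed a compensated trace of its own. 10 frames = 30 min, roughly the
#: duration of budding before cytokinesis.
DEFAULT_BUD_FRAMES = 10


@dataclass(frozen=True)
class CellRecord:
    """One tracked cell: lineage link plus per-frame measurements.

    ``mean_fluorescence`` and ``area`` cover exactly the frames
    ``first_frame..last_frame`` (inclusive); missing measurements are NaN.
    """

    cell_id: str
    mother_id: str | None
    first_frame: int
    last_frame: int
    mean_fluorescence: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError(
                f"cell {self.cell_id}: first_frame > last_frame")
        n = self.last_frame - self.first_frame + 1
        mf = np.asarray(self.mean_fluorescence, dtype=float)
        ar = np.asarray(self.area, dtype=float)
        if len(mf) != n or len(ar) != n:
            raise ValueError(
                f"cell {self.cell_id}: expected {n} per-frame values, got "
                f"{len(mf)} fluorescence / {len(ar)} area")
        object.__setattr__(self, "mean_fluorescence", mf)
        object.__setattr__(self, "area", ar)

    @property
    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1

    def value_at(self, frame: int) -> tuple[float, float]:
        """(mean_fluorescence, area) at an absolute frame index."""
        if not (self.first_frame <= frame <= self.last_frame):
            raise KeyError(
                f"cell {self.cell_id} not present at frame {frame}")
        i = frame - self.first_frame
        return float(self.mean_fluorescence[i]), float(self.area[i])


@dataclass(frozen=True)
class Phase:
    """One experiment phase: e.g. ('r1', 'glucose', 140, 219)."""

    label: str
    carbon_source: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError(f"phase {self.label}: start_frame > end_frame")


@dataclass
class TraceTable:
    """A collection of tracked cells plus the experiment's phase schedule."""

    records: list[CellRecord]
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H
    phases: list[Phase] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for ph in self.phases:
            if ph.start_frame <= prev_end:
                raise ValueError("phases must be disjoint and ordered")
            prev_end = ph.end_frame
        ids = [r.cell_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell_id in trace table")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def by_id(self) -> dict[str, CellRecord]:
        return {r.cell_id: r for r in self.records}

    @property
    def final_frame(self) -> int:
        if self.phases:
            return self.phases[-1].end_frame
        return max(r.last_frame for r in self.records)

    def phase(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(f"no phase labelled {label!r}")

    def daughters_of(self, cell_id: str) -> list[CellRecord]:
        return [r for r in self.records if r.mother_id == cell_id]


@dataclass(frozen=True)
class CompensatedTrace:
    """Artificial non-dividing cell: mother + progeny total GFP per frame.

    ``times`` start at 0 at the repression start; after
    :func:`truncate_and_rescale` the values are in 1e-7-rescaled units.
    """

    mother_id: str
    repression_label: str
    times: np.ndarray
    total_gfp: np.ndarray
    n_descendants: int = 0
    had_bud_at_start: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.total_gfp, dtype=float)
        if len(t) != len(g):
            raise ValueError("times and total_gfp must have equal length")
        if len(t) and (t[0] != 0.0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must start at 0 and strictly increase")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "total_gfp", g)


def compute_total_fluorescence(mean_fluorescence, area):
    """Total fluorescence = mean (per-pixel) fluorescence x segmented area.

    Raises ``ValueError`` on non-finite inputs or non-positive area.
    """
    mf = np.asarray(mean_fluorescence, dtype=float)
    ar = np.asarray(area, dtype=float)
    if not (np.all(np.isfinite(mf)) and np.all(np.isfinite(ar))):
        raise ValueError("non-finite fluorescence or area")
    if np.any(ar <= 0):
        raise ValueError("area must be > 0")
    return mf * ar


def filter_cells(table: TraceTable, final_frame: int | None = None) -> TraceTable:
    """Drop cells unusable for compensation; idempotent.

    Discards (logging one line per cell with the reason):

    * cells not imaged until ``final_frame`` (default: the experiment end),
    * cells with any missing (NaN) fluorescence or area value or
      non-positive area,
    * cells detected before their own mother (a segmentation error).
    """
    if final_frame is None:
        final_frame = table.final_frame
    first_frames = {r.cell_id: r.first_frame for r in table.records}
    kept: list[CellRecord] = []
    for rec in table.records:
        if rec.last_frame != final_frame:
            logger.info("discard %s: not imaged till final frame (%d != %d)",
                        rec.cell_id, rec.last_frame, final_frame)
            continue
        if (np.any(~np.isfinite(rec.mean_fluorescence))
                or np.any(~np.isfinite(rec.area)) or np.any(rec.area <= 0)):
            logger.info("discard %s: missing fluorescence/area values",
                        rec.cell_id)
            continue
        if (rec.mother_id is not None and rec.mother_id in first_frames
                and rec.first_frame < first_frames[rec.mother_id]):
            logger.info("discard %s: detected before its mother %s",
                        rec.cell_id, rec.mother_id)
            continue
        kept.append(rec)
    return TraceTable(records=kept, frame_interval=table.frame_interval,
                      phases=table.phases)


def build_progeny_set(
    table: TraceTable,
    mother_id: str,
    window: tuple[int, int],
    bud_frames: int = DEFAULT_BUD_FRAMES,
) -> set[str]:
    """All descendants of ``mother_id`` to sum into its compensated trace.

    Transitive closure of daughters first detected inside
    ``window = (start_frame, end_frame]`` — granddaughters included, since
    a daughter's own budding would otherwise leak fluorescence out of the
    artificial non-dividing cell — plus any bud present at the window
    start (a daughter first detected within ``bud_frames`` frames before
    the start) and the bud's own in-window progeny.
    """
    by_id = table.by_id
    if mother_id not in by_id:
        raise KeyError(f"unknown mother_id {mother_id!r}")
    start, end = window
    children: dict[str, list[CellRecord]] = {}
    for rec in table.records:
        if rec.mother_id is not None:
            children.setdefault(rec.mother_id, []).append(rec)

    def is_bud(rec: CellRecord) -> bool:
        return (start - bud_frames <= rec.first_frame <= start
                and rec.last_frame >= start)

    progeny: set[str] = set()
    stack = [mother_id]
    root = True
    while stack:
        cid = stack.pop()
        for child in children.get(cid, ()):  # direct daughters
            born_in_window = start < child.first_frame <= end
            if born_in_window or (root and is_bud(child)):
                if child.cell_id not in progeny:
                    progeny.add(child.cell_id)
                    stack.append(child.cell_id)
        root = False
    return progeny


def _bud_ids(table: TraceTable, start: int, bud_frames: int) -> set[str]:
    """Cells that are buds (of some cell present at start) at frame start."""
    present = {r.cell_id for r in table.records
               if r.first_frame <= start <= r.last_frame}
    buds: set[str] = set()
    for rec in table.records:
        if (rec.mother_id in present
                and start - bud_frames <= rec.first_frame <= start
                and rec.last_frame >= start):
            buds.add(rec.cell_id)
    return buds


def compensate_dilution(
    table: TraceTable,
    repression_label: str,
    bud_frames: int = DEFAULT_BUD_FRAMES,
) -> list[CompensatedTrace]:
    """One artificial non-dividing cell per mother present at repression start.

    A *mother* is any filtered cell already present at the first repression
    frame that is not itself a bud of another present cell. At each frame of
    the repression window, the mother's total fluorescence and that of every
    progeny cell present at that frame are summed. Mothers must cover the
    whole window (guaranteed after :func:`filter_cells`).
    """
    phase = table.phase(repression_label)
    start, end = phase.start_frame, phase.end_frame
    by_id = table.by_id
    buds = _bud_ids(table, start, bud_frames)
    traces: list[CompensatedTrace] = []
    for rec in table.records:
        if not (rec.first_frame <= start and rec.last_frame >= start):
            continue
        if rec.cell_id in buds:
            continue
        if rec.last_frame < end:
            raise ValueError(
                f"mother {rec.cell_id} does not cover the repression window; "
                "run filter_cells first")
        progeny = build_progeny_set(table, rec.cell_id, (start, end),
                                    bud_frames=bud_frames)
        had_bud = any(by_id[p].first_frame <= start for p in progeny)
        frames = np.arange(start, end + 1)
        total = np.zeros(len(frames))
        for cid in (rec.cell_id, *progeny):
            cell = by_id[cid]
            lo = max(cell.first_frame, start)
            hi = min(cell.last_frame, end)
            if lo > hi:
                continue
            sl = slice(lo - cell.first_frame, hi - cell.first_frame + 1)
            total[lo - start: hi - start + 1] += np.asarray(
                compute_total_fluorescence(cell.mean_fluorescence[sl],
                                           cell.area[sl]))
        traces.append(CompensatedTrace(
            mother_id=rec.cell_id,
            repression_label=repression_label,
            times=(frames - start) * table.frame_interval,
            total_gfp=total,
            n_descendants=len(progeny),
            had_bud_at_start=had_bud,
        ))
    return traces


def truncate_and_rescale(
    trace: CompensatedTrace,
    window_h: float = DEFAULT_WINDOW_H,
    scale: float = DEFAULT_SCALE,
) -> CompensatedTrace:
    """Restrict a trace to ``[0, window_h]`` hours and divide by ``scale``.

    A 2 h window at 3-min sampling keeps 41 points. Raises ``ValueError``
    if the trace is shorter than the window.
    """
    if trace.times[-1] < window_h - 1e-12:
        raise ValueError(
            f"trace {trace.mother_id} covers only {trace.times[-1]:.3f} h "
            f"< {window_h} h")
    keep = trace.times <= window_h + 1e-12
    return replace(trace, times=trace.times[keep],
                   total_gfp=trace.total_gfp[keep] / scale)


def normalize_population(
    traces: Sequence[CompensatedTrace],
) -> list[CompensatedTrace]:
    """Scale each trace to its own maximum (population-figure display).

    Raises ``ValueError`` on an empty collection or an all-zero trace.
    """
    if not traces:
        raise ValueError("empty trace collection")
    out = []
    for tr in traces:
        peak = float(np.max(tr.total_gfp))
        if peak <= 0:
            raise ValueError(f"degenerate all-zero trace {tr.mother_id}")
        out.append(replace(tr, total_gfp=tr.total_gfp / peak))
    return out


# ---------------------------------------------------------------------------
# I/O: CSV tables + YAML/JSON phase config
# ---------------------------------------------------------------------------

def load_phase_config(path) -> tuple[float, list[Phase]]:
    """Read frame interval and phase schedule from a YAML (or JSON) file.

    Expected layout::

        frame_interval: 0.05
        phases:
          - {label: r0, carbon_source: glucose, start_frame: 0, end_frame: 79}
          - ...
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    interval = float(cfg.get("frame_interval", DEFAULT_FRAME_INTERVAL_H))
    phases = [Phase(p["label"], p["carbon_source"],
                    int(p["start_frame"]), int(p["end_frame"]))
              for p in cfg.get("phases", [])]
    return interval, phases


def read_trace_table(
    cells_csv,
    measurements_csv,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H,
    phases: Iterable[Phase] = (),
) -> TraceTable:
    """Assemble a :class:`TraceTable` from the two-file CSV layout.

    ``cells_csv``: columns cell_id, mother_id (empty for founders),
    first_frame, last_frame. ``measurements_csv`` (long format): cell_id,
    frame, mean_fluorescence, area. Measurement rows are sorted by frame
    per cell; frames without a row become NaN (later discarded by
    :func:`filter_cells`).
    """
    cells = pd.read_csv(cells_csv, dtype={"cell_id": str, "mother_id": str})
    meas = pd.read_csv(measurements_csv, dtype={"cell_id": str})
    meas = meas.sort_values(["cell_id", "frame"])
    grouped = dict(tuple(meas.groupby("cell_id", sort=False)))
    records = []
    for row in cells.itertuples(index=False):
        first, last = int(row.first_frame), int(row.last_frame)
        n = last - first + 1
        mf = np.full(n, np.nan)
        ar = np.full(n, np.nan)
        g = grouped.get(str(row.cell_id))
        if g is not None:
            idx = g["frame"].to_numpy(dtype=int) - first
            ok = (idx >= 0) & (idx < n)
            mf[idx[ok]] = g["mean_fluorescence"].to_numpy(dtype=float)[ok]
            ar[idx[ok]] = g["area"].to_numpy(dtype=float)[ok]
        mother = None if pd.isna(row.mother_id) or row.mother_id == "" \
            else str(row.mother_id)
        records.append(CellRecord(str(row.cell_id), mother, first, last,
                                  mf, ar))
    return TraceTable(records=records, frame_interval=frame_interval,
                      phases=list(phases))


def write_trace_table(table: TraceTable, cells_csv, measurements_csv) -> None:
    """Write a table back to the two-file CSV layout (lossless round trip)."""
    cells = pd.DataFrame(
        {"cell_id": [r.cell_id for r in table.records],
         "mother_id": [r.mother_id or "" for r in table.records],
         "first_frame": [r.first_frame for r in table.records],
         "last_frame": [r.last_frame for r in table.records]})
    cells.to_csv(cells_csv, index=False)
    rows = []
    for r in table.records:
        for i, frame in enumerate(range(r.first_frame, r.last_frame + 1)):
            rows.append((r.cell_id, frame, r.mean_fluorescence[i], r.area[i]))
    pd.DataFrame(rows, columns=["cell_id", "frame", "mean_fluorescence",
                                "area"]).to_csv(measurements_csv, index=False)


def write_compensated_traces(traces: Sequence[CompensatedTrace], path) -> None:
    """Long-format CSV: mother_id, repression, time_h, total_gfp_rescaled."""
    rows = []
    for tr in traces:
        for t, g in zip(tr.times, tr.total_gfp):
            rows.append((tr.mother_id, tr.repression_label, t, g))
    pd.DataFrame(rows, columns=["mother_id", "repression", "time_h",
                                "total_gfp_rescaled"]).to_csv(path,
                                                              index=False)


def read_compensated_traces(path) -> list[CompensatedTrace]:
    """Inverse of :func:`write_compensated_traces`."""
    df = pd.read_csv(path, dtype={"mother_id": str})
    traces = []
    for (mid, label), g in df.groupby(["mother_id", "repression"],
                                      sort=False):
        g = g.sort_values("time_h")
        traces.append(CompensatedTrace(
            mother_id=str(mid), repression_label=str(label),
            times=g["time_h"].to_numpy(),
            total_gfp=g["total_gfp_rescaled"].to_numpy()))
    return traces
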