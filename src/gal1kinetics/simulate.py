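"""Ground-truth-known synthetic data: SSA traces and dividing cohorts.

Single-cell Gal1-GFP counts follow a linear birth--death process --
production at ``r_prod`` until the repression response delay ``t_delay``
(then switched off), or at a constant basal rate for uninduced cells --
and first-order degradation at ``r_deg``, sampled exactly with Gillespie's
stochastic simulation algorithm. Observations add Gaussian measurement
noise on a 3-min grid over 2 h.

Cohorts emulate the microfluidics study design: a mixed population of
induced (repressing) and uninduced (basal) mothers with heterogeneous
log-normal single-cell parameters, and budding events that hand ~1/3 of a
cell's fluorescence to a newly tracked daughter. Divisions only
redistribute signal, so summing mother + progeny recovers the
division-free latent trajectory exactly -- the property the dilution
compensation in :mod:`gal1kinetics.preprocessing` relies on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .preprocessing import (
    CellRecord,
    CompensatedTrace,
    Phase,
    TraceTable,
)

__all__ = [
    "SimulationSettings",
    "SimulatedTrace",
    "LogNormalSpec",
    "CohortSettings",
    "TwoRepressionShift",
    "gillespie_trace",
    "s3_benchmark",
    "S3_DEGRADATION_RATES",
    "simulate_cohort",
    "two_repression_cohort",
    "as_compensated_trace",
]

#: Linear gain mapping molecule counts to raw fluorescence units. With the
#: standard 1e7 rescaling before fitting, a 100-molecule cell lands at 1.0
#: in rescaled units, inside the fitting bounds [1e-10, 10].
DEFAULT_GAIN = 1e5

#: The benchmark's degradation-rate settings (1/h).
S3_DEGRADATION_RATES: dict[str, float] = {
    "fast": 0.5,
    "slow": 0.2,
    "super_slow": 0.04,
    "none": 0.0,
}


def _default_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 2.0 + 1e-9, 0.05), 10)


@dataclass(frozen=True)
class SimulationSettings:
    """One simulated cell.

    With ``repressing=True`` production runs at ``r_prod`` until
    ``t_delay`` and is then switched off; otherwise it stays at
    ``r_basal`` throughout. ``sigma`` is the additive Gaussian measurement
    noise in molecule units.
    """

    GFP_0: int = 100
    t_delay: float = 0.5
    r_prod: float = 100.0
    r_basal: float = 0.0
    r_deg: float = 0.5
    sigma: float = 5.0
    repressing: bool = True
    grid: np.ndarray = field(default_factory=_default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.GFP_0 < 0 or int(self.GFP_0) != self.GFP_0:
            raise ValueError("GFP_0 must be a non-negative integer count")
        for name in ("t_delay", "r_prod", "r_basal", "r_deg", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "grid",
                           np.asarray(self.grid, dtype=float))


@dataclass(frozen=True)
class SimulatedTrace:
    """Noisy observations plus the latent molecule counts on the grid."""

    times: np.ndarray
    observed: np.ndarray
    latent: np.ndarray
    settings: SimulationSettings


def _ssa_on_grid(rng: np.random.Generator, n0: int, grid: np.ndarray,
                 segments: Sequence[tuple[float, float, float]],
                 r_deg: float) -> np.ndarray:
    """Exact SSA of birth--death with piecewise-constant production.

    ``segments`` are ``(t_start, t_end, production_rate)`` covering the
    grid; within a segment rates are constant, so a proposed exponential
    waiting time crossing the segment boundary is simply discarded and the
    clock restarted at the boundary (memorylessness). Returns counts
    sampled at grid times.
    """
    counts = np.empty(len(grid), dtype=np.int64)
    gi = 0
    n = int(n0)

    def record_until(t_now: float) -> None:
        nonlocal gi
        while gi < len(grid) and grid[gi] <= t_now + 1e-12:
            counts[gi] = n
            gi += 1

    for (seg_start, seg_end, lam) in segments:
        t = seg_start
        while t < seg_end:
            total = lam + r_deg * n
            if total <= 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= seg_end:
                break
            t += dt
            record_until(t)
            if rng.random() * total < lam:
                n += 1
            else:
                n -= 1
        record_until(seg_end)
    record_until(np.inf)
    return counts


def gillespie_trace(settings: SimulationSettings) -> SimulatedTrace:
    """Simulate one cell exactly and observe it with Gaussian noise."""
    grid = settings.grid
    t_end = float(grid[-1])
    if settings.repressing:
        td = min(settings.t_delay, t_end)
        segments = [(0.0, td, settings.r_prod), (td, t_end, 0.0)]
    else:
        segments = [(0.0, t_end, settings.r_basal)]
    rng = np.random.default_rng(settings.seed)
    latent = _ssa_on_grid(rng, settings.GFP_0, grid, segments,
                          settings.r_deg)
    observed = latent + rng.normal(0.0, settings.sigma, size=len(grid)) \
        if settings.sigma > 0 else latent.astype(float)
    return SimulatedTrace(times=grid.copy(), observed=observed,
                          latent=latent, settings=settings)


def s3_benchmark(seed: int = 0) -> dict[str, SimulatedTrace]:
    """Four repressing cells differing only in degradation rate.

    Shared settings: ``GFP_0 = 100``, ``t_delay = 0.5 h``,
    ``r_prod = 100 /h``, ``sigma = 5``; ``r_deg`` takes the fast (0.5),
    slow (0.2), super-slow (0.04) and none (0) values. The zero-degradation
    cell is the known hard case: with nothing decaying after shut-off, its
    trace is expected to be classified as lacking repression kinetics.
    """
    out = {}
    for i, (label, r_deg) in enumerate(S3_DEGRADATION_RATES.items()):
        settings = SimulationSettings(GFP_0=100, t_delay=0.5, r_prod=100.0,
                                      r_deg=r_deg, sigma=5.0,
                                      repressing=True, seed=seed * 4 + i)
        out[label] = gillespie_trace(settings)
    return out


def as_compensated_trace(sim: SimulatedTrace, mother_id: str = "sim",
                         repression_label: str = "r1",
                         gain: float = DEFAULT_GAIN) -> CompensatedTrace:
    """Wrap a simulated cell as a raw-unit compensated trace.

    Molecule-unit observations are mapped to fluorescence via ``gain``;
    pass the result through ``truncate_and_rescale`` before fitting.
    """
    return CompensatedTrace(mother_id=mother_id,
                            repression_label=repression_label,
                            times=sim.times,
                            total_gfp=sim.observed * gain)


# ---------------------------------------------------------------------------
# Dividing cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal with a given median and natural-log sigma."""

    median: float
    sigma_log: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * np.exp(self.sigma_log * rng.standard_normal()))


def _default_repressing_params() -> dict[str, LogNormalSpec]:
    # Induced cells: high initial GFP from 3 h of galactose induction,
    # production ~100 molecules/h until a ~0.5 h shut-off delay.
    return {
        "GFP_0": LogNormalSpec(100.0, 0.3),
        "r_prod": LogNormalSpec(100.0, 0.3),
        "r_deg": LogNormalSpec(0.5, 0.2),
        "t_delay": LogNormalSpec(0.5, 0.2),
    }


def _default_basal_params() -> dict[str, LogNormalSpec]:
    # Uninduced cells: low starting GFP with a gradual basal rise.
    return {
        "GFP_0": LogNormalSpec(10.0, 0.3),
        "r_basal": LogNormalSpec(20.0, 0.3),
        "r_deg": LogNormalSpec(0.1, 0.2),
    }


@dataclass(frozen=True)
class CohortSettings:
    """A mixed dividing population on one repression window.

    ``fraction_repressing`` of the mothers are induced cells following the
    repression model; the rest follow the basal model. Each cell divides
    as a Poisson process (``division_rate_per_h``), handing
    ``daughter_fraction`` of its current fluorescence to a new tracked
    daughter; alternatively an explicit ``division_schedule`` (cell id ->
    division frames) can be injected.
    """

    n_mothers: int = 50
    fraction_repressing: float = 0.5
    repressing_params: Mapping[str, LogNormalSpec] = field(
        default_factory=_default_repressing_params)
    basal_params: Mapping[str, LogNormalSpec] = field(
        default_factory=_default_basal_params)
    sigma: float = 5.0
    gain: float = DEFAULT_GAIN
    division_rate_per_h: float = 0.5
    daughter_fraction: float = 1.0 / 3.0
    n_frames: int = 41
    frame_interval: float = 0.05
    repression_label: str = "r1"
    mother_area: float = 900.0
    division_schedule: Mapping[str, Sequence[int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_repressing <= 1.0):
            raise ValueError("fraction_repressing must lie in [0, 1]")
        if not (0.0 < self.daughter_fraction < 1.0):
            raise ValueError("daughter_fraction must lie in (0, 1)")


def _draw_cell_params(rng: np.random.Generator, repressing: bool,
                      settings: CohortSettings) -> dict[str, float]:
    spec = (settings.repressing_params if repressing
            else settings.basal_params)
    params = {name: s.sample(rng) for name, s in spec.items()}
    params["GFP_0"] = float(max(0, round(params["GFP_0"])))
    if "t_delay" in params:
        # keep the truth inside the fitting bounds (36 s .. 2 h)
        params["t_delay"] = float(np.clip(params["t_delay"], 0.011, 1.99))
    return params


def simulate_cohort(
    settings: CohortSettings,
) -> tuple[TraceTable, dict[str, dict]]:
    """Simulate a dividing cohort and its ground-truth registry.

    Per mother one division-free latent trajectory is simulated by SSA;
    budding then redistributes the signal among the mother and its
    (recursively dividing) daughters, conserving the total exactly.
    Returns the raw-format :class:`TraceTable` (one row per tracked cell,
    all imaged until the final frame) and a registry mapping each mother
    id to its true class, parameters and latent trajectory.
    """
    rng = np.random.default_rng(settings.seed)
    n_frames = settings.n_frames
    final_frame = n_frames - 1
    grid = np.round(np.arange(n_frames) * settings.frame_interval, 10)
    n_rep = int(round(settings.n_mothers * settings.fraction_repressing))

    if settings.division_schedule is not None:
        for cid, frames in settings.division_schedule.items():
            if any(f <= 0 for f in frames):
                raise ValueError(
                    f"invalid division schedule for {cid}: division at or "
                    "before the cell's first frame")

    records: list[CellRecord] = []
    registry: dict[str, dict] = {}
    for i in range(settings.n_mothers):
        mother_id = f"m{i:03d}"
        repressing = i < n_rep
        params = _draw_cell_params(rng, repressing, settings)
        sim = gillespie_trace(SimulationSettings(
            GFP_0=int(params["GFP_0"]),
            t_delay=params.get("t_delay", 0.0),
            r_prod=params.get("r_prod", 0.0),
            r_basal=params.get("r_basal", 0.0),
            r_deg=params["r_deg"],
            sigma=0.0,                  # noise added per tracked cell below
            repressing=repressing,
            grid=grid,
            seed=int(rng.integers(2 ** 31)),
        ))
        latent = sim.latent.astype(float)

        # Redistribute the latent signal across a growing pedigree: each
        # tracked cell holds a share of the artificial non-dividing cell.
        cells: list[dict] = [{
            "cell_id": mother_id, "mother_id": None, "first_frame": 0,
            "area": settings.mother_area, "share": 1.0, "n_kids": 0,
        }]
        shares = np.zeros((1, n_frames))
        p_div = 1.0 - np.exp(-settings.division_rate_per_h
                             * settings.frame_interval)
        for f in range(n_frames):
            for ci in range(len(cells)):
                cell = cells[ci]
                if f <= cell["first_frame"]:
                    continue
                if settings.division_schedule is not None:
                    divide = f in set(
                        settings.division_schedule.get(cell["cell_id"], ()))
                else:
                    divide = rng.random() < p_div
                if divide and cell["share"] > 0:
                    cell["n_kids"] += 1
                    daughter = {
                        "cell_id": f"{cell['cell_id']}d{cell['n_kids']}",
                        "mother_id": cell["cell_id"],
                        "first_frame": f,
                        "area": cell["area"] * settings.daughter_fraction,
                        "share": cell["share"] * settings.daughter_fraction,
                        "n_kids": 0,
                    }
                    cell["share"] -= daughter["share"]
                    cells.append(daughter)
                    shares = np.vstack([shares, np.zeros((1, n_frames))])
            for ci, cell in enumerate(cells):
                if f >= cell["first_frame"]:
                    shares[ci, f] = cell["share"]

        for ci, cell in enumerate(cells):
            first = cell["first_frame"]
            molecules = shares[ci, first:] * latent[first:]
            noisy = molecules + rng.normal(
                0.0, settings.sigma, size=len(molecules)) \
                if settings.sigma > 0 else molecules
            area = cell["area"]
            records.append(CellRecord(
                cell_id=cell["cell_id"],
                mother_id=cell["mother_id"],
                first_frame=first,
                last_frame=final_frame,
                mean_fluorescence=noisy * settings.gain / area,
                area=np.full(n_frames - first, area),
            ))
        registry[mother_id] = {
            "class": "repressing" if repressing else "basal",
            "params": params,
            "sigma": settings.sigma,
            "latent": latent,
            "n_tracked_cells": len(cells),
        }

    table = TraceTable(
        records=records,
        frame_interval=settings.frame_interval,
        phases=[Phase(settings.repression_label, "glucose", 0, final_frame)],
    )
    return table, registry


@dataclass(frozen=True)
class TwoRepressionShift:
    """How single-cell truths change from repression r1 to r2.

    ``t_delay`` shifts additively (hours); the other parameters scale
    multiplicatively. Defaults reproduce a shortened repression response
    delay with unchanged degradation.
    """

    t_delay_shift_h: float = -0.12
    GFP_0_factor: float = 1.0
    r_prod_factor: float = 1.0
    r_deg_factor: float = 1.0


def two_repression_cohort(
    settings: CohortSettings,
    shift: TwoRepressionShift | None = None,
    seed: int | None = None,
) -> tuple[tuple[TraceTable, dict], tuple[TraceTable, dict]]:
    """Paired r1/r2 cohorts sharing mother ids and per-cell truths.

    The r1 cohort is drawn from ``settings``; the r2 cohort reuses each
    mother's r1 parameters transformed by ``shift`` (fresh stochastic
    simulation and noise). Mothers keep their ids across repressions so
    the paired sign-test battery can be run with known ground truth.
    """
    shift = shift or TwoRepressionShift()
    seed = settings.seed if seed is None else seed
    r1_settings = replace(settings, repression_label="r1", seed=seed)
    table_r1, reg_r1 = simulate_cohort(r1_settings)

    rng = np.random.default_rng(derive_u32(seed, "r2"))
    n_frames = settings.n_frames
    grid = np.round(np.arange(n_frames) * settings.frame_interval, 10)
    records: list[CellRecord] = []
    registry: dict[str, dict] = {}
    p_div = 1.0 - np.exp(-settings.division_rate_per_h
                         * settings.frame_interval)
    final_frame = n_frames - 1
    for mother_id, entry in reg_r1.items():
        params = dict(entry["params"])
        repressing = entry["class"] == "repressing"
        if repressing:
            params["t_delay"] = float(np.clip(
                params["t_delay"] + shift.t_delay_shift_h, 0.011, 1.99))
            params["r_prod"] = params["r_prod"] * shift.r_prod_factor
        params["GFP_0"] = float(max(0, round(
            params["GFP_0"] * shift.GFP_0_factor)))
        params["r_deg"] = params["r_deg"] * shift.r_deg_factor
        sub_seed = int(rng.integers(2 ** 31))
        sub = replace(
            settings,
            n_mothers=1,
            fraction_repressing=1.0 if repressing else 0.0,
            repression_label="r2",
            seed=sub_seed,
        )
        table_i, reg_i = _simulate_single_mother(mother_id, params,
                                                 repressing, sub, grid)
        records.extend(table_i)
        registry[mother_id] = reg_i
    table_r2 = TraceTable(
        records=records,
        frame_interval=settings.frame_interval,
        phases=[Phase("r2", "glucose", 0, final_frame)],
    )
    return (table_r1, reg_r1), (table_r2, registry)


def _simulate_single_mother(mother_id: str, params: dict[str, float],
                            repressing: bool, settings: CohortSettings,
                            grid: np.ndarray) -> tuple[list[CellRecord], dict]:
    """One mother with fixed (not re-drawn) parameters; shares simulate_cohort's
    division bookkeeping by running it on a single-cell cohort."""
    fixed = {name: LogNormalSpec(value, 0.0) for name, value in params.items()}
    sub = replace(
        settings,
        repressing_params=fixed if repressing else settings.repressing_params,
        basal_params=fixed if not repressing else settings.basal_params,
    )
    table, registry = simulate_cohort(sub)
    entry = registry["m000"]
    entry["params"] = params

    def rename(cid: str | None) -> str | None:
        return None if cid is None else cid.replace("m000", mother_id, 1)

    records = [replace(rec, cell_id=rename(rec.cell_id),
                       mother_id=rename(rec.mother_id))
               for rec in table.records]
    return records, entry


def derive_u32(seed: int, *tokens) -> int:
    """Stable sub-stream seed below 2**31."""
    key = "|".join([str(seed), *map(str, tokens)]).encode()
    return zlib.crc32(key) % (2 ** 31)
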