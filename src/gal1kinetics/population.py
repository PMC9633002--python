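"""Population-level statistics of repression timing and fitted parameters.

Covers the downstream analysis of the fitted single-cell parameters:

* bootstrap (default 1e5 resamples of cells) mean +/- std of the time at
  which the population-mean total-GFP trace peaks;
* pairing of mother cells classified ``with_repression`` in both
  repressions r1 and r2;
* the hypothesis-test battery: two-sided median test (exact Fisher form),
  two-sided paired sign test (exact binomial), paired t-test, all reported
  with Bonferroni correction (m = 12 hypotheses for the main + replicate
  parameter comparisons, m = 8 for the noise-model comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .inference import FitResult
from .preprocessing import CompensatedTrace
from .selection import SelectionResult

__all__ = [
    "BootstrapSummary",
    "PairedParams",
    "mean_trace",
    "time_to_max",
    "bootstrap_time_to_max",
    "pair_cells",
    "median_test",
    "paired_sign_test",
    "paired_t_test",
    "bonferroni",
    "HYPOTHESES_M12",
    "M_MAIN",
    "M_NOISE_COMPARISON",
]

#: The fixed multiple-testing ledger of the main + replicate analysis:
#: 2 median tests of GFP_0 (with vs. without repression kinetics, r1 & r2)
#: and 4 paired sign tests (GFP_0, t_delay, r_prod, r_deg across r1/r2),
#: each counted for the main and the replicate experiment.
HYPOTHESES_M12: tuple[str, ...] = tuple(
    f"{exp}:{test}"
    for exp in ("main", "replicate")
    for test in ("median_GFP_0_r1", "median_GFP_0_r2",
                 "sign_GFP_0", "sign_t_delay", "sign_r_prod", "sign_r_deg")
)
M_MAIN = len(HYPOTHESES_M12)          # 12
M_NOISE_COMPARISON = 8                # 4 parameters x 2 repressions


@dataclass(frozen=True)
class BootstrapSummary:
    """Bootstrap distribution of the peak time of the population mean."""

    mean_time_to_max: float
    std_time_to_max: float
    n_cells: int
    n_bootstrap: int
    seed: int


@dataclass(frozen=True)
class PairedParams:
    """Fitted repression-model parameters of one mother in both repressions."""

    mother_id: str
    theta_r1: object
    theta_r2: object


def _common_grid(traces: Sequence[CompensatedTrace]) -> np.ndarray:
    if not traces:
        raise ValueError("empty trace collection")
    grid = traces[0].times
    for tr in traces[1:]:
        if len(tr.times) != len(grid) or not np.allclose(tr.times, grid):
            raise ValueError("traces are not on a common time grid")
    return grid


def mean_trace(traces: Sequence[CompensatedTrace]) -> CompensatedTrace:
    """Pointwise arithmetic mean of traces sharing one time grid."""
    grid = _common_grid(traces)
    stacked = np.stack([tr.total_gfp for tr in traces])
    return CompensatedTrace(
        mother_id="<population-mean>",
        repression_label=traces[0].repression_label,
        times=grid,
        total_gfp=stacked.mean(axis=0),
    )


def time_to_max(trace: CompensatedTrace) -> float:
    """Time (h) of the trace maximum; ties broken to the earliest time."""
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    return float(trace.times[int(np.argmax(trace.total_gfp))])


def bootstrap_time_to_max(
    traces: Sequence[CompensatedTrace],
    n_bootstrap: int = 100_000,
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap mean +/- std of the population-mean peak time.

    Cells (whole traces, not time points) are resampled with replacement;
    each replicate's mean trace is reduced to its earliest-peak time.
    """
    grid = _common_grid(traces)
    if len(traces) < 2:
        raise ValueError("need at least 2 traces to bootstrap")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    data = np.stack([tr.total_gfp for tr in traces])  # (n_cells, n_t)
    n = len(traces)
    rng = np.random.default_rng(seed)
    peak_times = np.empty(n_bootstrap)
    chunk = max(1, min(n_bootstrap, 20_000_000 // (n * 8)))
    done = 0
    while done < n_bootstrap:
        b = min(chunk, n_bootstrap - done)
        # resampling cells == multinomial weights on the original cells
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=b)
        means = counts @ data / n
        peak_times[done:done + b] = grid[np.argmax(means, axis=1)]
        done += b
    return BootstrapSummary(
        mean_time_to_max=float(peak_times.mean()),
        std_time_to_max=float(peak_times.std()),
        n_cells=n,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def pair_cells(
    selection_r1: Sequence[SelectionResult],
    fits_r1: Mapping[str, FitResult],
    selection_r2: Sequence[SelectionResult],
    fits_r2: Mapping[str, FitResult],
) -> list[PairedParams]:
    """Mothers labelled ``with_repression`` in both r1 and r2, with fits.

    Raises ``ValueError`` on duplicate mother ids within one repression.
    """
    def repressing(selection: Sequence[SelectionResult]) -> set[str]:
        ids = [s.mother_id for s in selection]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mother_id in selection results")
        return {s.mother_id for s in selection if s.label == "with_repression"}

    shared = repressing(selection_r1) & repressing(selection_r2)
    return [PairedParams(mother_id=m, theta_r1=fits_r1[m].theta_hat,
                         theta_r2=fits_r2[m].theta_hat)
            for m in sorted(shared)]


def median_test(group_a, group_b) -> float:
    """Two-sided median test: exact Fisher test on the pooled-median table.

    Counts per group how many values lie above the pooled median (values
    equal to it count as below) and evaluates the 2x2 contingency table
    with the exact hypergeometric (Fisher) test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med = float(np.median(np.concatenate([a, b])))
    table = [[int(np.sum(a > med)), int(np.sum(b > med))],
             [int(np.sum(a <= med)), int(np.sum(b <= med))]]
    if table[0][0] + table[0][1] == 0 or table[1][0] + table[1][1] == 0:
        raise ValueError("degenerate median test: all values on one side "
                         "of the pooled median")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def paired_sign_test(a, b) -> float:
    """Two-sided exact sign test on paired samples; ties are discarded."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    n_pos = int(np.sum(diff > 0))
    n_neg = int(np.sum(diff < 0))
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("degenerate sign test: all pairs tied")
    return float(stats.binomtest(n_pos, n, 0.5,
                                 alternative="two-sided").pvalue)


def paired_t_test(a, b) -> float:
    """Two-sided paired-sample t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    diff = a - b
    if diff.std(ddof=1) == 0.0:
        raise ValueError("degenerate t-test: zero variance of differences")
    return float(stats.ttest_rel(a, b).pvalue)


def bonferroni(p: float, m: int, alpha: float = 0.05) -> bool:
    """Bonferroni decision: significant iff ``p < alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return bool(p < alpha / m)
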