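"""End-to-end convenience: fit both models per trace and classify.

Thin orchestration over :mod:`inference` and :mod:`selection` used by the
command-line interface, the test suite and the acceptance script.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .inference import FitResult, NoiseKind, OptimizationConfig, fit_trace
from .preprocessing import CompensatedTrace
from .selection import SelectionResult, classify_trace

__all__ = ["fit_both_models", "analyze_repression", "fits_to_frame",
           "selections_to_frame"]


def fit_both_models(
    trace: CompensatedTrace,
    noise_kind: NoiseKind = "constant",
    config: OptimizationConfig | None = None,
) -> tuple[FitResult, FitResult]:
    """(repression fit, no-repression fit) for one trace."""
    fit_rep = fit_trace(trace, "repression", noise_kind, config)
    fit_norep = fit_trace(trace, "no_repression", noise_kind, config)
    return fit_rep, fit_norep


def analyze_repression(
    traces: Sequence[CompensatedTrace],
    noise_kind: NoiseKind = "constant",
    config: OptimizationConfig | None = None,
) -> tuple[dict[str, FitResult], dict[str, FitResult], list[SelectionResult]]:
    """Fit and classify every trace of one repression.

    Returns repression fits, no-repression fits (both keyed by mother id)
    and the per-trace selection results.
    """
    fits_rep: dict[str, FitResult] = {}
    fits_norep: dict[str, FitResult] = {}
    selections: list[SelectionResult] = []
    for trace in traces:
        fit_rep, fit_norep = fit_both_models(trace, noise_kind, config)
        fits_rep[trace.mother_id] = fit_rep
        fits_norep[trace.mother_id] = fit_norep
        selections.append(classify_trace(
            fit_rep, fit_norep, n=len(trace.times),
            mother_id=trace.mother_id,
            repression_label=trace.repression_label))
    return fits_rep, fits_norep, selections


def fits_to_frame(fits: dict[str, FitResult]) -> pd.DataFrame:
    """One row per trace: parameter estimates, logL and diagnostics."""
    rows = []
    for mother_id, fit in fits.items():
        row = {"mother_id": mother_id, "model": fit.model_kind,
               "noise": fit.noise_kind, "logL": fit.logL,
               "n_starts_used": fit.n_starts_used,
               "n_converged": fit.n_converged,
               "converged": fit.converged_flag}
        theta = fit.theta_hat
        for name in ("GFP_0", "r_basal", "r_prod", "r_deg", "t_delay",
                     "sigma", "Var_0"):
            if hasattr(theta, name):
                row[name] = getattr(theta, name)
        rows.append(row)
    return pd.DataFrame(rows)


def selections_to_frame(selections: Sequence[SelectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"mother_id": [s.mother_id for s in selections],
         "repression": [s.repression_label for s in selections],
         "bic_repression": [s.bic_repression for s in selections],
         "bic_no_repression": [s.bic_no_repression for s in selections],
         "delta_bic": [s.delta_bic for s in selections],
         "label": [s.label for s in selections],
         "converged": [s.converged for s in selections]})
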