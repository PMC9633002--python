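"""BIC model selection: cells with vs. without repression kinetics.

For each trace the repression and no-repression fits are compared by the
Bayesian information criterion, ``BIC = ln(n) k - 2 logL`` (natural log;
n data points, k fitted parameters). The more complex repression model is
accepted only when it beats the simpler one by more than 10 BIC units:
``BIC_repression < BIC_no_repression - 10``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .inference import FitResult

__all__ = ["SelectionResult", "bic", "classify_trace", "DEFAULT_BIC_THRESHOLD"]

DEFAULT_BIC_THRESHOLD = 10.0

Label = Literal["with_repression", "without_repression"]


@dataclass(frozen=True)
class SelectionResult:
    """Per-trace classification with both BIC values and their difference.

    ``delta_bic = bic_no_repression - bic_repression``; the label is
    ``with_repression`` iff ``delta_bic > threshold``.
    """

    mother_id: str
    repression_label: str
    bic_repression: float
    bic_no_repression: float
    delta_bic: float
    label: Label
    converged: bool = True


def bic(logL: float, n: int, k: int) -> float:
    """Bayesian information criterion ``ln(n) k - 2 logL``; lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if not np.isfinite(logL):
        warnings.warn("non-finite log-likelihood in BIC", RuntimeWarning,
                      stacklevel=2)
    return float(np.log(n) * k - 2.0 * logL)


def classify_trace(
    fit_rep: FitResult,
    fit_norep: FitResult,
    n: int,
    mother_id: str = "",
    repression_label: str = "",
    threshold: float = DEFAULT_BIC_THRESHOLD,
) -> SelectionResult:
    """Label one trace from its two model fits via the Delta-BIC rule.

    ``n`` is the number of fitted time points (41 for a full 2-h trace at
    3-min sampling). Traces whose fits did not both converge are still
    classified but flagged.
    """
    if fit_rep.model_kind != "repression" or \
            fit_norep.model_kind != "no_repression":
        raise ValueError("fits passed in the wrong order or of wrong kinds")
    if fit_rep.noise_kind != fit_norep.noise_kind:
        raise ValueError("fits use different noise models")
    b_rep = bic(fit_rep.logL, n, fit_rep.k)
    b_norep = bic(fit_norep.logL, n, fit_norep.k)
    delta = b_norep - b_rep
    label: Label = ("with_repression" if delta > threshold
                    else "without_repression")
    return SelectionResult(
        mother_id=mother_id,
        repression_label=repression_label,
        bic_repression=b_rep,
        bic_no_repression=b_norep,
        delta_bic=delta,
        label=label,
        converged=fit_rep.converged_flag and fit_norep.converged_flag,
    )
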