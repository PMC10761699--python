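"""Per-cell reporter expression from bulk fluorescence and predicted counts.

Bulk well fluorescence scales with both per-cell expression and cell
number. Dividing the total fluorescence by the GI-predicted cell
concentration C_p at a chosen time inside the calibration linearity
window yields an estimated expression level per cell, analogous to the
OD-normalised expression routinely reported for bacteria. Groups of
replicate per-cell values (e.g. induction doses) are compared with a
two-sided t-test (Welch by default).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import AnalysisError, ValidationError, WindowError
from .kinetics import PredictionResult

__all__ = [
    "ExpressionRecord",
    "per_cell_expression",
    "compare_groups",
    "significance_label",
]


@dataclass
class ExpressionRecord:
    """Bulk fluorescence over time for one well, plus its induction dose."""

    well_id: str
    times: np.ndarray
    fluor_total: np.ndarray
    dose: Optional[float] = None
    dose_units: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluor_total = np.asarray(self.fluor_total, dtype=float)
        if self.times.size != self.fluor_total.size:
            raise ValidationError(
                f"well {self.well_id!r}: fluorescence length does not match times"
            )


def per_cell_expression(
    rec: ExpressionRecord,
    prediction: PredictionResult,
    at_time: float,
    window: Optional[Tuple[float, float]] = None,
    align_tol: float = 1.0,
) -> float:
    """Total fluorescence divided by predicted cells/ml at ``at_time``.

    ``at_time`` must lie inside the calibration linearity ``window`` when
    one is given, and C_p must be defined and positive there. Units:
    intensity per (cells/ml) — proportional to intensity per cell for a
    fixed well volume.
    """
    if window is not None and not (window[0] <= at_time <= window[1]):
        raise WindowError(
            f"t={at_time} h is outside the linearity window [{window[0]}, {window[1]}] h"
        )
    i = int(np.argmin(np.abs(rec.times - at_time)))
    if abs(rec.times[i] - at_time) > align_tol:
        raise AnalysisError(
            f"well {rec.well_id!r}: no fluorescence reading within "
            f"{align_tol} h of t={at_time} h"
        )
    j = int(np.argmin(np.abs(prediction.times - at_time)))
    if abs(prediction.times[j] - at_time) > align_tol:
        raise AnalysisError(
            f"well {rec.well_id!r}: no predicted count within "
            f"{align_tol} h of t={at_time} h"
        )
    cp = prediction.cp[j]
    if not np.isfinite(cp) or cp <= 0:
        raise AnalysisError(
            f"well {rec.well_id!r}: C_p undefined at t={at_time} h"
        )
    return float(rec.fluor_total[i] / cp)


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> float:
    """Two-sided t-test p-value between two replicate groups.

    Welch's unequal-variance test by default (the safer choice for small
    replicate groups); pass ``equal_var=True`` for the pooled-variance
    variant. Symmetric in its arguments.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 replicates")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("groups must contain finite values only")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant and equal: no evidence of difference
        return 1.0
    return p


def significance_label(p: float) -> str:
    """Significance band for a p-value.

    Bands follow this assay's conventional legend verbatim — including
    its unusual ``ns: p > 0.5`` threshold (almost certainly a typo for
    the conventional 0.05, kept as-is rather than silently corrected;
    see the methods note). Values between 0.01 and 0.5 get a single
    ``*``.
    """
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p > 0.5:
        return "ns"
    return "*"
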