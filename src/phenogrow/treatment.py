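"""Dose-response analysis of growth rates under drug treatment.

Growth rates measured at each drug dose are expressed as a percent of the
mean untreated (dose 0) rate; the trend across doses is an OLS line of
relative rate on log10(dose), fitted over positive doses only (the control
cannot sit on a log axis). No sigmoidal IC50 model is fitted — the readout
is the per-decade slope of the log-linear trend.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .errors import FitError, NormalisationError, ValidationError
from .kinetics import _ols

__all__ = [
    "TrendFit",
    "DoseResponse",
    "normalize_rates",
    "fit_dose_trend",
    "percent_change",
    "build_dose_response",
    "rate_change_around",
]


class TrendFit(NamedTuple):
    slope: float  # percent per decade of dose
    intercept: float
    r2: float  # NaN when the response is constant (trend undefined)


@dataclass
class DoseResponse:
    """Per-dose relative growth rates and their log-dose trends."""

    doses: np.ndarray  # sorted, includes 0 for the control
    mu_p_rel: np.ndarray  # mean percent of control, per dose
    mu_c_rel: np.ndarray
    n_replicates: np.ndarray
    mu_p_trend: Optional[TrendFit] = None
    mu_c_trend: Optional[TrendFit] = None


def normalize_rates(
    rates_by_dose: Mapping[float, Sequence[float]]
) -> Dict[float, np.ndarray]:
    """Express every rate as percent of the mean dose-0 (control) rate."""
    if 0 not in rates_by_dose and 0.0 not in rates_by_dose:
        raise NormalisationError("no dose-0 control present; cannot normalise")
    control = np.asarray(rates_by_dose.get(0, rates_by_dose.get(0.0)), dtype=float)
    if control.size == 0:
        raise NormalisationError("dose-0 control has no replicates")
    ref = float(np.mean(control))
    if ref == 0:
        raise NormalisationError("mean control rate is 0; cannot normalise")
    return {
        float(d): 100.0 * np.asarray(r, dtype=float) / ref
        for d, r in rates_by_dose.items()
    }


def fit_dose_trend(
    doses: Sequence[float], relative_rates: Sequence[float]
) -> TrendFit:
    """OLS of relative rate (percent) on log10(dose), positive doses only.

    A constant response yields slope 0 with r2 flagged NaN (a trend r2 is
    meaningless when the response does not vary).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(relative_rates, dtype=float)
    if d.size != y.size:
        raise ValidationError("doses and relative rates must align")
    if np.any(d <= 0):
        raise ValidationError(
            "dose trend is fitted on a log axis: all doses must be > 0 "
            "(exclude the dose-0 control)"
        )
    if d.size < 3:
        raise FitError(f"need >= 3 positive doses for a trend fit, got {d.size}")
    x = np.log10(d)
    if np.ptp(y) == 0:
        return TrendFit(0.0, float(y[0]), float("nan"))
    slope, intercept, r2 = _ols(x, y)
    return TrendFit(slope, intercept, r2)


def percent_change(mu_treated: float, mu_reference: float) -> float:
    """Percent decrease of a treated rate vs a reference rate.

    100*(1 − mu_treated/mu_reference); exceeds 100 when the treated rate
    goes negative.
    """
    if mu_reference == 0:
        raise ValidationError("reference rate is 0; percent change undefined")
    return 100.0 * (1.0 - float(mu_treated) / float(mu_reference))


def build_dose_response(
    mu_p_by_dose: Mapping[float, Sequence[float]],
    mu_c_by_dose: Mapping[float, Sequence[float]],
) -> DoseResponse:
    """Normalise replicate rates per dose and fit both log-dose trends."""
    rel_p = normalize_rates(mu_p_by_dose)
    rel_c = normalize_rates(mu_c_by_dose)
    doses = np.array(sorted(set(rel_p) | set(rel_c)), dtype=float)

    def mean_at(rel, d):
        return float(np.mean(rel[d])) if d in rel else float("nan")

    mu_p_rel = np.array([mean_at(rel_p, d) for d in doses])
    mu_c_rel = np.array([mean_at(rel_c, d) for d in doses])
    n_rep = np.array(
        [len(rel_p.get(d, ())) + len(rel_c.get(d, ())) for d in doses], dtype=int
    )
    pos = doses > 0
    trend_p = trend_c = None
    if pos.sum() >= 3:
        ok_p = pos & np.isfinite(mu_p_rel)
        ok_c = pos & np.isfinite(mu_c_rel)
        if ok_p.sum() >= 3:
            trend_p = fit_dose_trend(doses[ok_p], mu_p_rel[ok_p])
        if ok_c.sum() >= 3:
            trend_c = fit_dose_trend(doses[ok_c], mu_c_rel[ok_c])
    return DoseResponse(
        doses=doses,
        mu_p_rel=mu_p_rel,
        mu_c_rel=mu_c_rel,
        n_replicates=n_rep,
        mu_p_trend=trend_p,
        mu_c_trend=trend_c,
    )


def rate_change_around(
    times: Sequence[float],
    ln_values: Sequence[float],
    t_treat: float = 24.0,
) -> Tuple[float, float, float]:
    """Growth rate strictly before vs after a treatment time.

    Fits OLS slopes on the points with t < ``t_treat`` and t >= ``t_treat``
    (at least two finite points each side) and returns
    (mu_before, mu_after, percent decrease). Used for colchicine-style
    before/after comparisons where the drug is added mid-assay.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ln_values, dtype=float)
    ok = np.isfinite(y)
    before = ok & (t < t_treat)
    after = ok & (t >= t_treat)
    if before.sum() < 2 or after.sum() < 2:
        raise FitError(
            "need >= 2 finite points on each side of the treatment time"
        )
    mu_before, _, _ = _ols(t[before], y[before])
    mu_after, _, _ = _ols(t[after], y[after])
    return mu_before, mu_after, percent_change(mu_after, mu_before)
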