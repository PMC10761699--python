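"""Exponential-phase kinetics: window detection, growth rates, calibration.

The analysis follows a three-step procedure. (1) On ln(C) vs time the
contiguous window of fastest growth — the exponential phase — is found
automatically; the slope of an ordinary-least-squares fit over that window
is the count growth rate mu_c (h^-1). (2) The very same time window is
fitted on ln(GI) vs time, giving the plate-reader growth rate mu_p.
(3) The in-window, time-aligned (GI, C) pairs are fitted as
ln(GI) = m*ln(C) + q. The conversion factor CF = mu_p/mu_c links the two
rates; on ideal power-law data CF equals m exactly, since
d ln(GI)/dt = m * d ln(C)/dt.

Once a calibration exists, cell concentration is predicted from GI alone
as C_p = (GI/exp(q))^(1/m), growth rates as mu_cp = mu_p/CF, and the
method's accuracy against parallel counts as A = mean(C_p)/mean(C).

Window detection is an exhaustive search over all contiguous windows with
at least ``min_points`` points whose fit reaches ``r2_min``; among those
the maximal slope wins, with ties (within a small relative tolerance that
absorbs float round-off on exactly linear data) broken by longer window,
then earlier start. At plate-reader problem sizes (<= a few hundred points
per curve) the O(n^2) search is instantaneous and exactly matches a
brute-force specification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    AnalysisError,
    CalibrationError,
    DetectionError,
    FitError,
    PredictionError,
)
from .series import CountSeries, GrowthIndexSeries

__all__ = [
    "ExpWindowFit",
    "Calibration",
    "PredictionResult",
    "CharacteriseResult",
    "detect_exponential_window",
    "fit_rate_in_window",
    "fit_calibration",
    "characterise_well",
    "conversion_factor",
    "predict_counts",
    "predict_mu_c",
    "accuracy",
]

#: Relative slope tolerance below which two candidate windows are tied.
SLOPE_TIE_RTOL = 1e-9


@dataclass
class ExpWindowFit:
    """A linear fit of a log-series over a contiguous time window."""

    i_start: int
    i_end: int  # inclusive, indices into the finite-value arrays used
    t_start: float
    t_end: float
    slope: float  # per-hour growth rate over the window
    intercept: float
    r2: float
    n_points: int

    @property
    def window(self) -> Tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass
class Calibration:
    """ln(GI) = m*ln(C) + q for one cell line / medium / condition."""

    m: float
    q: float
    r2: float
    cf: float
    window: Tuple[float, float]
    meta: Dict[str, Optional[str]] = field(default_factory=dict)


@dataclass
class PredictionResult:
    """Counts predicted from GI; NaN marks times where GI <= 0."""

    times: np.ndarray
    cp: np.ndarray
    accuracy: Optional[float] = None
    mucp: Optional[float] = None


@dataclass
class CharacteriseResult:
    """Full single-well characterisation: both window fits + calibration."""

    fit_c: ExpWindowFit
    fit_p: ExpWindowFit
    calibration: Calibration


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Slope, intercept, r2 of an ordinary least-squares line.

    A zero-variance response fits the constant line exactly: r2 is 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    if sxx == 0:
        raise FitError("cannot fit a slope: all x values identical")
    slope = float(dx @ dy) / sxx
    intercept = ym - slope * xm
    ss_tot = float(dy @ dy)
    if ss_tot == 0:
        return slope, intercept, 1.0
    resid = dy - slope * dx
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return slope, intercept, float(min(max(r2, 0.0), 1.0))


def _finite(times, values) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v) & np.isfinite(t)
    return t[mask], v[mask]


def detect_exponential_window(
    times: Sequence[float],
    ln_values: Sequence[float],
    min_points: int = 4,
    r2_min: float = 0.90,
) -> ExpWindowFit:
    """Find the contiguous window of fastest log-linear growth.

    Non-finite ``ln_values`` (e.g. the log of a non-positive GI) are
    dropped before the search. Among all contiguous windows with at least
    ``min_points`` retained points and OLS r^2 >= ``r2_min``, the window
    with the maximal slope is returned; ties go to the longer window, then
    to the earlier start. Raises :class:`DetectionError` if no window
    qualifies (common for flattened drug-treated curves — consider
    relaxing ``r2_min``).
    """
    t, y = _finite(times, ln_values)
    n = t.size
    if n < min_points:
        raise DetectionError(
            f"only {n} finite points; need at least min_points={min_points}"
        )
    # Prefix sums over globally centred coordinates keep the O(n^2) sweep
    # numerically well conditioned.
    tc = t - t.mean()
    yc = y - y.mean()
    one = np.concatenate(([0.0], np.ones(n))).cumsum()
    sx = np.concatenate(([0.0], tc)).cumsum()
    sy = np.concatenate(([0.0], yc)).cumsum()
    sxx = np.concatenate(([0.0], tc * tc)).cumsum()
    sxy = np.concatenate(([0.0], tc * yc)).cumsum()
    syy = np.concatenate(([0.0], yc * yc)).cumsum()

    best: Optional[ExpWindowFit] = None
    for i in range(0, n - min_points + 1):
        for j in range(i + min_points - 1, n):
            cnt = one[j + 1] - one[i]
            wsx = sx[j + 1] - sx[i]
            wsy = sy[j + 1] - sy[i]
            wsxx = sxx[j + 1] - sxx[i]
            wsxy = sxy[j + 1] - sxy[i]
            wsyy = syy[j + 1] - syy[i]
            det = cnt * wsxx - wsx * wsx
            if det <= 0:
                continue
            slope = (cnt * wsxy - wsx * wsy) / det
            ss_tot = wsyy - wsy * wsy / cnt
            if ss_tot <= 0:
                r2 = 1.0
            else:
                ss_reg = slope * (wsxy - wsx * wsy / cnt)
                r2 = min(max(ss_reg / ss_tot, 0.0), 1.0)
            if r2 < r2_min:
                continue
            cand = ExpWindowFit(
                i_start=i,
                i_end=j,
                t_start=float(t[i]),
                t_end=float(t[j]),
                slope=float(slope),
                intercept=float(
                    (wsy / cnt + y.mean()) - slope * (wsx / cnt + t.mean())
                ),
                r2=float(r2),
                n_points=int(cnt),
            )
            if best is None or _window_beats(cand, best):
                best = cand
    if best is None:
        raise DetectionError(
            f"no contiguous window with >= {min_points} points reaches r2 >= {r2_min}"
        )
    return best


def _window_beats(cand: ExpWindowFit, best: ExpWindowFit) -> bool:
    """Selection rule: max slope; ties -> longer window -> earlier start."""
    tol = SLOPE_TIE_RTOL * max(1.0, abs(best.slope))
    if cand.slope > best.slope + tol:
        return True
    if cand.slope < best.slope - tol:
        return False
    if cand.n_points != best.n_points:
        return cand.n_points > best.n_points
    return cand.i_start < best.i_start


def fit_rate_in_window(
    times: Sequence[float],
    ln_values: Sequence[float],
    window: Union[Tuple[float, float], ExpWindowFit],
) -> ExpWindowFit:
    """OLS fit over exactly the points inside a given time range.

    This is how mu_p is computed: on ln(GI) inside the window previously
    detected on ln(C).
    """
    if isinstance(window, ExpWindowFit):
        window = window.window
    t0, t1 = float(window[0]), float(window[1])
    t, y = _finite(times, ln_values)
    mask = (t >= t0) & (t <= t1)
    t, y = t[mask], y[mask]
    if t.size < 2:
        raise FitError(
            f"only {t.size} finite point(s) inside window [{t0}, {t1}] h; need >= 2"
        )
    slope, intercept, r2 = _ols(t, y)
    return ExpWindowFit(
        i_start=0,
        i_end=int(t.size - 1),
        t_start=float(t[0]),
        t_end=float(t[-1]),
        slope=slope,
        intercept=intercept,
        r2=r2,
        n_points=int(t.size),
    )


def _pair_nearest(
    t_ref: np.ndarray, t_other: np.ndarray, tol: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Match each reference time to its nearest partner within ``tol`` hours."""
    ref_idx, other_idx = [], []
    for i, t in enumerate(t_ref):
        if t_other.size == 0:
            break
        j = int(np.argmin(np.abs(t_other - t)))
        if abs(t_other[j] - t) <= tol:
            ref_idx.append(i)
            other_idx.append(j)
    return np.asarray(ref_idx, dtype=int), np.asarray(other_idx, dtype=int)


def fit_calibration(
    gi: GrowthIndexSeries,
    counts: CountSeries,
    window: Union[Tuple[float, float], ExpWindowFit],
    align_tol: float = 1.0,
    meta: Optional[Dict[str, Optional[str]]] = None,
) -> Calibration:
    """Fit ln(GI) = m*ln(C) + q over in-window, time-aligned pairs.

    Each count time inside ``window`` is matched to the nearest GI time
    within ``align_tol`` hours. Pairs with GI <= 0 are dropped with a
    warning; at least 3 pairs are required. The conversion factor
    CF = mu_p/mu_c is computed from the two window fits and stored.
    """
    if isinstance(window, ExpWindowFit):
        window = window.window
    t0, t1 = float(window[0]), float(window[1])

    with np.errstate(divide="ignore", invalid="ignore"):
        ln_c = np.log(counts.counts)
        ln_gi = np.log(np.where(gi.gi > 0, gi.gi, np.nan))
    mu_c = fit_rate_in_window(counts.times, ln_c, (t0, t1)).slope
    mu_p = fit_rate_in_window(gi.times, ln_gi, (t0, t1)).slope

    in_win = (counts.times >= t0) & (counts.times <= t1)
    ci, gj = _pair_nearest(counts.times[in_win], gi.times, align_tol)
    c_vals = counts.counts[in_win][ci]
    gi_vals = gi.gi[gj]
    pos = gi_vals > 0
    if np.any(~pos):
        warnings.warn(
            f"well {gi.well_id!r}: dropped {int((~pos).sum())} aligned pair(s) "
            "with non-positive GI"
        )
    c_vals, gi_vals = c_vals[pos], gi_vals[pos]
    if c_vals.size < 3:
        raise CalibrationError(
            f"well {gi.well_id!r}: only {c_vals.size} aligned (GI, C) pair(s) "
            f"inside window [{t0}, {t1}] h; need >= 3"
        )
    m, q, r2 = _ols(np.log(c_vals), np.log(gi_vals))
    return Calibration(
        m=m,
        q=q,
        r2=r2,
        cf=conversion_factor(mu_p, mu_c),
        window=(t0, t1),
        meta=dict(meta or {}),
    )


def characterise_well(
    gi: GrowthIndexSeries,
    counts: CountSeries,
    min_points: int = 4,
    r2_min: float = 0.90,
    align_tol: float = 1.0,
    meta: Optional[Dict[str, Optional[str]]] = None,
) -> CharacteriseResult:
    """The full calibration procedure for one well.

    Detect the exponential window on ln(C), fit mu_c there, fit mu_p on
    ln(GI) over the same time window, then fit the ln(GI)-ln(C)
    calibration (which also stores CF = mu_p/mu_c).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_c = np.log(counts.counts)
        ln_gi = np.log(np.where(gi.gi > 0, gi.gi, np.nan))
    fit_c = detect_exponential_window(counts.times, ln_c, min_points, r2_min)
    fit_p = fit_rate_in_window(gi.times, ln_gi, fit_c.window)
    cal = fit_calibration(gi, counts, fit_c.window, align_tol=align_tol, meta=meta)
    return CharacteriseResult(fit_c=fit_c, fit_p=fit_p, calibration=cal)


def conversion_factor(mu_p: float, mu_c: float) -> float:
    """CF = mu_p/mu_c (dimensionless)."""
    if mu_c == 0:
        raise AnalysisError("conversion factor undefined: mu_c is 0")
    return float(mu_p) / float(mu_c)


def predict_counts(
    gi: GrowthIndexSeries,
    cal: Calibration,
    window: Optional[Tuple[float, float]] = None,
) -> PredictionResult:
    """Predict C from GI via C_p = (GI/exp(q))^(1/m).

    Only defined where GI > 0; other times are flagged NaN. If ``window``
    is given, prediction is restricted to times inside it (the calibration
    linearity window).
    """
    if cal.m == 0:
        raise PredictionError("calibration has m = 0; prediction undefined")
    times = gi.times
    values = gi.gi
    if window is not None:
        mask = (times >= window[0]) & (times <= window[1])
        times, values = times[mask], values[mask]
    if not np.any(values > 0):
        raise PredictionError(
            f"well {gi.well_id!r}: no positive GI values to predict from"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = np.where(
            values > 0, np.power(values / np.exp(cal.q), 1.0 / cal.m), np.nan
        )
    return PredictionResult(times=times.copy(), cp=cp)


def predict_mu_c(mu_p: float, cf: float) -> float:
    """Predicted count growth rate mu_cp = mu_p/CF."""
    if cf == 0:
        raise AnalysisError("cannot predict mu_c: CF is 0")
    return float(mu_p) / float(cf)


def accuracy(
    prediction: PredictionResult,
    counts: CountSeries,
    align_tol: float = 1.0,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Accuracy A = mean(C_p)/mean(C) over time-aligned pairs.

    The closer A is to 1, the more accurate the GI-based estimate of cell
    concentration. Pairs where C_p is undefined (NaN) are skipped.
    """
    t_c, c = counts.times, counts.counts
    if window is not None:
        m = (t_c >= window[0]) & (t_c <= window[1])
        t_c, c = t_c[m], c[m]
    ci, pj = _pair_nearest(t_c, prediction.times, align_tol)
    if ci.size == 0:
        raise AnalysisError("no time-aligned (C_p, C) pairs to compute accuracy")
    cp = prediction.cp[pj]
    ok = np.isfinite(cp)
    if not np.any(ok):
        raise AnalysisError("all aligned predictions are undefined")
    return float(np.mean(cp[ok]) / np.mean(c[ci][ok]))
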