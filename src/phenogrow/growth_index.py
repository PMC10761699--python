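"""Growth index (GI) computation from dual-wavelength absorbance.

The growth index is the ratio of the acidic phenol-red absorbance peak
(430 nm) over the basic peak (560 nm), normalised to the background of the
cell-free medium. As cells grow they acidify the medium, shifting phenol
red towards its acid form, so GI rises with cell concentration.

Background normalisation is subtraction of a blank-derived ratio by
default: GI(t) = Abs430(t)/Abs560(t) − background. Subtraction is the mode
under which the outlier rule "curve with negative GI at six hours" can
fire at all (a ratio divided by a positive background is always positive);
``divide`` mode is offered for sensitivity analysis, with any constant
factor absorbed into the calibration intercept q.
"""
from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np

from .errors import ConfigurationError, DivisionError
from .series import GrowthIndexSeries, WellSeries

__all__ = ["raw_ratio", "estimate_background", "compute_gi", "compute_gi_plate"]

_MODES = ("subtract", "divide")


def raw_ratio(well: WellSeries) -> np.ndarray:
    """Per-time Abs430/Abs560 ratio (dimensionless).

    Invariant under any common photometer gain applied to both channels.
    Raises :class:`DivisionError` naming the first offending time if
    Abs560 is zero anywhere.
    """
    zero = np.flatnonzero(well.abs560 == 0)
    if zero.size:
        raise DivisionError(well.well_id, float(well.times[zero[0]]))
    return well.abs430 / well.abs560


def estimate_background(blanks: Iterable[WellSeries]) -> float:
    """Background ratio: mean over blank wells of the time-mean raw ratio."""
    means = [float(np.mean(raw_ratio(b))) for b in blanks]
    if not means:
        raise ConfigurationError(
            "no blank wells to estimate the background from; "
            "pass a constant background instead"
        )
    return float(np.mean(means))


def compute_gi(
    well: WellSeries,
    background: Optional[float] = None,
    mode: str = "subtract",
) -> GrowthIndexSeries:
    """Turn one well's absorbance into a :class:`GrowthIndexSeries`.

    ``subtract`` (default): gi(t) = ratio(t) − background;
    ``divide``: gi(t) = ratio(t)/background.

    When ``background`` is None the well's own first-reading ratio is used
    (so gi at the first reading is 0 or 1 depending on mode) and the mode
    string gains a ``"-self"`` suffix. ``gi0`` records the value at the
    earliest time (nominally six hours); it is a reference for the
    exclusion rules, not a divisor.
    """
    if mode not in _MODES:
        raise ConfigurationError(f"invalid background mode {mode!r}; use one of {_MODES}")
    ratio = raw_ratio(well)
    mode_label = mode
    if background is None:
        background = float(ratio[0])
        mode_label = mode + "-self"
    background = float(background)
    if not np.isfinite(background):
        raise ConfigurationError("background must be finite")
    if mode == "subtract":
        gi = ratio - background
    else:
        if background == 0:
            raise ConfigurationError("divide mode requires a non-zero background")
        gi = ratio / background
    return GrowthIndexSeries(
        well_id=well.well_id,
        times=well.times.copy(),
        gi=gi,
        gi0=float(gi[0]),
        background=background,
        mode=mode_label,
        restart_times=well.restart_times,
    )


def compute_gi_plate(
    wells: Dict[str, WellSeries],
    mode: str = "subtract",
    background: Optional[float] = None,
) -> Dict[str, GrowthIndexSeries]:
    """GI for every non-blank well of a plate.

    The background is estimated from the blank wells (mean of time-mean
    ratios) unless given explicitly; if the plate has no blanks and no
    background is supplied, each well falls back to its own first reading.
    """
    blanks = [w for w in wells.values() if w.meta.is_blank]
    if background is None and blanks:
        background = estimate_background(blanks)
    return {
        wid: compute_gi(w, background=background, mode=mode)
        for wid, w in sorted(wells.items())
        if not w.meta.is_blank
    }
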