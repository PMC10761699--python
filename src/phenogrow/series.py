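"""Core in-memory containers shared across the pipeline.

A plate-reader experiment is represented as a set of :class:`WellSeries`
(dual-wavelength absorbance, optionally fluorescence, per well), parallel
:class:`CountSeries` (cells/ml from a cell counter, usually on a sparser
grid), and the derived :class:`GrowthIndexSeries` (the background-normalised
Abs430/Abs560 ratio used as a non-invasive proxy for cell concentration).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["WellMeta", "WellSeries", "CountSeries", "GrowthIndexSeries"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class WellMeta:
    """Per-well metadata joined from the plate layout table."""

    cell_line: Optional[str] = None
    medium: Optional[str] = None
    phenol_red_mg_per_L: Optional[float] = None
    temp_C: Optional[float] = None
    carbon_source: Optional[str] = None
    dose: Optional[float] = None
    dose_units: Optional[str] = None
    is_blank: bool = False


@dataclass
class WellSeries:
    """One well's timestamped absorbance (and optional fluorescence) channels.

    Attributes
    ----------
    well_id : str
        Plate coordinate label, e.g. ``"A1"``.
    times : ndarray
        Hours since assay start, strictly increasing.
    abs430, abs560 : ndarray
        Absorbance at 430 nm (acidic phenol-red peak) and 560 nm (basic
        peak), one finite value per time point.
    fluor : dict
        Optional fluorescence channels, keyed by channel name; values are
        arrays aligned on ``times`` (NaN where a reading is missing).
    meta : WellMeta
        Layout metadata (cell line, medium, dose, blank flag, ...).
    restart_times : tuple of float
        Hours at which the plate reader was reopened (e.g. for parallel
        counting); the first reading after each restart is unreliable and
        is dropped by the exclusion rules.
    """

    well_id: str
    times: np.ndarray
    abs430: np.ndarray
    abs560: np.ndarray
    fluor: Mapping[str, np.ndarray] = field(default_factory=dict)
    meta: WellMeta = field(default_factory=WellMeta)
    restart_times: Sequence[float] = ()

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.abs430 = _as_float_array(self.abs430, "abs430")
        self.abs560 = _as_float_array(self.abs560, "abs560")
        n = self.times.size
        if self.abs430.size != n or self.abs560.size != n:
            raise ValidationError(
                f"well {self.well_id!r}: channel lengths do not match times"
            )
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"well {self.well_id!r}: times must be strictly increasing"
            )
        if not (np.all(np.isfinite(self.abs430)) and np.all(np.isfinite(self.abs560))):
            raise ValidationError(
                f"well {self.well_id!r}: absorbance values must be finite"
            )
        self.fluor = {k: _as_float_array(v, f"fluor[{k}]") for k, v in self.fluor.items()}
        for k, v in self.fluor.items():
            if v.size != n:
                raise ValidationError(
                    f"well {self.well_id!r}: fluorescence channel {k!r} length mismatch"
                )
        self.restart_times = tuple(float(t) for t in self.restart_times)

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class CountSeries:
    """Timestamped cell concentrations C (cells/ml) for one well.

    ``c0`` is the concentration at seeding (the earliest count unless given
    explicitly); it anchors the ``C < C0`` outlier-exclusion rule.
    """

    well_id: str
    times: np.ndarray
    counts: np.ndarray
    c0: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.counts = _as_float_array(self.counts, "counts")
        if self.counts.size != self.times.size:
            raise ValidationError(
                f"well {self.well_id!r}: counts length does not match times"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"well {self.well_id!r}: times must be strictly increasing"
            )
        if self.counts.size and not np.all(self.counts > 0):
            raise ValidationError(
                f"well {self.well_id!r}: counts must be positive (cells/ml)"
            )
        if self.c0 is None:
            if not self.counts.size:
                raise ValidationError(f"well {self.well_id!r}: empty count series")
            self.c0 = float(self.counts[0])
        self.c0 = float(self.c0)
        if self.c0 <= 0:
            raise ValidationError(f"well {self.well_id!r}: c0 must be positive")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class GrowthIndexSeries:
    """Background-normalised growth index GI over time for one well.

    ``gi0`` is the GI value at the earliest reading (nominally six hours
    into the assay). It is kept as the reference for the ``GI < GI0``
    exclusion rule and is *not* used to rescale the stored values.
    ``background`` and ``mode`` record how the raw Abs430/Abs560 ratio was
    normalised (``"subtract"`` or ``"divide"``; a ``"-self"`` suffix marks
    a background taken from the well's own first reading).
    """

    well_id: str
    times: np.ndarray
    gi: np.ndarray
    gi0: float
    background: float
    mode: str = "subtract"
    restart_times: Sequence[float] = ()

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.gi = _as_float_array(self.gi, "gi")
        if self.gi.size != self.times.size:
            raise ValidationError(
                f"well {self.well_id!r}: gi length does not match times"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"well {self.well_id!r}: times must be strictly increasing"
            )
        self.gi0 = float(self.gi0)
        self.background = float(self.background)
        self.restart_times = tuple(float(t) for t in self.restart_times)

    @property
    def n(self) -> int:
        return int(self.times.size)
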