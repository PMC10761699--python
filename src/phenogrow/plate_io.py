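"""Tabular I/O, the outlier-exclusion rules, and calibration persistence.

File conventions (this package's, chosen for interoperability):

* absorbance CSV — tidy long format, columns ``well,time_h,channel,value``
  with ``channel`` one of ``430``, ``560`` or ``fluor:<name>``;
* counts CSV — columns ``well,time_h,cells_per_ml``;
* layout CSV — one row per well with metadata columns
  ``well,cell_line,medium,phenol_red_mg_per_L,temp_C,carbon_source,dose,
  dose_units,is_blank``;
* calibration JSON — ``{cell_line, medium, condition, m, q, r2, cf,
  window:{t_start,t_end}}``.

Times are decimal hours from assay start.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ParseError, ValidationError
from .series import CountSeries, GrowthIndexSeries, WellMeta, WellSeries

__all__ = [
    "ExclusionReport",
    "ExclusionResult",
    "read_absorbance_table",
    "write_absorbance_table",
    "read_counts_table",
    "write_counts_table",
    "read_layout",
    "apply_exclusions",
    "write_exclusion_report",
    "save_calibration",
    "load_calibration",
]

ABSORBANCE_COLUMNS = ("well", "time_h", "channel", "value")
COUNT_COLUMNS = ("well", "time_h", "cells_per_ml")

#: Named exclusion rules (Methods-style outlier handling).
RULE_GI_BELOW_GI0 = "GI<GI0"
RULE_C_BELOW_C0 = "C<C0"
RULE_RESTART = "restart"
RULE_NEGATIVE_GI_6H = "negative_GI_at_6h"


@dataclass
class ExclusionReport:
    """Every removal performed by :func:`apply_exclusions`, with its rule."""

    excluded_points: List[Tuple[str, float, str]] = field(default_factory=list)
    excluded_curves: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.excluded_points and not self.excluded_curves


@dataclass
class ExclusionResult:
    gi: Optional[GrowthIndexSeries]
    counts: Optional[CountSeries]
    report: ExclusionReport


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _normalise_channel(ch: object) -> str:
    s = str(ch).strip()
    if s in ("430", "430.0"):
        return "430"
    if s in ("560", "560.0"):
        return "560"
    if s.startswith("fluor:"):
        return s
    raise FormatError(f"unrecognised channel {ch!r} (expected 430, 560 or fluor:<name>)")


def read_layout(path: Union[str, Path]) -> pd.DataFrame:
    """Read a plate layout table and index it by well id."""
    df = pd.read_csv(path)
    _require_columns(df, ["well"], "layout table")
    return df.set_index("well")


def _meta_from_layout(layout: Optional[pd.DataFrame], well_id: str) -> WellMeta:
    if layout is None or well_id not in layout.index:
        return WellMeta()
    row = layout.loc[well_id]

    def get(col, cast=None):
        if col not in row.index:
            return None
        v = row[col]
        if pd.isna(v):
            return None
        return cast(v) if cast else v

    return WellMeta(
        cell_line=get("cell_line", str),
        medium=get("medium", str),
        phenol_red_mg_per_L=get("phenol_red_mg_per_L", float),
        temp_C=get("temp_C", float),
        carbon_source=get("carbon_source", str),
        dose=get("dose", float),
        dose_units=get("dose_units", str),
        is_blank=bool(get("is_blank") or False),
    )


def read_absorbance_table(
    path: Union[str, Path],
    layout: Optional[Union[str, Path, pd.DataFrame]] = None,
    restarts: Optional[Mapping[str, Sequence[float]]] = None,
) -> Dict[str, WellSeries]:
    """Read a tidy absorbance CSV into one :class:`WellSeries` per well.

    The 430 and 560 nm channels must be present at every timestamp of a
    well (the union of its timestamps); a reading present in one channel
    but not the other raises :class:`AlignmentError` naming the well and
    time. Fluorescence channels are reindexed onto the same grid with NaN
    where missing. ``restarts`` optionally maps well ids to plate-reader
    restart times (hours).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ABSORBANCE_COLUMNS, "absorbance table")
    if isinstance(layout, (str, Path)):
        layout = read_layout(layout)
    df = df.copy()
    df["channel"] = df["channel"].map(_normalise_channel)

    wells: Dict[str, WellSeries] = {}
    for well_id, grp in df.groupby("well", sort=True):
        wide = grp.pivot_table(index="time_h", columns="channel", values="value")
        wide = wide.sort_index()
        for ch in ("430", "560"):
            if ch not in wide.columns:
                missing_t = float(wide.index[0])
                raise AlignmentError(str(well_id), missing_t, int(ch))
            bad = wide.index[wide[ch].isna()]
            if len(bad):
                raise AlignmentError(str(well_id), float(bad[0]), int(ch))
        fluor = {
            c[len("fluor:"):]: wide[c].to_numpy()
            for c in wide.columns
            if c.startswith("fluor:")
        }
        wells[str(well_id)] = WellSeries(
            well_id=str(well_id),
            times=wide.index.to_numpy(),
            abs430=wide["430"].to_numpy(),
            abs560=wide["560"].to_numpy(),
            fluor=fluor,
            meta=_meta_from_layout(layout, str(well_id)),
            restart_times=(restarts or {}).get(str(well_id), ()),
        )
    return wells


def write_absorbance_table(wells: Mapping[str, WellSeries], path: Union[str, Path]) -> None:
    """Write wells back to the tidy absorbance CSV (lossless round trip)."""
    rows = []
    for well_id in sorted(wells):
        w = wells[well_id]
        for ch, values in (("430", w.abs430), ("560", w.abs560)):
            for t, v in zip(w.times, values):
                rows.append((well_id, t, ch, v))
        for name, values in sorted(w.fluor.items()):
            for t, v in zip(w.times, values):
                if np.isfinite(v):
                    rows.append((well_id, t, f"fluor:{name}", v))
    pd.DataFrame(rows, columns=list(ABSORBANCE_COLUMNS)).to_csv(path, index=False)


def read_counts_table(path: Union[str, Path]) -> Dict[str, CountSeries]:
    """Read a counts CSV into one :class:`CountSeries` per well.

    ``c0`` is set to the earliest count. Non-positive counts raise
    :class:`ValidationError`; wells whose rows are all NaN are skipped
    with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COUNT_COLUMNS, "counts table")
    out: Dict[str, CountSeries] = {}
    for well_id, grp in df.groupby("well", sort=True):
        grp = grp.dropna(subset=["cells_per_ml"]).sort_values("time_h")
        if grp.empty:
            warnings.warn(f"counts table: well {well_id!r} has no counts; skipped")
            continue
        counts = grp["cells_per_ml"].to_numpy(dtype=float)
        if np.any(counts <= 0):
            t_bad = float(grp["time_h"].to_numpy()[counts <= 0][0])
            raise ValidationError(
                f"well {well_id!r}: non-positive count at t={t_bad} h"
            )
        out[str(well_id)] = CountSeries(
            well_id=str(well_id),
            times=grp["time_h"].to_numpy(dtype=float),
            counts=counts,
        )
    return out


def write_counts_table(counts: Mapping[str, CountSeries], path: Union[str, Path]) -> None:
    rows = []
    for well_id in sorted(counts):
        s = counts[well_id]
        rows.extend((well_id, t, c) for t, c in zip(s.times, s.counts))
    pd.DataFrame(rows, columns=list(COUNT_COLUMNS)).to_csv(path, index=False)


def apply_exclusions(
    gi: GrowthIndexSeries, counts: Optional[CountSeries] = None
) -> ExclusionResult:
    """Apply the outlier-exclusion rules and report every removal.

    Rules, in order:

    1. a curve whose GI at the first reading (nominally six hours) is
       negative is excluded entirely;
    2. the first GI reading after each recorded plate-reader restart is
       discarded (restarts are consumed, so re-application is a no-op);
    3. GI points below the ``gi0`` reference are removed;
    4. count points below ``c0`` are removed.

    Never raises: violations are reported, not errored. Idempotent — the
    reference values ``gi0``/``c0`` are carried through unchanged, so a
    second application removes nothing.
    """
    report = ExclusionReport()

    if gi.n and gi.gi[0] < 0:
        report.excluded_curves.append((gi.well_id, RULE_NEGATIVE_GI_6H))
        return ExclusionResult(None, counts, report)

    keep = np.ones(gi.n, dtype=bool)
    for t_restart in gi.restart_times:
        after = np.flatnonzero((gi.times > t_restart) & keep)
        if after.size:
            keep[after[0]] = False
            report.excluded_points.append(
                (gi.well_id, float(gi.times[after[0]]), RULE_RESTART)
            )
    low = gi.gi < gi.gi0
    for i in np.flatnonzero(low & keep):
        report.excluded_points.append((gi.well_id, float(gi.times[i]), RULE_GI_BELOW_GI0))
    keep &= ~low

    gi_out = GrowthIndexSeries(
        well_id=gi.well_id,
        times=gi.times[keep],
        gi=gi.gi[keep],
        gi0=gi.gi0,
        background=gi.background,
        mode=gi.mode,
        restart_times=(),
    )

    counts_out = counts
    if counts is not None:
        keep_c = counts.counts >= counts.c0
        for i in np.flatnonzero(~keep_c):
            report.excluded_points.append(
                (counts.well_id, float(counts.times[i]), RULE_C_BELOW_C0)
            )
        counts_out = CountSeries(
            well_id=counts.well_id,
            times=counts.times[keep_c],
            counts=counts.counts[keep_c],
            c0=counts.c0,
        )
    return ExclusionResult(gi_out, counts_out, report)


def write_exclusion_report(report: ExclusionReport, path: Union[str, Path]) -> None:
    rows = [(w, t, rule) for (w, t, rule) in report.excluded_points]
    rows += [(w, "", rule) for (w, rule) in report.excluded_curves]
    pd.DataFrame(rows, columns=["well", "time_h", "rule"]).to_csv(path, index=False)


_CALIBRATION_NUMERIC = ("m", "q", "r2", "cf")


def save_calibration(cal, path: Union[str, Path]) -> None:
    """Persist a :class:`~phenogrow.kinetics.Calibration` as JSON."""
    for name in _CALIBRATION_NUMERIC:
        v = getattr(cal, name)
        if not np.isfinite(v):
            raise ValidationError(f"calibration field {name!r} is not finite")
    payload = {
        "cell_line": cal.meta.get("cell_line"),
        "medium": cal.meta.get("medium"),
        "condition": cal.meta.get("condition"),
        "m": cal.m,
        "q": cal.q,
        "r2": cal.r2,
        "cf": cal.cf,
        "window": {"t_start": cal.window[0], "t_end": cal.window[1]},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_calibration(path: Union[str, Path]):
    """Load a calibration JSON; the round trip is bit-identical."""
    from .kinetics import Calibration  # local import to avoid a cycle

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"calibration file {path}: invalid JSON ({exc})") from exc
    for name in _CALIBRATION_NUMERIC:
        if name not in payload or payload[name] is None:
            raise ParseError(f"calibration file {path}: missing field {name!r}")
    window = payload.get("window") or {}
    if "t_start" not in window or "t_end" not in window:
        raise ParseError(f"calibration file {path}: missing field 'window'")
    return Calibration(
        m=float(payload["m"]),
        q=float(payload["q"]),
        r2=float(payload["r2"]),
        cf=float(payload["cf"]),
        window=(float(window["t_start"]), float(window["t_end"])),
        meta={
            "cell_line": payload.get("cell_line"),
            "medium": payload.get("medium"),
            "condition": payload.get("condition"),
        },
    )
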