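"""Mechanistic synthetic-plate generator with known ground truth.

The simulator couples four minimal mechanisms so that every qualitative
feature of a phenol-red growth assay can be generated and tested without
experimental data:

1. **Batch growth** — closed-form logistic
   C(t) = K*c0*exp(mu*t) / (K + c0*(exp(mu*t) - 1)), optionally with an
   instantaneous growth-rate multiplier from a treatment time onwards
   (piecewise in mu, continuous in C).
2. **Medium acidification** — cells excrete acid at a constant per-cell
   rate, so the cumulative acid load is a(t) = acid_yield * integral of
   C dt (trapezoidal on an internally refined grid), and a linear buffer
   maps it to pH(t) = ph0 - a(t)/buffer_capacity, floored at pH 6.
3. **Indicator speciation** — Henderson–Hasselbalch gives the acid
   fraction of phenol red, f(t) = 1/(1 + 10^(pH - pKa)).
4. **Spectrophotometry** — Beer–Lambert linearity in the indicator
   concentration P: Abs430 = baseline430 + eps430_acid*P*f and
   Abs560 = baseline560 + eps560_base*P*(1-f), plus optional
   multiplicative lognormal noise per reading.

Medium presets mirror the two common formulations: RPMI-like media carry
5 mg/L phenol red, DMEM-like media 15 mg/L; under identical growth the
richer indicator load produces a steeper Abs560 decline and a wider GI
dynamic range.

A note on fidelity: the cumulative-acid mechanism makes GI proportional
to C - c0 rather than to C, so the power-law calibration ln(GI) =
m*ln(C) + q is exact only once C >> c0 (or when the inoculum carries the
acid load of a steadily growing culture, ``acid0 = acid_yield*c0/mu`` —
see :func:`steady_state_acid0`). This mirrors the imperfect linearity of
the real assay. :func:`power_law_plate` generates the complementary
idealised plate whose GI follows the calibration relation exactly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .series import CountSeries, WellMeta, WellSeries

__all__ = [
    "SimConfig",
    "PlateData",
    "rpmi_like",
    "dmem_like",
    "steady_state_acid0",
    "logistic_counts",
    "acidification_absorbance",
    "simulate_plate",
    "generate_experiment",
    "power_law_plate",
]

PH_FLOOR = 6.0


@dataclass
class SimConfig:
    """Parameters of one simulated plate.

    Defaults describe a K562-like suspension culture: seeding at
    10^5 cells/ml, intrinsic growth rate 0.03 h^-1 (doubling time ~23 h),
    saturation near 2*10^6 cells/ml, absorbance every 6 h and counts every
    24 h over 9 days, DMEM-like indicator load (15 mg/L), and a buffer
    capacity under which a confluent 9-day run spans ~1.3 pH units.
    """

    mu: float = 0.03  # h^-1 intrinsic growth rate
    c0: float = 1e5  # cells/ml at seeding
    K: float = 2e6  # cells/ml carrying capacity
    duration_days: float = 9.0
    abs_cadence_h: float = 6.0
    count_cadence_h: float = 24.0
    phenol_red_mg_per_L: float = 15.0  # 5 = RPMI-like, 15 = DMEM-like
    acid_yield: float = 1e-9  # acid equivalents per cell per hour
    buffer_capacity: float = 0.18  # acid equivalents per pH unit
    ph0: float = 7.8
    pka: float = 8.0  # phenol red sulfonephthalein transition
    eps430_acid: float = 0.04  # AU per (mg/L) of acid-form indicator
    eps560_base: float = 0.06  # AU per (mg/L) of base-form indicator
    baseline430: float = 0.05  # medium + plate background, AU
    baseline560: float = 0.05
    acid0: float = 0.0  # acid load carried over with the inoculum
    noise_cv: float = 0.0  # multiplicative lognormal CV per absorbance reading
    count_noise_cv: float = 0.0  # same, per count
    per_cell_yield: Optional[float] = None  # fluorescence per cell, arbitrary units
    fluor_channel: str = "EBFP"
    fluor_background: float = 0.0
    seed: int = 0
    treatment: Optional[Tuple[float, float]] = None  # (time_h, rate_multiplier)
    n_replicates: int = 3
    integration_substeps: int = 10  # refinement of the acid integral grid
    cell_line: str = "K562-like"
    medium: str = "DMEM-like"

    def validate(self) -> None:
        if self.mu < 0:
            raise ValidationError("mu must be >= 0")
        if not (0 < self.c0 <= self.K):
            raise ValidationError("need 0 < c0 <= K")
        if self.duration_days <= 0:
            raise ValidationError("duration_days must be positive")
        for name in ("abs_cadence_h", "count_cadence_h"):
            cad = getattr(self, name)
            if cad <= 0:
                raise ValidationError(f"{name} must be positive")
            n = self.duration_days * 24.0 / cad
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(f"{name} must divide the assay duration")
        if self.noise_cv < 0 or self.count_noise_cv < 0:
            raise ValidationError("noise CV must be >= 0")
        if self.buffer_capacity <= 0 or self.acid_yield < 0 or self.acid0 < 0:
            raise ValidationError("acid/buffer parameters must be non-negative")
        if self.phenol_red_mg_per_L < 0:
            raise ValidationError("phenol_red_mg_per_L must be >= 0")
        if self.integration_substeps < 1:
            raise ValidationError("integration_substeps must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.treatment is not None:
            t_treat, mult = self.treatment
            if t_treat < 0 or mult < 0:
                raise ValidationError("treatment time and multiplier must be >= 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @property
    def duration_h(self) -> float:
        return self.duration_days * 24.0


def rpmi_like(**overrides) -> SimConfig:
    """RPMI-like preset: 5 mg/L phenol red (suspension-line media)."""
    cfg = SimConfig(phenol_red_mg_per_L=5.0, medium="RPMI-like")
    return cfg.replace(**overrides) if overrides else cfg


def dmem_like(**overrides) -> SimConfig:
    """DMEM-like preset: 15 mg/L phenol red (adherent-line media)."""
    cfg = SimConfig(phenol_red_mg_per_L=15.0, medium="DMEM-like")
    return cfg.replace(**overrides) if overrides else cfg


def steady_state_acid0(cfg: SimConfig) -> float:
    """Initial acid load of an inoculum in balanced exponential growth.

    A culture that has been growing exponentially at rate mu since
    negligible density has accumulated acid_yield*C/mu of acid; seeding
    with this carry-over makes the simulated GI exactly proportional to C
    (rather than C - c0), i.e. the regime in which the power-law
    calibration holds exactly.
    """
    if cfg.mu == 0:
        raise ValidationError("steady-state acid load undefined for mu = 0")
    return cfg.acid_yield * cfg.c0 / cfg.mu


def _counts_at(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    """Closed-form logistic concentration, piecewise under treatment."""

    def logistic(c_start: float, mu: float, dt: np.ndarray) -> np.ndarray:
        if mu == 0:
            return np.full_like(dt, c_start, dtype=float)
        g = np.exp(mu * dt)
        return cfg.K * c_start * g / (cfg.K + c_start * (g - 1.0))

    t = np.asarray(t, dtype=float)
    if cfg.treatment is None:
        return logistic(cfg.c0, cfg.mu, t)
    t_treat, mult = cfg.treatment
    out = np.empty_like(t)
    pre = t < t_treat
    out[pre] = logistic(cfg.c0, cfg.mu, t[pre])
    c_at_treat = float(logistic(cfg.c0, cfg.mu, np.array([t_treat]))[0])
    out[~pre] = logistic(c_at_treat, cfg.mu * mult, t[~pre] - t_treat)
    return out


class LogisticCounts(NamedTuple):
    dense: CountSeries  # on the absorbance grid (used for the acid integral)
    sampled: CountSeries  # on the counting cadence (what a counter would see)


def logistic_counts(cfg: SimConfig, well_id: str = "A1") -> LogisticCounts:
    """Noise-free logistic growth on the dense and counting grids."""
    cfg.validate()
    t_dense = np.arange(0.0, cfg.duration_h + 1e-9, cfg.abs_cadence_h)
    t_sampled = np.arange(0.0, cfg.duration_h + 1e-9, cfg.count_cadence_h)
    return LogisticCounts(
        dense=CountSeries(well_id, t_dense, _counts_at(cfg, t_dense)),
        sampled=CountSeries(well_id, t_sampled, _counts_at(cfg, t_sampled)),
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def acidification_absorbance(
    counts: CountSeries,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    is_blank: bool = False,
) -> WellSeries:
    """Phenol-red absorbance readings implied by a growth curve.

    ``counts`` must sit on the absorbance grid; the acid integral is
    evaluated by trapezoid on an internally refined grid (the closed-form
    growth law is re-evaluated at the sub-steps) so that the cadence does
    not bias the chemistry. Noise, if configured, is applied independently
    per reading and per channel.
    """
    cfg.validate()
    t = counts.times
    if cfg.integration_substeps > 1 and t.size > 1 and not is_blank:
        t_fine = np.linspace(
            t[0], t[-1], (t.size - 1) * cfg.integration_substeps + 1
        )
        c_fine = _counts_at(cfg, t_fine)
        acid_fine = cfg.acid0 + cfg.acid_yield * _cumtrapz(c_fine, t_fine)
        acid = acid_fine[:: cfg.integration_substeps]
    else:
        c = np.zeros_like(t) if is_blank else counts.counts
        acid = (0.0 if is_blank else cfg.acid0) + cfg.acid_yield * _cumtrapz(c, t)

    ph = np.maximum(cfg.ph0 - acid / cfg.buffer_capacity, PH_FLOOR)
    f_acid = 1.0 / (1.0 + np.power(10.0, ph - cfg.pka))
    P = cfg.phenol_red_mg_per_L
    abs430 = cfg.baseline430 + cfg.eps430_acid * P * f_acid
    abs560 = cfg.baseline560 + cfg.eps560_base * P * (1.0 - f_acid)

    fluor = {}
    if cfg.per_cell_yield is not None and not is_blank:
        fluor[cfg.fluor_channel] = (
            cfg.fluor_background + cfg.per_cell_yield * counts.counts
        )

    if rng is not None and cfg.noise_cv > 0:
        abs430 = abs430 * _lognormal_factors(rng, cfg.noise_cv, t.size)
        abs560 = abs560 * _lognormal_factors(rng, cfg.noise_cv, t.size)
        fluor = {
            k: v * _lognormal_factors(rng, cfg.noise_cv, t.size)
            for k, v in fluor.items()
        }

    meta = WellMeta(
        cell_line=None if is_blank else cfg.cell_line,
        medium=cfg.medium,
        phenol_red_mg_per_L=P,
        dose=None if cfg.treatment is None or is_blank else None,
        is_blank=is_blank,
    )
    return WellSeries(
        well_id=counts.well_id,
        times=t.copy(),
        abs430=abs430,
        abs560=abs560,
        fluor=fluor,
        meta=meta,
    )


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y, dtype=float)
    if y.size > 1:
        out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


@dataclass
class PlateData:
    """An in-memory simulated plate plus its generating ground truth."""

    wells: Dict[str, WellSeries]  # replicate sample wells + one blank
    counts: Dict[str, CountSeries]  # sampled at the counting cadence
    dense_counts: Dict[str, CountSeries]  # noise-free, absorbance grid
    layout: pd.DataFrame
    truth: Dict[str, object]


_SAMPLE_IDS = [f"A{i}" for i in range(1, 9)] + [f"B{i}" for i in range(1, 9)]
BLANK_ID = "F8"


def simulate_plate(cfg: SimConfig) -> PlateData:
    """Simulate replicate sample wells plus one blank well.

    Reproducibility contract: identical config (including ``seed``) gives
    identical output; with ``noise_cv = count_noise_cv = 0`` the numeric
    content is independent of the seed.
    """
    cfg.validate()
    if cfg.n_replicates > len(_SAMPLE_IDS):
        raise ValidationError(f"at most {len(_SAMPLE_IDS)} replicate wells supported")
    wells: Dict[str, WellSeries] = {}
    counts: Dict[str, CountSeries] = {}
    dense: Dict[str, CountSeries] = {}
    layout_rows = []

    for idx in range(cfg.n_replicates):
        wid = _SAMPLE_IDS[idx]
        rng = np.random.default_rng([cfg.seed, idx])
        lc = logistic_counts(cfg, well_id=wid)
        wells[wid] = acidification_absorbance(lc.dense, cfg, rng=rng)
        sampled = lc.sampled
        if cfg.count_noise_cv > 0:
            noisy = sampled.counts * _lognormal_factors(
                rng, cfg.count_noise_cv, sampled.n
            )
            sampled = CountSeries(wid, sampled.times, noisy)
        counts[wid] = sampled
        dense[wid] = lc.dense
        layout_rows.append(_layout_row(wid, cfg, is_blank=False))

    blank_rng = np.random.default_rng([cfg.seed, 10_000])
    blank_counts = CountSeries(
        BLANK_ID,
        np.arange(0.0, cfg.duration_h + 1e-9, cfg.abs_cadence_h),
        np.ones(int(round(cfg.duration_h / cfg.abs_cadence_h)) + 1),  # placeholder
    )
    wells[BLANK_ID] = acidification_absorbance(
        blank_counts, cfg, rng=blank_rng, is_blank=True
    )
    layout_rows.append(_layout_row(BLANK_ID, cfg, is_blank=True))

    truth = {
        "mu": cfg.mu,
        "K": cfg.K,
        "c0": cfg.c0,
        "m_implied": _implied_calibration_slope(cfg),
        "per_cell_yield": cfg.per_cell_yield,
        "seed": cfg.seed,
    }
    layout = pd.DataFrame(layout_rows).set_index("well")
    return PlateData(wells=wells, counts=counts, dense_counts=dense, layout=layout, truth=truth)


def _layout_row(wid: str, cfg: SimConfig, is_blank: bool) -> Dict[str, object]:
    # dose bookkeeping is the caller's concern; the simulator's treatment
    # is a rate multiplier, not a named compound
    dose = None
    dose_units = None
    return {
        "well": wid,
        "cell_line": "" if is_blank else cfg.cell_line,
        "medium": cfg.medium,
        "phenol_red_mg_per_L": cfg.phenol_red_mg_per_L,
        "temp_C": 37.0,
        "carbon_source": "glucose",
        "dose": dose,
        "dose_units": dose_units,
        "is_blank": is_blank,
    }


def _implied_calibration_slope(cfg: SimConfig) -> Optional[float]:
    """m from a noiseless GI-vs-C regression on this configuration."""
    import warnings

    from . import growth_index, kinetics  # deferred: avoids an import cycle

    quiet = cfg.replace(noise_cv=0.0, count_noise_cv=0.0, n_replicates=1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lc = logistic_counts(quiet)
            well = acidification_absorbance(lc.dense, quiet)
            blank = acidification_absorbance(
                CountSeries("blank", lc.dense.times, np.ones(lc.dense.n)),
                quiet,
                is_blank=True,
            )
            gi = growth_index.compute_gi(
                well, background=growth_index.estimate_background([blank])
            )
            res = kinetics.characterise_well(gi, lc.sampled)
            return res.calibration.m
    except Exception:
        return None


def generate_experiment(
    cfg: SimConfig, outdir: Union[str, Path]
) -> Dict[str, object]:
    """Write a simulated plate in the pipeline's file formats.

    Emits ``absorbance.csv``, ``counts.csv``, ``layout.csv`` and
    ``ground_truth.json`` into ``outdir`` and returns the paths plus the
    ground-truth record. Identical config and seed give byte-identical
    files.
    """
    from . import plate_io  # deferred: plate_io does not depend on simulate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plate = simulate_plate(cfg)
    paths = {
        "absorbance": outdir / "absorbance.csv",
        "counts": outdir / "counts.csv",
        "layout": outdir / "layout.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    plate_io.write_absorbance_table(plate.wells, paths["absorbance"])
    plate_io.write_counts_table(plate.counts, paths["counts"])
    plate.layout.reset_index().to_csv(paths["layout"], index=False)
    paths["ground_truth"].write_text(json.dumps(plate.truth, indent=2) + "\n")
    return {"paths": paths, "truth": plate.truth}


def power_law_plate(
    m: float = 0.99,
    q: float = -14.6,
    mu: float = 0.03,
    c0: float = 1e5,
    duration_h: float = 168.0,
    abs_cadence_h: float = 6.0,
    count_cadence_h: float = 24.0,
    background: float = 0.35,
    well_id: str = "A1",
    blank_id: str = BLANK_ID,
) -> Tuple[WellSeries, WellSeries, CountSeries]:
    """An idealised plate whose GI follows ln(GI) = m*ln(C) + q exactly.

    C grows exponentially from ``c0`` at rate ``mu``; the 560 nm channel
    is held at 1 and the 430 nm channel carries ``background`` plus the
    power-law GI, with a constant-ratio blank, so that subtract-mode
    background normalisation reproduces GI = exp(q)*C^m to float
    precision. This is the reference dataset for exactness tests of the
    calibration, conversion-factor and prediction machinery.
    """
    t_abs = np.arange(0.0, duration_h + 1e-9, abs_cadence_h)
    t_cnt = np.arange(0.0, duration_h + 1e-9, count_cadence_h)
    c_abs = c0 * np.exp(mu * t_abs)
    c_cnt = c0 * np.exp(mu * t_cnt)
    gi = np.exp(q) * np.power(c_abs, m)
    meta = WellMeta(cell_line="K562-like", medium="RPMI-like", phenol_red_mg_per_L=5.0)
    well = WellSeries(
        well_id=well_id,
        times=t_abs,
        abs430=background + gi,
        abs560=np.ones_like(t_abs),
        meta=meta,
    )
    blank = WellSeries(
        well_id=blank_id,
        times=t_abs,
        abs430=np.full_like(t_abs, background),
        abs560=np.ones_like(t_abs),
        meta=WellMeta(is_blank=True),
    )
    return well, blank, CountSeries(well_id, t_cnt, c_cnt)
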