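# Methods

## The growth index and its normalisation

Phenol red is a sulfonephthalein indicator whose basic form absorbs at
560 nm and acid form at 430 nm. Growing cells acidify their medium, so
the ratio R(t) = Abs430(t)/Abs560(t) rises monotonically with cumulative
growth. The growth index is this ratio normalised to the cell-free
background. Two normalisations are plausible from the assay description
— subtracting a blank-derived ratio, or dividing by it — and they are
not equivalent as formulas. `phenogrow` defaults to **subtraction**
(GI = R − background) because the curve-level exclusion rule "discard
curves with negative GI at six hours" can only ever fire if GI can be
negative, which division by a positive background forbids. Divide mode
is provided for sensitivity analysis; the choice only shifts the
calibration intercept q on ideal data. The background is the mean over
blank wells of each blank's time-mean ratio; without blanks the well's
own first reading is used (flagged by a `-self` suffix on the series'
mode field).

GI₀, the GI value at the earliest reading (nominally six hours), is
stored as a reference for the point-level exclusion rule GI < GI₀. It is
*not* used to rescale the series. After exclusion the reference values
(GI₀, C₀) are deliberately carried through unchanged rather than
recomputed from the filtered series; recomputing them would make the
exclusion non-idempotent (each pass could remove further points against
an ever-rising reference). For the same reason the reader-restart rule
consumes its restart timestamps: the filtered series carries none, so a
second application removes nothing.

## Exponential-window detection

The exponential phase is defined operationally as the contiguous window
of fastest log-linear growth. The detector enumerates **all** contiguous
windows with at least `min_points` points (default 4: the smallest
window for which an r² threshold is meaningfully restrictive, and ≥ 72 h
of daily counts), keeps those whose OLS fit reaches `r2_min` (default
0.90), and returns the one with maximal slope; ties go to the longer
window, then the earlier start. Exhaustive search is exact, trivially
specified, and O(n²) with incremental prefix-sum statistics — negligible
at plate-reader sizes (≤ a few hundred points per curve). The same
enumeration written naively with per-window `np.polyfit` serves as the
test oracle.

Two slopes within a relative tolerance of 1e-9 are treated as tied.
Without a tolerance, exactly linear data (where every window has the
same true slope) would be ranked by float round-off, and the tie-break
rules ("longer, then earlier") would never engage deterministically.

Non-finite log values — typically ln(GI) where GI ≤ 0 before growth has
produced measurable acidification — are dropped before the search.
Windows are detected on ln(C) whenever parallel counts exist, and µ_p is
then fitted on ln(GI) over that same time window; only in
prediction-from-absorbance-alone mode is the window detected on ln(GI)
directly.

## Calibration, prediction, accuracy

The calibration ln(GI) = m·ln(C) + q is an OLS fit over time-aligned
(GI, C) pairs inside the window. Counts (typically every 24 h) are
matched to the nearest GI reading (typically every 6 h) within
`align_tol` = 1 h — on a shared grid the match is exact, and the
tolerance absorbs real-world timestamp jitter without ever pairing
across readings. Pairs with GI ≤ 0 are dropped with a warning; at least
three pairs are required.

The conversion factor CF = µ_p/µ_c is stored with the calibration. On
data that follow the power law exactly, CF = m identically (chain rule);
on real or mechanistically simulated data the two differ slightly
because they weight the window differently, and their agreement is
itself a useful diagnostic. Reported per-condition CFs are unweighted
means over replicate wells.

Prediction inverts the calibration: C_p = (GI/e^q)^(1/m), defined only
where GI > 0 (other times are flagged NaN, never silently filled).
Accuracy is A = mean(C_p)/mean(C) over aligned in-window pairs.

## Dose-response and expression analysis

Rates at each dose are expressed as percent of the mean dose-0 control;
the trend is an OLS line of percent rate on log₁₀(dose) over positive
doses only (the control cannot sit on a log axis), giving a
percent-per-decade coefficient. A constant response returns slope 0 with
the trend r² flagged NaN. No IC50/4PL model is fitted: the readout of
this assay is the log-linear trend. For treatments added mid-assay,
`rate_change_around` compares OLS slopes strictly before and after the
treatment time (default 24 h).

Per-cell expression divides total well fluorescence by C_p at a chosen
time inside the linearity window. No fluorescence background subtraction
is applied — the assay definition leaves it unspecified, and any common
rescaling cancels in group comparisons. Group comparison uses a
two-sided t-test, Welch's unequal-variance variant by default (the safer
choice for small replicate groups), with a pooled-variance option. The
significance bands reproduce the assay's legend **as printed**, including
its "ns: p > 0.5" threshold; this is almost certainly a typo for 0.05,
but it is reproduced verbatim rather than silently corrected, and values
between 0.01 and 0.5 are labelled `*`.

## The synthetic-plate simulator

The simulator exists so every pipeline stage is testable against known
ground truth. Its mechanism chain is the minimal one that generates all
the qualitative behaviours the assay exhibits:

- **Growth**: closed-form logistic, C(t) = K·c0·e^{µt}/(K + c0·(e^{µt}−1)),
  with an optional instantaneous rate multiplier from a treatment time
  (piecewise in µ, continuous in C). Defaults: µ = 0.03 h⁻¹ (doubling
  ~23 h, typical of fast suspension lines), c0 = 10⁵ cells/ml (standard
  seeding), K = 2×10⁶ cells/ml, 9 days.
- **Acidification**: cumulative acid a(t) = acid0 + acid_yield·∫C dt
  (trapezoid on a grid refined `integration_substeps`× below the 6 h
  absorbance cadence, so cadence does not bias the chemistry), with
  acid_yield = 1e-9 equivalents·cell⁻¹·h⁻¹ and a linear buffer,
  pH(t) = pH₀ − a(t)/buffer_capacity floored at pH 6. Defaults pH₀ 7.8,
  buffer_capacity 0.18 eq/pH: a confluent 9-day default run spans
  ≈1.3 pH units, the visually obvious red-to-yellow transition of a
  saturating culture.
- **Speciation**: Henderson–Hasselbalch acid fraction
  f = 1/(1 + 10^{pH−pKa}) with pKa 8.0.
- **Spectrophotometry**: Beer–Lambert linearity in the indicator load P
  (mg/L): Abs430 = 0.05 + 0.04·P·f, Abs560 = 0.05 + 0.06·P·(1−f).
  Presets: P = 5 (RPMI-like) and P = 15 (DMEM-like); the medium
  baselines make the GI dynamic range increase with P, reproducing the
  wider GI excursion and steeper Abs560 decline of high-indicator media.
- **Noise**: multiplicative lognormal with unit mean, independent per
  reading and channel (absorbance noise scales with signal), CV
  `noise_cv`; counts get their own `count_noise_cv`. Streams are split
  per well from the seed, so identical configurations are byte-identical
  and noise-free output is seed-independent.

### What the simulator shows — and what it does not

Because acid is *cumulative*, the simulated GI is proportional to
C − c0, not to C. The power-law calibration is therefore exact only when
(a) the culture has been in balanced exponential growth since before the
assay started — equivalently the inoculum carries the acid load
acid0 = acid_yield·c0/µ of a steadily growing culture
(`steady_state_acid0`) — and (b) the pH excursion across the analysis
window is small enough that the indicator response is locally linear.
The end-to-end fidelity tests construct exactly that regime
(K = 10⁹ cells/ml so the window sits deep in exponential phase,
buffer_capacity = 100 eq/pH for a small excursion): there the pipeline
recovers the generating µ to ~0.03 %, predicts a second run's µ to
~0.03 %, and inverts counts with A − 1 ≈ 1e-5. The default fresh-medium
plate instead yields an *approximately* linear ln(GI)–ln(C) relation
with an effective slope well above 1 early in growth — mirroring the
moderate r² (~0.9) of the real assay's calibration. Passing tests on the
idealised regime therefore demonstrate correctness of the analysis
machinery, not that the power law is exact for arbitrary cultures;
applying the method to real data still requires per-condition
calibration, as the assay prescribes.

Other acknowledged simplifications: real media buffering is
bicarbonate/CO₂-coupled (the linear buffer is a deliberate reduction);
treatment is a growth-rate multiplier, not a death process; there is no
evaporation, metabolite (lactate/glutamine) or spectral-crosstalk
modelling; reader restarts are explicit metadata, not simulated gaps.

## Problem sizes and tolerances used in the test suite

Test plates use the assay's native cadences (6 h absorbance / 24 h
counts, 9–15 days; 37 absorbance and 10 count points at the default
duration). The window-detector oracle runs 200 random instances of up to
60 points. Noisy-recovery checks use 20 plates at 2 % CV with seeding at
10⁴ cells/ml so the earliest detectable window lies deep in exponential
phase (at 10⁵ cells/ml seeding against K = 2×10⁶, logistic curvature
alone biases the earliest-window slope by several percent — a property
of the growth curve, not of the estimator). Exactness tests on
power-law-constructed data assert at 1e-6 to 1e-9 relative; stochastic
and mechanistic bounds (median rate error < 5 %, A within 1e-3 in the
balanced regime) follow the tolerances stated alongside each test.

## Known limitations

- The method is only semi-quantitative for strongly growth-inhibited
  cultures: a flattened curve may have no window reaching `r2_min`, in
  which case detection fails loudly and the caller may relax the
  threshold.
- CF is condition-specific (medium, indicator load, temperature, carbon
  source); a calibration must not be reused across conditions, and the
  CLI warns when calibration and plate metadata disagree.
- The linearity between ln(GI) and ln(C) breaks down at saturation; the
  window detector excludes the saturated tail by construction, and
  predictions outside the window are not returned by default.
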