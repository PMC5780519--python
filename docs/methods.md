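# Methods

`dsfsim` is a software model of a differential scanning fluorimetry (DSF)
setup in which a PID-regulated silicone heat pad warms a 96-well plate
inside a fluorescence spectrometer, plus the analysis pipeline that turns
the recorded fluorescence tables into melting temperatures. This note
documents the models, the defaults and the reasoning behind the open
design choices.

## Thermal control model

**Thermistor.** The NTC glass-bead sensor follows the beta-equation
1/T = 1/T0 + ln(R/R0)/β with T in kelvin. Defaults β = 3950 K,
R0 = 10 kΩ at T0 = 298.15 K, typical for the 10 kΩ bead thermistors used
in hobby-grade controllers. The conversion and its inverse round-trip to
better than 1e-6 relative over three decades of resistance.

**Plant.** No thermal model of the pad is published, so the simulator
uses the simplest physics that reproduces settling plus a steady state: a
first-order lumped plant dT/dt = (P_max·u − k_loss·(T − T_amb))/C with
C = 60 J/°C, P_max = 50 W, k_loss = 0.5 W/°C and T_amb = 25 °C,
integrated by explicit Euler at a 1 s control tick. These constants give
a ~120 s open-loop time constant and require 70% duty at 95 °C — a
plausible small heat pad. The solid-state relay is modelled as a
continuous duty cycle in [0, 1] (the time-proportioned average of on/off
switching), which has the same mean power without simulating the
switching waveform.

**Controller.** Duty = clamp(kp·e + ki·I + kd·ė). The firmware's gains
are not published; the defaults kp = 0.5 /°C, ki = 0.02 /(°C·s), kd = 0
were chosen once by standard loop-shaping on the plant above: the
proportional term dominates the approach, the integral removes the
steady-state offset with a closed-loop settling time (~25 s) comfortably
inside the 5 min dwell, and no derivative action is needed on a
first-order plant. The integral contribution is clamped to ±1 duty unit
(anti-windup). Each control decision averages n_average = 8 noisy sensor
readings (Gaussian, sd 0.1 °C per reading by default), the firmware's
noise-suppression strategy.

**Schedule.** A run is an ordered list of setpoints from `start` to
`ceiling` in `step` increments, each held for `dwell` minutes of
incubation plus measurement. "Room temperature" is fixed at 25 °C: with
the standard 3 °C steps to 95 °C and 5 min dwell this yields 24 steps and
exactly 2 h, the advertised duration of a full run.

**Steady-state accuracy.** The instrument's pad accuracy is quoted as an
average standard deviation of 0.2 °C. Because the published figure does
not say across what that sd is taken, the package defines it as: the sd
of the terminal (steady-state) pad temperature at each setpoint across
seeded replicate runs, averaged over setpoints. Under the defaults the
simulator achieves ≈ 0.02 °C, an order of magnitude inside the bound.

## Pad-to-well transfer and calibration

Plastic conducts poorly, so wells run much cooler than the pad. The
measured relations are linear: pad surface vs setpoint
y = 1.008·x + 0.366 and well vs setpoint y = 0.681·x + 7.034 (°C), with
0.8 °C spread across plate positions. `WellThermalModel` uses exactly
these constants as defaults and adds i.i.d. Gaussian well-to-well noise;
at the 95 °C ceiling the mean well temperature is 0.681·95 + 7.034 =
71.729 °C, matching the ≈71.5 °C maximal well temperature observed.
`fit_calibration` is ordinary least squares (scipy's linregress) with
standard errors and residual sd; melting temperatures are reported on the
pad scale by default — the scale the instrument records — and
`apply_well_calibration` (or `--well-scale`) converts to true sample
temperature.

## Fluorescence model

No quantitative fluorescence model is published, so the generator uses
the minimal family that reproduces every curve shape the assay produces:

F(T) = background + interference·g(T)
     + (1 − aggregated_fraction)·[f_native + φ(T)·(f_unfolded − f_native)]
     − decay·max(0, T − T_full),  floored at 0,

where φ(T) = Σ w_i / (1 + exp((Tm_i − T)/s_i)) is a weighted mixture of
two-state sigmoids. One transition gives the classic melt; several
closely spaced equal-weight transitions (`UnfoldingModel.stepwise`)
flatten the curve the way stepwise cysteine exposure does in CPM assays;
two separated transitions give double-sigmoid curves of sequentially
denaturing subunits. T_full defaults to the last midpoint plus three
slope factors, where the transition is ≈95% complete; past it the signal
decays linearly (dye photobleaching/aggregation), producing the falling
tail that must be cut before fitting. `aggregated_fraction` scales the
protein amplitude only — the signature of air-exposed oxygen-sensitive
samples whose aggregates were spun out, which lowers the plateau ~30%
while leaving the curve shape intact. `interference_level` adds a fixed
monotone profile g(T) = 1/(1 + exp((55 − T)/10)) to blanks and samples
alike, the additive model adopted for the amine-oxide (DDAO) failure
mode; whether that failure is additive background or probe quenching is
unknown, and additive was chosen as the simpler mechanism consistent with
interference being "visible in blanks".

Measurement noise is Gaussian with sd = 0.02·|signal| + 1 AU. The 2%
relative term emulates detector gain noise and makes interference-swamped
wells noisy in absolute terms, as observed; the 1 AU floor keeps blank
wells from being noise-free. Dye amplitude defaults (hundreds to ~1100
AU) are arbitrary instrument units; only ratios matter downstream.

The generator does not model photophysics (inner-filter effects, quantum
yields), evaporation (the oil overlay is assumed effective), aggregation
kinetics, or dye saturation. Passing tests therefore demonstrate that the
analysis pipeline recovers transitions from curves with these noise and
artefact structures — not that it is robust to every failure mode of real
plates.

## Curve analysis

**Preprocessing.** Each replicate has the condition-matched mean blank
subtracted (plate-wide mean blank as fallback); replicates are then
averaged pointwise with a per-point sample sd. Whether blanks should be
subtracted before or after averaging is not prescribed anywhere;
per-replicate subtraction was chosen because it also works when replicate
counts differ between sample and blank groups.

**Truncation.** Signal past full denaturation decays and must not enter
the fit. The cut point is the argmax of the signal smoothed with a
centred 5-point moving average, refined to the raw maximum within half a
window (ties toward higher temperature, keeping more data). Only the
trailing segment is ever removed, so the transition region always
survives.

**Model choice.** The number of transitions is the number of
well-separated peaks in the smoothed first difference with prominence
above 25% of the maximum slope and separation ≥ 3 grid steps
(`scipy.signal.find_peaks`; both thresholds configurable), capped at
two. A curve whose smoothed range is below 3× a robust noise estimate
(1.4826 × median |residual about the smoothed curve|) counts zero
transitions — no melt.

**Fitting.** The Origin-style forms are used:
single F(T) = A2 + (A1 − A2)/(1 + exp((T − Tm)/dT)) and double
F(T) = A2 + (A1 − A2)·[f/(1 + exp((T − Tm1)/dT1)) + (1 − f)/(1 +
exp((T − Tm2)/dT2))], fitted by `scipy.optimize.curve_fit` with
data-driven initials (plateaus from the first/last decile means, midpoint
from the steepest ascent, slope from the grid step) and box bounds
keeping Tm inside the data range and slopes positive. Midpoints are
re-ordered Tm1 < Tm2 after the fit. Two gates keep fits honest: the
pre-fit range/noise gate above, and a goodness-of-fit gate requiring the
fitted amplitude |A2 − A1| to exceed 10× the fit's residual RMSE. The
second gate is what catches interference-dominated curves: their
converged "fits" chase common-mode blank noise and carry amplitudes only
~2–5× their residuals, while genuine melts in this data family run ~40×
and above, so the factor 10 sits in the middle of a decade-wide gap.
Failed gates yield a no-melt flag, never an exception.

**Fallback.** When a fit does not converge, the melting point is the
zero-crossing of the numerical second derivative of the smoothed signal
nearest the steepest ascent, located by linear interpolation between
bracketing grid points. The search excludes half a smoothing window plus
two points at each end (edge replication bends the smoothed curve there)
and requires the interior curvature to be significant relative to the
signal, so linear and flat curves return no melt rather than a spurious
crossing from floating-point dust.

**Reporting.** `analyze_run` emits one row per condition with Tm(s),
fit type, no-melt and fallback flags, rank by Tm, and ΔTm against a
reference condition (sds combined in quadrature). The ± on Tm is the sd
of replicate-wise fits when at least three replicates converge, else the
fit standard error — the provenance of published ± values being
ambiguous, the replicate sd is preferred as the more conservative of the
two. Screens are ranked descriptively; no multiple-testing machinery is
applied.

## File formats

Runs are stored as "one sheet per temperature step": either an xlsx
workbook (manifest sheet first, then `T_<setpoint>` sheets of
well/fluorescence pairs) or an equivalent plain-text directory
(`manifest.yaml` plus one CSV per step) so pipelines need no spreadsheet
dependency. The two dialects round-trip identically. Plate maps and
calibration lines are YAML. Run metadata deliberately excludes
timestamps so the same seed and arguments always produce byte-identical
files.

## Problem sizes

Test and acceptance computations use the default 24-step schedule; the
closed-loop simulator runs 7 200 one-second ticks per run. Recovery
suites use 200 seeded single-transition curves (2% noise), 10 seeded
double-transition triplicate plates (1% noise), 50–100 seeded trials for
the derivative/fit cross-checks, and 100 seeds for each calibration-slope
recovery; the whole suite completes in a few seconds on one core.

## Known limitations

- The plant and PID constants are artifact choices, not measured
  firmware values; only the closed-loop behaviour (settling within the
  dwell, ≤0.2 °C replicate spread) is anchored to published figures.
- Well-to-well temperature noise is i.i.d. per reading; real plates have
  spatially correlated gradients (edge effects).
- The double-Boltzmann shares plateaus between transitions; proteins
  with distinct per-domain amplitudes need the weighted mixture generator
  but are still fitted with the shared-plateau form, as in common
  practice.
- ΔTm screening is descriptive; no thermodynamic quantities (ΔH, ΔG,
  ligand Kd) are derived.
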