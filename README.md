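# dsfsim

Simulation and analysis toolkit for **differential scanning fluorimetry
(DSF)** on a heated 96-well plate.

DSF (the "thermal shift assay") estimates how stable a protein is in a
given buffer by heating it in the presence of a fluorescent reporter —
SYPRO Orange for soluble proteins, the thiol-reactive CPM dye for
membrane proteins, or the intrinsic flavin signal (ThermoFAD) — and
locating the midpoint Tm of the sigmoidal fluorescence rise that
accompanies unfolding. Screens compare Tm across conditions (pH, salts,
detergents, additives): a positive ΔTm means stabilisation.

`dsfsim` is a pure-software counterpart of a budget plate-heater DSF
instrument: a microcontroller reads an NTC thermistor, PID-regulates a
silicone heat pad under the plate through stepwise
heat–incubate–measure cycles, and the analysis pipeline converts the
recorded per-step fluorescence tables into melting temperatures. It is
aimed at people developing or validating DSF analysis code: every stage
of the real experiment has a controllable synthetic twin.

The package provides:

- **`dsfsim.thermal`** — closed-loop heater simulation: thermistor
  beta-equation (1/T = 1/T0 + ln(R/R0)/β), sensor averaging, clamped PID
  with anti-windup, a first-order heat-pad plant, and the step
  scheduler (default: 25 → 95 °C in 3 °C steps, 5 min dwell = 2 h).
- **`dsfsim.instrument`** — synthetic plate runs: the calibrated linear
  pad→well temperature lag (well = 0.681·pad + 7.034 °C, 0.8 °C spread),
  weighted-sigmoid unfolding models
  φ(T) = Σ wᵢ/(1 + exp((Tmᵢ − T)/sᵢ)), dye models with post-denaturation
  decay, air-exposure amplitude loss and detergent interference.
- **`dsfsim.analysis`** — blank subtraction, replicate averaging,
  truncation of the post-denaturation tail, Boltzmann fitting
  F(T) = A2 + (A1 − A2)/(1 + exp((T − Tm)/dT)), double-Boltzmann for
  two-transition curves, second-derivative fallback, OLS calibration
  lines, and ΔTm screening reports.
- **`dsfsim.io` / `dsfsim` CLI** — the "one sheet per temperature step"
  run workbook (xlsx or a plain-text directory dialect), YAML plate
  maps and calibrations, and `schedule` / `simulate` / `analyze` /
  `calibrate` subcommands.

## Worked example: a pH screen

Plate map (`map.yaml`) — triplicates of four pH conditions plus blanks,
with true well-scale midpoints 61/57/52/45 °C:

```yaml
groups:
  - condition: "pH 6.0"
    wells: A1-A3
    dye: SYPRO
    unfolding: {tm: 61.0, slope_factor: 1.5}
  - condition: "pH 7.0"
    wells: B1-B3
    dye: SYPRO
    unfolding: {tm: 57.0, slope_factor: 1.5}
  - condition: "pH 8.0"
    wells: C1-C3
    dye: SYPRO
    unfolding: {tm: 52.0, slope_factor: 1.5}
  - condition: "pH 5.0"
    wells: D1-D3
    dye: SYPRO
    unfolding: {tm: 45.0, slope_factor: 1.5}
  - condition: "buffer blank"
    wells: [A4, B4, C4]
    blank: true
    dye: SYPRO
```

```bash
dsfsim schedule --start 25 --step 3 --max 95 --dwell 5 | tail -1
# 24 steps, total 120.0 min (2.0 h)

dsfsim simulate --plate-map map.yaml --out run_dir --seed 11
# wrote 24-step run for 15 wells to run_dir

dsfsim analyze --run run_dir --plate-map map.yaml --out report.csv --reference "pH 7.0"
# analyzed 4 condition(s); report written to report.csv
```

`report.csv` (abridged):

```text
condition  fit_type        tm  tm_sd  rank  delta_tm
pH 6.0    boltzmann  79.46   0.25     1     +6.24
pH 7.0    boltzmann  73.22   0.60     2      0.00
pH 8.0    boltzmann  65.98   0.86     3     -7.24
pH 5.0    boltzmann  55.45   1.35     4    -17.77
```

Tm values are on the **pad temperature scale** (the scale the instrument
records); the ranking and ΔTm values reproduce the generating order. Add
`--well-scale` to convert through the calibration line — e.g. pad-scale
79.46 °C corresponds to 0.681·79.46 + 7.034 ≈ 61.1 °C in the well,
recovering the true 61 °C midpoint. `tm_sd` is the spread over
replicate-wise fits.

Conditions whose curves carry no credible transition — flat signal, or
probe–detergent interference that swamps the protein component (the
amine-oxide/DDAO failure mode) — are flagged `no_melt` instead of being
assigned a Tm.

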