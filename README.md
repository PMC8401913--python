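# pkquant

Internal-standard LC-MS/MS quantification, bioanalytical method validation
statistics, and noncompartmental pharmacokinetic (PK) analysis — with a
synthetic-data generator that provides ground truth for every stage, so the
whole pipeline is testable from plain-CSV inputs with no external data.

## What it does

- **`pkquant.synthetic`** — one-compartment IV-bolus and Bateman oral
  concentration–time profiles on sparse sampling schedules, IS-normalized
  calibration/QC/stability/dilution plates around a configurable linear
  response, and Gaussian MRM chromatogram peaks over baseline noise.
  Measurement error is median-preserving multiplicative lognormal;
  everything is deterministic per seed.
- **`pkquant.signal`** — chromatographic peak integration (flanking-region
  baseline, trapezoidal area, apex height) and signal-to-noise estimation;
  LLOQ determination as the lowest standard reaching an S/N threshold
  (default 10).
- **`pkquant.calibration`** — (weighted) least-squares fit of the analyte/IS
  response ratio on nominal concentration, back-calculation, the
  back-calculated-deviation table (15% limit, 20% at the LLOQ), and
  quantification of unknowns with BLQ/above-ULOQ flagging and dilution
  correction.
- **`pkquant.validation`** — accuracy (calculated/nominal × 100), within-run
  and between-run precision (CV%), IS-normalized matrix factor, carryover,
  stability ratios, dilution integrity, and the hydrolysis-arm comparison;
  each statistic judged against threshold presets `paper` (CV ≤ 5%,
  accuracy 85–115%, LLOQ 80–120%) or `ema` (CV ≤ 15%, 20% at LLOQ).
- **`pkquant.nca`** — λz by semi-log OLS over an adjusted-R²-selected
  terminal subset (or a fixed last-3 policy), T½ = ln 2/λz, Cmax/Tmax,
  linear-trapezoidal AUC0–t and AUMC0–t (oral curves prepend (0, 0); IV
  curves back-extrapolate C(0)), MRT, Vd and Cl for IV, absolute oral
  bioavailability against an IV reference, and mean ± SD summaries.
- **`pkquant.cli`** — `simulate`, `quantify`, `validate`, `nca`, `report`
  subcommands over the CSV schemas in `pkquant.io`.

## CLI quick start

```bash
pkquant simulate --seed 7 --out runs/sim            # profiles + plate + chromatograms
pkquant quantify runs/sim/plate.csv --out runs/q    # fit line, quantify unknowns
pkquant validate runs/sim/plate.csv --preset paper --out runs/v
pkquant nca runs/sim/profiles.csv --out runs/n      # per-subject + summary tables
pkquant report --out runs/r runs/v runs/n           # concatenated text report
```

Options can come from a flat `key = value` config file (`--config PATH`);
`--seed` overrides the config seed and is mandatory for `simulate`. Every
command writes its resolved configuration and seed to `manifest.json` next
to its outputs, and reruns with the same seed are byte-identical. Exit
codes: 0 success (a failing validation *flag* is still a successful run),
1 usage/configuration error, 2 I/O error.

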