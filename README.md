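# lipidcea

A Markov cohort cost-effectiveness model comparing an LDL-C-lowering
siRNA therapy added to statins against statins alone in patients with
established atherosclerotic cardiovascular disease, from a healthcare-system
perspective (2024 CNY).

The model tracks a cohort through six health states (baseline ASCVD, acute
MI, acute ischemic stroke, post-MI, post-IS, and death split into CV and
non-CV) over annual cycles. Event rates derive from a composite baseline
rate disaggregated into MI / IS / CV-death components; treatment shifts
them via rate ratios per 1 mmol/L LDL-C reduction raised to the achieved
reduction. Background non-CV mortality comes from an age-indexed life
table. Costs and QALYs are half-cycle corrected and discounted (4.5%/year
by default), and outputs include the ICER against a willingness-to-pay
threshold, one-way (tornado) sensitivity analysis, probabilistic
sensitivity analysis with acceptability curves, and horizon scenario
sweeps.

## Layout

| module | contents |
|---|---|
| `lipidcea.params` | validated model inputs, YAML config I/O, base-case defaults |
| `lipidcea.calibration` | rate arithmetic: population adjustment, treatment-effect mapping, rate/probability conversion |
| `lipidcea.markov` | life table, transition matrices, cohort engine |
| `lipidcea.economics` | incremental outputs, ICER, NMB, decision rule |
| `lipidcea.sensitivity` | distribution fitting, OWSA, PSA, CEAC, horizon sweep |
| `lipidcea.synthetic` | Gompertz–Makeham life-table generator and fixture bundle |
| `lipidcea.cli` | `lipidcea` command-line interface |

No external data is required: `lipidcea.synthetic` generates a plausible
age-indexed mortality schedule (calibrated so the base case reproduces the
published cohort results closely). A real mortality table can be supplied
as a CSV with columns `age,all_cause_rate,cv_rate` (rates per person-year).

## CLI

```bash
lipidcea run                        # base-case two-strategy table + ICER
lipidcea owsa --plot                # tornado table (and diagram)
lipidcea psa --draws 1000 --seed 42 # PSA draws + acceptability curve
lipidcea scenarios --horizons 5,10,15,20,25,30
lipidcea fixtures --out fixtures    # write params.yaml / life_table.csv
```

All commands accept `--params PATH` (YAML config; missing keys fall back to
the packaged base case), `--life-table PATH`, and `--horizon/--discount/--wtp`
overrides. Outputs are CSV (full precision alongside rounded display
columns) plus optional PNG plots; every run writes a `manifest.json`.

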