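# petpbpk

Whole-body physiologically based pharmacokinetic (PBPK) analysis of dynamic
mouse PET time-activity curves (TACs).

The package simulates and fits a nine-compartment whole-body model — blood
plasma (B), a reversible and an irreversible liver compartment (H1, H2),
gallbladder+intestine (G), two kidney compartments (R1, R2), two peripheral
tissue compartments (T1, T2) and urine (U) — to per-region activity curves,
and derives organ clearances and distribution parameters:

- hepatobiliary clearance `CL_H = k_BH1 · k_H1H2/(k_H1B + k_H1H2) · V_plasma`,
- renal clearance with the two kidney compartments merged,
- total clearance, hepatic extraction ratio `E_H = CL_H/Q_P,H`,
- the equilibrium tissue/plasma distribution coefficient `D_tissue`,
- a closed-form biexponential infusion model of the plasma curve
  (`CL = λ_z·V_z`, `t_1/2 = ln 2/λ_z`),
- homoscedastic two-sample t-tests between treatment groups.

Fitting follows a bounded multistart weighted least-squares protocol
(default 128 seeded random starts; residuals of the first two frames of
plasma, liver and kidney weighted ×5; physiological upper bounds on the
hepatic and renal uptake rate constants from organ plasma flows; optional
per-tracer bounds refinement at 0.5×min/2×max of the best fits).

A synthetic-data module generates scans from known ground-truth parameters
through the full observation model (frame-averaged amounts, vascular blood
fractions, multiplicative lognormal noise), so the entire pipeline is
testable without raw PET data.

## Layout

| module | contents |
| --- | --- |
| `petpbpk.core_data` | domain types, physiological constants, TAC table I/O |
| `petpbpk.tac_preprocess` | concentration → amount conversion, SUV, scan preparation |
| `petpbpk.plasma_model` | biexponential infusion model and its fit |
| `petpbpk.pbpk_model` | ODE right-hand side, simulation, observation model, flux bookkeeping |
| `petpbpk.fit_engine` | weighted objective, bounds, multistart fit, bounds refinement |
| `petpbpk.derived_pk` | clearance/distribution functionals, group statistics |
| `petpbpk.synthetic_data` | scenario presets and synthetic scan generation |
| `petpbpk.pipeline` / `petpbpk.cli` | study orchestration and the command line |

## Data formats

TAC tables are delimited text with columns `frame_start_s`, `frame_end_s`
and one column per region, `<region>_conc_kBq_per_ml` or
`<region>_amount_kBq` (regions: `blood`/`plasma`, `liver`, `gi`, `kidney`,
`tissue`, `urine`; `gi` and `urine` are amount-only). A YAML sidecar
(`<stem>.config.yaml`) carries `scan_id`, `body_weight_g`, `dose_MBq`,
`infusion_duration_s`, `group`, `tracer`. Internal units are minutes, ml,
kBq; clearances are reported in µl/min.

## CLI

```sh
# generate a synthetic scan from a preset
petpbpk simulate-scan --preset mt107_control_like --seed 1 --out scans/

# fit the plasma infusion model / the whole-body model to one scan
petpbpk fit-plasma scans/mt107_control_like_s1.csv
petpbpk fit-pbpk scans/mt107_control_like_s1.csv --starts 32 --seed 0 --out fit.json

# simulate a trajectory from a parameter file, derive PK, compare groups
petpbpk simulate params.yaml scan.yaml --out traj.csv
petpbpk derive fit.json scans/mt107_control_like_s1.config.yaml
petpbpk compare -a fitA1.json -a fitA2.json -b fitB1.json -b fitB2.json

# full study (per-scan fits, group summary, t-tests), optional refinement
petpbpk run study.yaml --rounds 1
```

A study YAML lists scans and fitting options:

```yaml
scans:
  - tac: scan1.csv        # sidecar config found automatically
  - tac: scan2.csv
fit: {n_starts: 32, seed: 1}
output_dir: out
```

## Tests

```sh
python -m pytest tests/            # full suite (~6 min single CPU)
```

`tests/test_acceptance.py` holds the acceptance criteria: plasma-model
structural identities, matrix-exponential and steady-state oracles for the
ODE system and the clearance formulas, multistart parameter recovery, and
group-effect detection at n = 4.

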