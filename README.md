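# t2dsim

Patient-level type 2 diabetes outcomes microsimulation. The package
simulates annual health-state transitions for a cohort of people with
type 2 diabetes — mortality, twelve diabetes-related complications, and
the time paths of BMI, HbA1c, systolic blood pressure and LDL-cholesterol —
and quantifies the health (life-years, QALYs) and economic (direct cost)
consequences of controlling risk factors versus letting them progress.

## What it contains

| module | purpose |
| --- | --- |
| `t2dsim.cohort` | synthetic baseline cohort generator calibrated to marginal *and* joint target-failure fractions; sex-specific mean imputation; event-panel fixtures |
| `t2dsim.risk` | 13-outcome risk equations: exponential / Weibull / Gompertz (proportional hazards), log-logistic / log-normal (accelerated failure time), logistic annual mortality, flexible parametric (spline on log time); maximum-likelihood fitting with right censoring; AIC family selection |
| `t2dsim.biomarkers` | one-step biomarker progression regressions (linear or logit-rescaled), fitting and deterministic/stochastic forward paths |
| `t2dsim.scenarios` | strict-inequality targets (HbA1c < 7 %, BP < 130/80 mmHg, LDL < 2.6 / 1.8 mmol/L with prior CVD), attainment classification, immediate / ramped / partial-coverage control scenarios |
| `t2dsim.engine` | vectorised annual-cycle Monte Carlo with half-cycle death exposure and per-(person, cycle, outcome) common random numbers across scenarios |
| `t2dsim.economics` | additive utility decrements, event-year vs subsequent-year costs, 3 % discounting (first year undiscounted), scenario deltas, per-complication decomposition |
| `t2dsim.reporting` / `t2dsim.cli` | pipeline runner, baseline/outcome table rendering, `t2dsim` command line |
| `t2dsim.catalogs` | default **synthetic** coefficient catalogs (clearly marked; loadable replacements via YAML) |

All default coefficient values are synthetic placeholders: the intercept of
each risk equation is solved from a stated target event rate at a reference
covariate vector so runs are internally consistent, but they are not fitted
to any real population. Externally estimated catalogs can be dropped in as
YAML files with the same schema (`t2dsim export-catalogs` writes templates).

## Command line

```bash
t2dsim synth --n 10000 --seed 1 --out cohort.csv      # synthetic cohort
t2dsim report --cohort cohort.csv --out table1.csv     # baseline target failure
t2dsim simulate --cohort cohort.csv --scenario combined --out ledger.csv
t2dsim fit --panel panel.csv --out fitted.yaml         # AIC family selection
t2dsim demo --n 5000 --seed 17 --outdir demo_out       # full pipeline
```

`demo` runs: generate → impute → classify → simulate the natural path and
the four control scenarios under common random numbers → economics → CSV
tables (baseline failure counts, population/per-person outcome deltas by
sex and horizon, per-complication decomposition) plus a metadata JSON with
seeds and config hashes. Reruns with the same config are byte-identical.

## Python API sketch

```python
from t2dsim import (
    CohortProfile, generate_cohort, impute_missing, preset_scenarios,
    simulate_cohort, aggregate_scenario_delta,
)
from t2dsim.catalogs import (
    default_risk_catalog, default_biomarker_catalog,
    default_utility_catalog, default_cost_catalog,
)

cohort = impute_missing(generate_cohort(CohortProfile(n=5000, seed=1)))
scn = preset_scenarios(10)
base = simulate_cohort(cohort, default_risk_catalog(), default_biomarker_catalog(),
                       scn["natural"], horizon=10, master_seed=1)
ctrl = simulate_cohort(cohort, default_risk_catalog(), default_biomarker_catalog(),
                       scn["combined"], horizon=10, master_seed=1)
table = aggregate_scenario_delta(base, ctrl, cohort, scn["combined"],
                                 default_utility_catalog(), default_cost_catalog())
```
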