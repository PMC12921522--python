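# lupus-cea

Cost-utility analysis of **early versus delayed belimumab initiation** in
biologic-naive adults with clinically active systemic lupus erythematosus
(SLE), from the US payer perspective.

The package is aimed at health-economics and HTA practitioners who want a
transparent, scriptable re-implementation of a published SLE
cost-effectiveness model: a 6-state Markov cohort engine, an auditable
parameter ledger, probabilistic and deterministic sensitivity analysis, and
a calibration layer that pins the synthetic inputs to the published
base-case totals.

## The model

A Markov cohort model on monthly cycles over a 15-year horizon with six
health states — pretreatment, complete response (SRI-4), partial response,
nonresponse, no treatment, death — expanded internally by drug context
(belimumab → anifrolumab switch, off treatment).  Mortality combines a
life table with age/sex-specific standardized mortality ratios on the
hazard scale.  Utilities are EQ-5D state values with a time trend and a
glucocorticoid disutility of 0.005 per mg/day prednisone-equivalent; costs
(2024 USD) combine WAC-based drug acquisition with state-stratified
secondary costs.  Both costs and QALYs discount at 3%/year.  Decision
metrics:

- ICER = (C_early − C_delayed) / (Q_early − Q_delayed)
- INMB = ΔQ · λ − ΔC at willingness-to-pay λ = $50,000/QALY

A strategy that gains QALYs while saving money is *dominant*.  Full model
documentation is in [docs/methods.md](docs/methods.md).

## Worked example

```python
from lupus_cea import AnalysisSettings, evaluate_comparison
from lupus_cea.synthetic import calibrated_default_ledger, generate_life_table

life_table = generate_life_table()
ledger, calibration = calibrated_default_ledger(life_table=life_table)
settings = AnalysisSettings()          # 15 y, 3%, $50k/QALY, monthly cycles

early, delayed, ce = evaluate_comparison(
    ledger.base_parameter_set(), settings, life_table)
print(f"early   : ${early.cost_discounted:,.2f}  {early.qaly_discounted:.2f} QALYs")
print(f"delayed : ${delayed.cost_discounted:,.2f}  {delayed.qaly_discounted:.2f} QALYs")
print(f"dC ${ce.delta_cost:,.2f}  dQ {ce.delta_qaly:.2f}  "
      f"ICER ${ce.icer:,.2f}/QALY  INMB ${ce.inmb:,.2f}  [{ce.dominance}]")
```

prints

```
early   : $1,910,438.61  7.68 QALYs
delayed : $2,036,775.73  7.38 QALYs
dC $-126,337.12  dQ 0.30  ICER $-421,123.73/QALY  INMB $141,337.12  [dominant]
```

Early initiation costs $126,337 less and gains 0.30 QALYs per patient over
15 years — it dominates, and the negative ICER is reported with the
dominance label rather than compared to the threshold.

The same pipeline is available from the shell:

```sh
lupus-cea base     --config examples/config.yaml --out results/
lupus-cea psa      --config examples/config.yaml --out results/ --n-sims 10000
lupus-cea dsa      --config examples/config.yaml --out results/
lupus-cea horizons --config examples/config.yaml --out results/ --years 1-25
lupus-cea scenario --config examples/config.yaml --out results/ --id biosimilar_sub_60
```

Outputs are JSON summaries and CSV tables (per-cycle audit trail, CE-plane
draws, CEAC, tornado) plus a manifest recording the settings snapshot,
ledger hash and seed of every run.  `examples/ledger.yaml` holds the
calibrated parameter ledger; supply your own ledger or a real `age,sex,qx`
life-table CSV through the config file to replace the synthetic inputs.

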