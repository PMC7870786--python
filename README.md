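# psmcea

Partitioned-survival cost-effectiveness modelling toolkit for oncology
treatment comparisons, built around a genomic-test-directed treatment
decision: survival-curve machinery (parametric families including
Royston-Parmar-style log-cumulative-hazard splines and mixture/non-mixture
cure models, right-censored MLE, AIC selection), pseudo individual-patient
data reconstruction from digitized Kaplan-Meier curves with numbers-at-risk,
a weekly-cycle partitioned-survival engine with hazard-ratio tail
extrapolation and companion-diagnostic (NGS) screening costs, incremental
cost-effectiveness outputs (ICER / INHB / INMB, dominance), and the full
uncertainty apparatus (tornado, probabilistic sensitivity analysis, CEAC,
hazard-ratio subgroups).

## Layout

| module | contents |
| --- | --- |
| `psmcea.survival` | `SurvivalDistribution`, `survival_at`, `hazard_at`, `fit_mle`, `select_best` |
| `psmcea.reconstruct` | `DigitizedKM`, `PseudoIPD`, `reconstruct_ipd` (interval-wise KM inversion) |
| `psmcea.engine` | `StrategyConfig`, `ModelSettings`, `Trace`, `build_trace`, `adjusted_survival`, `nns`, `screening_cost` |
| `psmcea.econ` | `CEResult`, `evaluate`, `compare` (ICER / INHB / INMB, dominance labels) |
| `psmcea.uncertainty` | `derive_beta/lognormal/gamma`, `ParamSpec`, `one_way`, `psa`, `ceac`, `subgroup` |
| `psmcea.simulate` | `simulate_ipd`, `digitize_km`, `make_fixture_config` (complete two-scenario fixture) |
| `psmcea.config` | YAML (de)serialization, config hashing |
| `psmcea.cli` | `psmcea` command-line entry point |
| `psmcea.benchmarks` | bundled published base-case cells used by worked-example tests |

## CLI

A complete fixture configuration (scenarios `A` — 3-gene population, and `B`
— 15-gene population) is bundled; `fixture:A` / `fixture:B` can be used
anywhere a config path is expected, or written out first:

```bash
psmcea make-config --scenario A --out config_a.yaml
psmcea run  --config config_a.yaml --out out/run          # traces + summary JSON
psmcea dsa  --config fixture:A --out out/dsa              # tornado CSV
psmcea psa  --config fixture:A --seed 1 --iterations 10000 --out out/psa
psmcea subgroup --config fixture:A --hr-pfs 0.34 --hr-low 0.25 --hr-high 0.47 --out out/sub
psmcea report --config fixture:B --seed 1 --out out/report
```

Survival-curve workflows:

```bash
psmcea fit --ipd ipd.csv --arm olaparib --family weibull --family gamma --out out/fit
psmcea reconstruct --curve km_points.csv --risk risk_table.csv --out out/ipd
```

IPD CSVs use columns `time,event[,arm]` (event 1 = event, 0 = censored);
digitized curves use `time,survival` plus `time,n_at_risk`.  Every command
writes a `manifest.json` with the config hash, seed, version and artifact
list; all randomness flows from `--seed`.

## Notes and limitations

* Published survival-model parameter tables are assumed to be on a monthly
  time scale; `scale_on_log` switches the log-scale reading of `scale`
  parameters where the source is ambiguous.
* Spline knot locations are not published.  For the scenario-A progression
  curve the bundled knots make the published coefficients reproduce the
  trial median; for the scenario-B overall-survival spline no knot placement
  yields a plausible monotone curve, so fixture-B engine totals are not
  meaningful (the trace remains valid via the engine's monotone clamp).
* Unpublished inputs (adverse-event incidences, salvage-regimen mix and
  duration, time horizon) carry documented placeholder defaults; absolute
  base-case totals are therefore not reproduction targets.
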