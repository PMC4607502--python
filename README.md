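# neusep

Mechanistic modeling of neutrophil phenotype dynamics in acute bacterial
sepsis, and in-silico evaluation of an extracorporeal CXCR-1/2–trapping
treatment.

## The problem

In early sepsis, neutrophils both clear the pathogen and — when their
killing program is misdirected — drive organ damage. The chemokine IL-8
controls this balance through two receptors: CXCR-1 triggers the killing
program, CXCR-2 the migratory one. `neusep` implements a 17-state ODE
model coupling receptor-level CXCR-1/2 trafficking (binding,
internalization, recycling, and a treatment-induced trapped state) to
systemic dynamics: pathogen load `P`, IL-8, four neutrophil phenotypes
(basal `N_B`, migratory `N_M`, killer `N_K`, dual `N_K/M`), a bounded
damage variable `D ∈ [0,1]` and creatinine as its clinical read-out,

```
dP/dt  = k_PG·P − k_P−NK/M·N_K/M·P − k_p·P/(k_pd+P) − k_PL·P²
dD/dt  = k_D−NK·N_K·(1−D) − k_D·D
dN_B/dt = k_NG·(1 + k_NB−G·F/(k_NB−Gd+F)) − k_NK−IL8·N_B·C_R1s
          − k_NM−IL8·N_B·C_R2s − k_NB·N_B − k_fMLP−NB·N_B
```

(and analogous equations for the remaining states; see
`docs/methods.md`). The package bundles the published survivor /
non-survivor parameterizations of a 16-baboon *E. coli* bacteremia study
(5 of 16 animals survived) and provides, as tested library code:

* **Simulation** — stiff integration with event-exact treatment windows,
  damage metrics (`AUC_D`, peak damage), pathogen detection-limit
  censoring (4.4 CFU).
* **Synthetic data** — study-structured mean ± SD time-series datasets
  from any ground truth, and surrogate parameter ensembles
  (moment-matched lognormal resampling of the published tables).
* **Calibration** — Bayesian ensemble estimation by parallel tempering
  (6-chain ladder, 23% acceptance / 15–30% swap servos, Gelman-Rubin
  PSRF < 1.1 convergence), with the two-round shared/split protocol for
  jointly fitting both outcome groups.
* **Ensemble statistics** — three-way stepwise logistic key-parameter
  selection, Kolmogorov-Smirnov marginal comparisons, t-tests on
  phenotype peaks.
* **Sensitivity analysis** — third-order RS-HDMR meta-modeling of
  cumulative damage with Sobol' indices split into independent and
  correlated contributions, validated against a pick-and-freeze
  Monte-Carlo oracle.
* **Virtual trial** — mixed 69/31 virtual populations, a damage-feature
  logistic outcome classifier, and the (onset, offset, device-affinity)
  treatment grid.

## Worked example

```python
import neusep

model = neusep.SepsisEnsembleModel({})   # bundled tables, no data needed
for group in ("survivor", "nonsurvivor"):
    traj = model.simulate(group, horizon=144.0)
    auc, peak = neusep.damage_metrics(traj)
    print(f"{group:12s}  AUC_D={auc:6.3f}  peak_D={peak:.4f}  "
          f"peak N_K={traj.state_series('N_K').max():5.1f}")

trt = neusep.TreatmentSpec(t_on=4.0, t_off=76.0, Kd_device=1e-3)
treated = model.simulate("nonsurvivor", horizon=144.0, trt=trt)
print("treated nonsurvivor AUC_D=%.3f" % neusep.damage_metrics(treated)[0])
```

prints

```
survivor      AUC_D= 2.356  peak_D=0.0563  peak N_K= 13.1
nonsurvivor   AUC_D= 6.394  peak_D=0.1424  peak N_K= 36.5
treated nonsurvivor AUC_D=3.137
```

Under the published mean parameters, non-survivors accumulate ~2.7× the
cumulative damage of survivors, driven by a much stronger killer
neutrophil spike; trapping free CXCR-1/2 receptors from 4 h to 76 h
post-infection at a device affinity one decade stronger than the IL-8
anchor roughly halves non-survivor damage.

Calibration runs through the same object when observation data are
attached:

```python
data = neusep.generate_dataset(truth_params, init, group="survivor", seed=1)
model = neusep.SepsisEnsembleModel(data, free=["k_NK", "k_NK_IL8"])
results = model.fit()          # parallel tempering
print(results.summary())       # posterior table, acceptance, PSRF
```

A thin CLI mirrors the main operations:
`neusep simulate|fit|select-keys|gsa|trial --help`.

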