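# Methods

## The model

`neusep` implements a mechanistic ordinary-differential-equation model of
the acute innate immune response to a bloodstream bacterial challenge,
centered on IL-8 signalling through the neutrophil surface receptors
CXCR-1 and CXCR-2. Seventeen state variables are integrated:

* **Systemic level** — pathogen load `P` (CFU); IL-8 `C_IL8` and a generic
  proinflammatory peptide `C_fMLP` (nM); four neutrophil phenotypes
  (10^3 cells/ul): basal `N_B`, migratory `N_M`, killer `N_K` and the
  dual killer/migratory `N_KM`; a mobilization filter `F` (a first-order
  delay between pathogen and neutrophil influx); systemic damage
  `D in [0,1]`; creatinine `C_creat` (nM) as the damage read-out; and the
  elastase/alpha1-PI complex `C_elas` (ng/ml), an exact algebraic slave of
  `N_K` (`C_elas = k_NE * N_K` when both start at zero).
* **Receptor level** — non-dimensionalized CXCR-1/2 fractions:
  surface-bound (`C_R1s`, `C_R2s`), internalized (`C_R1i`, `C_R2i`) and,
  under extracorporeal treatment, trapped (`C_R1t`, `C_R2t`). Receptor
  number is conserved; the free fraction is the remainder
  `1 - s - i - t`.

The pathogen grows linearly with a quadratic population cap and a
saturable clearance term, and is killed by `N_KM` (mass action). IL-8 is
produced by pathogen (Hill) and by damage (`D^2` Hill, a positive
feedback loop), and decays first order. Surface-bound receptor fractions
drive the phenotype transitions `N_B -> N_K` (CXCR-1), `N_B -> N_M`
(CXCR-2), `N_M -> N_KM` (CXCR-1), `N_K -> N_KM` (CXCR-2); a
receptor-independent fMLP pathway moves `N_B -> N_KM` directly. Damage is
produced by `N_K` with a `(1 - D)` saturation and recovers first order,
so `D` cannot leave `[0, 1]`. Creatinine has constant production and a
damage-impaired clearance `k_creat * (1 - D) * C_creat`.

Two parameterizations are bundled (`neusep/data/baboon_tables.yaml`):
*survivor* and *non-survivor* columns of a 16-animal baboon E. coli
bacteremia study (2x10^9 CFU/kg over two hours; 5 of 16 animals
survived). Each parameter carries a mean and a posterior SD; constants
fixed to literature values have SD 0.

### Closure constants

Four constants appear in the equations but have no published value; they
are closed deterministically in `complete_params`:

| constant | closure | rationale |
|---|---|---|
| `k_f1`, `k_f2` | `k_r / K_D_IL8` = 79.2 / 2.5e-3 = 31 680 | detailed balance from the published dissociation rate and affinity |
| `k_creat_P` | `k_creat * C_creat(0)` | creatinine stationary at the healthy baseline when `D = 0` |
| `k_IL8_Dd` | configuration, default 1.0 | dimensionless damage-squared Hill scale |

The printed treatment equations place the Heaviside capture flux in the
surface-bound equation; implemented verbatim this drives the bound
fraction to -1 under strong trapping and lets the device activate
receptors without ligand. We instead model the device as an exchange
between the *free* (unliganded) pool and the trapped pool: capture
`H(t) * k_ft * free` and release `k_ft' * trapped` both live in the
trapped-state equation, the surface-bound state keeps pure binding
kinetics, and conservation holds by construction. Release rates mirror
the receptor recycle rates (`k_ft' = k_i'`) and capture follows from the
device dissociation constant, `k_ft = k_ft' / Kd_device`, so equal
device/ligand affinity reproduces the IL-8 on/off ratio. Device `Kd`
values (1e-2 … 1e-5) are interpreted on the same concentration scale as
the IL-8 affinity anchor 2.5e-3.

The fMLP-pathway flux is `k_fMLP_NB * N_B` as printed (no ligand factor);
a `fmlp_mass_action` switch multiplies it by `C_fMLP` for users who
prefer the mass-action reading. WBC maps to `N_B` by default
(`wbc_total=True` sums all four phenotypes).

## Numerics

Integration uses LSODA with `rtol = 1e-7` (1e-6 inside the likelihood)
and a per-state absolute-tolerance vector, because state scales span ~18
decades (pathogen up to the ~6.05e6 CFU carrying capacity, fMLP
equilibrium ~1e-11 nM). Treatment on/off switches restart the integrator
exactly at `t_on`/`t_off`. Right-hand-side fluxes are evaluated on
`max(y, 0)`: adaptive steppers probe transiently negative states, where
the quadratic pathogen term would otherwise turn a decaying mode into a
finite-time blowup; inside the physical domain the guard is the identity.
A post-hoc floor check errors if any state falls below
`-1e-8 * max(1, its peak)`; surviving round-off negatives are clipped to
zero in the stored trajectory. Halving the tolerances moves the damage
area by < 0.1% on the mean-parameter trajectories (tested). The default
output grid is 0.1 h; ensemble work uses 0.5 h, which changes AUC_D by
well under the Monte-Carlo noise. Cumulative damage is the trapezoid rule
on the output grid over 0-144 h; treated simulations run to
`max(144 h, t_off + 48 h)` so post-treatment rebounds are visible to the
metrics.

## Synthetic data generator

`generate_dataset` emulates the structure of the animal study: per-group
mean +/- SD time series of the five fitted observables (pathogen, IL-8,
WBC, elastase/alpha1-PI, creatinine) at the acute-arm schedule (1, 2, 4,
11, 23, 35, 47, 72, 144 h), for `n = 8` virtual animals per group.
Independent Gaussian measurement noise with a 20% coefficient of
variation per observable (SD floored at `cv * 5%` of the series peak so
zero-valued observations keep a finite SD; in the noise-free limit a 1%
CV floor is kept so the dataset remains a usable likelihood target),
truncation at zero, and per-animal censoring of pathogen counts below the
4.4 CFU assay detection limit. The 20% CV is a typical biological assay
CV; the likelihood uses the dataset's own SDs, so the choice is
self-consistent.

`sample_surrogate_ensemble` builds stand-in posterior ensembles by
moment-matched lognormal sampling of each published mean/SD pair
(constants with SD 0 reproduced exactly). **Fidelity limit:** only
marginals are published, so the surrogates carry no posterior covariance.
Measured consequence: the within-group spread of cumulative damage is
much wider than the calibrated ensembles' (survivor AUC_D CV ~1.7 here),
the two groups' damage distributions overlap substantially, and the
damage-feature outcome classifier reaches only ~60% held-out accuracy.
Results that depend on tight within-group damage distributions (the 31%
untreated baseline of the virtual trial, the existence of a harm region
for early short treatment) are therefore not reproduced by the
surrogates, and the corresponding checks are expected to fail until real
posterior ensembles are supplied. Pipeline logic is unaffected: with
calibrated or otherwise covariance-bearing ensembles the same code runs
unchanged.

## Calibration (parallel tempering)

The fitness of a parameter set is the weighted negative sum of squared
standardized residuals, `-sum w (y - yhat)^2 / (2 sigma^2)` over time
points, observables and datasets, with simulated pathogen censored at
4.4 CFU before residuals; integration failure scores `-inf`. Weights
default to 1.

Sampling runs a ladder of Metropolis chains (default 6) in log10
parameter space under log-uniform priors spanning +/-3 decades around the
published means. Initial states are prior draws passing a maximum-energy
screen (fitness above the 1st percentile of 1000 prior draws). Adjacent
temperatures attempt swaps every 25 steps. Two servos run during the
adaptation phase and then freeze: per-chain step sizes move toward a 23%
acceptance rate (multiplicative update with a `2/sqrt(round)` gain) and
log-temperature gaps expand/contract toward a 15-30% swap band from a
geometric initial ladder (max temperature 1e3). Only post-freeze cold
chain samples are kept. Convergence is the Gelman-Rubin potential scale
reduction factor on equal post-freeze segments, with PSRF < 1.1 as the
pass mark; degenerate (zero-variance) parameters report 1.0.

The two-group protocol fits each group separately (round 1), screens for
*key parameters* — those selected by all of L1-regularized logistic
regression (penalty by 5-fold cross-validation), forward conditional
stepwise (likelihood-ratio entry p < 0.05) and backward conditional
elimination (removal p > 0.10) on standardized log-scale draws — and then
refits both datasets jointly (round 2) with shared parameters common and
each key parameter split per group; the per-group fixed constants
(neutrophil source, creatinine clearance) keep their published values.
Predictors exclude columns constant within a group, which would identify
the label deterministically. Desk-scale runs shrink the adaptation and
sample budgets (stated per test) but keep the servo logic.

## Global sensitivity analysis (RS-HDMR)

The output is the damage area AUC_D over 0-144 h. Inputs are mapped to
(0, 1) by empirical CDF ranks, so the ensemble sample itself supplies the
input measure (correlations included). The meta-model is
`f = f0 + sum g_l` with shifted-Legendre orthonormal components of order
up to three, fitted jointly by least squares and pruned by a block F-test
(alpha = 0.05), in three hierarchical stages (first-order for all inputs;
pairs ranked by first-order strength; triples over inputs active in
surviving pairs), with the candidate coefficient count capped at a tenth
of the sample count at every stage. Basis degrees default to (7, 3, 2)
per dimension for first/second/third order: degree 7 is the smallest that
resolves oscillatory benchmark responses (the Ishigami sin^2 term) to
0.05 per index at 4000 samples, and the moderate pair degree leaves
budget for enough interaction pairs on wide multiplicative responses.

Inputs with few distinct values (the two-valued group-fixed constants of
a combined two-group population) get their basis degree capped at one
less than their cardinality, and exactly rank-duplicated input columns
are reduced to a single representative before fitting.

Indices follow the covariance decomposition: `S_l = Cov(f, g_l)/Var(f)`,
split into the independent part `S_l^a = <g_l, g_l>/Var(f)` and the
correlated part `S_l^b` (cross inner products); totals per input sum
every retained component containing it. An independent pick-and-freeze
Monte-Carlo estimator (Sobol'-Saltelli first order, Jansen totals)
cross-checks the meta-model on independent-input benchmarks (linear,
Ishigami, Sobol g-function) to within 0.05 per index. Exactly duplicated
inputs make the first-order design rank-deficient and raise an error
naming the collinear pair.

## Virtual treatment trial

A mixed population draws 69% of its members from the non-survivor
ensemble and 31% from the survivor ensemble (the experimental outcome
composition), labels retained for evaluation only. The outcome classifier
is a logistic regression on two untreated damage features — AUC_D and
peak damage — trained on a stratified 20% subset (decision threshold
0.5, effectively unregularized); held-out accuracy is reported on the
remaining 80%. The trial grid varies onset 0-12 h (1 h step), offset
0-100 h (4 h step) and device Kd in {1e-2, 1e-3, 1e-4, 1e-5}; cells with
`t_off < t_on` are invalid, zero-duration cells equal the untreated
baseline by construction, and cells with > 1% integration failures are
flagged. Each valid cell simulates every member with the treatment window
and reports the percent labeled survivor.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: 1000
draws per surrogate ensemble; 1000-member mixed populations; 4000
resampled parameter sets per GSA; calibration runs of 6 chains with
6250-12500 adaptation proposals and 20 000 saved cold-chain samples
(saved every step); the Gaussian-target servo checks use 10 000
post-freeze proposals. Production-scale protocols (200 000 x 25 saved
steps) are reachable through `PTConfig` unchanged.

## Known limitations

* Surrogate ensembles lack posterior covariance (see above) — the main
  fidelity limit for trial baselines and harm-region behaviour.
* The weighting function of the fitness is unit (values unpublished).
* No pharmacokinetics of the antibiotic co-treatment; no secondary
  infection under immunosuppression; no device engineering parameters
  (flow rate, surface area).
* The 28-day chronic arm is supported only as a sampling time
  (`horizon` is configurable); no chronic-phase biology is added.
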