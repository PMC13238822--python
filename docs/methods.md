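# Methods

`rebuildsim` simulates a one-way predator–prey pair of harvested groundfish:
lingcod (*Ophiodon elongatus*), a productive, sexually dimorphic predator,
and yelloweye rockfish (*Sebastes ruberrimus*), a long-lived, slow prey
rebuilding from depletion while taken as bycatch in the predator fishery.
This note records the model, its numerical choices, the calibration the
package performs, and what the synthetic study conditions do and do not
represent.

## Model

### State and time structure

The model is semi-discrete: continuous within-year mortality punctuated by
annual pulses of recruitment and aging.  The prey is tracked as numbers at
age `Y_i`, i = 1..65 (sex-aggregated, age 65 an absorbing plus group); the
predator as numbers at age and sex `L_{j,s}`, j = 1..20.  Within a year,

    dL_{j,s}/dt = -(M_s + nu_{j,s} F) L_{j,s}
    dY_i/dt    = -(M_Y + nu_i b F) Y_i  -  Y_i * sum_{j,s} a_{i,j,s} L_{j,s}
                  / (1 + delta * sum_i' a_{i',j,s} Y_i' + delta q)

with sex-specific predator natural mortality `M_s` (0.18 yr⁻¹ females,
0.32 males), prey natural mortality `M_Y` = 0.044 yr⁻¹, knife-edge
length-based fishery vulnerability `nu` (predator 56 cm, prey 25 cm),
predator fishing rate `F`, bycatch proportionality `b` (prey fishing rate =
`b F`, default 0.05), and a size-selective Holling type-II predation term
(below).  The predator system is linear and autonomous and is advanced by
its exact exponential solution; the prey system is integrated numerically.

### Pulses, spawning, recruitment

Lengths follow von Bertalanffy growth with t0 = 0, weights a mass–length
power law, maturity a logistic ogive in age (predator females a50 = 4 yr,
prey a50 = 17.5 yr, slope 0.5 yr⁻¹ — the midpoints of the reported
50%-maturity ranges; both configurable).  Spawning biomass is measured at
the annual pulse instant (start of year, after aging and recruitment) —
the standard assessment convention — and recruits entering at the next
pulse derive from it:

    R_{k+1} = alpha S_k / (1 + beta S_k) * exp(eps_{k+1} - sigma^2/2)

with `alpha = 4h/((1-h) phi)` and `beta = (5h-1)/((1-h) phi R0)` derived
from steepness `h`, unfished recruitment `R0` and unfished spawning biomass
per recruit `phi` (survivorship `l_1 = 1`, geometric plus-group closure;
for the sex-structured predator, `phi` is mature-female biomass per *total*
recruit, i.e. the 0.5 birth sex ratio is folded in, and the pulse then
splits recruits 0.5 per sex).  This timing makes the deterministic unfished
fixed point satisfy `S0 = R0 phi` exactly and the steepness identities
`R(S0) = R0`, `R(0.2 S0) = h R0` hold to machine precision in simulation,
which the per-recruit equilibrium oracles rely on.  Deviates `eps` are a
stationary AR(1) series (`eps_0 ~ N(0, sigma^2)`,
`eps_k | eps_{k-1} ~ N(rho eps_{k-1}, sigma^2 (1 - rho^2))`) with the
`-sigma^2/2` correction giving the multiplier unit mean; deterministic
phases use multiplier 1, targeting the mean-recruitment equilibrium.
Aging shifts every class by one, the plus group absorbing its own survivors
plus the penultimate class.

### Size-selective predation

A predator of length `l_p` can consume prey of length `l ∈ [Y5 l_p,
Y95 l_p]` (diet size-spectra quantile slopes Y5 = 0.05, Y95 = 0.29,
boundaries inclusive) — gape limitation, which leaves yelloweye older than
roughly age 13 invulnerable to even the largest lingcod.  The attack-rate
array `a_{i,j,s}` is constructed from three ingredients: the predator's
annual ration `C = a_c W^{b_c}` (kg/yr), the gape window, and the prey
specialization `gamma` (share of consumed biomass that is yelloweye;
scenarios: none 0, generalist 0.001, intermediate 0.014, specialist 0.05):

1. target prey biomass intake per predator: `gamma * C`;
2. allocated across acceptable prey ages in proportion to available prey
   biomass at a reference state (uniform allocation available as a switch);
3. per-age annual proportion consumed `p = allocation / (W_i Y_i^ref)`
   converted to an instantaneous rate `a = -ln(1 - p)`;
4. alternate-prey availability `q` set from the `(1-gamma)/gamma` diet
   share: `q = q_scale * delta * (1-gamma)/gamma * mean_{j,s}(sum_i a Y^ref)`,
   so alternate prey occupy the predator in proportion to the rest of its
   ration.  `q` is then nearly gamma-invariant, consistent with a
   gamma-independent alternate-prey field.

The reference state is the deterministic unfished no-predation stable age
distribution (R0-scaled) — reproducible and scenario-independent.  A
construction error is raised if per-predator demand reaches the available
pool (`p >= 1`).

**Kernel conditioning.** The absolute scale of realized predation is not
identifiable from the printed parameters alone: at the printed recruitment
scales (R0 = 4848 predator vs 220 prey) the nominal demand `gamma C`
exceeds what the prey population can supply by orders of magnitude, so the
functional-response denominator must do almost all of the regulating.  The
package therefore treats `gamma`'s operational meaning as anchored to its
documented steady-state effect: `q_scale` is solved at run time (bracketed
root finding on `log10 q_scale`) so that the deterministic unfished prey
equilibrium under specialist predation (`gamma = 0.05`) equals 0.66 of the
no-predation equilibrium.  One global `q_scale` (≈ 276 at the defaults) is
conditioned once and reused for every scenario and GSA draw; every other
scenario contrast is unconstrained model output.  A consequence worth
stating plainly: at the conditioned point the denominator is ≈ 6·10³, so
the realized response is effectively linear in predator abundance
(mass-action), and prey-density feedback through handling is negligible.
Fluctuation-level behaviour (variance transfer from predator to prey,
rebuilding-time spread) therefore reflects this linear regime; see
"Limitations".

## Calibration and scenarios

* **Unfished equilibria** `S0` per species and per `gamma`: deterministic
  F = 0 run to convergence (relative per-year change < 1e-8, 2000-yr cap)
  from 1.5× the unfished no-predation age structure.  Without predation the
  result matches `R0 phi` to <0.1%; prey `S0` decreases with `gamma`.
* **F40**: the predator fishing rate whose deterministic equilibrium
  spawning biomass is 40% of unfished, solved by Brent root finding on the
  per-recruit closed form `S_eq(F) = (alpha phi_F - 1)/beta` (tolerance
  1e-5 in F; ≈ 0.152 yr⁻¹ at the defaults) and confirmed by simulation.
* **Historical depletion**: each scenario starts with a 100-yr
  deterministic burn-in at species-specific historical rates solved
  (bracketed root finding, per `gamma`) so that each species ends at
  22% ± 0.5% of its unfished spawning biomass.  The predator rate is solved
  first (its dynamics are prey-independent), then the prey's own direct
  rate with the predator's depletion trajectory in place.  Burn-in endpoint
  depletion is asserted before every rebuilding run.
* **Rebuilding phase**: 350 stochastic years at the scenario's `(F, b)`;
  prey fishing is bycatch only (`nu_i b F`).  150 replicates by default;
  replicate ensembles are advanced as one batched ODE system.  Seeds derive
  from `(master seed, gamma, F, b)` through `numpy.random.SeedSequence`, so
  a run is bit-reproducible under a fixed master seed and replicate count.

## Outcome measures

Over the last 150 years of each 450-yr trajectory: mean spawning biomass;
stability = 1 / (mean across replicates of the per-replicate temporal CV of
annual spawning biomass; population SD, ddof = 0); and the mean share of
total *numbers* in the plus group.  Rebuilding time is the first
rebuilding-phase year with spawning biomass ≥ 0.4 of the scenario's
deterministic unfished level; replicates never reaching it are censored at
the phase length, reported, and excluded from the mean/SD.  Cross-scenario
comparisons are percent changes relative to the stated baseline (decline
negative).

## Global sensitivity analysis

2000 (configurable) uniform Monte-Carlo draws over {gamma, delta, q_scale,
sigma, rho_L, rho_Y, Y95}; default bounds are ±50% of each default, except
gamma spans its full admissible range [0, 0.1], the AR(1) autocorrelations
span the stationary range [0, 0.9], and q_scale varies [0.5, 1.5]× its
conditioned value.  Each draw rebuilds the kernel and runs one stochastic
unfished (F = 0) simulation of 450 years (no depletion burn-in: the
last-150-yr steady-state metrics are insensitive to the initial transient).
Draws whose kernel is infeasible (`p >= 1`, possible at high gamma with a
narrow gape window) are recorded and skipped.  Importance is %IncMSE from a
bagged regression-tree ensemble computed directly: 500 bootstrap
`DecisionTreeRegressor` trees (max_features = p//3), out-of-bag MSE
increase under single-feature permutation, expressed as a percentage of the
mean OOB MSE, with an injected standard-normal noise column as the
reference predictor.  Only rank orderings are interpreted.

## Numerical choices

* Prey ODE: `scipy.integrate.solve_ivp`, rtol 1e-6, atol 1e-8; LSODA for
  single trajectories, RK45 for batched ensembles (stacking replicates into
  one system makes LSODA's stiff-branch dense Jacobian a liability; the
  dynamics are non-stiff and the two agree to solver tolerance — a standing
  test).  Integration undershoots more negative than −1e-6 (100× atol)
  raise; smaller ones clamp to zero.
* Gape-window boundaries compare with a 1e-12 relative epsilon so the
  printed boundary cases are inclusive under float rounding.
* Degenerate metrics: a constant SSB series has CV 0 and stability is
  reported missing (NaN) rather than infinite; an extinct trajectory yields
  zero biomass and missing stability.
* Steepness h = 1 (recruitment independent of biomass) is rejected rather
  than approximated (infinite alpha).

## Problem sizes used in the shipped analyses

The acceptance script runs the full study conditions: 150 replicates ×
450 years for each of the seven (gamma, F) ensembles.  The test suite runs
the same contrasts at 50 replicates and the GSA at 500 draws — scaled-down
ensembles whose Monte-Carlo error is small relative to the asserted
tolerances.

## What the study conditions represent — and limitations

The "data" of this analysis are the printed parameter tables and
pseudo-random recruitment deviates; there is no estimation from survey or
catch data, no spatial structure (one closed area), no predator dependence
on prey (one-way coupling), and no sub-annual reporting.

Known limitations, stated because they shape which reported contrasts the
package reproduces:

* The kernel reconstruction is conditioned on one deterministic mean-level
  quantity (specialist unfished depletion 0.66).  Mean-level contrasts —
  specialist vs none spawning-biomass loss, harvest-driven losses of
  spawning biomass, stability and age structure in the generalist scenario
  — emerge within a few percentage points of the documented values.
* In the conditioned (mass-action) regime the predator→prey variance
  transfer is weak: specialist predation lowers prey stability by ~6–9%,
  not the documented ~70%, and predator harvest does not raise specialist
  prey stability.  Reproducing those would require a functional-response
  nonlinearity (or predation–age structure) that the available inputs do
  not identify.
* Predation falls mostly on prey ages 1–3, fed by small, unfished predator
  classes; harvest of large predators therefore relieves little predation.
* With steepness 0.718, recruitment at 22% depletion is ~0.73 R0, so the
  burn-in leaves a nearly full juvenile pipeline: rebuilding to 0.4 S0
  takes ~18 years with sub-year replicate spread, and percent changes in
  rebuilding-time mean/SD across scenarios are accordingly much larger
  (mean) or smaller (gamma contrast) than the documented ones, which imply
  longer, more stochastic rebuilding trajectories.

Passing tests on the synthetic conditions show internal consistency of the
model and its calibration, not predictive skill for the real fishery.
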