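# rebuildsim

Age-structured predator–prey simulation of a rebuilding groundfish prey
under predator harvest and bycatch, built around the lingcod
(*Ophiodon elongatus*) – yelloweye rockfish (*Sebastes ruberrimus*) pair of
the U.S. West Coast groundfish fishery.  It is aimed at fisheries modellers
who want to ask: if the predator of a slowly rebuilding stock is itself
fished — incidentally killing some of the prey — does predation release or
bycatch mortality win, and how does the answer depend on how specialized
the predator's diet is?

## The model

A semi-discrete (impulsive) age-structured model: continuous within-year
mortality punctuated by annual pulses of Beverton–Holt recruitment and
aging.  Prey numbers-at-age `Y_i` (i = 1..65, plus group) and predator
numbers-at-age-and-sex `L_{j,s}` (j = 1..20) follow, between pulses,

    dL_{j,s}/dt = −(M_s + ν_{j,s} F) L_{j,s}
    dY_i/dt     = −(M_Y + ν_i b F) Y_i − Y_i Σ_{j,s} a_{i,j,s} L_{j,s}
                   / (1 + δ Σ_{i'} a_{i',j,s} Y_{i'} + δ q)

with a size-selective Holling type-II predation term: lingcod of length
`l_p` eat yelloweye between `0.05 l_p` and `0.29 l_p` (gape limitation),
with handling time δ and alternate-prey availability q, and attack rates
`a_{i,j,s}` built from the predator's annual ration `C = a_c W^{b_c}` and
the prey-specialization parameter γ (the yelloweye share of consumed
biomass; generalist 0.001 … specialist 0.05).  Recruitment at each pulse is

    R_{k+1} = α S_k / (1 + β S_k) · exp(ε_{k+1} − σ²/2),

with α, β derived from steepness h, R0, and spawning biomass per recruit
φ, and ε an AR(1) series (ρ = 0.23, σ = 0.5).  Scenarios cross γ with the
predator fishing rate F ∈ [0, 0.4]; the prey is fished only as bycatch at
rate `b·F` (b = 0.05).  Every run starts with a 100-year deterministic
burn-in calibrated to deplete both species to 22% of unfished spawning
biomass, followed by 350 stochastic rebuilding years across 150 replicates.
Outcomes: mean spawning biomass, stability (1/CV of annual spawning
biomass), plus-group share of numbers (all over the last 150 years), and
rebuilding time to 0.4·S0.  A global sensitivity analysis (2000 uniform
Monte-Carlo parameter draws, random-forest permutation %IncMSE) ranks the
predation and recruitment parameters by influence.

The absolute scale of the predation kernel is not identifiable from the
printed parameter tables; the package conditions the alternate-prey
multiplier (q-scale) at run time so that the deterministic unfished
specialist equilibrium sits at 66% of the no-predation equilibrium.  See
`docs/methods.md` for the construction, the calibration, and its limits.

## Worked example

```python
import rebuildsim as rs
from rebuildsim.io import scenario_table
from rebuildsim.metrics import relative_change

system = rs.System()          # builds schedules, conditions the kernel
print(f"q_scale = {system.q_scale:.2f}, F40 = {system.F40:.4f}")

runs = [
    rs.run_scenario(system, rs.ScenarioSpec(gamma=g, F=F, b=0.05,
                                            n_replicates=50, seed=1))
    for g, F in [(0.0, 0.0), (0.05, 0.0), (0.05, system.F40)]
]
t = scenario_table(runs)
print(t.round(3).to_string(index=False))
print("specialist vs none SSB change: %.1f%%"
      % relative_change(t.mean_ssb[1], t.mean_ssb[0]))
```

prints

```
q_scale = 276.20, F40 = 0.1521
 gamma     F    b  n_replicates  mean_ssb  stability  plus_group_proportion  rebuild_mean  rebuild_sd  rebuild_censored  S0_prey   S0_pred   F40
  0.00 0.000 0.05            50  6425.436     17.089                  0.060         17.88       0.325                 0 6494.693 37553.772 0.152
  0.05 0.000 0.05            50  4331.193     15.526                  0.059         17.88       0.325                 0 4287.335 37553.772 0.152
  0.05 0.152 0.05            50  3346.013     14.328                  0.037         23.18       1.873                 0 4287.335 37553.772 0.152
specialist vs none SSB change: -32.6%
```

Reading the table: `F40` (0.152 yr⁻¹) is the lingcod rate giving 40% of
unfished predator spawning biomass at equilibrium.  Specialist predation
(γ = 0.05, F = 0) lowers mean steady-state yelloweye spawning biomass from
6425 kg to 4331 kg (−32.6%) and its unfished reference `S0_prey`
accordingly; fishing lingcod at F40 costs a further ~23% of prey spawning
biomass through bycatch, shrinks the plus-group share from 5.9% to 3.7%,
and lengthens mean rebuilding time from 17.9 to 23.2 years while spreading
it across replicates (SD 0.33 → 1.87 yr).

A command-line interface mirrors the library:

```bash
rebuildsim calibrate                      # q-scale, F40, S0, historical rates
rebuildsim run --gamma 0.05 --F 0.152 --reps 150 --seed 1 --outdir results
rebuildsim grid --reps 150 --seed 1       # full gamma x F x b grid
rebuildsim gsa --n 2000 --seed 1          # sensitivity analysis
```

Parameters load from YAML (`--config`) with dotted overrides
(`--set yelloweye.M=0.03`); outputs are tidy CSV plus a JSON manifest
sufficient to re-run bit-identically.

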