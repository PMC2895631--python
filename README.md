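# crowdshift

Postprocessing analysis of **macromolecular crowding effects on protein
open/closed conformational equilibria and transition barriers**.

Inside cells, inert macromolecules occupy 30% or more of the volume. For a
protein that interconverts between an expanded "open" and a compact "closed"
conformation, this excluded volume penalises the open state: it is harder to
find a cavity for a larger object. `crowdshift` quantifies that penalty for
atomistic protein structures without simulating the crowded solution
directly. Conformational ensembles are sampled in dilute conditions (e.g. MD
snapshots) and *postprocessed*: each conformation is assigned the
chemical-potential change Δμ of transferring it into a fluid of hard-sphere
crowders (radius R_c, volume fraction φ), and state-level free energies
follow. The package is aimed at computational biophysicists studying
conformational equilibria, allostery, or enzyme kinetics under cell-like
conditions.

## The model

Crowders are hard spheres; protein–crowder interactions are hard-core. For a
rigid conformation the transfer free energy is

    βΔμ = −ln f,

where f is the probability that the conformation, placed at a random
position and orientation in a box of equilibrated crowders, overlaps none of
them. Two routes to Δμ are implemented:

1. **Particle-insertion Monte Carlo** (`crowdshift.crowders.insertion_probability`)
   — the direct estimator, exact but useless once f is astronomically small.
2. **Generalized fundamental-measure theory (GFMT)**
   (`crowdshift.crowders.gfmt_delta_mu`) — βΔμ as a linear function of the
   volume v_p, surface area s_p and linear size l_p of the *crowder-exclusion
   surface* (the molecular surface computed with probe radius R_c):

       βΔμ = −ln(1−φ) + 3q·(l_p/R_c) + (3q + 4.5q²)·(s_p/4πR_c²)
             + ρ(1+φ+φ²)/(1−φ)³ · v_p ,      q = φ/(1−φ),

   with coefficients pinned so that a spherical solute reproduces the
   scaled-particle-theory insertion free energy exactly.

Per-conformation values are Boltzmann-averaged over each state's ensemble
(−ln⟨e^(−βΔμ)⟩, i.e. an average of insertion probabilities), giving Δμ_open
and Δμ_closed. The crowding-induced shift of the open/closed free-energy
difference and the relative change of the population ratio are

    βΔΔG = βΔμ_open − βΔμ_closed,      κ = e^(−βΔΔG) − 1.

For kinetics, umbrella-sampling windows along an open/closed reaction
coordinate are combined by WHAM; crowding enters by reweighting every sample
with its insertion probability f, and barrier shifts convert to rate factors
e^(±Δbarrier).

## Worked example

The headline arithmetic, starting from measured placement probabilities of
an open/closed pair at R_c = 15 Å, φ = 35%:

```python
import math
from crowdshift.thermo import delta_delta_g, population_ratio_change

mu_open = -math.log(2.96e-8)     # beta*dmu of the open state
mu_closed = -math.log(1.36e-7)   # beta*dmu of the closed state
ddg = delta_delta_g(mu_open, mu_closed)
effect = population_ratio_change(ddg)
print(f"beta*ddG = {ddg:.3f} kT")
print(f"fold change = {effect.fold_change:.2f}")
print(f"open/closed ratio reduced by {effect.percent_reduction:.0f}%")
```

prints

```
beta*ddG = 1.525 kT
fold change = 4.59
open/closed ratio reduced by 78%
```

— crowding at that condition reduces the open population ~4.6-fold. The same
machinery end-to-end on a synthetic two-state toy protein (two atom lobes
whose separation defines open vs closed):

```python
from crowdshift.pipeline import RunConfig, run_equilibrium
from crowdshift.synthetic import TwoStateToySpec

config = RunConfig(
    synthetic=TwoStateToySpec(n_atoms=100, closed_radius=5.0,
                              opening_displacement=10.0, jitter_sd=0.3,
                              n_conformations=3, seed=21),
    r_c_grid=(15.0, 30.0), phi_grid=(0.1, 0.35), seed=21,
)
report = run_equilibrium(config)
cols = ["R_c", "phi", "beta_dmu_open", "beta_dmu_closed", "beta_ddg", "kappa"]
print(report[cols].round(4).to_string(index=False))
```

```
 R_c  phi  beta_dmu_open  beta_dmu_closed  beta_ddg   kappa
15.0 0.10         0.4033           0.3097    0.0936 -0.0893
15.0 0.35         2.2075           1.6413    0.5662 -0.4323
30.0 0.10         0.2261           0.1890    0.0370 -0.0364
30.0 0.35         1.0913           0.8837    0.2076 -0.1875
```

κ < 0 everywhere (crowding favours the closed state), the effect grows with
φ and shrinks with crowder size — the expected excluded-volume phenomenology.

A command-line interface mirrors the library (`crowdshift equilibrium`,
`measures`, `insert`, `pmf`, `simulate`); see `crowdshift --help`.

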