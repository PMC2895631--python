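# Methods

This note documents the models, numerical choices and limitations of
`crowdshift`. Energies are in units of k_BT throughout; lengths in Å.
k_BT = 0.5961 kcal/mol at the default temperature of 300 K (used only to
convert umbrella force constants given in kcal/mol/Å²).

## Crowding model and its assumptions

The crowded solution is an equilibrium fluid of monodisperse hard spheres
(radius R_c, volume fraction φ); the protein–crowder interaction is pure
hard-core repulsion. Under these assumptions the transfer chemical potential
of a rigid conformation is βΔμ = −ln f, with f the probability of inserting
the conformation at a uniformly random position and orientation without
overlap. Everything downstream (ΔΔG, κ, PMF reweighting) follows exactly
from this; what is approximate is (a) the hard-sphere representation of real
crowders, (b) the neglect of soft protein–crowder attractions, and (c) the
estimators for f described below. Conformations are taken from
dilute-solution ensembles — the postprocessing assumption that crowding
reweights but does not create conformations.

State-level quantities use the exponential (f-space) ensemble average
βΔμ_state = −ln⟨e^(−βΔμ_i)⟩ computed by log-sum-exp. This is the only
average consistent with pooling insertion probabilities over an ensemble;
the arithmetic mean of βΔμ_i is available behind a flag for sensitivity
analysis only. The average is dominated by the most insertable
conformations: it lies in [min_i βΔμ_i, min_i βΔμ_i + ln n].

## Exclusion-surface measures (v_p, s_p, l_p)

The crowder-exclusion surface is the molecular (contact + re-entrant)
surface with probe radius R_c; the enclosed region equals the morphological
closing of the van der Waals union by a ball of radius R_c. Numerically:

1. The probe-center-excluded region D (union of r_i + R_c balls) is
   voxelized on a cubic grid (default spacing h = 0.5 Å; 0.25 Å for
   convergence checks). Membership uses the exact surface distance
   min_i(|x − c_i| − r_i), evaluated from the k = 16 nearest atom centres
   (k = 1 when all radii are equal); this is exact whenever radii vary by
   less than the neighbour spacing, which holds for van der Waals sets.
2. A Euclidean distance transform of D gives d(x), the distance to D's
   complement. The closing is the super-level set d ≥ R_c; its boundary is
   extracted by marching cubes at level R_c, giving v_p (mesh volume via the
   divergence theorem) and s_p (mesh area).
3. l_p (integrated mean curvature / 4π) comes from a least-squares fit of
   inflated volumes V(ε), ε ∈ {0.5, 1.0, 1.5, 2.0} Å, to the Steiner
   polynomial V(ε) = v_p + s·ε + 4π l_p ε² + (4π/3)ε³ with v_p fixed and the
   cubic coefficient fixed. Inflation reuses the same distance field
   (marching cubes at level R_c − ε), which is valid for ε < R_c and keeps
   discretization biases consistent across ε. The Steiner relation is exact
   for convex bodies and a controlled estimator for the near-convex closings
   produced by probes R_c ≥ 10 Å.

Against analytic spheres the implementation is accurate to well under 1%
in v_p and s_p at h = 0.5 (single atoms and 600-atom sphere-filling
clusters) and ~1% in l_p. Grids coarser than the smallest atom radius are
rejected.

SASA uses Shrake–Rupley with a 1.4 Å probe and a deterministic Fibonacci
lattice (default 960 points per atom; no RNG). It is cross-checked in the
tests against biotite's independent implementation with identical radii.

Default atomic radii are the Bondi van der Waals set; hydrogens are kept
when present (a flag strips them). Radii only enter overlap tests and
surface construction, and the table is replaceable.

## The two Δμ estimators

**Insertion Monte Carlo.** Crowder boxes are periodic cubes (length ≥ 6R_c;
default 8R_c) filled to N = round(φL³/v_c) spheres by random sequential
insertion (simple-cubic lattice start above φ = 0.3, where RSA stalls) and
equilibrated by Metropolis single-sphere displacement sweeps (step 0.3R_c,
default 500 sweeps; every non-overlapping move accepted). φ ≥ 0.55 is
refused — beyond reliable fluid equilibration for this sampler. Insertion
trials use uniform positions and uniform random-quaternion rotations;
overlap tests query a periodic k-d tree of crowder centres. The reported
standard error of f is the **larger of the binomial SE and the between-box
SE** of per-box success fractions: trials within one box share that box's
configuration, so with few crowders per box the binomial term alone would
understate the uncertainty. When no trial succeeds the estimate reports a
one-sided lower bound on βΔμ (−ln of the 97.5% Wilson upper bound on f)
instead of infinity — the regime where only the theory below is usable.

**GFMT.** βΔμ is linear in (v_p, s_p, l_p) with coefficients taken from the
scaled-particle equation of state of the crowder fluid, such that for sphere
measures the prediction reduces *exactly* (to machine precision) to the SPT
insertion free energy −ln(1−φ) + 3qx + (3q + 4.5q²)x² +
φ(1+φ+φ²)/(1−φ)³x³ (q = φ/(1−φ), x = r/R_c). The constant −ln(1−φ) is the
Euler-characteristic term for one connected body; for the multi-component
structures only the tests construct, the geometric terms still dominate.
Published variants of the theory refine the quadratic coefficient against
simulations; the sphere-pinned form is adopted here because it is analytic
and internally testable, and the two routes agree within Monte Carlo error
at φ ≤ 0.2 on the fixtures tested.

## WHAM and crowding reweighting

Umbrella windows carry harmonic biases ½k(x − x₀)². The standard WHAM
fixed point is iterated on a grid of half-open bins (default 0.1 Å over
[min centre − 1 Å, max centre + 1 Å]); convergence is max|Δ ln P| < 1e-7
(max 10⁵ iterations; non-convergence raises with the residual). Empty bins
are dropped from the update and reported as NaN gaps, never interpolated.
Crowding reweights every sample by its insertion probability f: window
counts N_i and histogram entries n_i(x_j) become sums of f. If f depends on
x only, the crowded PMF is the dilute one shifted by βΔμ(x) plus a
constant — an identity the tests assert with synthetic weights. Bootstrap
errors resample within windows (block size 1; no autocorrelation
correction, appropriate for subsampled snapshots) and are deterministic per
seed. Barrier heights are the maximum of W between the two basin minima
minus the departing minimum; rate changes are quoted as
100·(e^|Δbarrier| − 1) percent, increase for a lowered barrier and decrease
for a raised one (the |factor − 1| convention reproduces both of the
worked rate numbers, 65% and 22%).

## Synthetic data

The generators produce every pipeline input with known ground truth:

- **Sphere clusters**: atoms tiling a shell (Fibonacci lattice at
  target − r_atom) plus a quasi-uniform interior fill. The probe surface
  sags between shell atoms by ≈ d²/2·(1/r_shell + 1/(r_atom + R_c)) for
  spacing d, so fixtures meant to match sphere closed forms tightly use
  denser shells (600 atoms, shell fraction 0.75 for a 10 Å target: ≤1%
  error in v_p).
- **Two-state toys**: two overlapping lobes; opening rigidly separates them
  (default 10 Å), per-conformation Gaussian jitter (default 0.5 Å) is the
  only within-state variation. Defaults produce 100 conformations per
  state with sub-1.5% relative SASA spread — the tight single-state
  ensembles the analysis expects. What the toys do *not* emulate: real
  protein topology, secondary structure, anisotropic flexibility, or
  force-field energetics; passing tests demonstrate the analysis machinery,
  not force-field realism.
- **Umbrella samples**: drawn exactly from the biased Boltzmann densities
  by inverse-CDF on a 4001-point grid (no MCMC), using the 32-window layout
  (centres 11.5–20.8 Å, 0.3 Å spacing, 5 kcal/mol/Å² default) and a quartic
  double well (minima 12.5/20 Å, 3 k_BT barrier) as the default truth.
  Adjacent windows sharing <1% density mass trigger a warning.

## Problem sizes and determinism

Tests and the acceptance script run end-to-end analyses at reduced scale
chosen for desk-side turnaround: toy pipelines use 2–3 conformations per
state and 100–200 atoms (the scan caches measures per conformation and
crowder radius, so the φ grid is free); insertion checks use 20 boxes ×
10⁵ trials; surface convergence uses one 600-atom fixture at two grid
spacings. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); reruns with the same configuration are
bit-identical.

## Known limitations

- Monodisperse spherical crowders only; no soft interactions, no
  polydispersity, no crowder–crowder attractions.
- GFMT coefficients are the sphere-pinned SPT forms (see above).
- The voxel surface is a controlled numerical approximation, not an
  analytic reduced-surface computation; accuracy is enforced against sphere
  oracles, and very coarse grids are refused rather than extrapolated.
- No MBAR estimator, 2-D PMFs, or autocorrelation-aware error analysis.
- PDB ensembles must be multi-model files (or directories); trajectory
  formats (DCD/XTC) are out of scope.
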