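# Methods

## The estimation problem

Ion leak through a mutated voltage-sensor domain (a gating-pore or
ω-current) is a rare event: the permeating ion must cross a free-energy
barrier of order 10 kT at the hydrophobic constriction, so unbiased
simulation of a single passage is hopeless at any reasonable cost.
Voronoi tessellated Markovian milestoning (VTMM) reconstructs both the
thermodynamics (the potential of mean force along the pore axis) and the
kinetics (mean first passage times, MFPTs) from many *short, confined*
simulations that each sample one cell of a partition of the reaction
coordinate, at a cost independent of the barrier height.

`vtmm` implements the full soft-wall VTMM estimator for a 1D reaction
coordinate, a Brownian-dynamics engine that generates the confined
per-cell trajectories on analytic model potentials, closed-form oracles
that independently predict what the estimator should recover, and the
trajectory observables used alongside such calculations (hydration
counts, density profiles, ion coordination, salt-bridge distances,
backbone RMSD).

## The milestoning model

The coordinate interval is partitioned into M Voronoi cells B_1..B_M with
centers z_1 < ... < z_M; in 1D the cell boundaries are the midpoints of
adjacent centers, and these M−1 internal edges are the *milestones*.
Each cell is sampled by a trajectory confined with half-harmonic walls

    V_wall(z) = k/2 (z − z_u)² for z > z_u,   k/2 (z − z_l)² for z < z_l,

(zero inside the cell; default k = 100 kcal/(mol·Å²)).  Trajectory
portions transiently outside the cell are excluded from the statistics.

Per cell α the tracker records:

* `N_ij^α` — the number of transitions i → j: milestone j is crossed while
  milestone i was the last crossed one;
* `R_i^α` — the in-cell time during which milestone i was the last crossed;
* `T_α`   — the total labelled in-cell time;
* the in-cell → out-of-cell crossing counts of each boundary and the total
  in-cell occupancy time (used for the balance equation, below).

Cell probabilities π_α solve the flux-balance equation Σ_β π_β k_βα =
π_α Σ_β k_αβ with attempted-crossing rates
k_αβ = (boundary crossings from α toward β)/(occupancy time of α),
normalized to Σ π = 1.  Cell free energies are F_α = −k_B T ln π_α
(k_B = 0.0019872 kcal/(mol·K); default T = 310 K).  Global milestone
statistics are the probability-weighted averages

    N_ij = Σ_α π_α N_ij^α / T_α,     R_i = Σ_α π_α R_i^α / T_α,

the rate matrix is q_ij = N_ij / R_i with generator diagonal
q_ii = −Σ_{j≠i} q_ij, and the MFPT vector to a target milestone K solves
Σ_j q_ij τ_j = −1 over the milestones with row/column K removed
(τ_K = 0).  The target may be either chain end, so both inward and
outward passages are available; the non-target end is reflecting by
default (single entry/exit permeation path), with additional absorbing
milestones available as an option.

### Numerical conventions and tie-breaks

* Crossing detection is a strict sign change of (z − edge) between
  consecutive samples; a sample landing exactly on an edge keeps the side
  it came from (measure-zero event, deterministic tie-break).
* A single step jumping across both cell edges counts only the final edge
  and emits a warning suggesting a smaller dt.
* Time before the first milestone crossing in a cell carries no label: it
  is excluded from R_i^α and T_α (a milestone must first have been "the
  last crossed") but included in the occupancy time that normalizes the
  boundary-crossing rates, which are defined from the start of sampling.
* Two time denominators therefore coexist deliberately: `T_α` (labelled
  in-cell time) normalizes the milestone statistics, `occupancy_time`
  (all in-cell time) normalizes the escape rates.
* Unsampled cells (π = 0) and never-visited milestones are reported as
  NaN/excluded with explicit warnings, never imputed.
* A disconnected cell graph raises an error listing the components; a
  milestone that cannot reach the MFPT target raises an error naming it.
* Convergence diagnostic: every scenario run splits each cell trajectory
  into halves and reports the max |ΔF| between the half-models and the
  relative MFPT change (defaults regarded as converged: 0.2 kcal/mol and
  20%).

### Known estimator biases (measured on this implementation)

* *Discrete-time transition undercount.*  With sign-change detection at
  sampling interval dt, a round trip i → j → i completed between two
  samples is invisible.  The resulting undercount of N_ij scales like
  sqrt(2 D dt)/(milestone spacing) — about 3–4% at the default
  dt = 0.001 ps, D = 0.1 Å²/ps and 0.4–0.5 Å cells — and biases MFPTs
  *up* by a similar few percent.  This is the standard cost of the
  deterministic detection rule; it vanishes as dt → 0.
* *Noise floor of the balance equation.*  Edge-crossing counts are
  strongly clustered (measured variance/mean ≈ 16 at default conditions),
  so each cell-pair probability ratio carries an error limited by the
  number of independent edge excursions, ~T·2D/L² per run.  ln π
  accumulates these errors as a random walk along the chain: with 20
  cells of 0.5 Å and 3×5·10⁵ steps per cell the typical peak-to-peak
  free-energy noise is ≈ 0.2 kcal/mol, shrinking as 1/sqrt(total
  sampling).
* *Convexity bias of the MFPT.*  τ is a convex functional of the noisy
  counts, so under-sampled runs overestimate it; the kinetic benchmark
  therefore uses 2·10⁶ steps per cell (per seed), at which the block
  convergence diagnostic is satisfied and the residual bias is within a
  few percent.

## The Brownian engine and what it stands for

The engine integrates overdamped Langevin (Euler–Maruyama) dynamics

    z ← z − (D/k_B T) V′(z) dt + sqrt(2 D dt) ξ,

with the soft-wall force added when confinement is set.  It is a 1D
diffusive model of the permeating ion's motion along the pore axis: a
deliberate stand-in for all-atom molecular dynamics that preserves
exactly the features the estimator consumes (diffusive barrier crossing,
equilibrium Boltzmann statistics, soft-wall confinement) and nothing
else.  Defaults: D = 0.1 Å²/ps, dt = 0.001 ps, T = 310 K.  The diffusion
coefficient of an ion in a protein lumen is not independently known here,
so synthetic MFPTs are meaningful as *ratios* between scenarios, not as
absolute times.  The flat-bottom lateral cylinder used in 3D simulations
is recorded as provenance metadata only; its entropic contribution is not
modelled in 1D.  Reflecting boundaries in unbiased runs use position
mirroring, which preserves the equilibrium density of overdamped
dynamics.

Model potentials are sums of Gaussians plus an optional harmonic term.
The shipped shapes are scenarios, not fits: `single_barrier` (default
peak 15 kcal/mol) emulates a wild-type-like profile dominated by one
hydrophobic constriction; `dual_barrier_with_well` (default main peak
8 kcal/mol, secondary peak and interposed well) emulates a mutant-like
profile; `double_well` and `harmonic` serve the thermodynamic tests.
Every factory calibrates its amplitudes by dense scan so that the stated
barrier equals max V − min V on the interval exactly.

## Oracles

Two independent references close the loop on the estimator:

* *Thermodynamic*: π_α ∝ ∫_cell e^{−V/k_B T} dz by dense trapezoid
  quadrature (grid-refinement verified), giving reference cell free
  energies.
* *Kinetic*: the closed-form 1D first-passage double integral
  τ = (1/D) ∫_start^abs e^{V(y)/kT} [∫_refl^y e^{−V(x)/kT} dx] dy,
  evaluated on a dense grid with one refinement step (relative tolerance
  10⁻⁴), plus brute-force unbiased first-passage sampling with censoring
  bookkeeping.

These are used only as cross-checks in tests and benchmarks, never inside
the estimator.

## Benchmark problem sizes

The validation benchmarks (also recomputed by `scripts/acceptance.py`)
run at desk scale, chosen so the whole set completes in minutes on one
core: 20 uniform cells over a 10 Å domain (0.5 Å cells, the same width
scale as a production 84×0.67 Å grid) — 8 Å domain for the kinetic
benchmark so that ≥200 brute-force replicas over a 2.5 kcal/mol barrier
remain affordable; 3 seeds × 5·10⁵ steps per cell for the profile
benchmarks, 3 × 2·10⁶ for the kinetic one; 50 randomized planted frames
for the structural counting checks.  At these sizes the flat-potential
free-energy spread sits at its statistical noise floor (~0.2 kcal/mol,
see above), the double-well profile matches quadrature within
0.3 kcal/mol, and the milestoning MFPT matches the double-integral oracle
within a few percent and brute force within two standard errors.

## Structural observables

These operate on labelled frames (atom name, residue, group tag ∈
{water, protein, lipid, ion}) read from multi-MODEL PDB or multi-frame
XYZ via MDAnalysis, with group tagging from configurable residue-name
tables.  Conventions: water is located by its oxygen atom; hydrogens are
identified by the leading character of the whitespace-normalized atom
name (PDB convention); intervals and balls are closed (distance equal to
the cutoff counts); minimum-image displacements are used when an
orthorhombic box is present.  The axial coordinate increases from the
extracellular to the intracellular side, and the hydrophobic-constriction
center must be supplied on the axis spec (it is defined structurally by
the V103/F137/V175 ring, whose axial position depends on the model at
hand).  The slab count uses an unbounded cross-section by default.  The
named-distance registry maps d1–d4 to the last side-chain carbons of the
salt-bridge partners (R207CZ–E130CD, Q204CD–E130CD, R210CZ–E140CD,
R213CZ–D172CG) and cd1–cd5 to Cα pairs on facing helices
(V99–D172, V103–V175, S110–V182, Y141–M211, I134–L203).  RMSD uses
least-squares rigid-body superposition (with a no-fit variant); a
degenerate-geometry fallback performs an explicit Kabsch fit.

The synthetic frame generator plants waters, coordination shells and
scaffolds with ground truth bookkept at construction time, so tests can
assert exact integers.  It emulates only the *geometry* of hydration and
coordination — planted positions with known memberships — not the physics
of water structure, hydrogen bonding or electrostatics; passing counts
therefore validate the counting operations, not any hydration model.

## Limitations

* 1D reaction coordinates only; no 2D/3D tessellations, no hard-wall
  (velocity-reflection) confinement, no MD-engine coupling.
* The engine is overdamped with constant D; no inertia, no
  position-dependent diffusion.
* Milestoning assumes the confined sampling has equilibrated within each
  cell; the block diagnostic flags, but cannot repair, unconverged cells.
* Absolute times from synthetic scenarios are not comparable to
  experiment without an independently calibrated D.
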