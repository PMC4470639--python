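# Methods

## Model overview

`tumorpotts` implements a two-dimensional Glazier–Graner–Hogeweg (GGH,
also called Cellular Potts) virtual-tissue model of early tumor growth and
somatic evolution.  Generalized cells are connected-or-not domains of
voxels sharing an index σ on a periodic square lattice; index 0 is the
Medium, a single unconstrained generalized cell standing in for stromal
tissue and ECM.  The effective energy is

    H = Σ_pairs −b(σ(x), σ(y)) + Σ_c λ_vol(v_c − V_c)² + Σ_c λ_sur(s_c − S_c)²

where the adhesion sum runs over unlike voxel pairs within the order-3
neighbor shell (squared distances 1, 2 and 4; 12 sites), and

    b(i, j) = Σ_{m,n} k_{m,n} · min(N_m^i, N_n^j)

is the binding energy per unit contact computed from adhesion-molecule
surface densities (cadherin, integrin, fibronectin).  Bond formation is
energetically favorable, so each unlike pair contributes −b to H; the
printed contact-energy sums in the source literature carry the opposite
sign, but only the negative convention reproduces the cell–Medium surface
tension γ = b(cell,cell)/2 − b(cell,Medium) that the model uses as its
cohesion/invasion diagnostic (γ > 0 cohesive, γ < 0 invasive).  With the
reference densities (Cad = Int = 8, Medium FN = 16, k_CadCad = 2.0,
k_IntFN = 0.2) this formula gives γ = 6.4; a value of "about 2.4" also
circulates for the same configuration and cannot be reproduced from the
formula — we report the formula value and do not guess at the discrepancy.

Dynamics are Metropolis voxel-copy attempts: a target voxel is drawn
uniformly, a source from its order-3 neighborhood, and the source index
overwrites the target with probability 1 if ΔH ≤ 0 and exp(−ΔH/T_m)
otherwise (T_m = 50).  One Monte Carlo step (MCS) is N attempts, N the
voxel count; matching simulated to observed tumor-cell migration speeds
(0.1 voxel/MCS against 4 µm/h, with 4 µm voxels) calibrates 1 MCS = 6 min.
Same-cell draws consume an attempt but are rejected without an energy
evaluation; whether they should consume an attempt is unspecified in the
source material, and this convention is fixed here.  Copies involving
Medium use the global T_m.  Cells may in principle fragment; no
connectivity constraint is imposed, only the density bounds that keep
fragmentation rare.

ΔH is evaluated from local terms only (the 12 contact pairs of the target
voxel, the volume terms of the two cells, and the surface terms of the two
cells plus the owners of the four first-order neighbors), and volume,
surface and center of mass are maintained incrementally.  The surface of a
cell is the count of directed first-order links to unlike voxels.  Centers
of mass are kept in unwrapped coordinates — every added or removed voxel
is taken at its periodic image nearest the cell's current center — so the
center never jumps when a cell crosses the boundary; coordinates are
wrapped only for output.  All incremental quantities are verified against
full lattice recounts in the test suite (exact for volume and surface, to
float round-off for centers of mass).

## Glucose transport

Glucose G (fmol/voxel) is the single growth-limiting resource, solved to
steady state on the lattice:

    0 = D_G ∇²G − εG + α·[Medium] − u_max G/(G+K)·[living tumor voxel]

with D_G = 13500 voxel²/MCS (600 µm²/s), decay ε = 0.45 /MCS applied at
every voxel, Medium secretion α = 0.145 fmol/voxel/MCS, and
Michaelis–Menten uptake u_max = 2.25 (proliferating) or 1.69 (quiescent)
fmol/voxel/MCS with K = 0.00256 fmol/voxel (0.04 mM).  Tumor-free stroma
equilibrates at α/ε = 0.322 ≈ 0.32 fmol/voxel (5 mM).  Applying decay
globally (rather than in Medium only) follows the solver configuration
that produced the published results rather than the continuum equation,
which names ε only in Medium; the difference inside tumor voxels is small
against the MM uptake.  The field is re-solved every 10 MCS and held
frozen in between.

Numerics: the discrete nonlinear system is solved by damped projected
Newton iteration — backtracking line search with an Armijo-style
sufficient-decrease test, iterates projected to G ≥ 0 (outside which the
MM term degenerates) — with a sparse LU factorization of the Jacobian.
The factorization is cached across re-solves and reused quasi-Newton
style, rebuilt only when the residual contraction stalls below a factor
of 4 per step; this makes the in-loop re-solve ~20× cheaper than a full
Newton solve, since the tumor moves only slightly between solves.  Simple
relaxation sweeps were tried first and stall badly: the uptake derivative
u_max·K/(G+K)² approaches u_max/K ≈ 880 /MCS in depleted regions, making
the problem far too stiff for Jacobi/Gauss–Seidel iteration.  Convergence
is declared at max-norm residual below 10⁻⁶ of the source scale; the
solver raises with the residual if 50 damped Newton steps do not converge.

## Cell states, growth, division and mutation

Each living tumor cell accrues, once per MCS, either starvation damage or
health from the glucose concentration at the voxel containing its wrapped
center of mass, through the saturating rate M(x) = m·x/(x+k) (m the
cell's own u_max, k = K): damage |M(G) − M(x_thresh)| when G < x_thresh,
health M(G) − M(x_thresh) otherwise.  The starvation threshold x_thresh
defaults to 0.032 fmol/voxel (0.5 mM × 0.064 fmol/voxel per mM, the
self-consistent calibration); the reference table also prints 0.0032,
available as a config override (`GluD`).  Transitions use strict
inequalities and reset health: PCancer necroses above 102, QCancer above
204, PStem above 408, QStem above 916 units of damage; quiescent cells
whose health passes 79.5 return to proliferation.  Necrosis is
irreversible.  At zero glucose a PCancer cell therefore dies after
ceil(102 / 2.083) = 49 MCS; the "24 hours of starvation" gloss sometimes
attached to that threshold is not self-consistent with the 6-min MCS and
is not enforced here — thresholds are taken verbatim.

Proliferating cells grow their target volume by 0.2·max(0, G − 0.032) per
MCS, with target surface following S = 4√V (slightly above the circular
2√(πV), permitting mildly elongated shapes).  Quiescent cells neither grow
nor shrink.  Necrotic cells lose min(0.01, V) of target volume per MCS
(the 0.01 table value; a 0.05 figure appears in prose and is available by
config) and are retired when neighbors overwrite their last voxel.

A cell whose actual volume exceeds its doubling volume (32 voxels;
quiescent cells caught past it divide too) is split along a line through
its center of mass at a uniformly random angle: voxels are ordered by
signed distance to the line and the upper half becomes a new cell, so the
parts always differ by at most one voxel.  Both products reset V = 16,
S = 16, λ_vol = 15, λ_sur = 5 and both clocks.  Non-stem products senesce
against a fresh draw R ~ N(8, 2): the pair becomes quiescent (counters
advancing, the daughter copying the parent's incremented count) while the
counter is ≤ R, and both necrose once it exceeds R.  A stem parent
re-enters quiescence; its daughter is a stem cell with probability 0.2
(counter reset to zero) and a non-stem cancer cell otherwise.  Finally,
independently for cadherin and integrin, the parent's expression level
mutates with probability 0.1 by a Gaussian step of s.d. 2.0, *rejected*
(not clamped) outside [0, 16] so no probability mass piles at the ends;
the daughter inherits the final levels exactly.  In the absence of
selection this mutation scheme drifts the population mean toward the
interval midpoint 8, which is why initial levels are set at 8.

## Schedule and reproducibility

Each MCS executes: Monte Carlo step → glucose re-solve (every 10 MCS) →
after the 50-MCS initial relaxation window: accumulation → transitions →
growth/shrinkage → mitosis (two-phase: all candidates collected, then
divided, so one division cannot trigger another within the same MCS) →
snapshot (every `snapshot_interval` MCS).  The source material lists these
components in this order without fixing a schedule; the order is fixed
here as part of the contract.  The relaxation window (`MCSThr`) is
interpreted as "no biology before MCS 50", the only reading consistent
with its name; the source never defines it.  All randomness flows through
one seeded generator in a fixed call order, so (config, seed) determines
every output byte.

The initial condition is a single 3×3-voxel quiescent stem cell at the
lattice center (the configuration actually shipped with the published
model); an 8×8 variant mentioned in prose is available via
`initial_cell_size: 8`.

## Analysis layer

Snapshots (one row per living cell: id, type, volume, surface, cadherin,
integrin, wrapped center of mass) are written every 1000 MCS (reference)
as one CSV per run with `#`-comment metadata (seed, config hash).  All
metrics are pure functions of snapshots.  The cluster census defines a
cluster as a single-linkage connected component of the ≤6-voxel
center-of-mass distance graph with at least 5 members — the literal
reading of "at most 6 voxels from their nearest cluster-mate" — with
groups of 2–4 as transient associations and lone cells as singletons; a
DBSCAN-parameterized mode (eps = 6, min_samples = 5) is provided behind a
flag because the two definitions differ on chain-like sets and the
published analysis names DBSCAN without stating its core-point semantics.
Periodic distances use the minimal-image convention.  Lifetimes and travel
distances bin each cell by the type it had at first appearance; travel
sums minimal-image displacements between consecutive snapshots.  Replica
ensembles are summarized as min/median/max envelopes per time point.
"First invasion" is the first snapshot in which the census finds at least
one cluster and at least one living tumor cell outside every cluster (by
single linkage such a cell is more than 6 voxels from every cluster
member).

## Problem sizes, what the scaled runs show, and limitations

The reference configuration (500×500 lattice, 10⁶ MCS ≈ 11 simulated
years) reproduces the published regime: a compact tumor capped near
500 µm by the glucose supply, central necrosis, and — over simulated
years — evolution toward low-cadherin, high-integrin invasive phenotypes.
Test and acceptance runs use scaled profiles (`smoke`: 50×50, 500 MCS;
`desk`: 100×100, 5000 MCS default, longer horizons where stated) that keep
every rate constant and shrink only the lattice and duration.

Scaling down changes the biology in a way worth stating precisely.  The
glucose screening length inside a tumor mass, √(D_G/(u_max/(G+K))) ≈ 44
voxels, is a property of the rate constants and does not shrink with the
lattice.  A 100×100 lattice supports a supply-limited population of only
~30–40 cells (tumor radius ~13 voxels), so interior voxels never fall
below the starvation threshold: necrosis at desk scale comes from
senescence, not starvation, and the survival-stratification selection
pressure on cadherin is weak relative to the genetic drift of a ~30-cell
population.  Desk-scale replicas accordingly show the early qualitative
sequence — activation of the seeded stem cell, growth to the
supply-limited size, emergence of necrotic cells inside the cluster,
boundary-biased division with cell sorting — and a weak, fluctuating
downward pressure on cadherin, but they do not reliably reach the
negative-surface-tension invasive regime within accessible run lengths;
in a 300,000-MCS desk replica the mean cadherin level wandered between
6.3 and 8.5 without crossing into invasiveness.  Starvation-driven
stratification requires tumor radii beyond the 44-voxel screening length,
i.e. populations of several hundred cells (lattices ≳ 300×300).  The
acceptance suite therefore checks the emergent-behavior clauses that the
desk scale can express and documents this scale threshold; single-cell
detachment events ("first invasion") do occur at desk scale and their
timing is used for the mutation-parameter trend check.

The emergent-behavior checks run five desk replicas (seeds 1–5) to
30,000 MCS each; the mutation-parameter trend check runs a
{P_m = 0.1, 0.3} × {δ_am = 0.5, 2.0} grid with three replicas per cell on
the desk profile, capped at 36,000 MCS, with never-invading replicas
censored at the cap (replicas at δ_am = 0.5 typically remain cohesive for
the whole horizon, which matches the published behavior of that corner of
parameter space).  These sizes are the package's chosen trade-off between
statistical resolution and a test suite that completes in minutes.

Other limitations: the model is 2D with a single implicit stromal
compartment (no explicit ECM fibers, vasculature or angiogenesis, no
oxygen/pH fields); the stem-daughter fraction is fixed, not evolvable;
fibronectin does not mutate; and snapshot-based metrics cannot resolve
events faster than the snapshot interval.
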