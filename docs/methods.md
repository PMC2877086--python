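# Methods

`gghtumor` simulates a single-phenotype avascular tumor growing in a
homogeneous tissue matrix (TM) with one limiting nutrient, using the
Glazier–Graner–Hogeweg (GGH / Cellular Potts) model, and quantifies the
resulting morphologies. This note records the model, the numerical choices,
and the places where the design was genuinely open.

## Model

**Cell lattice.** Space is a cubic lattice of `L³` voxels (default
`L = 100`, voxel = 60 µm, so the domain is 6 mm per side). Every voxel
carries the index σ(x) of the Generalized Cell occupying it. Tumor cells are
spatially extended domains (initially 3×3×3 voxels); the entire TM is one
additional unconstrained Generalized Cell (reserved id 1; index 0 is never
used, which avoids the ambiguity of "medium = 0" conventions in other CPM
codes).

**Effective energy.**

    H = Σ_pairs J(τ,τ′) + Σ_cells λ_V (V − V_t)² + Σ_cells λ_S (S − S_t)²

The contact sum runs over unordered voxel pairs within the fourth-order
neighborhood (32 neighbors per voxel, which reduces lattice anisotropy) that
straddle a cell boundary. The constraint sums skip the TM cell. The surface
S entering the λ_S term is counted as the number of face-adjacent voxel
pairs spanning the cell's boundary — the cheapest estimator that updates
incrementally in O(1) per copy; the choice is recorded here because the
energy landscape (and hence bit-level trajectories) depends on it.

**Dynamics.** Metropolis copy attempts: a uniformly random *target* site x
adopts the index of a uniformly random fourth-order neighbor (a cell
"extends its boundary" into x), with acceptance probability 1 if ΔH ≤ 0 and
exp(−ΔH/T_m) otherwise. One Monte Carlo Step (MCS) = L³ attempts;
out-of-domain neighbor picks and same-cell picks are no-op attempts that
still count toward the budget, keeping the MCS definition exact. 400 MCS
correspond to one day. ΔH is evaluated locally and is tested to equal the
global energy difference to 10⁻⁹.

**Fields.** Three scalar fields co-occupy space with the cells, all
normalized to [0, 1]:

* TM density `f` (nondiffusing), degraded by MDE: ∂f/∂t = −δ m f.
* Matrix-degrading enzyme `m`: ∂m/∂t = D_m ∇²m, plus point production μ at
  each living tumor cell's center of mass once per MCS, capped at 1.
* Substrate `c`: ∂c/∂t = D_c ∇²c + S_prod · f · (1−c) Θ(1−c), plus point
  uptake k at each living tumor cell's center-of-mass voxel once per MCS,
  clamped at 0. The Heaviside factor saturates production at c = 1.

Production and consumption are defined *per Generalized Cell* and applied at
the nearest voxel to the real-valued center of mass (ties rounded toward
−∞); if a non-convex cell's center of mass falls outside the cell, the point
terms are still applied there.

**Biology.** A proliferating cell's target volume grows with the local
substrate, V_t ← V_t + g·c(com) per MCS; there is no growth threshold, so
cells deep in the tumor (where c ≈ 0) simply barely grow — implicit
quiescence. The target surface tracks S_t = 6·V_t^(2/3) (anchored by the
initial cube: V_t = 27 → S_t = 54), keeping cells roughly spherical. At the
doubling volume V_d = 54 the cell splits along a plane through its center of
mass with uniformly random orientation (uniform on the sphere, not
axis-restricted, to avoid lattice bias); both daughters inherit the
phenotype and half the parent's V_t. Optional rules studied separately:
reversible quiescence and irreversible necrosis (shrinking at g_necrotic
until removal), both triggered by c(com) < c_threshold.

**Diffusion limitation.** The single control parameter is
G = 0.05 · k L²/D_c, the ratio of the maximum tumor consumption rate to the
maximum substrate transport rate. G is varied through k: with the default
D_c, the per-cell consumption rates k = 0.05…0.2 map onto G = 50…200, the
range that spans all morphologies — compact spheroids at G ≈ 50, fingered
(invasive) growth at G ≈ 150–200, modulated by the tumor–TM surface tension
γ = J(t,TM) − J(t,t)/2 ∈ [0, 6] (varied through J(t,t) = 16…4 at
J(t,TM) = 8).

## Parameters

| parameter | symbol | default | units | origin |
|---|---|---|---|---|
| lattice size | L | 100 | voxels | study conditions (6 mm domain) |
| tumor–TM contact energy | J(t,TM) | 8 | energy/area | study conditions |
| tumor–tumor contact energy | J(t,t) | 4–16 | energy/area | sets γ = 6…0 |
| motility | T_m | 60 | energy | study conditions |
| inverse compressibility | λ_V | 20 | energy/vox² | study conditions |
| inverse membrane elasticity | λ_S | 0.4 | energy/area² | study conditions |
| doubling volume | V_d | 54 | voxels | 2 × initial cell volume |
| shape constant | — | 6 | — | S_t/V_t^(2/3) of the initial cube |
| growth rate | g | 0.25 | vox/MCS per unit c | calibrated, see below |
| substrate diffusion | D_c | 0.5 | vox²/MCS | calibrated, see below |
| MDE diffusion | D_m | 0.01 | vox²/MCS | "very slow" MDE transport |
| TM degradation | δ | 0.5 | 1/MCS per unit m | strong degradation |
| MDE production | μ | 1 | conc/MCS per cell | saturates m under tumor |
| substrate production | S_prod | 0.1 | conc/MCS per unit f | keeps c→1 far away |
| consumption | k | 0.05–0.2 | conc/MCS per cell | sets G = 50–200 |

Two constants are not pinned directly by the study conditions and were
fixed once by closed-form reasoning against the regime anchors, before any
simulation was scored:

* **g = 0.25.** In the growth-limited regime (G = 50) the reference timing
  adopted for this model is ~2 days = 800 MCS from 8 to 1000 cells, i.e. ≈7 doublings of ≈115 MCS.
  One doubling adds 27 voxels of target volume at c ≈ 1, giving
  g ≈ 27/115 ≈ 0.25.
* **D_c = 0.5.** With point uptake k per cell, the substrate penetration
  depth into a tumor of per-voxel cell density 1/V_cell is
  ℓ = √(D_c·V_cell/k). The study regime requires ℓ ≈ a few cell diameters
  (7–10 voxels) at k = 0.2 and ℓ comparable to the 1000-cell tumor radius
  (~20 voxels) at k = 0.05; both pin D_c ≈ 0.5. Larger values (e.g. D_c on
  the order of 10) make substrate transport so fast that no diffusion
  limitation appears anywhere in the k range — G would then not be the
  morphology control it is supposed to be.

## Numerics

* **Field integration.** Forward Euler with the 7-point Laplacian.
  No-flux boundaries are realized by mirror ghosts (edge-clamped indexing),
  which makes the diffusion step conserve mass exactly (tested to 1e-10
  relative). Each field advances through the smallest substep count n with
  D/n ≤ 0.8/6 (3D stability bound with a 0.8 safety factor): 4 substeps/MCS
  for the substrate at D_c = 0.5, 1 for MDE. Within one MCS the substrate
  sees the TM density frozen (operator splitting); all updates read
  start-of-substep values. Clamping order: diffusion → production → clamp
  to [0,1]; point consumption → clamp at 0.
* **Update order per MCS** (fixed, since the interleaving is a free choice):
  Metropolis sweep → field substeps + point secretion/uptake → growth →
  mitosis → phenotype transitions → removal of emptied cells.
* **RNG.** Copy attempts draw from one seeded generator (numba's global
  stream); division axes draw from a separate seeded generator so the two
  streams do not interact. Runs are bit-reproducible for a fixed seed.
  Attempt sites are drawn with replacement and are not restricted to
  boundary sites.
* **Incremental bookkeeping.** Volume, face-count surface, center-of-mass
  sums and bounding boxes are updated in O(1) per accepted copy; an audit
  recomputes everything from the lattice and must agree exactly (run at
  every snapshot; any mismatch aborts the run).
* **Division edge cases.** A drawn plane that leaves one daughter empty is
  redrawn (≤10 times), then the coordinate axis of largest extent is used;
  a cell whose last voxel is overwritten by neighbors is unregistered.

## Morphometrics

Sphericity s = π^(1/3)(6V)^(2/3)/A and circularity c = 4πA/P², both on the
union of all tumor components (the sections of fingered tumors are visibly
disconnected, so union is the consistent reading); per-plane component
counts are also reported. Mean circularity c̄ averages the three mid-plane
sections (plane index ⌊L/2⌋ — stated explicitly since L = 100 has no exact
center plane). Components: 26-connectivity in 3D, 8-connectivity in 2D.
Censored quantities (tumors that never reach the boundary or the cell
target) are reported as explicit censored values, never as 0.

Surface/perimeter estimators (configurable, recorded in every output):

* `mesh` (default) — marching cubes/squares at level 0.5 on the binary
  occupancy. It carries the classic staircase bias (a digitized ball reads
  s ≈ 0.92) but measures the voxel-scale roughness of CPM surfaces at face
  value, and it is the estimator under the phase-diagram tables: with it the
  growth-limited full-scale run reads s(1000 cells) ≈ 0.75.
* `mesh_aa` — the mask is 2× upsampled (linear) and pre-smoothed with a
  small Gaussian (σ = 0.7 in 3D, 0.8 in 2D, calibrated per dimension)
  before contouring, with a floor that keeps every occupied voxel inside
  the iso-surface so thin fingers cannot drop out of the mesh. Digitized
  balls/disks then read within 3% of 1 and an a = 32 cube within 2% of
  (π/6)^(1/3). Use it when the absolute compactness of a smooth object
  matters.
* `face` — exposed-voxel-face counting; biased by up to ~50% and kept only
  as a diagnostic.

The characteristic time τ of fingering is the time constant of a
least-squares fit s(t) = s₀·exp(−(t/τ)²) to the sphericity series ("quasi-
Gaussian" decay; two free constants). Series that do not decay within the
observation window leave τ unidentified and are flagged as non-converged
with τ = ∞ rather than silently reported.

## Study profiles and problem sizes

* `full_profile` — L = 100, the full-scale conditions above.
* `reduced_profile` — L = 50 with D_c scaled to 0.125 so that both the G
  grid *and* the per-cell consumption rates k = 0.05…0.2 are unchanged; the
  same 8-cell seed block is used (cells cannot be scaled below the
  27-voxel/54-voxel doubling structure). This is the default test profile.

The test suite exercises the morphology trends on the reduced profile at a
fixed 500-cell stage (three seeds per phase-diagram cell), and the
growth-limited column quantitatively at full scale (three seeds, 1000-cell
stage). The long diffusion-limited full-scale cells (boundary-reach times up
to 100 days ≈ 40 000 MCS) are reachable through `run_sweep` /
`gghtumor sweep`, which tabulates every phase-diagram quantity (s and c̄ at
boundary, s at 1000 cells, days to boundary and to 1000 cells, τ) with
per-combination means, standard deviations and explicit censoring.

## What the synthetic fixtures do and do not show

The fixture generator produces digitized balls, cubes, ellipsoids, ball
pairs and a U-shaped tube with known continuum metrics. They calibrate the
estimators and the connectivity logic (including the geometric artifact
that 2D sections of a connected 3D object can be disconnected), but they are
deterministic geometry: they say nothing about the stochastic dynamics,
which are validated by the trend and regime tests above.

## Known limitations

* Cubic-lattice anisotropy can imprint on high-surface-tension dendrites;
  no hexagonal/FCC cross-check is implemented.
* A single tumor phenotype; no haptotaxis, no explicit mechanical
  confinement by normal tissue, no vasculature.
* The field constants not pinned directly by the study conditions were
  reconstructed from regime anchors (see Parameters); absolute times and
  morphologies at intermediate G inherit that uncertainty, though the
  dimensionless control G and the k↔G correspondence are preserved.
* The quiescence/necrosis rules are unit-tested at the level of their
  mechanics (threshold transitions, reversibility vs irreversibility,
  shrink-out and removal) but their effect on whole-tumor morphology is not
  benchmarked by the test suite.
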