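# Methods

## Scope and model

`mesopolar` simulates reaction-diffusion kinetics on a 2D periodic square
membrane with two stochastic engines that share one model description
(`ModelSpec`):

* a **mesoscopic engine** (`mesopolar.rdme`): the reaction-diffusion master
  equation (RDME) sampled exactly with the Next Subvolume Method (NSM);
* a **microscopic engine** (`mesopolar.particles`): Brownian dynamics of
  point particles with λ-ρ bimolecular reactions, used as ground truth.

Membrane and cytosol are *coincident* 2D domains; a species' compartment
affects only its diffusion coefficient (cytosolic D ≫ membrane D).  Units
are μm, s, molecules throughout.

The headline content is the treatment of diffusion-limited bimolecular
reactions on a grid: voxel propensities `k_meso·n_A·n_B/h²` use either

* `naive`: `k_meso = k_micro`, correct only in the reaction limit;
* `k_h` (scale-dependent): chosen so that the mean association time of an
  isolated pair on the grid reproduces the microscopic two-molecule result
  `τ_micro(R) = (πR²/k_micro)(1 + α F(ρ/R))`, `α = k_micro/(2πD)`,
  `F(ν) = ln(1/ν)/(1−ν²)² − (3−ν²)/(4(1−ν²))`, matched against the
  mesoscopic pair time
  `τ_meso = L²/(2πD)·ln(L/h) + 0.1951·L²/(4D) + L²/k_meso`.  This gives
  `k_h = k_micro[1 + (k_micro/D)G]⁻¹` with
  `G = ln(h/(√π ρ))/(2π) − (3/(2π) + 0.1951)/4`, defined only above
  `h_min = √π·exp[(3+2·0.1951·π)/4 − 2πD/k_micro]·ρ` (≈ 4.5–5ρ for strongly
  diffusion-limited reactions);
* `k_c` (concentration-dependent): the pair problem is solved in the local
  mean free area `A_c = h²/max(n_A, n_B)` instead of the whole domain,
  giving an occupancy-dependent rate
  `k_c(n) = k_micro[1 + α F(ρ/R_c)]⁻¹`, `R_c = h/√(πn)`, capped at
  `k_micro` once `R_c ≤ ρ`.  It is precomputed into a lookup table up to the
  cap occupancy `⌈h²/(πρ²)⌉` and read per event.

Reversible associations scale their dissociation rate by the same factor,
`k_meso^d = k_micro^d·k_meso/k_micro`, which preserves the two-molecule
equilibrium exactly (the single-pair stationary bound fraction on a grid of
V voxels is `q/(q+V)` with `q = k_micro/(h²·k_micro^d)` in *every* rate
mode; the test suite checks the simulated value against this closed form).
As `k_micro → 0` the scale factor tends to 1, so a dissociation whose
forward reaction is switched off (e.g. complex formation disabled in a
parameter sweep) keeps its microscopic rate.

### Choices the derivation leaves open

* The `k_h` construction identity `τ_meso(k_h) = τ_micro` holds exactly for
  the small-ν form `F(ν) ≈ ln(1/ν) − 3/4`; with the full `F` the residual is
  O(ν² ln ν) (ν = √π ρ/L, relative ~10⁻³–10⁻⁴ at the scales used here).
  `tau_micro` implements the full formula; `tau_micro_small_nu` is exposed
  so the identity can be asserted to machine precision.
* In `k_c` mode the occupancy at which an occupancy-dependent dissociation
  rate is evaluated is not uniquely defined; we use
  `max(n_A, n_B, 1)` of the forward reaction's reactants in the complex's
  voxel at propensity-update time, so an isolated complex dissociates at the
  two-molecule (n = 1) rate.  This is an interpretation, flagged here.
* Natural logarithms everywhere; the constant 0.1951 is the square-torus
  first-passage constant.

## NSM implementation

State is `counts[species, voxel]`.  Each voxel keeps its next-event time in
an indexed binary min-heap whose keys are stored in the heap slots (better
memory locality than indirecting through a per-voxel array).  Channels
within a voxel are [diffusion per species | unimolecular | bimolecular];
the event channel is drawn proportionally to channel propensities.  After
an event only the channels that depend on the changed species are
recomputed (the species→channel incidence lists are precomputed), the
voxel's propensity sum is updated incrementally, the fired voxel redraws a
fresh exponential waiting time, and a diffusion target voxel's pending time
is rescaled by the old/new propensity ratio (the standard NSM update).
Diffusion propensity is `4nD/h²` (n·D/h² per neighbour); a bimolecular
event consumes both reactants from one voxel and places products in it.
The kernels are numba-compiled; the polarity-scale workload (~1.5×10⁷
events per simulated second) sustains ≳10⁶ events/s on one core.

RNG: numba's global MT19937 seeded once per realization; ensembles derive
independent 31-bit child seeds from one base seed via `SeedSequence`.
Identical seed + configuration reproduces a trajectory bit-for-bit.

Snapshots record voxel counts; "pseudo-coordinates" for analysis or display
are sampled uniformly within each molecule's voxel, so grid and particle
output share one analysis code path.  They are presentation-level only.

## Particle engine

Fixed-step scheme: Euler-Maruyama displacement `Z√(2DΔt)` per coordinate
with periodic wrap; first-order reactions per molecule with
`P = 1−exp(−kΔt)`; bimolecular attempts for every reactant pair within ρ
with `P = 1−exp(−λΔt)`, `λ = k_micro/(πρ²)`.  Pair candidates come from a
linked cell list (all-pairs scan for ≤64 molecules; the two are verified
equivalent in tests); the candidate list is shuffled and processed
sequentially, each molecule reacting at most once per step.  Operator order
within a step is diffuse → unimolecular → bimolecular; neither the conflict
resolution nor this ordering is prescribed by the scheme itself — both are
explicit choices, guarded by a Δt-halving convergence test.  Dissociation
places one product at the complex position and the other at ρ+ε
(ε = 10⁻³ρ by default) in a uniformly random direction, so the fresh pair
is not reaction-eligible on the next step.  Default steps:
`Δt = (0.1ρ)²/(4D_tot)` for benchmarks, `Δt = ρ²/(4D_cyto)` for polarity
runs.

Two documented accuracy limits of this microscopic scheme (both inherent to
the scheme, not bugs, and visible in the tests):

* the λ-ρ ↔ contact-rate identification `k_micro = λπρ²` is exact only in
  the reaction limit; in the strongly diffusion-limited benchmark regime
  (λπρ²/D_tot = 50) the pair mean association time runs ~5–10% above the
  Smoluchowski closed form, and the gap persists as Δt → 0;
* placing dissociation products at ρ+ε (outside the reactive disc) breaks
  microscopic reversibility, so for strongly diffusion-limited *reversible*
  reactions the particle stationary bound fraction sits below the
  detailed-balance value that the mesoscopic `k^d` construction preserves
  exactly (about 2× at the benchmark parameters).  Irreversible benchmarks
  and the polarity model (whose association/dissociation cycle is not a
  simple reversible pair) are unaffected.

## Polarity model

Seven reactions couple GEF and Cdc42 membrane/cytosol shuttling, GEF- and
complex-catalyzed activation, complex formation (membrane and cytosolic GEF
routes) and, in the *updated* model, direct recruitment/activation of
cytosolic Cdc42D by the complex.  Parameters default to the 2D microscopic
table (total Cdc42 = 5000; GEF 15–700; ρ = 0.02 μm; D_cyto = 10,
D_memb = 0.0045 μm²/s; domain 8×8 μm).  `k_4a` has no single tabulated
value (it is swept over 0–2 μm²/s) and must be given explicitly; the named
scenarios pin `k_4a = 2 μm²/s`.  The 2D↔3D conversions multiply every
reaction in which a cytosolic species binds the membrane by `V_c/A_m` and
leave membrane-confined reactions unchanged; geometry constants satisfy
`V_m = A_m·Δz` and `η = V_m/V_c` by construction.

Tagged ("washout") species for dwell-time measurements are generated
mechanically: every membrane species carrying the tagged molecular unit
gets a twin with identical kinetics; reactions are expanded over tag
combinations with tags propagated along per-product source-reactant maps;
cytosolic products are always untagged (detachment erases the tag).  This
keeps tagged and untagged kinetics provably identical and conservation
exact.

## Analysis

* `H(r) = √(A/π·∫₀ʳP) − r` from the pairwise-distance density `P(r)`
  (minimum-image distances, default bin 0.05 μm, r ≤ L/2).  Zero in
  expectation for uniform patterns; the maximum marks the cluster scale.
  `H(r = 1.1 μm)` of active Cdc42 (Cdc42T + Cdc42T-GEF) is the polarization
  metric.
* Patch centroid via per-axis circular means (the unambiguous toroidal
  choice); tracks sampled every 1 min, unwrapped with minimum-image steps,
  broken at jumps > 6 μm.  MSD pools all interval pairs over
  sub-trajectories; `MSD(1 min)` (within-patch jitter) is subtracted by
  default before the log-log fit `log MSD = log(4D_patch) + β log Δt` over
  a default Δt window of 2–10 min (configurable; the window stands in for
  the by-eye "initial linear range").  Note: applied to a noise-free β = 1
  walk the baseline subtraction provably biases the fitted slope upward
  (`log(4D(Δt−1))` vs `log Δt` has slope ≈ 1.2 on that window), so the
  synthetic parameter-recovery tests run with subtraction disabled; on real
  patch tracks the 1-min MSD is dominated by intra-patch jitter, which is
  what the subtraction is for.
* `CV_patch`: per-location temporal SD/mean of local active-Cdc42 counts
  (1 s sampling over 1 min), averaged over locations with abundance
  weights.  SD/mean is the conventional CV; for independent Poisson counts
  with mean μ the statistic tends to 1/√μ.
* Dwell times: run to steady state, convert the membrane species carrying
  the unit of interest into tagged twins inside a disc around the patch
  centroid (default radius: argmax of H(r)), record the tagged totals and
  fit a single exponential on a window that skips the initial fast
  transient (membrane detachment of inactive Cdc42).  The fitted rate is
  checked in tests against the slowest eigenvalue of the tagged-state
  Markov generator on models where that is computable.
* Polarization time: earliest time after which the ensemble SD of
  H(1.1 μm) stays within ±10% (configurable) of its mean over the final
  minute — a concrete estimator for "the moment the SD stabilizes".

## Synthetic data in the tests, and what passing shows

Test fixtures are generated programmatically: uniform and Gaussian point
patterns, exact fractional-Brownian centroid tracks (Cholesky of the fGn
covariance; β ∈ {0.85, 1}), Poisson count fields, and the built-in
benchmark scenarios (association at λπρ²/D_tot = 50, A=B=5 low-density and
a 1000-molecule/0.45-μm high-density variant scaled from the 5000-molecule
benchmark at equal density, chosen so the full suite runs on one core in
minutes).  Oracles are closed forms (τ_micro, detailed-balance equilibria,
two-state Markov fractions, Poisson CV, fGn exponents), brute-force scans
(all-pairs neighbour search, O(N²) histograms), exact CTMC stationary
solves on tiny grids, and the well-mixed CME.  These validate the engines'
*statistical exactness* and the analysis pipeline's *estimator
correctness*; they do not probe biological realism (no GDI kinetics, no
explicit GAPs, no membrane geometry beyond the flat torus) nor the
hour-scale patch-mobility regimes, which need ensembles of 50×1 h runs at
~2×10⁷ events per simulated second — supported by the engines but outside
the default test scale.  Desk-scale polarity checks use a single short run
(tens of seconds) of the full-size model: long enough for activation and
visible clustering of active Cdc42, far short of the ~130–240 s
polarization plateau.

## Numerical and degenerate-input choices

* Voxel-size validation: L/h must be integral (relative tolerance 1e-9);
  `k_h` mode refuses h < h_min with the bound reported in μm and multiples
  of ρ.
* Propensity sums are maintained incrementally in float64 (drift ≲1e-7
  relative over 10⁹ events) and a full re-sum guards against a negative
  total; non-finite propensities abort with a diagnostic.
* Empty active-Cdc42 snapshots yield NaN metrics (flagged, not fatal);
  centroids of patterns with no directional concentration raise.
* MSD fits require ≥3 usable points after baseline subtraction; dwell fits
  reject non-decaying series (tagging leak).
* A+A bimolecular reactions and >2-reactant stoichiometries are rejected at
  model validation (the supported networks never need them).

## Known limitations

* 2D periodic square domains only; no 3D RDME, no spherical-surface
  simulation (only the 2D→3D parameter conversions are provided).
* The particle engine's reversible-reaction equilibrium carries the ρ+ε
  placement bias discussed above.
* `k_c` slightly under-reacts at very low occupancy in reversible settings
  (the n = 1 confinement area overestimates the rebinding time when the
  true partner is the only molecule in the domain); accuracy improves with
  finer grids, which `k_c` — unlike `k_h` — admits.
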