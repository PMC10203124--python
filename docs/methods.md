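# Methods

## Model and assumptions

One grid square is modelled as an L×L membrane whose perimeter — the metal
grid bars — is clamped at the cryostage temperature T₀ = 77 K.  The bars are
treated as ideal isothermal heat sinks: their metal (copper, gold, nickel)
never enters the model, which is consistent with the equal measured
thresholds for copper- and gold-bar grids of identical film.  Convective
cooling by the cold nitrogen gas is neglected against in-plane conduction.
Absorbed excitation light is a distributed heat source q(x,y)·α, where
q is the local illumination power density (W/cm²) landing on film (beam
intensity × film-presence mask) and α lumps the film's absorptivity A over
its conductance c, with film thickness absorbed into c.  α (units
K·µm⁻²·(W/cm²)⁻¹) is the model's only free thermal parameter; A and c are
not separately identifiable from threshold measurements, so α is always
calibrated, never assembled from handbook values.  The model is
deliberately qualitative: it captures the geometry scalings (1/L², 1/η_c)
and the boundary-sink structure, not absolute material physics.

The 1D steady balance d²T/dx² = −P·α with T(0) = T(L) = T₀ integrates to
T(x) = T₀ + (P·α/2)·x·(L−x).  (A widely circulated closed form with the
opposite sign and no ½ factor dips below T₀ and does not satisfy the stated
source; the form used here is the one the boundary-value problem actually
has.)  Devitrification begins where T exceeds T_max; the default
T_max = 136 K is the crystallisation onset of amorphous ice.

## Numerical choices

* **2D solver.**  Five-point Laplacian on a node grid spanning [0,L]
  inclusive, Dirichlet rows eliminated, direct sparse LU solve with a
  verified discrete residual < 1e-10 (relative) and a conjugate-gradient
  fallback before failing.  The 1D parabola is exact for the discrete
  operator at the nodes; the 2D peak converges as O(h²) (verified against
  the classical double-Fourier-series solution of the unit-square Poisson
  problem, peak 0.0736713...).
* **Masked sources.**  `node_source` antialiases the hole mask by averaging
  a 4×4 sub-grid per node cell: a raw binary mask at practical resolutions
  carries a systematic discrete-disk area bias (≈7 % at 4 px/µm for a 2/1
  pattern) that the supersampling removes.  `film_mask` itself stays a
  binary raster, pixel centres at (i+0.5)/resolution, hole lattice
  phase-centred on the square.
* **Closed form vs 2D solver.**  The closed-form threshold is the 1D slab
  model.  A full square cools from four edges, so its peak factor is
  0.0737·αqL² rather than the slab's 0.125·αqL² — the two routes agree only
  in the slab limit (y-invariant source, Ly ≫ Lx), where they match to
  <1e-6 relative.  On the true square the explicit-hole-mask route and the
  α·η_c homogenisation agree within 5 % (measured ≈0.7 % for a 2/1 pattern
  at 4 px/µm), which is the consistency that matters for catalogue work.
* **Transient solver.**  κ·∂T/∂t = ∇²T + α·q with backward Euler (matrix
  factored once per run) by default; the explicit scheme is provided for
  cross-checking and enforces dt ≤ κ/(2(1/hx² + 1/hy²)), naming the bound
  in its error.  κ ("heat_capacity_scale") only sets the equilibration
  pace — the paper-level observation is that heating equilibrates within
  tens of milliseconds, so all threshold analysis uses the steady state —
  and is a demonstration parameter with default 1.
* **Calibration.**  Thresholds span a > 40-fold range, so the fit is on the
  log scale (multiplicative error): α̂ is the geometric mean of per-row
  inversions 8·(T_max−T₀)/(η_c·P·L²).  Censored rows ("> 690 W/cm²": the
  measurement rig's ceiling, combining both laser lines; "< 50 W/cm²")
  never enter the point fit; they yield one-sided α bounds and a
  consistency flag against the fitted prediction.  CFlat and Quantifoil
  carbon are calibrated as separate materials: identical geometries differ
  ~2× in threshold, attributed to manufacturing/thickness.
* **Geometry conventions.**  Hole lattice is square with pitch d+s — the
  only lattice that reproduces all three catalogued carbon percentages
  (65/97/82 %) after integer rounding; a hexagonal lattice does not and is
  not offered.  Standard meshes use the catalogued square sizes
  (200/300/400 → 90/58/37 µm), which take precedence over the
  inch-pitch-minus-bar formula because no single bar width reproduces all
  three; non-standard meshes use 25400/mesh − 26.5 µm.  Scaling-law
  comparisons use full-precision η_c and the larger product as the
  denominator; under this convention the CFlat film-geometry pair differs
  by 1.70 % and the Quantifoil pair by 3.39 % (the latter is "about 3 %"
  only after rounding η_c to whole percent — the convention is fixed and
  the discrepancy reported, not hidden).
* **Damage states.**  The four experimental severity states are visual
  categories; the model maps them to the fraction of square area above
  T_max with configurable boundaries f_onset = 0.05 (state 2: onset
  confined near the centre) and f_severe = 0.50 (state 4: a large fraction
  of the square).  Damage is irreversible: under a power schedule the
  reported extent (and state, in the ramp simulator) is the running
  maximum.  The 70 % operating rule is applied as stated; the reference
  experiments ran gold film at 186.5 W/cm², ≈73 % of its 254 W/cm²
  threshold, and this slack is noted rather than resolved.

## Synthetic data

The generator emulates the threshold-measurement design behind the
catalogue: per-grid true thresholds from the forward model, multiplicative
log-normal noise with σ² = ln(1 + CV²), right-censoring at the 690 W/cm²
instrument ceiling.  Defaults: two carbon makes with α of the calibrated
order (CFlat 3.4e-3, Quantifoil 3.8e-3), six designs per material (the
three standard hole patterns × 200/300 mesh), noise CV 5 %.  The catalogue
itself gives no replicate counts or error bars, so the noise level is a
simulation choice, not a measured one.  Randomness flows from one study
seed through counter-based per-(replicate, grid) substreams, so row order
never changes draws and identical seeds give bit-identical datasets.

What the generator does *not* emulate: ice-thickness variation, film tears,
cryoprotectant effects, stage-to-stage thermal differences, or the visual
classification noise of real damage scoring.  Passing recovery tests
therefore show that the estimator inverts the model correctly under its own
error assumptions — not that the model predicts absolute thresholds for
arbitrary real samples (the mesh-series measurements deviate ~39 % from the
1/L² prediction, and the analysis reports that deviation as a
model-adequacy figure rather than hiding it).

## Problem sizes

Defaults keep everything interactive on one CPU: 1D profiles at 257 nodes;
2D solves at 33–233 nodes per side (unit-square oracle at 129², masked
square at 4 px/µm); transient demonstrations on 41² grids; recovery studies
at 200 replicates × 12 grids.  All are package choices and scale up by
passing larger resolutions or replicate counts.

## Known limitations

No radiative transfer, temperature-dependent conductivity, latent heat,
through-thickness gradients, or sample/ice-thickness effects; rectangular
meshes are supported only as distinct Lx/Ly in the 2D solver, without
anisotropy modelling.  Absolute temperature predictions are meaningful only
after calibration of α for the film in question.
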