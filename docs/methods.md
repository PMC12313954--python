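# Methods

`speleoplan` models, designs and evaluates pillar-array energy modulators
("SpeleoFilters") for scanned proton beams. A SpeleoFilter is a grid of
square pillars (default 1 mm pitch) of varying height on a thin common
base. Each pillar pulls the Bragg peak of the protons crossing it
upstream by its water-equivalent thickness (WET = path length × relative
stopping power), so the *distribution* of pillar heights under a beam
footprint converts a single scanned energy into a polyenergetic depth
dose — for example a spread-out Bragg peak (SOBP) — and a single-energy
arc delivery becomes possible with few or no energy switches.

## Dose engine

The engine is fully analytic and sits behind a small functional interface
(`bragg_curve`, `shift_curve`, `beamlet_dose`, `field_dose`) so a Monte
Carlo back-end could replace it without touching the planning code.

**Range–energy rule.** `R(E) = α·E^p` with water defaults
α = 2.2·10⁻³ cm·MeV⁻ᵖ and p = 1.77 (both configurable). All depths are
water-equivalent millimetres.

**Pristine depth dose.** The closed-form power-law stopping power
`S(z) ∝ (R−z)^{1/p−1}` plus a linear nuclear fluence-loss term
(β = 0.012 cm⁻¹, γ = 0.6) is convolved with a Gaussian whose width
combines range straggling (σ_mono = 0.012·R^0.935 in cm) and the
accelerator energy spread mapped through dR/dE. Default energy spread
0.5 MeV, depth grid 0.5 mm. The resulting distal-90% depth agrees with
the power-law range to within one grid step at 150 MeV; peak-to-entrance
ratio is ≈5 — sharper than measured clinical beams, which matters only
for absolute entrance-dose levels, not for the counting, uniformity and
ordering results this package targets.

**Lateral model.** A single 2-D Gaussian per beamlet,
σ(d) = √(σ_air² + (k·d)²) with σ_air = 3 mm at isocentre and k = 0.03 by
default. These are configurable engine parameters, not measured beamline
values; the nuclear halo and collimator edge scatter are not modelled.
The collimating aperture is an ideal field mask: beamlets outside the
field are rejected rather than attenuated.

**Filters in the beam.** A beamlet that crosses a filter is treated as a
mixture: the WET histogram of the pillars under its Gaussian footprint
(σ_air at the filter plane) weights a superposition of shifted pristine
curves. This reproduces the measured two-peak behaviour of an
alternating-height prototype; a point footprint degenerates to a single
ray-traced WET shift. Protons keep their lateral distribution through
the filter (filter-induced extra scattering is neglected).

**Radiological depth** is accumulated along the central ray with
nearest-neighbour stopping-power sampling at segment midpoints, which is
exact for piecewise-uniform voxel phantoms. Off-axis voxels reuse the
central-ray depth at their projected position (standard pencil-beam
approximation).

## SOBP designer

The designer works on the superposition model: under a uniformly scanned
field the central-axis dose is the mean of WET-shifted pristine curves,
one per pillar. A coordinate-descent sweep visits each pillar, proposes
± the current step (schedule 5, 1, 0.25, 0.1 mm; 15 sweeps per step),
accepts only objective-improving moves immediately, and compiles the
sweep into the new reference filter; the objective trace is therefore
non-increasing by construction.

Three design elements are the package's own choices:

* **Goal construction.** A flat goal needs an absolute level the
  superposition can actually deliver. A small non-negative least-squares
  fit over a 1 mm WET spread produces an ideal-SOBP template that fixes
  the plateau level and the natural entrance dose; the goal is that
  template with the plateau flattened, a shoulder band (one pristine
  90→20% falloff width) beyond the distal edge, and a linear falloff.
  Point weights: plateau 1, distal falloff 0.5, entrance 0.25.
* **Spatial placement.** The model constrains only the height
  *multiset*; a raster sweep leaves spatially correlated heights, so the
  local histogram under a central beamlet differs badly from the design.
  `distribute_heights` re-places the sorted heights along an R2
  low-discrepancy lattice ordering so every footprint samples the full
  distribution (this is what suppresses hot/cold streaks). The multiset,
  and hence the full-field histogram, is preserved exactly.
* **Goal augmentation.** Because the model ignores edge effects the full
  engine sees (equilibrium loss with depth, shoulder rounding), the
  design loop re-evaluates the filter with the engine on a water phantom
  and moves the working goal opposite to the residual:
  `goal' = goal + damping·(original − engine)` on the plateau plus the
  shoulder band. Defaults damping = 1.0 and 3 correction rounds, chosen
  for convergence of this fixed point; the reported uniformity always
  comes from the final engine evaluation, never from the model.

With the defaults, the engine-verified maximum plateau deviations are
≈2.0/2.1/2.5% for 3/5/7 cm SOBPs at 150 MeV over a 5×5 cm field, with
100% of plateau points within 2.5% of the mean.

## Arc and IMPT planning

Spot placement offers the arc layout (one primary beam's-eye-view column
per discrete angle, secondary columns at ±2.5 and ±5 mm so a 10 mm band
is scanned per angle) and a full-surface mode (every field position at
every angle) used by the fixed-filter studies. Fixed-field IMPT
enumerates energy layers on a 2.5 MeV grid, either derived from the
target's radiological depth interval or passed explicitly.

**Energy segmentation** ray-traces the target's radiological depth
interval per angle, compares it with the filter's SOBP interval shifted
by each candidate energy's range difference, and greedily extends
segments while the per-angle feasible-energy sets intersect — which
yields the minimal number of contiguous segments. When no energy covers
some angle within the coverage tolerance (default 5 mm), best-effort
mode relaxes the tolerance to the smallest feasible value (strict mode
raises instead). Energy changes are counted as segment transitions for
arcs and as (layers − 1) summed over fields for IMPT.

**Weight optimisation** minimises a weighted sum of per-ROI quadratic
terms (two-sided for the target prescription, one-sided for max-dose
penalties) over non-negative spot weights with a monotone FISTA
projected-gradient scheme (relative tolerance 10⁻⁶, ≤2000 iterations,
x₀ = 0); `scipy.optimize.nnls` serves as the independent oracle in
tests. Plans are renormalised so the target D95 equals the
prescription. Default penalty weights (target 1, ring 0.3, skin 0.3,
body 0.05) are package choices that reproduce qualitative trade-offs,
not any published absolute dosimetry.

## Co-optimisation of filter and weights

Each outer iteration builds beamlet libraries for three scenarios — the
nominal filter and a seeded random pillar subset (default 25%)
systematically raised/lowered by δ (default 1 mm, clamped at zero) —
re-optimises weights on the nominal scenario, applies them to all three
(re-optimising per scenario is available but off by default), and forms
per-voxel objective maps. The per-pillar sensitivity is the central
finite difference of the scenario objectives restricted to the voxels
influenced by beamlets crossing that pillar; heights move by −η·g
clipped to |step| ≤ δ. The step scale is backtracked (1, ½, ¼, ⅛) with
every trial judged by its own re-optimised weights — judging at fixed
weights systematically rejects good steps, because weight compensation
makes any height change look locally worse. The loop stops when the
best objective fails to improve for two consecutive outer iterations.

The recovery harness (`make_ground_truth_case`) builds a planar cylinder
phantom irradiated from three angles through a coarse-pitch pillar strip
with smooth random heights and random positive weights, takes the
resulting dose as the planning goal (so the optimum is known and
achievable), and starts from the truth distorted by ≈2 mm RMS. Fine
(1 mm) dose sampling along the beam makes each pillar's distal falloff
visible to the objective — that is what identifies heights against
compensation by the free weights. Seeded cases recover to well under
1 mm RMS.

## Evaluation

DVHs are cumulative volume-weighted histograms (0.1 Gy bins); D-metrics
use exact percentiles. Conformity is the whole-grid isodose volume over
the target volume, with the target encapsulation fraction reported
alongside so the "completely encapsulated" premise is checkable.
Integral dose is Σ dose·voxel volume over the body in 10⁻³ Gy·m³.
Dmax(1cc) is the minimum dose of the hottest 1 cm³. The skin ROI is the
inner 5 mm rind from the body perimeter and the ring the 10 mm shell
around the target, both generated morphologically (the Euclidean
distance transform is offset by half a voxel because it measures
centre-to-centre distances).

**Gamma analysis** uses global normalisation to the reference maximum,
a search radius of 3× the distance criterion and reference resampling at
0.1× the distance criterion. Resampling uses *integer* upsampling
factors so every original reference node stays on the fine grid —
otherwise identical distributions score nonzero gamma wherever the dose
gradient is steep.

**Sensitivity study**: with weights fixed, all pillar heights are
shifted by ±0.5 and ±1 mm (clamping at zero is flagged) and the dose is
re-evaluated; reported are the changes in target prescription coverage,
target and ring hottest-1cc dose, and the central-axis distal-80%
falloff depth, which moves by −δ·RSP for a uniform height error δ.

## Materials and fixtures

The default pillar material is a clear printing photopolymer: density
1.19 g/cm³, adipose-like composition (H 11.4, C 58.9, N 0.7, O 28.7,
Na/S/Cl 0.1 mass %), relative stopping power 1.16 derived once by Bragg
additivity from that density and composition and stored as a
configurable constant. Mesh export rounds heights to 0.01 mm, well
below the 0.127 mm tolerance of the printing process this targets.
Prototype fixtures: a solid block, an alternating 50/3 mm pattern
(checkerboard or stripes — the spatial layout of the physical prototype
is not public, so it is a config option), and arbitrary height matrices.
Phantoms are 25 cm water cylinders (axis along y) with a 5 cm
cylindrical target, centred or offset 5 cm toward the 0° entrance, plus
a planar single-voxel-slab mode for fast studies; all fixtures
regenerate deterministically from their spec and seed.

## Problem sizes and limitations

Planning studies run on planar phantom slabs with 2.5 mm voxels and 10°
arc sampling; SOBP designs use the full 50×50 pillar grid with a
2×2×1 mm evaluation phantom. These sizes are the package's deliberate
desk-scale choices; finer sampling changes absolute dosimetry only
marginally and no counting or uniformity result above.

Known limitations:

* Absolute dosimetric values (conformity indices, skin and integral
  doses in Gy) are engine-specific and are not reproduction targets;
  only counts, uniformity statistics and qualitative behaviour are.
* With this idealized engine and a converged sparsity-promoting weight
  optimiser, the 4-field IMPT baseline achieves a *lower* integral dose
  than the fixed-width-filter full arc on the central-target phantom
  (the arc's fixed 5 cm plateau overshoots short edge chords, and a
  filter-degraded beam has a higher entrance-to-peak ratio than a
  lower-energy pristine beam). Delivery-chain overheads that penalise
  many-field, many-layer plans in practice — minimum-MU floors above
  all — are deliberately not modelled, so this ordering should not be
  read as a statement about clinical deliveries. The arc's skin-sparing
  advantage is robust in either case.
* No nuclear halo, no filter-induced lateral scattering, no collimator
  edge scatter, no CT-number conversion, no delivery-time model.
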