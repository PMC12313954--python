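# speleoplan

Design and evaluation toolkit for **SpeleoFilters** — pillar-array
energy modulators that let a scanned proton beam deliver arc therapy
with almost no energy switching.

A pencil-beam-scanning (PBS) proton arc rotates the gantry while
scanning spots, but conventionally needs many energy-layer switches to
track the target's radiological depth, and switching is slow. A
SpeleoFilter is a block of printable plastic made of ~1 mm square
pillars of varying height on a thin base. Each pillar pulls the Bragg
peak upstream by its water-equivalent thickness (WET), so the local
*distribution* of pillar heights turns one beam energy into a
polyenergetic depth dose — e.g. a flat spread-out Bragg peak (SOBP) —
and a full arc can be delivered with a single energy.

The package provides, for medical-physics researchers prototyping such
devices:

* an analytic pencil-beam **dose engine** (Bortfeld-style pristine
  curves `R(E)=αE^p`, α=2.2·10⁻³ cm·MeV⁻ᵖ, p=1.77; WET shifting;
  Gaussian lateral spread) behind an interface a Monte Carlo back-end
  could replace;
* **filter geometry**: exact WET ray tracing through the pillar boxes,
  footprint WET histograms, prototype fixtures (solid block,
  alternating 50/3 mm pillars), STL mesh export, and design-vs-scan QC
  (DICE, surface distances);
* the **SOBP designer**: coordinate-descent pillar-height optimisation
  against a goal profile under the superposition model
  `D(z) = Σ_b m_b · D_pristine(z + WET_b)`, with engine-in-the-loop
  goal augmentation;
* an **arc/IMPT planner**: spot placement over arcs and fixed fields,
  greedy minimal energy segmentation, sparse dose-influence matrices,
  non-negative least-squares weight optimisation, energy-change
  accounting;
* a **co-optimiser** that jointly refines pillar heights and spot
  weights from three perturbed-filter scenarios and per-voxel
  objective maps;
* **plan evaluation**: DVHs, conformity indices CI90/CI50, skin and
  integral dose, percent-depth-dose extraction, gamma analysis
  (dose-difference / distance-to-agreement), and a construction-error
  sensitivity study;
* deterministic synthetic **phantoms** (25 cm water cylinder with a
  central or 5 cm offset 5 cm target) and ground-truth recovery cases.

See `docs/methods.md` for the model, its assumptions and known
limitations.

## Worked example

Design a filter that turns a 150 MeV beam scanned over 5×5 cm into a
5 cm flat SOBP, and verify it with the full engine:

```
$ speleoplan design-sobp --width 50 --energy 150 --seed 1 --out runs/sobp50
max plateau deviation 2.11%
```

The run writes `heights.csv` (the 50×50 pillar-height matrix in mm),
`profile.csv` (the engine-computed central-axis depth dose),
`trace.csv` (the optimiser's objective per sweep) and `design.json`:

```json
{
 "uniformity": {
  "max_deviation_pct": 2.1108785779799684,
  "mean": 0.26309256297329225,
  "within_2p5_pct": 100.0
 },
 "status": "ok",
 "plateau_mm": [102.63369643884599, 152.633696438846]
}
```

Reading: the designed filter's SOBP plateau spans water depths
102.6–152.6 mm; when the filter is re-evaluated by delivering the full
scanned field through it onto a water phantom, no point on the plateau
deviates more than 2.11% from the plateau mean and every point is
within 2.5%. The same objects are available from Python:

```python
from speleoplan import design_sobp_filter

out = design_sobp_filter(50.0, energy=150.0)
print(out.uniformity)           # engine-verified plateau statistics
out.filter.heights              # 50x50 pillar heights, mm
```

Planning studies build on the same pieces: `speleoplan.studies`
compares a single-energy full-arc delivery through a fixed 5 cm filter
(0 energy changes) against a 4-field IMPT baseline (80 changes on its
100–150 MeV, 2.5 MeV-spaced layer grid) on the cylindrical phantom, and
`speleoplan.coopt` recovers known pillar heights to sub-millimetre RMS
on seeded synthetic cases.

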