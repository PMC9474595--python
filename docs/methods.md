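# Methods

## Scope and design intent

`autoplan` models rule-based external-beam planning for locally advanced
cervical cancer: aperture construction from anatomy, forward field-in-field
(FIF) optimization, coverage normalization, and constraint reporting. The
package replaces two components a clinical deployment would have with
declared stand-ins:

* patient CTs and auto-contours → a parameterised **synthetic pelvic
  phantom**;
* a commercial dose algorithm → a **surrogate dose engine** with exactly the
  properties the planning logic consumes.

Everything downstream of those two substitutions — landmark detection,
beam's-eye-view (BEV) geometry, PTV construction, normalization, FIF, DVH
metrics — is the real algorithm, implemented and tested in full.

## Coordinate and beam conventions

Arrays are indexed `(x, y, z)` with +x patient-left, +y posterior,
+z superior; world coordinates are millimetres, voxel centre of `(i, j, k)`
at `origin + (i, j, k)·spacing`. Gantry angles are restricted to the four
cardinal directions; the source sits anterior at 0°, patient-left at 90°,
posterior at 180°, patient-right at 270°. Projection is **parallel**
(non-divergent). A clinical system projects with source divergence; parallel
geometry preserves every algorithmic relation used here (projection/
backprojection duality, aperture ⊆/⊇ relations, mirror symmetry of opposed
beams) and admits exact oracles, so it is the declared simplification
throughout. Oblique angles, collimator and couch rotations are out of scope.

## Mask morphology

Margins are physical. Per-direction expansion uses an octant-wise
ellipsoidal structuring element built in millimetres (an offset is included
iff Σ(oᵢ/mᵢ±)² ≤ 1 with the directional margin matching the offset sign),
applied by FFT convolution, so asymmetric margins such as the 10/10/10/10/5/5
mm internal-motion margin are millimetre-true on anisotropic grids. Uniform
shrinkage thresholds the Euclidean distance transform of the mask interior,
strictly (`depth > m`), which makes `shrink(expand(M, m), m) ⊇ M` exact on
the lattice; the image border is padded as foreground so anatomy that leaves
the field of view does not erode from the grid edge. Hot-spot components use
26-connectivity and strict thresholds (">"), matching the "more than 107 %"
phrasing of the hot-spot rule.

## Dose engine

Per monitor unit, `dose = D₀ · F(p) · PDD(d)` with `F` the aperture
indicator convolved with a 2D Gaussian (σ = 3 mm) in the BEV plane, and

```
PDD(d) = (d/d_max)²            d < d_max        (build-up)
       = exp(−μ(d − d_max))    d ≥ d_max        (exponential falloff)
```

with μ = 0.005 mm⁻¹ (≈5 %/cm, 6 MV-like), d_max = 15 mm and
D₀ = 0.01 Gy/MU. Water-equivalent depth accumulates along the parallel ray
over attenuating tissue only; a rectal gas cavity is non-attenuating, which
raises dose downstream of it — the mechanism by which a gas-filled rectum
perturbs plans. Dose is zero outside the body; there is no scatter kernel,
heterogeneity correction, output-factor or off-axis model. All dose
quantities are reported relative to the prescription, so the absolute
calibration D₀ is cosmetic. Linearity in MU and additivity over beams are
exact by construction (unit doses are cached per aperture and summed with
their MU weights), which is what makes the FIF MU-shift solvable in closed
form.

## Phantom

The phantom is schematic geometry, not an atlas: the planning algorithms
consume only bony-landmark positions and target–organ spacing, so those are
the relations built to be faithful. Design choices that matter:

* **Body outline**: superellipse (exponent 4), default 360 mm lateral ×
  240 mm AP, tapering 8 % from hips to waist. The boxy cross-section keeps
  the four-field overlap region inside tissue at more than build-up depth
  (an elliptic outline puts its corners in air), and the taper gives the
  central dose a gentle cranio-caudal gradient, as real trunk thickness
  variation does. Both features exist in patients and both are needed for
  dose–volume quantiles to behave realistically.
* **Bones**: pelvic ring at *inlet* scale (outer 190 × 150 mm) with two
  obturator through-holes; L4/L5 as stacked blocks with a 5 mm interspace at
  z = 237.5 mm (recorded in metadata, so tests can check the detected
  superior border analytically); sacrum carved behind the ring; femoral
  shafts + heads. AP/PA fields end up ~18 cm wide, as in practice.
* **Targets**: primary CTV = uterus/cervix ellipsoid plus an upper-vaginal
  canal reaching toward the inferior field border — the cold tail of the PTV
  DVH therefore sits at the inferior field edge, which is where clinical
  reviewers observe under-coverage; nodal CTV = two pelvic-sidewall columns
  ending below the L4/L5 interspace.
* **Habitus scaling**: `lateral_diameter`/`ap_diameter` rescale the outline
  and all structure positions; the clearance belt between the targets and
  the bowel space scales with them (16 mm at default habitus). A slim
  phantom therefore has strictly less target–bowel distance and a larger
  bowel fraction inside the bone-defined fields — the low-BMI failure mode
  of the box technique.
* **organ_scale** applies to bladder, rectum, gas cavity and spinal cord
  only. Target sizes are fixed: the bowel space is carved around the targets
  with the habitus clearance, so letting targets grow with `organ_scale`
  would shrink the bowel and break the monotonicity contract (soft-tissue
  volumes non-decreasing in `organ_scale`).
* **Determinism**: the seed drives only ±1.5 mm anterior–posterior and
  superior–inferior jitter of soft-organ centres; bones are never jittered
  (landmark tests stay exact) and no lateral jitter is applied (the phantom
  stays left–right symmetric, which the dose-symmetry property uses).
* **Grid**: 2.5 mm isotropic, sized to the body plus a 60 mm air margin per
  side (192 × 144 × 120 voxels by default) — the 7 mm morphology is well
  resolved and a full plan fits comfortably in memory. Module tests run the
  same anatomy at 5 mm for speed; coverage-precision checks stay on the
  2.5 mm grid because a 5 mm DVH knee is quantised more coarsely than the
  half-point tolerance.

What the phantom does **not** emulate: CT intensities and heterogeneity,
organ shape variability, contouring error (the L4 failure mode is modelled
by deleting the mask, not by mis-contouring), bowel loops (the bowel is the
whole space, matching how the constraint is evaluated). Passing tests
therefore demonstrate the planning logic and its failure-mode mechanisms,
not clinical dosimetric accuracy on patients.

## Normalization

`normalize` scales dose so the `L×rx` isodose covers fraction `p` of a
target: the covering dose is the top-p percentile of target voxel doses
with linear interpolation, making the scale exact rather than
grid-quantised, and idempotent to 10⁻⁶. Presets: 100 %/97 % on the
synthetic PTV (4-field box), 100 %/95 % on the PTV (3D-CRT), 95 %/99 %
(alternative reviewer preference). Coverage counts voxels by centre
inclusion.

On the synthetic-PTV rationale (normalizing 100 %/97 % on the beam-geometry
surrogate ≈ normalizing 100 %/95 % on a contoured PTV): the two recipes
agree in **dose scale** to better than 1 % on the default phantom, and the
package asserts that agreement (within 2 %) plus PTV V(0.97·rx) ≥ 95 %
under synthetic-PTV normalization. The headline coverage number V(rx)
itself is *not* asserted between the two recipes: the four-field dose
inside the PTV is flat to a few tenths of a percent, so V(rx) sits on a
near-vertical DVH segment where a 0.2 % dose difference moves coverage by
tens of points — a cliff metric that no smooth surrogate engine can pin
down, and whose instability is a property of the metric, not of the
planning method.

## FIF optimizer

One subfield per iteration, largest hot spot first, donor = open field
contributing the most dose at the hot spot's maximum voxel (ties to the
lower beam id). The MU shift Δ is solved from linearity at the hot voxel,
`Δ = (D(v) − T)/(u_parent(v) − u_subfield(v))`, then clipped so the parent
keeps ≥ 7 MU and any new subfield receives ≥ 7 MU (an existing
identical-aperture subfield is topped up instead, avoiding floor deadlock).
Blocking margin 3 mm — deliberately equal to the penumbra σ so the blocked
region's dose actually falls. Renormalization to the recorded coverage
happens once a clean state is reached, and the search then repeats, because
upscaling can push regions back over threshold; with renormalization
disabled, dose is pointwise non-increasing across iterations and per-angle
MU totals are conserved exactly. Budgets: 6 subfields per beam, 60
iterations — automated forward FIF needs more segments than hand planning
(the default box plan on the default phantom converges with ~8), and
exhaustion returns a warning status, never an exception. Hot spots are
searched inside the body, restricted to the RHD when the plan is normalized
on the synthetic PTV; dose outside the RHD is governed by the separate
exterior rule (`suppress_exterior_dose`), which applies the same machinery
with no minimum volume to components above a level (e.g. 70 % of rx)
outside the RHD. In opposed-beam geometry much of the peri-RHD spill is
collinear with the target and physically irreducible; the operation
guarantees monotone improvement and a recorded termination reason, not
elimination.

## Evaluation

VxGy uses the `≥ x` boundary (conventional DVH semantics, stated because the
source rule tables do not say). Dmax is the maximum voxel dose; Dcc is
available for near-maximum reporting. Femur metrics pool left+right. The
bowel rules are evaluated on the whole bowel space by construction;
loop-based bowel limits are intentionally absent. Missing structures make a
rule "not evaluable", never a silent pass.

## Problem sizes and numerical choices

Default runs use the 192 × 144 × 120 phantom grid; unit beam doses are
float32 (summed in float64), one grid per distinct aperture, cached. The
acceptance script completes in ~15 s and the full test suite in ~2 min on
one CPU. Margins/percentiles are exact in mm (FFT dilation threshold 0.5;
EDT-based erosion); geometric assertions use one-voxel tolerances, coverage
assertions 0.5 percentage points, scale assertions 10⁻⁶–10⁻¹².

## Known limitations

Parallel beams (no divergence) slightly understate field growth with depth;
the penumbra is a single Gaussian (no scatter shoulder), making field-edge
DVH tails sharper than clinical profiles; the phantom's femoral geometry
sits medially of patient anatomy, so femur dose metrics are pessimistic for
the box technique; the engineered hot-spot scenario perturbs beam weights
because the surrogate engine has no other source of localized overdose.
None of these affect the contracts the package asserts.
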