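# Methods

This note documents the models, numerical choices and limitations of
`platefatigue` at the level a maintainer or reviewer needs.

## Scope and units

The package predicts the maximum bending moment a metallic bone plate
can sustain for 10⁶ cycles (the "runout") in a four-point-bending
fatigue test, from the plate's surface mesh and the raw-material
ultimate tensile strength. Lengths are mm, stresses MPa, moments
N·mm, loads N. The plate's longitudinal axis is z, the load
(thickness) direction y, the bending axis x; cross-sections live in
the x–y plane at station z.

## Geometry extraction

**Orientation.** The longest axis-aligned bounding-box edge is taken
as the longitudinal axis and rotated to z; the shortest becomes the
thickness direction y. Ties (bounding-box edge ratio below 1.05) are
resolved deterministically in the order z > y > x and flagged with a
warning. The mesh is also centered at its bounding-box midpoint so
that every downstream quantity — including section centroids — is
invariant to rigid motion of the input.

**Slicing.** The test region (by default the central 50 % of the
plate, or the center span *a* when supplied) is cut by *n* = 100
equidistant planes. Each plane–mesh intersection is resolved to closed
polylines (trimesh performs the segment chaining); planes that miss
the mesh or produce open/self-intersecting contours are excluded with
a warning, and polylines with area below 10⁻⁶ of the station's largest
polyline are dropped as slivers from planes grazing a hole edge. For
curved plates a second pass re-slices at the centroid polyline of the
first pass, with plane normals from central differences of consecutive
centroids (one-sided at the ends); this removes the 1/cos(tilt)
area inflation of inclined cuts.

**Section properties.** Polygon area, centroid and I_xx come from the
closed-form (Green's theorem) polygon moments with winding
normalized. Stations with multiple polylines (holes) are composed by
Varignon's theorem (area-weighted centroid) and the parallel-axis
theorem. Width and thickness are the axis-aligned 2-D bounding box of
all section vertices — a slight overestimate for strongly tilted
sections, accepted and documented. The hole gap *d* is the minimum
distance between polyline pairs; stations with more than two polylines
generalize the same formulas and warn that the downstream notch chart
assumes one circular hole.

**Critical section and refinement.** The critical section minimizes
I_xx (ties broken by smallest station). Because the plane stack
samples I_xx(z) discretely, the discrete minimum can sit up to half a
plane spacing from the true one (worst case: a hole center exactly
between two planes). `critical_from_mesh` therefore refines the
bracket between the two neighbouring stations with a few extra planes
per iteration (defaults: 7 planes, 2 iterations), using centroid-line
normals; this reduces the station-alignment error to the mesh
discretization level (≪ 0.1 % on the synthetic fixtures) while
`critical_section` itself remains a plain argmin.

## Fatigue model

**Stress concentration.** K_t for transverse bending of a finite-width
plate with a central circular hole is interpolated bilinearly from an
encoded grid over d/w ∈ [0.05, 0.65] and d/t ∈ [0.25, 4]. The grid is
a smooth surrogate of the published transverse-bending curves: an
infinite-plate backbone K_t,inf(d/t) = 1.79 + 1.21/(1 + d/t), spanning
the thin-plate (Kirchhoff) limit 1.79 and the small-hole
three-dimensional limit ≈ 3, attenuated linearly in d/w on the
net-section nominal. It reproduces the qualitative structure of the
chart (monotone decrease in both ratios, values in (1, 3]) but is not
a digitization of any specific edition; with no hole K_t = 1 exactly
(a section without a hole has no concentrator — note the conceptual
discontinuity against the chart's d → 0 limit, which describes a
vanishingly small but existing hole). Out-of-domain queries clamp to
the boundary with a warning.

**Notch sensitivity.** K_f = 1 + q (K_t − 1). Steels use Neuber's
q = 1/(1 + √ρ/√r) with the average grain size ρ (mm), which is not in
a material certificate and must be supplied by the user; the notch
radius is the hole radius r = d/2, the only radius the geometry
extraction yields. Titanium (alloyed or pure) uses q = 1,
conservatively taking K_f = K_t.

**Fatigue limits.** Specimen limit σ*_D−1 = 0.5 σ_UTS; component limit
σ_D−1 = σ*_D−1 ∏Cᵢ / K_f with ∏Cᵢ = 1 by default (no surface-finish
correction, 50 % reliability); the size/surface/loading factors are
individually settable for reuse.

**Mean-stress correction.** The load line σ_a = R_a σ_m with
R_a = (1 − R)/(1 + R) (0.8181… at R = 0.1; a `paper_rounding` option
carries the two-decimal 0.82 for comparison against hand calculations)
is intersected with the Goodman line and the Gerber parabola in closed
form; each solution is back-substituted into its criterion equation
and required to satisfy it to 1e-9 relative. R = −1 returns the
fully-reversed limit (σ_m = 0, σ_a = σ_D−1). Gerber always lies at or
above Goodman for tensile mean stress, so the band ordering
M_goodman ≤ M_gerber is structural, not numerical.

**Moment conversion.** M = σ_max I_xx/(t/2) with σ_max = σ_D + σ_m,
and L = 2M/h for loading span h. This is a purely elastic formula —
see Limitations.

## S–N and M–N bands

Basquin curves σ_a = A N^b are anchored exactly at
F(10³, 0.9 σ_UTS (1 − R)/2) and G(N_G, σ_D) per criterion,
b = log(σ_D/σ_F)/log(N_G/10³). Beyond N_G the curve is a flat fatigue
limit (infinite-life plateau); below 10³ cycles evaluation is allowed
but flagged as outside the estimated region. Both criteria share F, so
the Goodman/Gerber moment band has zero width at 10³ cycles and grows
monotonically to the runout band at N_G. σ_D ≥ σ_F is rejected (the
curve would rise); equality is accepted as a flat curve with a
warning. Exported tables use a log-spaced cycle grid, 50 points per
decade.

## Verification

Records are labeled **runout** (≥ N_G cycles without failure, plotted
and evaluated at N_G), otherwise **plastic** or **elastic** by
comparing the elastic peak stress M(t/2)/I_xx against the yield
strength, a required user input. Records below 10³ cycles are excluded
from scoring with a warning. The score is
R² = 1 − Σ(pred−exp)²/Σ(exp−mean exp)², i.e. the coefficient of
determination about the 45° identity line; it equals 1 iff predictions
match experiments elementwise and can be negative. R² is computed
independently per criterion and per interval (a 2 × 3 table), pooling
all supplied plates: pooling matters because a single plate's exact
runout records share one moment value, which makes the denominator
vanish. Campaign bookkeeping: hours = n·N/f/3600 (3 × 10⁶ cycles at
5 Hz ≈ 167 h) and the hours avoidable by excluding planned loads above
the Gerber upper limit.

## Synthetic data

The generator emulates the relevant features of certification
campaigns, not their full realism:

* **Plates** are rectangular-section bars with plain cylindrical
  through-holes (no countersinks, locking threads or anatomical
  contouring), optionally bent to a constant radius, so the section
  properties have exact closed forms: away from holes
  I_xx = w t³/12; through a hole of diameter d at offset δ the chord
  c = 2√((d/2)² − δ²) removes width but not lever arm,
  I_xx = (w − c) t³/12. Meshes are built from a structured cap
  triangulation (plain bands plus a radial O-grid around each hole)
  extruded through the thickness; they are watertight and
  deterministic. Hole circles are polygonized at the cap resolution,
  which biases the measured gap low by ~cos(π/m); at the default
  0.5 mm resolution this is well inside the 1 % oracle tolerance.
* **Campaigns** follow the staircase protocol: start at 90 % of the
  proof load, multiply by (1 − decrement) after each failure
  (default decrement 10 % — the standard's step size is a lab choice;
  a multiplicative step keeps the relative resolution constant), stop
  at the first load reaching 10⁶ cycles, repeat the runout on three
  samples. Failure cycles come from inverting the true Basquin curve,
  with optional lognormal scatter (σ_log, natural log) and an optional
  yield cap on the driving stress so plastic-range records deviate
  from the elastic formula as real over-yield tests do. With zero
  noise the recovered runout load is mathematically within one
  decrement step below the true runout load — the systematic
  underestimation inherent in a down-stepping protocol.

Passing tests on these fixtures demonstrates the correctness of the
extraction and prediction machinery, not the accuracy of the fatigue
model on real plates, whose scatter, surface condition, residual
stresses and geometry are richer than the generator's.

## Numerical choices

* Plane-contour chaining tolerance and closure are delegated to
  trimesh; unclosable contours reject the station.
* Sliver threshold: polyline area < 10⁻⁶ × largest polyline at the
  station.
* Criterion back-substitution tolerance 1e-9 relative; Basquin anchor
  tolerance 1e-9 relative; all enforced, not just tested.
* Orientation ambiguity threshold 1.05 on bounding-box edge ratio;
  tie-break z > y > x.
* Test problem sizes (mesh resolution 0.5–0.8 mm, 41–100 planes,
  10⁶ Monte-Carlo samples, 50-record campaigns) were chosen so the
  oracle tolerances are met with an order-of-magnitude margin.

## Limitations

* The moment formula is elastic; above the yield point real stresses
  are lower than computed, so low-cycle (plastic-range) predictions
  are systematically poor — visible in the degraded plastic-interval
  R² of the synthetic campaigns.
* The K_t chart is a smooth surrogate (see above); for regulatory
  work the grid file can be replaced by a digitization of the user's
  preferred chart edition without code changes.
* w/t from an axis-aligned bounding box slightly overestimates tilted
  sections; the Peterson chart assumes a single circular hole, while
  sections with more than two polylines only warn.
* No multiaxial criteria, no local strain (Neuber/Glinka) plasticity
  correction, no reliability factors beyond ∏Cᵢ, no statistical S–N
  regression of experimental data, no CAD (STEP) input and no FE
  analysis.
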