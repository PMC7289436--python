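# Methods

## Physical model

The package treats low-frequency (< ~100 Hz) endogenous cortical fields in
the quasi-static approximation. A current dipole **p** (nA·m) at distance r
in an infinite homogeneous conductor of conductivity σ produces the
potential Φ = **p**·r̂/(4πσr²) and field
**E** = (3(**p**·r̂)r̂ − **p**)/(4πσr³); for **p** along ẑ this is the
polar form (p/4πσr³)(2cosθ r̂ + sinθ θ̂), so the on-axis field is exactly
twice the equatorial field at equal r and decays as r⁻³. The analytic
homogeneous medium is a deliberate surrogate for finite-element tissue
models: it preserves the r⁻³ single-source regime and the superposition
structure of patch fields while remaining closed-form and desk-scale.
Tissue-boundary effects (skull, CSF) are out of scope; the conductivity
table (scalp 0.33, skull 0.008, CSF 1.79, grey matter 0.40, white matter
0.15 S/m) is carried as reference data, and computations use a single
scalar σ, defaulting to grey matter.

Coupling to neurons uses the lambda-E rule: an elongated population with
effective space-constant vector **λ** in a locally uniform field suffers a
membrane perturbation δΦ = **λ**·**E**, largest at fiber terminations.
Pyramidal cells are taken as oriented along the local cortical surface
normal, so **λ**_x = λ₀**n**_x.

## The index

Each vertex is simultaneously an emitter (dipole p₀δA **n**_y) and a
receiver (λ₀**n**_x). The per-vertex index is

ε₁(x) = −κ Σ_{y≠x} Θ[−**n**_x·**n**_y] Θ[l₀−r] (**n**_x·**n**_y)/r³ [δA_y],
κ = λ₀p₀/(2πσ),

and the global index is the mean over valid vertices. Both step functions
are strict (Θ[x] = 0 for x ≤ 0, 1 for x > 0): pairs need **n**_x·**n**_y < 0
and r < l₀. The orientation gate selects geometrically opposing patches
(cross-sulcal geometry); under it every admitted term is nonnegative, which
makes the global index non-decreasing in l₀. The distance gate models
temporal coherence: beyond a few millimetres, sources stop adding in phase.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| λ₀ | 1 | mm | effective space constant of the receiving population |
| p₀ | 0.5 | nA·m/mm² | dipole surface density of synchronously active cortex |
| σ | 0.40 | S/m | grey-matter conductivity |
| l₀ | 5 | mm | coherence range; strict Euclidean distance gate |
| use_area | False | — | include source vertex areas δA_y |

κ evaluates to 198.94 µV·mm at the defaults with r in mm.

### Unit convention

With `use_area=True` the sum carries δA_y (mm²) and the map is in µV; it is
mesh-convergent and matches the parallel-plate closed form
2πκ(1/d − 1/l₀) (250.0 µV at d = 2.5 mm, l₀ = 5 mm) at interior vertices.
With `use_area=False` (the default) the bare Σ1/r³ carries mm⁻³ and the map
is reported in model units of µV/mm²; its value scales with mesh density
(refining the mesh by 2× roughly quadruples it), which deliberately
up-weights densely meshed high-curvature regions. Every result records the
convention, all physical parameters and κ in its metadata.

δA in the area-weighted branch is the **source** vertex area, because the
area enters through the emitter's dipole moment p₀δA**n**_y, not through the
receiver.

### Variants

`emod1` (both gates, signed kernel) is the only variant with a fixed
definition. `emod0` and `emod1a` are registered as named placeholders that
require an explicit `SupportSpec`; their exact support functions are not
publicly defined and the package invents no defaults.

### Implementation and numerics

The production path builds radius-limited vertex pairs with a k-d tree
(strictly r < l₀, and r > 10⁻⁶ mm to guard the 1/r³ kernel against residue
of merged vertices) and accumulates contributions in fixed ascending
(receiver, source) order. An independent O(N²) brute-force evaluator over
full distance rows serves as a testing oracle; the two agree to 1e-9
relative on all phantoms. If a pair list was built with a smaller radius
than the requested l₀ the computation raises rather than silently
truncating; a larger build radius is allowed because the strict gate
re-filters. Exact invariances verified numerically: rigid motions, global
normal flips, linearity in p₀, and the scaling law (coordinates and l₀
scaled by s multiply the area-free index by s⁻³ and the area-weighted index
by s⁻¹).

## Surface handling

Meshes are read/written in the FreeSurfer binary triangle dialect
(big-endian, magic 0xFFFFFE; coordinates taken as mm verbatim), ASCII PLY
and OFF; per-vertex maps as FreeSurfer curv (new format, float32) or CSV.
Repair merges duplicate vertices at 1e-9 mm, removes degenerate and
duplicate faces, and makes winding consistent per component, flipping a
closed mesh to outward orientation when its signed volume is negative; it
is idempotent and never increases the vertex count. Vertex normals are the
area-weighted average of incident face normals, renormalized; vertex areas
use the one-third-of-incident-face-area rule so they sum exactly to the
surface area. On a unit icosphere the area-weighted normal converges to the
radial direction at first order in edge length (≈7e-4 max deviation at
~164k vertices); angle-weighted normals would converge faster but
area-weighting matches common surface-pipeline output and is stable on
irregular triangulations.

Geodesic distances are Dijkstra shortest paths on the edge graph with
Euclidean edge weights. On lattice-triangulated grids this is exact along
edge and diagonal directions but overestimates oblique directions by up to
~41% (the usual edge-graph limitation); it always upper-bounds the Euclidean
distance. The smoothing kernel uses these graph distances consistently on
both sides (weights and radii), so the half-maximum calibration is
unaffected.

## Phantoms

The sulcus phantom is an **open** surface — two planar walls at separation
`width`, a semicylindrical fundus, optional gyral crowns — rather than a
closed volume: the index needs only the grey-matter sheet, and the field
surrogate is analytic. Facing interior wall vertices have exactly
anti-parallel normals and the minimal cross-wall distance equals the width
by construction. `n_folds > 1` produces a corrugated sheet whose adjacent
folds share semicircular crowns at period 2×width; this is the geometry
used for gyrification checks, since the convex hull of a *single* open fold
hugs its walls too closely for a realistic outer-surface contrast.
Parallel plates are the idealized wall limit with a closed-form index;
spheres and flat sheets are gated-index null cases (on a sphere of radius R,
any pair within r has **n**_x·**n**_y = 1 − r²/2R² > 0 whenever l₀ ≤ √2 R).

The synthetic cohort emulates age-related sulcal widening:
w(age) = 0.8 + 0.03·age mm + N(0, 0.15 mm), ages uniform over 16–83 years,
40 subjects by default — artifact defaults chosen to give mid-life widths
in the 1–3 mm range that the field analysis covers, not empirical claims.
A thickness model t(age) = 2.8 − 0.01·age mm + N(0, 0.1 mm) generates a
white surface offset inward along the vertex normals, so
corresponding-vertex thickness recovers t exactly. Widths are floored at
2.05× the mesh spacing to keep every gap resolvable. All subjects share one
topology (profile segment counts are fixed from the width model at the
mid-range age), so vertex correspondence across the cohort holds without
registration. Generation is a pure function of the spec, seed included.

What the phantoms do **not** emulate: realistic folding statistics, mesh
irregularity of MRI-derived surfaces, registration error, regional
heterogeneity of dipole density, or tissue inhomogeneity. Passing tests
therefore demonstrate the correctness of the machinery and the direction of
the width→index→age coupling, not effect sizes in real cohorts.

## Morphometric proxies and statistics

Thickness is the distance between corresponding white/pial vertices (index
correspondence required) — a simplification of the symmetric definition
used by full MRI pipelines. The gyrification proxy uses the convex hull as
the outer surface (rather than a morphological closing) and compares pial
area to hull area inside matched Euclidean balls; the hull is resampled at
the mesh's own edge scale so both area sums share boundary-sampling
statistics (on a convex mesh the ratio is then exactly 1). Smoothing is a
geodesic-truncated Gaussian (σ = FWHM/2.355, truncated at 3σ, weights
normalized per vertex; FWHM 0 is the identity), not the iterative scheme of
MRI pipelines; a calibration test checks the half-maximum radius of a
smoothed point source.

Vertex-wise association uses Pearson correlation with two-sided p-values
from t = r√((n−2)/(1−r²)); constant vertices are masked. Multiple
comparisons are controlled by Benjamini–Hochberg step-up FDR at q = 0.05
(via statsmodels, cross-checked against direct step-up enumeration). Global
metric trends against age use OLS polynomial fits (order 1 or 2) with R²
and the overall F-test p-value. Global metrics are computed unsmoothed;
smoothing is applied only to vertex-wise maps.

## Problem sizes

Default test and acceptance runs use phantoms of ~500–4,000 vertices,
cohorts of 40 subjects (~800-vertex meshes) and 20 replicate seeds; the
brute-force oracle is exercised up to 2,000 vertices. These sizes keep every
closed-form comparison well inside its tolerance while the full suite runs
in about a minute and a half.

## Known limitations

- Homogeneous-medium fields only; no FEM/BEM, no realistic head geometry.
- The index is the simplified gated pair sum, not a full ephaptic-field
  calculation with tissue-accurate fields.
- Edge-graph geodesics overestimate oblique directions on regular grids.
- The gyrification outer surface (convex hull) differs from the
  morphological-closing wrap of standard pipelines; it is monotone in
  folding on phantoms but not numerically interchangeable.
- The area-free unit convention makes absolute index values
  mesh-density-dependent; comparisons are meaningful within a fixed
  meshing protocol (the cohort generator guarantees one).
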