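# Methods

## Scope and model of the data

The package analyzes 3D reconstructions of sensilla and ORN dendritic
segments as they come out of a serial-section EM segmentation workflow:
closed contours drawn on serial sections (pixel units with anisotropic
voxel calibration, typically 5 × 5 × 40 nm), meshed into continuous
surfaces, skeletonized, and measured as separate objects (sensillum
cuticle, proximal outer dendrite, distal outer dendrite). All geometry is
stored in µm; pixel-to-µm conversion happens once, at contour load.

Because the raw EM volumes behind such studies are not redistributable at
desk scale, the package carries a first-class synthetic generator that
emits the same substrates (contour stacks, watertight meshes, SWC
skeletons) for parametric dendrite shapes with closed-form morphometrics —
every downstream stage is validated against analytic ground truth rather
than against hand-segmented data.

## Mesh construction and morphometrics

Contour stacks are lofted into watertight meshes: each contour is
resampled by arc length to a common vertex count (original vertices are
preserved so polygon corners survive; extra vertices fill the largest arc
gaps), consecutive rings are aligned by the cyclic shift minimizing vertex
displacement, ring pairs are joined by triangle strips, and the first and
last contours are closed with planar ear-clipped caps. Meshes are held in
`trimesh`; watertightness is checked by exact edge pairing (vertices
merged at 1e-9 µm, no fuzzy welding).

Surface area is the triangle-area sum; volume is the divergence-theorem
signed volume, required watertight and returned positive. For tube-like
objects whose enclosed lumen is segmented as a separate inner object
(fully curled sheets), the membrane volume is V_outer − V_inner and the
sensory surface SA_outer + SA_inner — both membrane faces count.
Containment of the inner object is verified by ray-parity sampling of its
vertices (points nudged 1e-6 toward the centroid so coincident end-cap
planes do not trip the test).

End caps at truncation planes are **included** in surface areas, on both
members of a hollow pair. This is a declared convention: for the
coaxial-cylinder fixture (r_o = 0.5, r_i = 0.3, L = 5 µm) it gives
SA = 27.27 µm², i.e. 2πr_oL + 2πr_o² + 2πr_iL + 2πr_i², rather than the
annular-end alternative 2π(r_o + r_i)L + 2π(r_o² − r_i²) = 26.14 µm².
Caps are a few percent of segment surface at these aspect ratios.

An independent volume oracle (`voxel_fill_volume`) counts 20 nm voxel
centres inside plane sections of the mesh; it shares no code path with the
divergence-theorem volume and agrees with it to ≤ 0.02% on smooth test
solids. Ray casting (Möller–Trumbore, vectorized over faces) and end-cap
triangulation (ear clipping) are implemented in-package so no optional
compiled geometry engines are needed.

## Skeletons and centerlines

Skeletons follow SWC semantics (unique ids, parent forest, two-pass load
so forward parent references parse; type codes 1 = soma, 3 = dendrite,
0 = undefined). Segment length is the Euclidean parent-child edge sum.
Branch points are nodes with ≥ 2 children, termini are leaves, the branch
count of a neuron is its number of termini (1 for an unbranched chain),
and the primary branch point is the branch point at the smallest path
distance from the root (smallest node id on ties).

`centerline_from_mesh` replaces interactive skeletonization: starting at
the mesh end of lowest projection on a caller-supplied axis hint, the
tracer cuts the mesh perpendicular to its current direction, takes area
centroids of the section components (overlapping loops are unioned first,
so junction regions of multi-tube meshes do not spawn spurious branches),
advances by a fixed 0.2 µm arc step, and spawns one branch per component
when the lumen separates. Tips attach to the nearest centroid within 2×
the arc step and, on termination, are extended to the mesh surface along
the local direction, which removes the half-step bias at end caps. The
0.2 µm step resolves the shortest segments of interest (~4.8 µm) with
> 20 stations; on capped cylinders (r ∈ 0.05–0.25 µm, L ∈ 5–20 µm) length
recovery is exact to < 0.1%, on a quarter-torus of centerline radius 5 µm
the error is ~1%. A `prune_short_branches(min_length)` utility removes
spurious terminal twigs; the threshold is caller-controlled with no
default, since no principled value exists independent of mesh quality.

`planar_layout` replaces manual 2D spreading of branches: leaves receive
evenly spaced directions inside a 60° fan, internal nodes take the mean
direction of their leaves, and every edge is drawn straight at its true 3D
length — edge lengths are preserved exactly and sibling subtrees occupy
disjoint sectors.

## The cuticle-proportion coordinate

The sensillum cuticle centerline (unbranched, base → tip; the base is the
end nearer the antennal surface, designated by the caller) is resampled at
0.05 µm and arc-length parameterized. A landmark's cuticle proportion is
the arc fraction of its nearest point on the centerline: 0 at the base, 1
at the tip. Points below the base project onto the basal ray — the first
segment's direction extrapolated backwards — and score
−(distance below base)/L, so −1 is one cuticle length down. Nearest-point
ties go to the lower arc-length station (the ray, with negative stations,
wins ties against the base). For multi-branch neurons each terminus is
reported individually and the neuron-level dendritic terminus (DT) is the
maximum proportion over termini.

## Morphology classification

Cross-section profiles are sampled every 0.02 of cuticle length from the
base to the terminus. Each station records: number of membrane-bounded
components, self-enclosure (any component carries a lumen hole),
and the aspect ratio of the largest component (max/min principal-component
extent of its outline vertices — rotation-invariant).

A station shows *flattening evidence* if its aspect ratio is ≥ 2.0, or it
is self-enclosed, or it has ≥ 2 components. The aspect threshold separates
the ~1:1 profiles of cylindrical dendrites from sheets; the two extra
clauses are needed because a sheet that has curled fully closed reads as a
ring of aspect ≈ 1, and a sheet split into sheetlets may present modest
per-component aspect — both are flattened morphologies by construction.
The flattening point (FP) is the first station whose evidence is sustained
for ≥ 0.5 µm of arc (the persistence window suppresses single-station
mesh artifacts); cylinders return none.

Over the flattened span, curl evidence is the fraction of stations with
self-enclosure, split evidence the fraction with ≥ 2 components. With a
persistence fraction of 10%: both → *mixed* (which takes precedence, being
defined as the combination), curl only → *fully curled*, split only →
*split*, neither → *loosely curled*. Branched/unbranched calls for
cylindrical-dendrite neurons come from skeleton topology alone.

All thresholds (aspect 2.0, persistence 0.5 µm, evidence fraction 0.10,
station step 0.02) are surfaced in `RunConfig` and serialized with a hash
into every output bundle; none is hidden. On real data the detected FP
position shifts with the aspect threshold; on the synthetic archetypes
classification is invariant to mesh resolution (16- vs 64-vertex contours)
and the confusion matrix is diagonal.

## Statistics

Paired two-tailed t-tests compare segments within neurons (identical
samples short-circuit to p = 1; non-zero constant differences are an
error). Two-sample comparisons pass each group through Shapiro-Wilk at
α = 0.05: both normal → unpaired two-tailed t, otherwise Mann-Whitney.
Mann-Whitney uses exact null enumeration when the pooled sample is ≤ 12
without ties, else the tie-corrected normal approximation with continuity
correction; the exact branch is verified against brute-force enumeration
of all rank assignments. Kruskal-Wallis (tie-corrected) is followed by
Dunn's z post-hoc on pooled mean ranks with Holm adjustment, rendered as a
compact letter display via the insert-and-absorb algorithm over groups
sorted by mean rank: significant pairs never share a letter,
non-significant pairs always do (verified by brute force). When the
omnibus test is non-significant, all groups share one letter and no
post-hoc is run. Correlations are OLS fits reported with R²; α = 0.05
throughout. Test distributions come from `scipy.stats`; Dunn and the
letter display are implemented here.

## Synthetic data: what it emulates and what it does not

Archetypes are extruded along the cuticle axis from parametric
cross-sections: circles (cylinders), arc strips (sheets of width w,
thickness t, bent over a curl angle — a bent strip keeps the flat sheet's
section area wt and perimeter 2(w+t), so flat-sheet closed forms apply),
annular hollow pairs (fully curled tubes), strip pairs (split), a tube
plus a wrapping strip (mixed), and cylinder fans joined at a branch point
(trees, branch values summed per the branch-summing convention). Default
dimensions are chosen so the archetypes sit at the published population
scale: proximal radius 0.28 µm (V/L 0.25 µm²), sheets 2.0 × 0.09 µm
(SA/V ≈ 23 µm⁻¹), tree trunks 0.147 µm and branches 0.056 × 6.0 µm,
cuticle 9.5 µm long with a 1.45 → 1.05 µm taper chosen to land near the
published cuticle volume. Flattening points are drawn from the published
0.13–0.53 range (mean 0.40), termini from 0.62–0.98 (mean 0.89), branch
points from 0.08–0.44, branch counts 2–7.

Population tables are sampled per metric from truncated normals
(lower bound 0) at the published per-category mean ± SD, with totals and
the derived V/L and SA/V recomputed per row. Sampling L, SA and V
independently ignores the real inter-metric correlations (a thick dendrite
is long, large and voluminous together), so simulated *totals* have
slightly smaller SD than printed and between-metric covariances are not
reproduced; column means and the within-row arithmetic identities are.
Geometry-level populations, by contrast, derive all metrics from shape
parameters and are self-consistent by construction. Neither route emulates
EM noise, segmentation error, or membrane roughness — passing tests show
the pipeline's correctness on clean geometry, not robustness to imaging
artifacts.

Seeding: one run seed fans out to per-neuron substreams keyed by a stable
hash of the neuron id, so adding or reordering neurons does not perturb
the others; identical seeds give byte-identical outputs.

## Numerical conventions

- Sample SD uses the n−1 denominator; CV = SD/mean; summaries need n ≥ 2.
- Printed-value reproduction rounds half away from zero at the printed
  precision.
- The sensillum "midpoint" is proportion 0.5 of cuticle arc length; branch
  counting at that plane counts outer loops only (an enclosed lumen is
  lymph, not dendrite).
- Identity assignment ranks neurons by combined soma + inner-dendrite +
  outer-dendrite surface area; ties within 1% are flagged ambiguous rather
  than silently ordered.
- Default mesh resolution is 64 vertices per contour at 0.2 µm plane
  spacing, which keeps every lofted archetype within 0.6% of its closed
  forms (2% is the working tolerance).
- Analyses here run at the study's own scale (populations of 25 and 21
  neurons; 2000 replicates for the type-I calibration), so the whole
  pipeline completes in minutes on one CPU.

## Known limitations

- Lofting assumes one contour per section per object (no within-object
  topology changes mid-stack); objects that split are represented as
  separate meshes, as in the source segmentation convention.
- End caps are planar and ear-clipped; strongly non-planar or
  self-intersecting contours are rejected rather than repaired.
- The centerline tracer assumes a roughly monotone long axis per object;
  hairpin geometries would need a smaller step and may still fold back.
- The classifier's thresholds are conventions. They recover the designed
  categories perfectly on clean synthetic geometry; borderline real
  profiles (aspect ≈ 2, transient enclosures) will be sensitive to them.
- The binary IMOD model format is out of scope; contour stacks enter via
  the documented JSON dialect, meshes via ASCII PLY/OBJ, skeletons via SWC.
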