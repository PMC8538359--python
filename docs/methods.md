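# Methods

This note documents the geometric model behind `kneeplan`, the
conventions chosen where standard descriptions are verbal or ambiguous,
and what the synthetic fixtures do and do not establish about real data.

## Coordinate frame and units

All geometry lives in a right-handed frame in millimetres: **+z
proximal** (along the mechanical axis of the intact fixture), **+x
lateral** for a right femur, **+y anterior**. Angles are degrees. A left
femur is generated as the exact mirror of the right through the sagittal
plane x = 0; chirality-sensitive quantities (PCA, varus/valgus) flip
sign under that mirror, as they must.

## Synthetic femur

The generator (`kneeplan.femur`) emulates the product of a CT →
segmentation → mesh-repair chain: a watertight triangle mesh of the
femur plus named anatomical landmarks. It is built from four watertight
parts — icosphere head, cylindrical shaft tilted by the
anatomical–mechanical angle (default 6°) in the coronal plane, a neck,
and a bicondylar distal block swept from a rounded cross-section with an
intercondylar notch (20 mm wide, 12 mm high) — concatenated into one
edge-manifold mesh.

Deliberate metric properties, chosen so every downstream measurement has
an exact reference:

- the distal condylar surfaces are **locally flat** at the joint line
  (z = 0), exactly `tubercle_to_jointline` (default 42.5 mm) distal of
  the adductor tubercle along the mechanical axis;
- the posterior condylar surfaces are flat at the posterior tangent
  plane (y = −AP/2); the posterior condylar landmarks sit on that flat
  band (5 mm above the condylar round) so that a 5 mm measurement patch
  never sees surface curvature;
- the mechanical axis passes through the femoral head centre and the
  trochlear notch centre by construction; the native posterior condylar
  angle (default 3°) is realised by the antero-posterior offset of the
  two epicondylar landmarks relative to the posterior condylar tangent;
- with the default 75 mm medio-lateral width, the distal condylar
  landmarks span 45 mm and the posterior ones 50 mm — these spans are
  what convert millimetre defects into degrees (e.g. a 7 mm medial
  distal loss ↔ atan(7/45) ≈ 8.84° varus).

**Defects** are segmental plane cuts: vertices of the named condylar
region beyond the cut plane are projected onto it. This preserves
watertightness and topology, strictly decreases volume, leaves every
other vertex bit-identical, and produces a flat defect floor whose depth
is exact — which is why depth recovery can be asserted to 0.2 mm.
Cavitary (contained) defects are not modelled. Depths must stay below
the condylar thickness (12 mm distal, 15 mm posterior).

The generator is fully parametric and deterministic; the seed is
recorded and only consumed by the cohort sampler. The **cohort**
machinery draws per-patient scenarios from a given mix (the study
conditions use n = 19 with mix 3/19, 14/19, 2/19) and integer defect
depths uniform on 2–10 mm — a fixture choice representing mild-to-
moderate (AORI ≤ 2) loss, since no severity thresholds are standard.

What the fixtures do **not** show: performance on real segmented bone
(noise, cartilage remnants, osteophytes, cavitary loss, anatomical shape
variation), or landmark identification itself — landmarks are inputs
here, whereas on CT data they are the hard part.

## Spacer CAD kernel

The femoral component (`kneeplan.spacer`) is a swept solid:

- **Sagittal bone-facing profile**: five straight facets (anterior
  flange, anterior chamfer, distal, posterior chamfer, posterior) with
  amplitudes `A_AS, A_ACS, A_DS, A_PCS, A_PS` and exterior turning
  angles `ϑ_AC, ϑ_D, ϑ_PC, ϑ_P` (defaults 45° each — the classic
  five-cut femoral box, giving a C-shaped profile with a 180° total
  turn). Profile simplicity is validated; self-intersections are
  reported by facet pair.
- **Articular outer curve**: the profile offset outward by a thickness
  field — `D1` on the anterior flange, `D2` distal, `D3` posterior
  (this D-to-facet assignment is a documented convention), blended
  linearly in arc length across the chamfers, with circular fillets at
  the facet joints (outer fillet radius ≈ local thickness; the
  bone-facing corners carry a small 0.1·min(D) fillet so the sweep has
  no degenerate triangles).
- **Sweep** across `size_ML` with per-station modulation: two
  half-ellipse condylar lobes (amplitude 4 % of `size_ML`) outside the
  intercondylar span; a trochlear groove (depth 15 % of `D1`) on the
  anterior flange inside the notch; and a **cam-post roof** — a
  circular-arc outward bulge of height `HP` over chord `WP` on the
  posterior facets inside the notch. `HP`/`WP` are stated only to
  control the cam-post "thickness and amplitude", so the circular-arc
  realisation is a convention; it makes volume strictly monotone in
  `HP`, which the tests pin.
- **Augment pads** displace the bone-facing surface toward the bone on
  the distal or posterior facet, over `A_MC` (from the medial edge) or
  `A_LC` (lateral) of the sweep — so volume grows by pad thickness ×
  footprint (asserted within 5 %).

The component frame puts the distal bone-facing facet in z = 0 and the
posterior bone-facing facet in y = 0; placement only needs these two
planes. All construction is homogeneous of degree 1 in the length
parameters, so uniform scaling scales volume exactly cubically (a test
invariant). Mesh resolution: `resolution` samples per facet and 8 ×
`resolution` + 1 sweep stations (default 81 stations, ≈ 24 k faces,
≈ 0.1 s to build).

## Axis measurements

- **Femoral head centre**: least-squares sphere fit — algebraic linear
  fit followed by geometric (orthogonal-distance) refinement via
  `scipy.optimize.least_squares` (tolerances 1e-12). This is the 3-D
  analogue of the radiographic Mose-circle template: exact on noiseless
  spheres, ≈ unbiased under isotropic noise.
- **Anatomical axis (Moreland's two points)**: the proximal-distal
  direction is taken from the superior head aspect to the distal medial
  condyle; P1 is the mesh slice **area centroid** at half the
  proximal-to-distal length (centring the point both medio-laterally
  and antero-posteriorly — the A–P centring is unspecified in the
  classical description, the slice centroid is the natural 3-D
  realisation), P2 the slice centroid 100 mm above the knee-joint
  surface (most distal condylar point; selectable). Slices are
  assembled by `trimesh` sections and measured with `shapely`.
- **Mechanical axis**: head centre → knee centre (default: trochlear
  notch centre), oriented distal → proximal.
- **Surgical TEA**: lateral epicondylar prominence → medial epicondylar
  sulcus line, oriented medial → lateral.
- **PCA**: signed angle in the transverse plane (normal = mechanical
  axis) from the TEA to the posterior condylar tangent; **positive =
  posterior condyles internally rotated** relative to the TEA.
- **Coronal deviation**: signed departure of a medial→lateral joint
  line from perpendicularity to the mechanical axis; **varus positive**
  (medial side proximally deficient reads positive).

Both signed conventions are fixed here (verbal sources give directions
only in words) and are pinned by fixture and mirroring tests. On
defective bone the condylar tangent points are relocated onto the
actual surface by ray probing (`probe_condyles`), so a posterior-lateral
defect of depth d over span s shifts the PCA by atan(d/s).

## Planning

**Placement** aligns the component's distal-plane normal with the
mechanical axis, its medio-lateral axis with the TEA projected into the
transverse plane, and puts the distal plane `target` mm (default
42.5 mm, the midpoint of the accepted 40–45 mm window) distal of the
adductor tubercle *measured along the mechanical axis* (the
along-axis/Euclidean choice is unstated in the source description;
along-axis is used and reported).

**Gap measurement** ray-casts the bone from a disc patch (radius 5 mm,
13 rays) centred on each native condylar landmark, along the planned cut
normal (mechanical axis distally; the anterior normal of the posterior
cut plane posteriorly). The patch plane passes through the landmark, so
the gap is the **per-condyle deficit relative to the native condylar
surface**: intact bone reads 0 and a segmental defect reads its depth.
This per-condyle referencing matters posteriorly: the posterior cut
plane is TEA-aligned and therefore rotated by the native PCA (≈ 3°)
relative to the posterior condylar tangent, which on a 50 mm span would
otherwise masquerade as a ±1.3 mm pseudo-gap. That rotation belongs to
the resection plan, not to the bone-loss accounting that augments must
restore.

**Solver**: symmetric distal augment = shared (minimum, clipped at 0)
distal deficit; asymmetric distal / posterior augment = side-to-side
difference on the deficient side; all rounded **half-up to 1 mm**
(augments are manufactured in whole millimetres; configurable step).

**Verification** rebuilds the component with the planned pads and
re-measures: residual gap = gap − pad thickness per condyle. Residual
distal imbalance tilts the implant joint line
(atan(Δ/45 mm)); residual posterior imbalance shifts the effective PCA
(atan(Δ/50 mm)); a residual symmetric distal deficit lets the component
settle proximally by that amount. The restoration criteria are < 1° of
coronal and PCA deviation and a joint line inside 40–45 mm.

**Classification**: symmetric distal → `JOINT_LINE`, asymmetric distal
→ `CORONAL`, asymmetric posterior → `ROTATIONAL`, threshold 1 mm;
multiple flags resolve to the largest magnitude with exact ties broken
by the fixed priority CORONAL > ROTATIONAL > JOINT_LINE (mixed defects
are an artifact of the solver; the scenarios are clinically disjoint).
Cohort summaries report counts and nearest-integer (half-up)
percentages; with the n = 19 study mix this yields 16 % / 74 % / 11 %
from 3/19, 14/19, 2/19.

## Numerical choices

- Ray casting is an exact vectorised Möller–Trumbore intersection over
  all triangles (meshes here are ≈ 10–25 k faces; no spatial index
  needed). Point-surface distances use exact point-triangle distance.
- Degenerate inputs raise typed errors: coplanar sphere points, axis
  endpoints closer than 50 mm, epicondyles closer than 10 mm, joint
  lines within 5° of the mechanical axis, meshes shorter than the
  100 mm Moreland offset, defect depths reaching the notch.
- STL: the ASCII dialect round-trips vertices exactly; binary STL
  stores float32 and is exact only to ≈ 1e-5 relative. Duplicate
  vertices are merged at 1e-6 mm on read.
- Default problem sizes (femur resolution 16 segments/90°, ≈ 10 k
  faces; spacer resolution 10, ≈ 24 k faces; cohorts of 19) keep a full
  pipeline run under ~0.3 s, the whole test suite under a minute, and
  the acceptance script a few seconds.

## Known limitations

Flexion–extension kinematics, ligament tensioning, patellar tracking,
cement/antibiotic dosing, tibial components and any whole-limb (tibial/
ankle) axis are not modelled. The solver assumes purely segmental
defects measurable along the two cut normals; combined rotational +
coronal defects are planned additively without re-posing the component
between steps. Landmark identification error — the dominant error
source on real data — is outside the synthetic fixtures' scope.
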