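# Methods

This note documents the models, conventions, numerical choices and known
limitations of `bullseye17`. It complements the README, which describes the
pipeline at a glance.

## Coordinate and angle conventions

Volumes are float32 Hounsfield-unit arrays indexed `[x, y, z]` with an
axis-aligned affine (`diag(spacing)`, origin in mm). Slices run along z;
after short-axis alignment the apex sits at the lowest slice index and the
mitral plane at the highest.

Circumferential positions use two coordinates. Absolute in-plane angles
θ = atan2(dy, dx) in degrees, wrapped to [0, 360), describe groove
annotations and raster pixels. The dividers work in

    α = (anterior_groove − θ) mod 360,

which runs from the anterior interventricular groove in the direction of
increasing AHA segment number. The septal arc is α ∈ [0, span) with
span = (anterior − posterior) mod 360; the free wall follows, ordered
4, 5, 6, 1 (basal) from the posterior groove. This is the unique orientation
in which the anterior groove is the 1|2 boundary and the posterior groove
the 3|4 boundary.

## Short-axis alignment

A single minimal rotation (Rodrigues) takes the mitral→apex unit vector onto
+z, centered on the long-axis midpoint. The output grid is isotropic
in-plane at the finer of the two input in-plane spacings with slice spacing
preserved (no detail loss, no invented resolution); HU are trilinearly
interpolated, masks nearest-neighbour, out-of-field voxels are filled with
−1024 HU (air, the CT convention). In-plane rotation about the long axis is
deliberately unconstrained: the circumferential reference is fixed later by
the grooves, not by alignment. Applying the operator twice is an identity up
to interpolation, which the suite asserts.

## LV segmentation

Region growing is thresholding plus 26-connected component analysis: the
component ≥ `hu_min` containing seed SP2 (midpoint of the long axis),
clipped between the apex and mitral-plane slices. The 200 HU constant is the
contrast blood/myocardium separation threshold used throughout; because no
separate value is stated for the region-growing step itself, the same
200 HU is the default for the blood pool and a lower `hu_epi_min = 50` HU
(between soft-tissue background and myocardium) recovers the epicardial
extent. Both are configurable.

Initial contours place 10 control points at 36° steps around the slice
component's centroid, each at the farthest in-component sample along its ray
(the component's directional maximum boundary); control points are accurate
to about one voxel. The closed curve through them is a periodic interpolating
cubic spline with uniform parameterization. Masks are per-slice polygon
fills of the dense splines (scikit-image `polygon2mask`); an endocardial
curve escaping its epicardial curve is an error naming the slice. Apex-cap
slices carry an epicardial contour only and fill solid.

Aortic-root removal selects myocardial-mask voxels **strictly above**
200 HU within the septal angular sector on the basal portion of the stack
(default: basal third, matching the ring geometry below), closes them with
dilate-then-erode (default ball radius 2 mm — the operations are specified
by the method, the structuring element is a package choice) and removes the
result from both compartments. When nothing exceeds the threshold the
operation is a no-op.

## Segment division

Slices are assigned to basal/mid/apical slabs by splitting the apex-to-base
slice range into equal thirds — consistent with the bull's-eye rings at 1/3
and 2/3 of the maximum radius — with solid-cap slices (no chamber) as the
apex slab (segment 17). The conventional divider uses fixed wedges (60°
basal/mid, 90° apical, the apical frame offset 15° so septal segment 14 is
centered on the septum); its reference angle (the 1|2 boundary) defaults to
the anterior groove so the two models are comparable. The patient-specific
divider splits the septal arc equally into the two septal segments (whole as
14 apically) and the free wall equally into four (basal/mid) or three
(apical) wedges. Equal angular subdivision is the one choice that introduces
no additional parameters; weighting by epicardial arc length was considered
and rejected because the published polar maps show straight radial
boundaries.

With grooves placed at the conventional 1|2 and 3|4 boundary positions
(septal span 120°) the two dividers coincide on basal and mid slabs. They
cannot coincide apically: the patient-specific apical free wall then has
three 80° wedges against the conventional 90° wedges.

Groove annotations may be sparse; angles are interpolated linearly over
slice index along the shortest angular path and extrapolated as constants.

Every divider records, per slice, the exact angular rule it applied
(reference angle, wedge starts, labels). Downstream consumers that need a
label at an arbitrary angle (the bull's-eye projection) use this rule rather
than re-reading voxel labels, which removes voxel-lattice quantization from
the polar map. The voxel label map itself remains the source for 3D
quantities (mass).

## Thickness and the bull's-eye map

The per-slice myocardial center is the mean of the epicardial and
endocardial polygon centroids (epicardial alone at the apex). For each
sample angle (1° default) the endocardial border point at that angle is
located and the thickness is its Euclidean distance to the nearest point of
the epicardial border polyline on the same slice — the closest-point rule,
computed exactly against the polyline segments, not against sampled points.

Two border sources are supported. The contour path measures on the 10-point
splines (the clinical workflow's representation). The mask path
(`measure_thickness_from_mask`) traces sub-voxel borders with marching
squares on the voxel masks; it resolves sharp regional thickening that a
10-control-point curve cannot represent (a spline chords across any notch
narrower than its 36° knot spacing) at the cost of ~half-voxel border noise.

The polar raster (default 512 px canvas, maximum radius R = 255 px) places
the apex at the center and the base at the rim. Ring boundaries sit at R/3
(mid/apical) and 2R/3 (basal/mid). A printed description ordering those two
radii the other way is geometrically impossible for concentric rings ordered
apex-outward and the package uses the only consistent assignment. Within
each ring, radius maps linearly onto that slab's slices, so the drawn ring
circles coincide exactly with the slab boundaries. The apex cap (segment 17
disc) has no stated radius; the default is R/6, configurable. Pixels in the
cap display the innermost measured slice's value.

Segment areas are bull's-eye pixel counts multiplied by the square of the
display dot pitch (0.2692 mm), reported in cm². The conversion uses the
squared pitch — the linear reading of the original phrasing is dimensionally
inconsistent with areas in cm² of the reported magnitude on a ~512 px disc.
Per-segment maximum thickness takes the maximum over thickness samples
assigned (via the nearest myocardial voxel to the midwall point) to the
segment; a segment with no samples — normally only the apex cap — reports
missing, not zero. Mass is labeled voxel count × voxel volume × 1.05 g/cm³.

## Statistics

Group comparison is Welch's unpaired two-sample t per segment with
significance tiers (<0.001, <0.01, <0.05, ns). The description of the
cohort analysis as "paired" t-tests cannot apply to groups of unequal size;
pairing is used where it exists — the operator-variability analysis, where
the same ten subjects are measured in every session (p = 1 is reported for
identically zero differences). The diagnostic classifier fits a univariate
Gaussian per group on one segment's parameter, classifies by the larger
likelihood (sensitivity = correctly classified fraction of the disease
group, specificity of the control group) and computes the AUC by sweeping
the log-likelihood-ratio threshold (trapezoidal, via the ROC). Whether the
original analysis ranked by likelihood ratio or by the raw measurement is
not recorded; both are exposed (`score="likelihood"|"raw"`) — they coincide
whenever the likelihood ratio is monotone in the measurement, i.e. for
near-equal group variances.

## The phantom

The generator emulates a contrast-enhanced LV at end diastole: a truncated
half-ellipsoid shell, open at the mitral plane, apex closed. Per slice the
epicardial border is the ellipsoid cross-section and the endocardial border
is it shrunk by the wall thickness, so the **in-plane** wall width equals
the requested thickness wherever a chamber exists — which is what the
per-slice closest-point rule measures on a short-axis stack. Defaults
describe a plausible adult LV on contrast CT: 70 mm long axis, 30 mm basal
epicardial radius, 10 mm wall, 120° septal arc, blood 350 HU, myocardium
100 HU, aortic root 400 HU, background −80 HU, 1 mm voxels. The intensity
values are plausible rather than reproduced — the source states only the
200 HU separation threshold. AS-like phantoms thicken the wall (13 mm) and
narrow the septal arc (110° vs 150°), mimicking the direction of
hypertrophic remodeling without claiming cohort magnitudes.

Grooves exist only as ground-truth angles (no image ridge): the pipeline
consumes them through the annotation pathway exactly as it would a human
operator's markings. Regional thickening uses a raised-cosine profile —
hypertrophy is smooth, and a hard-edged step could not be represented by
the 10-point contour model in any case. The optional aortic root is a
high-HU cylinder in the outer basal septal wall with a clearance band to
the blood pool, emulating root contamination inside the LV contour. What
the phantom does **not** emulate: trabeculae and papillary muscles, motion
and gating artifacts, beam hardening, non-elliptical cross-sections.
Passing tests therefore demonstrate correctness of the geometry and
statistics pipeline, not segmentation robustness on clinical images.

## Numerical notes and measurement granularity

- Voxel-lattice anisotropy: counting voxels of a 60° wedge on a ~1 mm grid
  at LV radii carries ±1.3–2.8° of pure lattice noise (verified on
  synthetic rings, independent of the divider). Wedge-geometry assertions
  at voxel level therefore use a 3° tolerance; the precise checks (0.1°
  granularity) count pixels on the bull's-eye raster, which is also the
  method's own area measurement.
- Control points quantize to ~1 voxel; contour-based thickness on automatic
  contours is accurate to ~1 voxel. Sub-voxel thickness recovery (half a
  voxel) is demonstrated on expert-grade contours, which the phantom
  supplies as analytic truth (`truth_contours`) — mirroring the clinical
  workflow in which experts correct the automatic contours.
- Determinism: all randomness flows through a single integer seed
  (phantom noise, cohort simulation); reruns are bit-identical.
- Simulation sizes: the statistical calibration tests use 1000 null tables
  (type-I error), 10⁴ permutations, 10⁴ subjects per group for the binormal
  AUC check, and 100 cohort replicates at n = 6 per group on a shared
  1.5 mm phantom; the end-to-end group-difference demonstration uses 8 + 8
  phantoms at 1.75 mm. These sizes were chosen to keep the full suite in
  the low minutes while leaving the Monte-Carlo error well below each
  test's tolerance.

## Known limitations

- Landmarks and grooves are inputs (manual in the original workflow);
  no automatic detection is attempted.
- The region-growing threshold is global; no adaptive or atlas-based
  segmentation (named as future work in the source) is provided.
- The basal extent of the aortic-root search sector ("between the basal
  anteroseptal and inferoseptal regions") is under-specified; the basal
  third is used, configurable.
- Cohort-dependent results (per-segment means, p-values,
  sensitivity/specificity/AUC of the 179-subject study) are not
  reproducible without the original scans; only the direction of the
  septal-area effect is demonstrated, at phantom scale.
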