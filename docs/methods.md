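# Methods

This note documents the models, conventions and numerical choices behind
`corochar`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Grid and coordinate conventions

Voxel centers sit at `origin + direction @ (index * spacing)`; indices are
0-based, the in-memory axis order is `(x, y, z)`, world coordinates are mm.
The canonical orientation is LPS (DICOM patient frame); files are reoriented
at read time, and no operation resamples implicitly — a grid mismatch
between an image and its label map is an error.

## Centerline extraction

The extraction operates on the interior voxel graph of the lumen mask
(26-connectivity, Euclidean mm edge lengths) rather than on a surface mesh:
this avoids a meshing dependency in the critical path and makes the
shortest-path computations exactly testable against brute-force oracles.
Surface-based quantities map to the nearest interior voxel.

* **Seeding.** Per 26-connected coronary component, the seed is the lumen
  voxel whose center minimizes Euclidean distance to the aorta voxel set
  (no distance cutoff; ties broken by lexicographic voxel index).  That
  voxel lies on the lumen *surface*, so before tracing it is pulled onto the
  medial axis by steepest ascent on the interior distance transform — a
  parameter-free hill climb with deterministic tie-breaking.
* **Normalized geodesic distance.** Dijkstra from the seed
  (`scipy.sparse.csgraph`), normalized by the component maximum, so
  g(seed) = 0 and max g = 1.  Unreachable voxels (other components) carry
  NaN.
* **Endpoint recursion.** The superlevel sets g > 1 − δ are thresholded for
  δ = 0.05, 0.10, …, 1 (the increment is configurable; 0.05 is the default).
  Each 26-connected region that does not already contain a claimed endpoint
  emits its argmax-g voxel.  Every branch tip is a local maximum of g and is
  eventually the argmax of a fresh region, so all tips are found; the
  schedule's granularity only affects the order of discovery.
* **Tracing.** Minimal path from seed to each endpoint with edge weight
  `euclidean_step / (eps + DT(target))`, where DT is the distance transform
  and eps = 0.1 voxel; the inverse-medialness weight pulls the path onto the
  vessel axis.  The voxel path is resampled at 0.5 mm, smoothed with a
  5-point moving average, and then extended along its end tangents to the
  mask boundary — the extension recovers the arc length that endpoint
  snapping clips at the tube caps (without it a straight 60 mm tube traces
  about 4 mm short).  Branch `g` is the abscissa divided by the component's
  maximal geodesic distance: along a branch the geodesic distance from the
  ostium *is* the arc length, and this form is exactly 0 at the ostium,
  monotone, and free of nearest-voxel sampling jitter.
* **Deduplication.** Endpoint recursion can yield two endpoints whose paths
  are nearly identical; branches sharing ≥ 90% of their points with a longer
  branch (within 1.5 resampling steps) are dropped, and each kept branch
  records the longer branch it shares the most points with as its parent.

Zones: proximal g ≤ 0.33, medial 0.33 < g ≤ 0.66, distal g > 0.66 —
boundaries inclusive exactly as written.

## Tortuosity

Pointwise measures use a sliding reference arc of 10 mm (1 cm), centered at
the evaluation point; window endpoints are linearly interpolated at exact
abscissae, so the arc length of the window is exact.  Points whose window
would extend beyond the branch are flagged invalid and excluded from every
summary (no truncated windows).

* **LT** = window arc length / chord between the interpolated window ends;
  clamped below at 1 (float guard).
* **TA** = angle between least-squares line directions of the upstream and
  downstream half-arcs (the same 1 cm reference arc split at the point).
  Directions come from the first principal component of each half-arc point
  set, oriented along increasing abscissa (PCA lines are sign-ambiguous);
  the angle is evaluated in the atan2 form, which is well conditioned near
  0°.  Degenerate fits (collapsed points) give TA = 0 with a warning.

  On a circular arc the half-arc fit is the tangent at the half-arc
  *midpoint*, so TA at the arc center equals the rotation across **half**
  the window — (window/2)/R radians — not the full window's subtended
  angle.  At a sharp polyline vertex the halves are straight and TA equals
  the full direction change.  Both facts are asserted in the tests.
* **Bends.** A bend is a maximal contiguous run of valid points with
  TA ≥ 45°; runs separated by less than 2 mm of sub-threshold abscissa merge
  into one bend (noise robustness), and the bend angle is the run's maximum
  TA.  The multiplicity rule (run-based, 2 mm separation) is this package's
  decision: a continuous TA profile does not by itself define "how many"
  bends.
* **TS** counts branches of arc length ≥ 20 mm (the "main branch" floor;
  configurable) with ≥ 3 bends.  TS = 0 is labeled none, 1–3 moderate,
  ≥ 4 severe.
* **Tract tortuosity** is L₀/L over the maximal contiguous sub-tract of a
  branch inside one zone (≥ 2 points, else excluded); the patient-level zone
  value is the mean over branches.  LT and TA are additionally summarized by
  their 95th percentile over all valid points (per zone and overall), which
  suppresses isolated outliers.

Known estimator bias: voxelization, path smoothing and the fillet arcs
inside the reference window each *attenuate* the recovered bend angle.  On
analytic filleted polylines (1 mm fillets) the attenuation is ~1–3°; after
rasterization at 0.4 mm and tracing it grows to ~5–9°.  Consequently a bend
whose true angle sits within a few degrees of the 45° counting threshold is
intrinsically ambiguous; the validation suites therefore prescribe bend
angles on a 5° grid over 20–80° that omits 45° itself, and the end-to-end
pipeline tests use pronounced (≥ 60°) bends.

## Calcium

* **Threshold.** θ_HU = μ + k·σ of the image attenuation inside the aorta
  mask, k = 2.5.  In contrast CT a fixed 130 HU rule is useless (the
  opacified lumen exceeds it); the aortic blood pool calibrates the
  patient's contrast level.
* **Search volume.** Candidates (≥ θ_HU) are sought inside the coronary mask
  dilated by 2 mm (configurable): lumen annotations often exclude wall
  plaque.
* **Region growing.** Lesions expand into 26-neighbours whose attenuation
  exceeds the 98th percentile of attenuation inside the coronary *lumen
  mask proper*, iterated to a fixpoint, restricted to the dilated search
  volume (so plaque can exceed the annotation without leaking into the
  aortic pool).  The percentile is computed once per patient, not per
  lesion.  Computing it on the lumen proper rather than the dilated volume
  matters: the dilated volume admixes soft-tissue background, drags the
  percentile into the blood-pool tail, and lets growth percolate through
  blood texture.  With a calcific burden present — the regime the method is
  meant for — the lumen P98 sits at the foot of the calcium intensities and
  the expansion is selective.  A patient with *no* calcium never grows
  anything (growth starts only from detected candidates).
* **Artifact filter.** Lesions whose maximal axial (z) cross-section is
  below 1 mm² are removed.  The size floor can alternatively be read
  volumetrically (1 mm³); both modes are implemented
  (`area_mode="axial_area"` default, `"volume"` optional).
* **Projection.** Each lesion voxel maps to its nearest centerline point;
  distance from the ostium = minimum mapped abscissa, extent = max − min
  mapped abscissa, zone = zone of the min-abscissa point (one zone per
  lesion).
* **Scoring.** VS per zone and total (voxel count × voxel volume), PPV =
  100 × VS_total / lumen volume.  The PPV denominator is the lumen
  annotation volume, not the grown plaque volume.

## Segmentation stack

Preprocessing clips to [−30, 800] HU and z-scores over the clipped volume.
The Dice–Focal loss is

DFL = λ_F · mean_i[ −α(1−ŷ_i)^γ y_i log ŷ_i − (1−α) ŷ_i^γ (1−y_i) log(1−ŷ_i) ]
    + λ_D · [ 1 − 2Σy_i ŷ_i / (Σy_i + Σŷ_i) ]

with α = 0.6, γ = 2; stage-1 weights λ_F = 1.1, λ_D = 0.4 and stage-2
weights λ_F = 0.5, λ_D = 1.  The focal term is aggregated as a mean over
voxels so the loss scale is independent of patch size; posteriors are
clamped to [1e−7, 1−1e−7].  Multi-view fusion takes the element-wise maximum
of the axial/coronal/sagittal posteriors and thresholds at 0.5.

The U-Nets are five-level encoder/decoders with skip concatenation: the 2D
variant uses 3×3 kernels, instance normalization and PReLU on 1-channel
slices; the 3D variant uses 5×5×5 kernels, batch normalization and a
2-channel input (image + preliminary mask).  They are implemented as a
compact numpy layer framework — convolution by shifted-slice accumulation
over kernel offsets (memory-flat for 5³ kernels), analytic backward passes
for every layer, Adam — which keeps the whole stack dependency-light and
lets the gradients be verified against finite differences in the tests.

Smoke training is deliberately small: width-8 (2D) / width-4 (3D) models,
5 epochs, 8 straight-tube phantoms at 0.5 mm spacing, 192 slices per epoch
drawn with foreground bias (70% of draws from vessel-bearing slices —
without the bias the mostly-empty axial stacks dominate the short run).
Across seeds this reaches held-out Dice ≈ 0.95 on the phantom task in about
half a minute on one CPU.  This demonstrates that losses, gradients and data
plumbing are correct; it says nothing about clinical segmentation accuracy,
which requires cohort-scale training outside this package's scope.

## Statistics

Continuous group comparisons use the two-sided Mann–Whitney U test (exact
enumeration when both samples have ≤ 8 observations and no ties, normal
approximation with tie correction otherwise); zone comparisons use one-way
ANOVA; normality (Shapiro–Wilk) only drives report formatting (mean ± SD vs
median [min; max]).  Tortuosity incidence (TS ≥ 1) is compared with
Pearson's χ² *without* continuity correction, paired with the odds ratio
OR = ad/bc — the OR itself is a pure count ratio and unaffected by that
choice.  Method agreement uses Pearson correlation and Bland–Altman
(bias ± 1.96 sample SD).  Significance is read at p < 0.05 and no
multiple-testing correction is applied.

## The phantom generator

What it emulates: HU-scale intensities (blood pool 400 ± 30, background
50 ± 20, lesion peak 800), tapering tubes of clinically relevant caliber
(floor 0.75 mm, half the 1.5 mm reporting floor), an attached aortic
cylinder whose surface is within 2 mm of the ostium, spatially correlated
tissue texture (correlation length 1.5 mm — contrast mixing is smooth, not
voxel-i.i.d., so it survives the PSF with its stated SD), Gaussian PSF blur
(σ = 0.35 mm ≈ 0.8 mm FWHM, typical of sharp cardiac reconstruction
kernels), and i.i.d. Gaussian detector noise (20 HU) added after the blur.
Spacing is constrained to [0.3, 0.7] mm per axis (the clinical acquisition
range); a fixed sub-voxel grid offset prevents axis-aligned structures from
degenerate lattice alignment that would bias voxel-counted volumes.

Calcific inclusions are ellipsoids whose first semi-axis follows the local
vessel tangent; their painted density is 1 in the core and falls linearly to
0 across a band of width `margin_mm` (default 0.5 mm, about one PSF width)
centered on the stated surface.  The half-density convention makes the
stated ellipsoid the natural target of attenuation-threshold volumetry: a
uniformly dense blob would place every super-threshold contour *outside*
the true surface after blurring and bias all recovered volumes upward.

Ground truth (centerlines with arc-length parameterization, per-bend
angles, per-lesion volume/extent/min-abscissa/center) is recorded
analytically before rasterization.  Vessels may touch only at declared
junctions (a child starting on its parent's centerline, then monotonically
separating); any other lumen contact is an error because abscissae would be
ambiguous.

What it does **not** emulate: cardiac anatomy and motion, beam hardening
and blooming around dense calcium, contrast gradients along the tree,
non-calcified plaque, stents, and DICOM acquisition metadata.  Tests passing
on phantoms therefore validate the geometry and intensity logic of the
pipeline, not its robustness to scanner artifacts.

## Validation suites and what the numbers mean

* **Bend/TS recovery** (20 branches, analytic centerlines, prescribed angles
  on the 5° grid): ≥ 19/20 branches match their ≥ 3-bends status; bend-angle
  MAE ≤ 3°.
* **Calcium recovery** (20 lesions, semi-axes 1.5–4 mm, 0.4 mm voxels, full
  rasterize→centerline→detect→grow→project chain): suite-mean absolute
  errors ≤ 20% (volume), ≤ 1.5 mm (extent and ostium distance).  Errors are
  summarized as suite means because per-lesion volume accuracy is
  resolution-limited: at 0.4 mm spacing a half-voxel surface shell on a
  1.5 mm lesion is already ~35% of its volume.
* **Oracle equivalences**: the Dijkstra geodesic field equals a brute-force
  relaxation oracle exactly on small masks; region growing equals the
  brute-force closure; the Dice–Focal loss matches hand arithmetic on a
  2×2×1 grid and its gradient matches finite differences.

Problem sizes throughout (phantom grids of roughly 100–250³ voxels at
0.4–0.5 mm, 20-element recovery suites, width-8 five-epoch smoke training)
were chosen so the full validation runs in minutes on a single CPU while
every stage still operates in its intended regime.

## Known limitations

* The centerline is voxel-graph based; sub-voxel centerline accuracy is
  bounded by the resampling/smoothing pipeline (~0.3 mm on phantoms).
* Recovered bend angles are attenuated by smoothing (up to ~9° after
  rasterization); threshold-adjacent bends are ambiguous by construction.
* The region-growing gate assumes a nontrivial calcific burden in the
  coronary intensity distribution; in a nearly calcium-free tree the P98
  gate sits in the blood-pool tail and grown lesions can over-extend.
* The 2.5D/3D training stack is numpy-based and single-threaded; it is a
  correctness reference and smoke-test harness, not a performance trainer.
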