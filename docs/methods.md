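# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `wrinklefind`, in enough detail to reproduce or
modify the pipeline.

## Problem and model

The target structure is the nasolabial fold: a single dark, curved crease on
the cheek, annotated as 20 ordered landmarks (nose end → chin end) alongside
68 standard face-feature landmarks.  The detector assumes that

* the wrinkle is a *valley* of the intensity surface — darker than its
  flanking skin, with a roughly Gaussian cross profile a few pixels wide;
* face landmarks for the input image are available (from annotation files or
  an upstream landmarker); the package localizes the wrinkle, not the face;
* one nasolabial line per cheek side is of interest; bilateral detection is
  two calls with `side="left"` / `side="right"`.

### Ridge stage

The Hessian at scale σ is computed by convolution with
derivative-of-Gaussian kernels and γ-normalized (multiplied by σ²) so that
responses are comparable across scales.  Its eigenvalues are evaluated in
closed form per pixel,

λ = ½[(H_xx + H_yy) ± √((H_xx − H_yy)² + 4 H_xy²)],

and the dark-ridge response is max(λ₁, 0): across a valley of depth *d* and
cross-profile width *w* the second derivative at the centerline is +d/w²
(smoothed: d·σ²·(w² + σ²)^(−3/2) after γ-normalization), while a linear
illumination gradient contributes nothing.  The response is thresholded
(Otsu by default, computed over the masked cheek pixels only), skeletonized,
split at branch points into polylines, and filtered:

* arc length ≥ LLT (default 100 px) — discards short noise fragments;
* total absolute turning < LAT (default π) — discards distorted lines that
  reverse direction.

The surviving candidate with the largest arc_length × mean_response whose
centroid lies in the cheek work region on the requested side of the
nose-bridge midline becomes the *unique initial shape*, resampled to 20
points at uniform arc length.

### Shape, texture, and fitting

Shapes are modeled by a point-distribution model: generalized Procrustes
alignment (similarity transforms; the mean is renormalized to unit centroid
size each round, convergence at 1e−7 mean movement or 100 rounds, no
tangent-space projection) followed by PCA of the sample covariance
(divisor n−1), keeping the smallest number of components reaching 98 %
variance.  The texture model warps each training image piecewise-affinely
(Delaunay triangulation of the mean shape, fixed at training time) into a
reference frame at half the mean training scale, normalizes each texture to
zero mean / unit variance, and keeps 95 % texture variance.

Fitting uses the classic fixed-Jacobian steepest descent: the Jacobian
column for parameter j is the average of (g(p + δe_j) − g(p))/δ over all
training images and displacements δ (±0.25 σ and ±0.5 σ per shape mode,
±2 px translation, ±5 % scale, ±5° rotation), with texture-model components
projected out.  Each iteration predicts ∂p = (JᵀJ + εI)⁻¹Jᵀ∂g (Tikhonov
ε = 1e−8 against rank deficiency of small training sets) and tries step
sizes α ∈ {1, ½, ¼, ⅛}, accepting the first that lowers the error; the fit
stops when no step size lowers it.  Pose is four similarity parameters
(a, b, t_x, t_y) composed with the shape coordinates; error is the squared
norm of the texture residual after reconstruction by the texture basis.

The *modified* fit used by the unique-shape pipeline passes the per-image
initial shape as the shape-model offset (`s = s_init + E q`, q starting at
0), exactly the baseline algorithm with the global mean replaced by a
per-image mean.  The generic-mean baseline instead starts from the trained
mean positioned by the face landmarks, with q initialized by projection.

Before fitting, the raw ridge-derived 20-point shape is optionally replaced
by its reconstruction from an L1-regularized projection (λ = 1e−6) onto the
similarity-aligned training wrinkle shapes, solved by cyclic coordinate
descent with soft thresholding.  This snaps skeleton noise onto the span of
plausible wrinkle structures.  It is applied once, pre-fit: applying it to
the initial shape is the least intrusive placement consistent with its role
of regularizing the initialization.

### Evaluation

Truth and detection are rasterized as 1 px polylines and symmetrically
expanded into tolerance bands: pixels within (expansion − 1)/2 of the line,
i.e. the nearest symmetric rasterization of a nominally `expansion`-wide
band (19 px for the default 20).  Symmetric expansion keeps the Jaccard
index a true set similarity (expanding only one side would make it
asymmetric); one-sided expansion is available via a flag.  A detection is
correct iff its index strictly exceeds 0.8; dataset accuracy is the fraction
of correct detections, and reports include mean and median index per
initialization mode.

## Synthetic study conditions

`synthetic_data` stands in for an annotated multi-subject face dataset.
Defaults (frozen; all intensities on the [0, 1] scale):

| parameter | default | why |
| --- | --- | --- |
| image size | 520 × 545 px | face fills the frame; wrinkle arcs ≈ 110–125 px clear LLT = 100 |
| face ellipse semi-axes | (210, 240) px | portrait-crop face scale |
| wrinkle depth | 0.25 (dataset: U(0.18, 0.30)) | clearly visible but far from saturating |
| wrinkle cross-profile σ | 2.5 px (dataset: U(2.0, 3.0)) | a few-pixel-wide crease |
| skin noise σ | 0.02, band-limited (blur 0.8 px) | mild speckle |
| illumination gradient | 2e−4 /px, horizontal | visible shading, zero second derivative |

Dataset generation randomizes, per fixture and seeded: the face ellipse
center (±8 px) and each semi-axis independently (±5 %), emulating
person-to-person head geometry (aspect-ratio changes are *not* similarity
transforms, so the generic mean shape cannot absorb them); and the wrinkle —
a whole-curve lateral shift within the cheek (U(−0.09, 0.01) of the face
width; the fold's distance from the mouth varies strongly between persons),
endpoint jitter, and interior control-point jitter for curvature variety.
The 68 face landmarks are a fixed template scaled to the ellipse; the 20
wrinkle landmarks are a uniform arc-length resampling of the rendered
centerline, nose end first.

What the fixtures deliberately do **not** emulate: real skin micro-texture
(pores, stubble), multiple or branching wrinkles, shadows and specular
highlights, 3-D pose, and expression-driven non-rigid face deformation.
Passing tests therefore demonstrate correctness of the algorithms and the
claimed ordering of initialization strategies under controlled conditions —
not performance on photographs.

## Numerical choices

* **Histogram equalization is off in the ridge stage by default**
  (`equalize="none"`; `"global"` and `"clahe"` are implemented and
  selectable).  Equalization maps intensities through the cumulative
  histogram of the masked region; when the wrinkle covers only a few percent
  of the masked pixels it is compressed into the darkest histogram tail
  while the dominant skin mode — including its noise — is stretched to full
  range, *inverting* the curvature signal-to-noise ratio.  Equalization
  helps cross-image photometric normalization, not within-image valley
  contrast.
* **Hessian kernels** use a wide truncation (8 σ) so the derivative kernels
  are zero-sum to machine precision; default scale σ = 2 px, single scale
  (an optional multi-scale maximum is deliberately not the default).
* **Turning measurement**: polylines are resampled at 15 px spacing before
  summing |turn angles|; at finer steps the ±0.5 px skeleton quantization
  jitter dominates the measure (a smooth curve would read > π), at 15 px the
  measure matches the generating curve's analytic turning to ~0.3 rad.
  Constructed polylines may carry an explicit turning value.
* **Spur pruning**: side branches shorter than 12 px hanging off skeleton
  junctions are removed (up to 3 rounds) before splitting, so one noisy
  junction cannot fragment the main line below LLT.
* **Mask margin**: the cheek work mask is eroded by 4 px (≈ 2 σ of the ridge
  filter) so mask-boundary and feature edges do not leak into the response.
* **Stopping rule**: relative error improvements below 0.1 % count as "no
  improvement" — a floating-point guard that makes the accept-only-if-lower
  rule a genuine fixed-point test instead of chasing roundoff.
* **Eigenvalue/PCA floors**: shape eigenvalues below 1e−12 of the raw
  coordinate energy (and texture eigenvalues below 1e−12 of the unit
  texture variance) are treated as zero, so identical training shapes yield
  an honestly empty basis.
* **Degenerate inputs**: flipped/collapsed mesh triangles abort a fit step
  (the line search skips that α); a constant image yields a zero texture
  vector; an empty ridge map yields an empty candidate list and the detector
  falls back to the generic mean shape with a flag.

## Known limitations

* The left/right cheek border polygons resolved from the landmark template
  are narrow crescents hugging the jaw and nose-lip lines; the default work
  mask is therefore the coarse cheek quadrilateral minus the nose and mouth
  polygons, which covers the nasolabial region robustly.  The named regions
  remain available and validated.
* The fit's accuracy floor on clean fixtures is ≈ 1 px mean point error;
  texture evidence alone cannot resolve finer displacements at this noise
  level and texture-model richness.
* Candidate selection assumes one dominant wrinkle per cheek; with several
  comparable creases the arc_length × response score may pick a different
  one than a human annotator.
* Training and fitting are single-scale; there is no image pyramid, so
  initializations more than ~15 px off may fall outside the fit's capture
  range (by design, the unique initial shape makes that rare).
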