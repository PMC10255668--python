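# Methods

This note documents the models, algorithms and numerical choices behind
`thermomesh`, the assumptions of its synthetic validation scenes, and the
limits of what the test suite demonstrates.

## Problem setting

An infrared camera measures the skin temperature of a transtibial residual
limb as 240 x 320 rasters of degrees Celsius, seven views stepping 45
degrees around the limb at 120 cm from its axis, once after walking and once
after rest.  A depth-scanner mesh of the same limb (about 16 000 vertices
after clean-up) provides the 3D geometry.  The package's job is to estimate,
for every 2D frame, the 6-DoF camera pose relative to the mesh; to transfer
the thermal images onto the mesh as per-vertex temperatures; to compute the
post-walk minus rest differential map; and to quantify the registration
error intrinsically, using small hollow-cube fiducials ("thermal markers")
glued to the skin that are visible both thermally (ambient air keeps them
colder than skin) and geometrically (they bump out of the scan).

## Colour codec

Temperatures are encoded with a jet colormap saturated at fixed anchors
(28 and 37 degC): `r(x)=clamp(1.5-|4x-3|,0,1)` and cyclic shifts for g and
b, sampled at 256 levels, scaled to 8 bits and rounded half-up.  The
closed form is implementation-independent and reproduces the classic
half-intensity blue/red endpoints.

Decoding must invert colours that do **not** sit on the colormap arc,
because per-vertex blending across views smooths seams and creates new
colours.  The inverse model is a regularized least-squares fit whose basis
is (i) the colour's arc-length coordinate along the continuous jet curve
(nearest of 2048 precomputed samples -- a fixed, data-independent feature
that linearizes the target and keeps extrapolation well-posed at the arc
ends), (ii) a constant, and (iii) Gaussian radial basis functions over
RGB/255 with spread 0.35, grown greedily on the worst training residual.
Training splits the colour table 50/50 at random (seeded) and stops when
the held-out mean squared error reaches 1e-4 degC^2; exhausting the centre
budget (128) raises an error that reports the best MSE.  A pure-RGB
Gaussian basis was tried first and failed the MSE contract on a few percent
of random splits (endpoint extrapolation); the arc feature removed all
failures over 60 splits and brought the worst full-ramp round-trip error to
0.012 degC.  Predictions are clipped to the anchor span, so arbitrary
off-arc colours always decode to a finite in-range temperature.

The colour table itself pools every (temperature, colour) pair of the input
frames, compares temperatures at 0.01 degC resolution, averages the
temperatures that share one colour, and sorts ascending.  Pairs outside the
anchor span are excluded: saturation maps all background (~23 degC) and
cold-fiducial pixels onto the two extreme colours, which is not a 1:1
association and would pull those rows several degrees off the arc.

## Camera model and calibration

Standard pinhole with per-axis focal lengths, principal point, zero skew,
two radial terms `(1 + k1 r^2 + k2 r^4)` and two tangential terms fixed at
zero by default.  Calibration consumes planar-grid correspondences (corner
detection in thermal images is a GUI concern, out of scope): per-view DLT
homographies with Hartley normalization, closed-form intrinsics from the
absolute-conic constraints, extrinsics per view, then joint
Levenberg-Marquardt over intrinsics, distortion and all poses.  Acceptance
follows the sub-pixel rule: mean reprojection error < 1 px.

At the validation conditions (20 views of a 9x5 corner grid, 0.1 px corner
noise) a Cramer-Rao computation gives a principal-point standard deviation
of about 1 px.  Percent-style bounds are therefore asserted on the focal
lengths (scale parameters) and on the principal point normalized by the
focal length; a percent error of an offset coordinate is not statistically
or dimensionally meaningful at these conditions.

## Registration

Per view, in two stages:

1. **Fiducial initialization.**  Pixels within 1 degC of the marker
   temperature form 8-connected blobs (components under 3 px discarded);
   blob centroids are matched one-to-one to the projected marker centres
   under the nominal platform pose (optimal assignment, 30 px gate,
   back-facing markers excluded).  The pose then minimizes the squared
   reprojection error of the matched centres by Levenberg-Marquardt.  With
   exactly three markers the problem is exactly determined and its depth
   direction ill-conditioned, so the pipeline adds a weak prior pulling the
   camera centre toward the nominal platform position (sigma 20 mm) -- the
   rotating platform fixes the camera-to-axis distance at 120 cm, and the
   prior encodes that knowledge without overriding the fiducials in the
   well-conditioned directions.  Without an initial pose (library use), a
   multi-start over coarse viewing directions replaces the platform
   geometry and no prior is applied.

2. **Mutual-information refinement.**  The pose is polished by maximizing
   the MI between the thermal frame and a rendered Lambertian-shading image
   of the mesh (normal dot view direction), the shading being pose-sensitive
   and correlated with the thermal shading of a curved limb.  MI uses a
   32 x 32 equal-width joint histogram over the *full* image: including the
   background rewards silhouette alignment, whereas restricting the
   histogram to the rendered silhouette lets a misaligned pose import cold
   background pixels into its mask and can raise MI at wrong poses (we
   measured exactly this failure).  The optimizer is Nelder-Mead over six
   pose increments (axis-angle radians, translation metres; initial steps
   0.01 rad / 4 mm), restarted once from the best point with quartered
   steps; the best pose ever evaluated -- including the initial one -- is
   returned, so the MI score never decreases.  Basin capture is local by
   design: a 90-degree initial error stays wrong and is reported as such.

## Rendering and texturing

A numba-compiled z-buffer rasterizer projects all vertices through the
distorted camera and scan-converts each triangle over its pixel bounding
box with perspective-correct barycentric interpolation of one scalar
attribute.  It serves three roles: synthesizing thermal frames (attribute =
temperature), shading images for MI, and depth/face-id buffers for
visibility.

A vertex is textured from a view iff it projects inside the image, faces
the camera with cosine above 0.15, passes the z-buffer occlusion test
(tolerance 0.5 mm, covering interpolation error across pixel-sized
triangles), and at least one of its four bilinear neighbour pixels shows a
surface within 2 mm of the vertex's own depth.  The last two thresholds
matter: without the neighbour depth test, background and fiducial-cube
pixels bleed into silhouette and marker-adjacent vertices (raising
recovery RMSE from ~0.01 to ~0.5 degC); without the cosine floor, grazing
pixels whose footprint spans several millimetres of surface sample the
temperature field far from the vertex.  Colours come from the single
best (largest-cosine) view, or -- by default -- from the cosine-weighted
average over all visible views with per-neighbour depth masking; blending
smooths seams and deliberately produces off-arc colours, which is the case
the inverse colour model exists for.  Vertices visible nowhere receive the
reserved sentinel colour (0,0,0) and decode to NaN.

Scan clean-up keeps the largest connected component, drops degenerate and
duplicate faces, removes interior geometry that none of 14 surrounding
viewpoints can see, and decimates by uniform-grid vertex clustering, with
the cell size bisected until the output lands within +/-10% of the target
vertex count.  Clustering was chosen over quadric edge collapse: it is a
few lines of vectorized numpy, handles millions of vertices in seconds,
bounds the geometric error by the cell diagonal (on the order of the
output's edge length), and preserved the Euler characteristic in all
validation runs; its drawback -- isotropic treatment of flat and curved
regions -- is immaterial for smooth limb scans.

## Differential map and accuracy assessment

Both conditions are textured onto the same mesh, so the differential map is
a per-vertex subtraction; NaN propagates.  Colours stretch the jet map
linearly from the observed minimum (first colour) to the maximum (last).

Each fiducial cube has the same temperature in both conditions, so its
neighbourhood in the differential map contains a near-zero "halo".  For
each marker, vertices within 15 mm of the cube centre with |dT| <= 0.3 degC
(about 4x the sensor noise floor) form the halo; the misalignment is the
distance from the cube centre to the halo centroid projected onto the
plane perpendicular to the marker's outward normal -- the halo lies on the
limb surface while the centre sits mid-cube a few millimetres above it, and
only the in-surface component measures registration error.  Markers whose
halo has fewer than 3 vertices are reported missing and excluded.  The
median, standard deviation (n-1) and range over markers summarize the
combined error of registering both conditions.

Hot-spot summaries take connected components of supra-threshold vertices on
the vertex adjacency graph, accumulating one third of each incident face's
area per vertex.

## Synthetic scenes: what they emulate and what they do not

The generator builds a watertight tapered cone (20 cm long, radii 5 to
4 cm) capped by a hemisphere, with 0.1 mm radial vertex jitter as scan
noise, about 16 000 vertices, and five cube-on-disc fiducials (5 mm cubes
on 14 mm x 0.5 mm bases) spread 72 degrees apart in azimuth at varied
heights so every 45-degree view sees at least three.  Cube vertices are
pinned at 26 degC in both conditions (ambient air flows through the hollow
cube); the thin base disc sits in full skin contact and follows the local
skin field.  Skin fields are a base level plus Gaussian bumps in chord
distance (spot radii are small against the limb radius, so chord distance
approximates geodesic distance well): rest = 31 degC with a cooler distal
tip; post-walk = 32.5 degC with peri-knee hot spots reaching ~36 degC, so
the differential map is nowhere near zero except at the fiducials.

Frames render through the calibrated camera model (the default intrinsics
and two-term radial distortion) at 320 x 240, background at the 23 degC
ambient,
plus Gaussian sensor noise of 0.07 degC (the camera's NETD).  True view
poses deviate from the ideal platform geometry by a seeded wobble of 0.5
degrees / 2 mm sd, emulating platform step error and imperfect centring of
the limb on the rotation axis; registration is initialized from the ideal
geometry and must recover the wobble.  All randomness is seeded; geometry,
wobble and sensor noise use independent child streams so the mesh is
reproducible when the noise level changes.

Not emulated: infrared physics (reflection, angular emissivity), soft-tissue
deformation between conditions, scan holes and topological noise, knee
flexion and the optional distal view, and marker self-heating.  Passing the
synthetic suite therefore demonstrates the correctness and numerical
accuracy of the processing chain under rigid geometry and Gaussian noise,
not robustness to the artefacts of real scans.

## Problem sizes and runtimes

Validation uses the full default scene (about 18 000 vertices, 7 views per
condition, both conditions) for the end-to-end accuracy checks and a
5 000-vertex limb for the orchestration tests; the decimation check runs on
a million-vertex sphere.  The complete demonstration -- simulate, process
both conditions, differential map, halo statistics -- takes well under a
minute on one CPU core, and the whole test suite a few minutes.

## Known limitations

- The halo statistic saturates at the marker-vertex geometry when
  registration is much better than a millimetre; sub-0.1 mm medians mean
  "no detectable misalignment", not literal accuracy of that order.
- MI refinement is local (basin of a few degrees / centimetres); it
  depends on the fiducial initialization for capture.
- The PLY reader handles ASCII and binary little-endian files with
  triangular faces (the dialects the package writes and the common scanner
  output), not the full PLY zoo.
- Pose estimation from three fiducials leaves the camera depth direction to
  the platform prior; absolute pose accuracy along the view axis is then
  bounded by the platform geometry, not by the fiducials.
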