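# Methods

This note documents the models, numerical choices and known limitations of
`kneemorph`. Everything here is implemented and exercised by the test
suite; no empirical claim is made beyond what the tests and
`scripts/acceptance.py` compute.

## Data model

All geometry lives on *corresponded* triangle meshes: meshes of the same
bone across subjects share vertex count and face array, so a vertex index
is an anatomical address. Landmarks are therefore stored as vertex-index
sets on a reference template and transferred to any case by pure lookup.
A multi-vertex landmark group (an attachment *area*) reduces to a point as
the centroid of its transferred vertices. Cohort landmark averaging is
done in coordinate space on corresponded vertices, then re-anchored to the
nearest template vertex (nearest-vertex ties break to the lowest index,
everywhere, for determinism). Units are millimetres throughout.

## Cartilage thickness maps

Thickness at a region vertex is measured by casting a ray from the bone
vertex along its angle-weighted vertex normal and taking the first
intersection with the corresponded cartilage surface; where the ray misses
(grazing geometry) the distance to the *corresponding* cartilage vertex is
used, and negative/inward values clamp to zero. Angle-weighted normals are
used because they are insensitive to the varying triangle shapes of
quasi-isometric meshes.

Size normalization is linear in femoral length, measured between two
designated landmark vertices (so distal-only meshes work): each case's map
is rescaled by `mean_length / case_length` *before* per-vertex averaging
(normalize-then-average), and prediction rescales the mean map by
`target_length / mean_length`. Region edges — region vertices with a mesh
neighbor outside the region — are sealed to zero so the predicted surface
meets the bone smoothly. Relative error maps divide by the mean thickness
only where it exceeds 0.05 mm; sealed edges are reported as undefined (NaN)
rather than divided.

## Elastic wrapping

Chains (ligament lines, meniscal and cruciate centerlines) and grids
(ligament membranes, the tendon sleeve) are relaxed to minimize a discrete
spring energy subject to non-penetration:

- **Energy.** Chains: sum of squared segment lengths (zero-rest-length
  springs — the minimizer is the taut string). Grids: fiber (column)
  springs are zero-rest-length, but transverse (row) springs carry the rest
  lengths of the initial ruled surface. With zero-rest transverse springs a
  free membrane contracts laterally and a closed sleeve collapses onto its
  axis; the rest lengths make the flat free-space solution exactly the
  ruled strip while fibers still pull taut around obstacles.
- **Iteration.** Red-black Gauss–Seidel sweeps with over-relaxation
  (omega = 1.9 by default) move each free node toward its spring-optimal
  position; obstacle projection runs after every sweep; a sweep is accepted
  only if the energy does not increase, otherwise the step is halved and
  retried, so the recorded energy trace is non-increasing by construction.
  Plain under-relaxed Jacobi averaging also converges, but its slowest mode
  decays as 1 - O(1/n²) per sweep — about 50 000 sweeps for a 200-node
  chain at the default tolerance — so over-relaxation plus the hierarchy
  below is used instead. Convergence: max node displacement < 1e-4 mm or
  10 000 sweeps (both configurable).
- **Coarse-to-fine.** Chains are solved at ~9 nodes first and repeatedly
  upsampled (arc-length resampling) to the requested count; long-wavelength
  modes converge on the coarse levels where sweeps are cheap. Doubling the
  final node count changes the converged length of the sphere benchmark by
  < 0.5%.
- **Offsets.** `wrap_chain_offset` keeps node *i* at clearance
  `offset[i]` from every obstacle — the primitive behind the meniscal
  h/2 rule and the cruciate minimal-offset constraint. Cruciate offsets
  apply to the connecting nodes *between* spring elements; the endpoint
  anchors are attachments on bone and carry no offset.
- **Penetration handling.** During sweeps, signed distances come from the
  closest surface point and an angle-weighted pseudo-normal blended at its
  barycentric location, with two guards: a point farther away than half the
  obstacle's smallest bounding-box extent is provably outside (a point at
  depth *d* contains a radius-*d* ball), and distances are only resolved
  exactly below the clearance band of interest. Violating nodes move to
  the closest surface point plus the required offset along the outward
  direction, deepest obstacle first. Final corrections (meniscal wedge,
  ligament solids, tube surfaces, converged chains) instead decide
  containment by generalized winding numbers — exact on watertight
  surfaces, robust to the folded slivers that penetration-corrected
  geometry can carry — and fall back to summed multi-obstacle corrections
  when two constraints conflict, so no output vertex remains inside any
  obstacle beyond 1e-6 mm. A point stuck in the crevice between two
  *touching* obstacles (a meniscus sits glued onto the cartilage) cannot
  escape along penetration normals at all; such stragglers are rescued by
  a deterministic direction search — the normal bisector, the seam
  tangents of every violated pair, and a fixed lattice fan, scanned with a
  growing step ladder — accepting the smallest winding-verified feasible
  displacement.

## Menisci

The centerline is wrapped root-to-root at clearance h(s)/2; s is the
normalized cumulative chord length (0 at the anterior, 1 at the posterior
root). At each station a triangular cross-section is placed: the thick
outer edge of vertical extent h(s) at the station, the apex at distance
d(s) toward the meniscal center — the arc-length-weighted centroid of the
centerline projected onto the tibial plateau best-fit plane; the "up"
direction is that plane's normal, giving a consistent wedge orientation.
Consecutive triangles are stitched into a closed wedge (two triangles per
quad per side, the end sections as caps), then penetrating vertices are
projected onto the composite bone–cartilage surface, which fits the wedge
between the cartilage layers. The meniscal center is a single fixed point
per meniscus; a per-node inward direction would also be defensible but the
fixed centroid keeps the construction deterministic and matches the
wedge-ring anatomy of the analog fixtures.

## Ligaments, patellar tendon

Attachment areas become boundary curves by projecting the group onto its
best-fit plane and ordering by polar angle about the centroid (opened at
the widest angular gap; near-collinear groups are ordered along their
principal axis instead), then resampling an interpolating spline. The
insertion curve is reversed when that shortens the fiber columns, which
un-crosses mismatched travel directions. The solid band extrudes the
converged midsurface symmetrically by the ligament's published
mid-substance thickness; both sMCL bundles use the single published sMCL
value. The patellar tendon fits *closed* periodic splines through its
attachment loops, resamples both from the most medial point travelling in
the same rotational sense, and connects corresponding points with a
periodic membrane; no thickness is assigned — the sleeve geometry is the
tendon.

## Cruciates

The centerline is a 15-element spring chain (16 nodes); the default minimal
offset is the mean of the structure's radius profile, standing in for the
ligament's half-width. Radius profiles are polynomials of the relative
course (degree 2 ACL / 4 PCL by default), floored at 0.1 mm. Tubes are
generalized cylinders: tangents by central differences (second-order
one-sided stencils at the ends), Frenet normals where the discrete
curvature exceeds 1e-6 /mm and rotation-minimizing (parallel) transport
elsewhere, with a sign convention keeping successive normals within 90°;
end normals are transported from their interior neighbor because the
one-sided curvature stencil is only first-order. Rings of 24 vertices (by
default) are stitched and the ends capped, giving a watertight tube that
can serve as an obstacle; the built ACL is added to the obstacle set before
the PCL is wrapped. The cruciates run inside the capsule, so their
obstacle set is the osseous–cartilage–meniscus surfaces (plus the ACL tube
for the PCL); the peripheral ligament bands, which the pipeline plasters
onto the bone surfaces, are not cruciate obstacles — including them would
create zero-gap regions with no feasible non-penetrating position. Tube
vertices then get the same winding-exact penetration correction as the
meniscal wedge; radius can exceed the centerline offset (e.g. near
attachments), and a 15-segment polyline cuts corners between nodes by the
chord sagitta l²/8R, so contact-region interpenetration below that
discretization bound is expected and documented rather than repaired.

## Profile fitting and degree selection

Height/width/radius measurements versus relative position are fitted by
least squares in a Chebyshev basis (reported as power-basis coefficients).
The degree is selected by a sensitivity analysis against a deliberately
over-fitted 20th-degree reference: for each degree d the RMSE between the
degree-d fit and the reference on a dense 1000-point grid is computed, and
the selected degree is the first d whose improvement over d-1 falls below
5% of the degree-0 RMSE (an explicit elbow rule; both the reference degree
and the threshold are arguments). When the samples cannot support degree
20 the reference drops to n_distinct - 1. Pooled samples are fitted
directly; per-case aggregation is available upstream of the fit.

## Validation

RMSE, ASD and HD summarize reference-to-predicted nearest-neighbor
distances (one-directional by default, symmetric as an option; HD is the
one-directional maximum). Thickness maps are compared in value space —
per-vertex absolute differences through the same formulas. Leave-one-out
builds the model from all cases but one and pools per-case metrics as
median and (min-max) range. For non-negative distances ASD <= RMSE <= HD
(power-mean inequality), asserted on every report.

## Synthetic cohorts

The generator emulates the statistical role of a corresponded MRI cohort
with three analog bones produced by displacing icosphere templates (exact
correspondence by construction): a distal femur (radius 25 mm sphere with
two condylar lobes), a proximal tibia (flattened ellipsoid with two shallow
articular dips), and a patellar lens, at true anatomical scale so geometric
tolerances transfer. Cartilage = bone + smooth thickness field (2 mm
plateau, smoothstep taper to exactly zero at the region boundary) scaled
linearly with the case's femoral length, plus i.i.d. Gaussian per-vertex
noise; noise is only added where the base field exceeds 0.5 mm —
sub-half-millimetre cartilage is below imaging measurement resolution, and
keeping the taper band noise-free avoids clipping at zero, so the noisy
mask is exactly the i.i.d. regime the closed-form LOO error
sigma*sqrt(n/(n-1)) describes. Femoral lengths are drawn uniformly from
46-54 mm (about +/-8% around the 50 mm template, comparable to adult
femoral-length spread). One pseudorandom stream per case derives from
(seed, case index), so extending a cohort never perturbs earlier cases.
Profile samples come from known truth polynomials at equispaced positions
(slice-wise measurements are equispaced) with 1% noise; the degree-recovery
sampler builds truths in an orthonormal Legendre basis with linearly
declining per-degree RMS amplitudes, because a polynomial whose top-degree
component is negligible has no operationally recoverable degree.

What the fixtures do *not* emulate: real shape variability beyond uniform
scaling, segmentation artifacts, correspondence error, anatomically
accurate attachment footprints, or cartilage loss patterns. Passing tests
therefore demonstrate the correctness and calibration of the machinery,
not clinical accuracy; the study-scale errors reported for real cohorts
cannot be reproduced without the imaging data.

## Problem sizes and statistical power

Default sizes: icosphere subdivisions (4, 4, 3) for femur/tibia/patella,
60 meniscal stations, 30x20 membrane grids, 15 cruciate segments, 24
circumferential tube segments. The leave-one-out calibration experiment
uses the finer femur template (subdivision 5, ~2500 noisy vertices per
case): the per-case RMSE is a chi-like statistic with relative standard
error 1/sqrt(2m), so m must be large enough that the 10% acceptance band
sits many standard errors away — at m~700 it is only ~3.8 s.e. and
occasional seed-level excursions beyond 10% are expected; at m~2500 the
band is ~7 s.e.

## Known limitations

- Menisci are static; meniscal position under knee flexion is out of scope.
- Obstacle projection is quasi-static geometry; no friction, strain or
  material behavior.
- Self-intersecting tubes (radius exceeding the local turn radius) are
  flagged, not repaired.
- The membrane's transverse rest lengths freeze the ruled-surface width;
  strong obstacle-driven spreading of a ligament band is damped
  accordingly.
- Attachment-curve extraction assumes roughly planar attachment areas.
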