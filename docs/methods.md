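# Methods

This note records the geometric model behind `afogen`, the parameter
choices, the numerical decisions, and what the synthetic test bed does and
does not establish about real scans.

## Coordinate conventions

All geometry is in millimetres.  The canonical patient frame is
right-handed with +Z proximal (up the shank), +X anterior (toward the
toes), +Y = Z × X; the sagittal plane is XZ and the coronal plane YZ.
Analysis never relies on the input being expressed in this frame: every
measurement is made in a *shank-fixed frame* derived from the landmarks
themselves (ẑ = leg axis C_T→C_K; ŷ = malleolar line LM−MM orthogonalized
against ẑ; x̂ = ŷ × ẑ, with ŷ and x̂ flipped together if x̂ points away
from heel→MH2).  Because malleoli and condyles belong to the shank, this
frame is invariant under any foot deformity and under any rigid transform
of the whole leg — the measured angles are rigid-transform invariant and
scale invariant by construction.

Deriving the anterior axis from the malleolar line (rather than from
heel→MH2) is a deliberate choice: the heel and MH2 move when the foot is
deformed, and an anterior axis that moves with the foot couples the two
deformity angles.  The malleolar line gives a reference that the foot
rotation cannot perturb.

## Deformity measurement as an exact two-rotation decomposition

The foot's deviation from neutral is modelled as two successive rotations
about axes through the malleolar midpoint C_T: plantarflexion δ about the
malleolar axis ŷ, composed with eversion ε about the anterior axis x̂
(foot pose = R_ŷ(δ)·R_x̂(ε)).  The two measurements invert this
decomposition exactly:

* **Sagittal angle** — the angle in [0°, 180°] between the x̂ẑ-plane
  projections of the foot axis (C_T→MH2) and the leg axis.  Neutral is
  90°; >90° is plantarflexed (drop foot), <90° dorsiflexed.  The foot
  axis points anteriorly so that plantarflexion *increases* the angle:
  sagittal = 90° + δ.
* **Eversion angle** — the plantar-plane normal (through heel, MH1, MH5,
  oriented toward C_K) is first de-rotated about ŷ by −(sagittal − 90°),
  then its signed tilt in the coronal plane is read off:
  ε = atan2(−n·ŷ, n·ẑ).  Positive values mean the sole faces laterally
  (eversion).  De-rotating first, instead of projecting the raw normal
  onto the coronal plane, is what makes the decomposition exact: a raw
  projection mixes tan ε with 1/cos δ and would misread the eversion of a
  strongly plantarflexed foot by over 2° at δ = 30°, ε = 15°.

Both angles are reported in degrees to six decimals.  Degenerate
configurations raise typed errors: coincident landmarks (axis undefined),
collinear plantar landmarks (no plane), projections under 1e-6 in length.

## Neutralization

`correct_dorsiflexion` rotates the foot by (90° − sagittal) about ŷ
through C_T; `correct_eversion` by −ε about x̂; `neutralize` composes them
in that order (the order is part of the contract — the measurement model
above makes the pair an exact inverse of the deformity, so one pass
suffices and `neutralize` is idempotent to machine precision).

The rotation is applied to mesh vertices with a weight that is 1 below
C_T − 20 mm along ẑ, 0 above C_T + 20 mm, and a smoothstep
(3u² − 2u³) in between; the rotation *angle* is scaled by the weight.
Outside the band the motion is rigid (pairwise distances preserved to
1e-6 mm per correction); inside, the smooth falloff trades strict rigidity
for a crease-free ankle.  Foot landmarks (heel, MH1, MH2, MH5) receive the
full rotation; malleoli and condyles are shank landmarks and never move.
A sagittal deviation beyond 60° is rejected as implausible — at that point
the landmarks, not the ankle, are suspect.

## Template geometry and parameters

The shell outline is a boolean keep-predicate over points, assembled from
neutralized landmarks (a pose more than 1° from neutral raises an error
directing the caller to neutralize first):

| parameter | default | role |
|---|---|---|
| malleolar_relief_radius_mm | 30 | open exclusion disc around LM and MM |
| heel_oblique_distance_mm | 60 | sole-level point anterior of the heel anchoring the oblique trim |
| oblique_angle_deg | 45 (fixed) | inclination of the trim plane to the plantar plane |
| clearance_mm | 2 | gap between skin and shell inner surface |
| thickness_mm | 3 | printed wall thickness |
| shank_trim_fraction | 0.8 | shell height as a fraction of \|C_T−C_K\| |
| footplate_toe_margin_mm | 10 | footplate length beyond \|heel−MH2\| |
| footplate_side_margin_mm | 5 | footplate width beyond \|MH1−MH5\| |
| posterior_wrap_fraction | 0.5 | kept fraction of the shank circumference, centered posteriorly |

Linear dimensions scale with the landmarks; radii and margins are absolute
millimetres.  The relief radius and heel offset have no published
reference values; the defaults reflect adult malleolar prominence and
posterior-leaf-spring practice, and every value is overridable in the
design YAML.  The algorithm, not these constants, is the substance.

The heel oblique plane contains the mediolateral direction, passes through
heel + 60 mm·x̂, and falls anteriorly at 45° to the plantar plane (the
45° is enforced against the measured plantar normal, so it is exact —
1e-9 — for any accepted landmark set, not only at perfect neutral).
Points strictly on its anterior-superior side, below the malleolar level,
are excluded; this frees the dorsum of the foot and shapes the flexible
neck between footplate and calf shell.  Boundary ties everywhere use
strict inequality: a point at exactly the relief radius or exactly on the
plane is kept.

## Shell construction

Order: offset the *whole* leg first, then trim, then thicken.  Offsetting
first keeps vertex normals well-defined everywhere (no boundary-normal
artifacts along trim edges).

* **Offset** — each vertex moves by the clearance along its area-weighted
  vertex normal; displacements are halved (up to 10 rounds) on vertices
  whose motion would invert an adjacent triangle.  Non-manifold input is
  refused.
* **Trim** — faces whose centroids fail the keep-predicate are dropped and
  the largest edge-connected component kept.  Centroid-level trimming is a
  resolution-controlled approximation of the template curves: the
  realized boundary is within one edge length of the exact curve.
* **Relief clearance** — centroid trimming can leave boundary-face
  vertices up to an edge length inside a relief disc, and the outward wall
  extrusion can move outer-skin vertices slightly toward a malleolus, so
  the trim/thicken pair is iterated (at most 6 rounds, each removing at
  least one face) until no vertex of the final solid is within
  relief radius − 1 mm of either malleolus.  The 1 mm is the discretization
  allowance of the vertex-level gate.
* **Thicken and seal** — the outer skin is the trimmed shell offset by the
  wall thickness along its vertex normals; boundary loops are stitched
  with two triangles per boundary edge, windings arranged so the solid is
  a consistently oriented closed 2-manifold.  Self-intersections are
  counted (edge-versus-triangle over KD-tree candidate pairs; coplanar
  overlaps without an edge crossing are not counted) and logged as a
  warning, never repaired — repair belongs to print preparation.

Watertightness is defined by edge incidence alone: no boundary edges
(1 face), no non-manifold edges (≥3 faces).  Wall thickness QA casts rays
from seeded area-weighted samples on the inner skin along the outward
normal onto the outer skin (vectorized Möller–Trumbore); the gate requires
≥95 % of samples within thickness ± 0.5 mm.  With a fixed RNG seed the
entire design, including QA, is bit-reproducible.

## Synthetic leg

The generator sweeps a closed surface from knee to toe: a tapered circular
shank (proximal radius 45 mm, distal 35 mm, length 380 mm), a quarter-torus
ankle bend whose outer side forms the heel, and a foot of egg-shaped
cross-section (dorsal half-height equal to the bend radius, plantar drop
30 mm, half-width derived from the requested 80 mm forefoot width) with an
elliptically tapered toe.  Two malleolar bumps (compactly supported
quartic displacement, apex protrusion 10 mm) are raised on the distal
shank.  The construction places the landmarks *exactly* on the analytic
surface and realizes the neutral references exactly: heel, MH1 and MH5 lie
in one horizontal plane, and MH2 sits on the dorsal ridge at the height of
the malleolar midpoint, so the neutral leg measures sagittal = 90.000°,
eversion = 0.000°.  Deformities are applied with the same blended rotation
the alignment stage uses, so recovery error isolates algorithmic error.

Ground-truth landmarks are returned after the deformity and before any
noise.  Vertex jitter emulates scanner noise (it never changes
connectivity, so the mesh stays watertight); a separate landmark-jitter
flag emulates manual marking error.  First-order propagation of 1 mm
isotropic marking error gives ≈1.0° standard deviation in eversion
(√2 mm over the 80 mm MH1–MH5 baseline) and ≈0.3° in the sagittal angle
(over the ≈220 mm foot-axis lever) — the tests check 4σ bounds of exactly
these rates.

What the fixture does *not* emulate: soft tissue, plantar arches, toes,
scan holes or registration artifacts, non-rigid deformity.  Passing the
suite therefore demonstrates correctness of the geometry pipeline on
clean, closed, landmark-consistent input, not robustness to pathological
scans; `validate_mesh` is the gate that real input must pass first.

## Problem sizes and determinism

Default resolutions (64 circumferential × 80 axial stations, ≈10,000
triangles per leg; 500 thickness samples per design) were chosen so a full
design completes in under a second and the complete 5×5 deformity grid —
25 measurements, 25 neutralizations, 25 designed and QA'd shells — runs in
well under a minute.  All randomness (QA sampling, jitter) flows from
explicit integer seeds; identical inputs and seeds give byte-identical STL
and QA output.

## Known limitations

* The eight landmarks are inputs; no automatic landmark detection.
* One-piece (jointless) posterior-shell design only; no articulated
  templates, no lace-eyelet modelling.
* Self-intersection is reported, not repaired; slicing, supports and
  material behaviour of the flexible print polymer are out of scope.
* Vertex welding on read is exact-match only (scan exports duplicate
  triangle vertices bit-identically); meshes needing epsilon merging or
  repair should be cleaned upstream.
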