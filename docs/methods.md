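# Methods

This note records the models, algorithms and numerical choices behind
`vasctree`, including the places where the design was genuinely open and
what the synthetic validation does and does not demonstrate.

## Synthetic volumes

Vessels are painted into a 100 mm cubic volume at 0.6 mm isotropic voxels
(typical CTA acquisition resolution) with the sigmoid cross-profile

    HU(r) = C + C(1/2 − 1/(1 + e^{−a(r−R)}))

so the wall (r = R) sits exactly at C, the axis approaches 1.5·C and the
far field C/2. Defaults C = 150 HU, a = 10 (a sharp, well-contrasted
artery); the background is initialized to the far-field value C/2 so
thresholding behaves identically near and far from vessels. A brush with a
cubic support of half-width 1.5·R max-composes the profile into the
volume; strokes are placed every quarter voxel along the swept curve, so
painting is idempotent and order-independent, and overlapping vessels
merge like contrast-filled lumina rather than adding.

Generators and their analytic ground truth:

* **torus** — circle of radius `R1` in the mid-plane, tube diameter `D`;
  curvature 1/R1, torsion 0; closed-form distance to the centerline.
* **helix** — `(R1 cos t, R1 sin t, bt)` with `b = R2/2π` (`R2` = axial
  rise per full turn); curvature `R1/(R1²+b²)`, torsion `b/(R1²+b²)`.
  The sweep is clipped to at most 1.5 turns inside the volume; the grid
  rejection rule `R1 ≥ 2D`, `R2 ≥ 2D` prevents self-overlap.
* **artificial bifurcation zone (ABZ)** — a trunk along +z (length 20 mm,
  diameter `D_T`) meeting two straight branches (15 mm, `D_1`, `D_2`) at
  the volume center; branch i leaves the trunk axis by `A_i` degrees in
  the x–z plane and is tilted out of it by `A_i_pl`. Reference angles are
  computed from the actual construction vectors, and the reference
  division plane is spanned by the two branch directions (so branch
  coplanarity indices are identically 0 and the trunk index follows the
  literal definition). Parameter ranges mirror cerebral-artery anatomy:
  `A ∈ [15°, 80°]`, tilts ±15°, `D_T ∈ [3.5, 4.5]`, `D_1 ∈ [2.5, 4.2]`,
  `D_2 ∈ [2, 3]` mm; sampling is uniform and independent per field (the
  distribution is not otherwise constrained). The aneurysm weight `wAn`
  is stored but has no geometric effect; an optional spherical aneurysm
  of diameter `D_an` can be placed on the bisector at the apex.

What the phantoms do **not** emulate: acquisition noise, beam hardening,
motion, venous contamination, non-circular lumina, and curvature of real
parent vessels. Passing the validation therefore demonstrates geometric
correctness of the measurement chain at CTA-like resolution and contrast,
not robustness to clinical image quality.

## Preprocessing

All geometry is computed in physical millimetres (point = origin +
index·spacing, 0-based). Inside a user box (VOI) the volume is resampled
to 0.2 mm isotropic with cubic-spline interpolation (the spline
coefficients are prefiltered once; constants and linear ramps are
reproduced to round-off away from borders). Segmentation is a plain lower
threshold; 150 HU (the profile's wall value) for phantom work, with
100–120 HU appropriate for clinical-like data — thin vessels near the
acquisition voxel size can lose connectivity at the wall threshold, which
is why the centerline experiment uses 100 HU. The distance map is the
exact Euclidean distance transform in mm (anisotropy honored); "distance
to the wall" means distance to the nearest background-voxel center, which
carries a documented half-voxel bias relative to the continuous boundary.

## Cross-section measurement

The plane normal comes either from the analytic tangent/tracking
direction or from a two-stage search (two tilt angles refined alternately
by bounded golden-section minimization of the fan area, ~1°; an oblique
plane sees an elliptical, larger section). The center `P_sc` is the
intensity-weighted centroid of the connected in-plane region with values
in the core range `[C_min, C_max]` containing the click. Rays march at
0.1 mm; the border is the sub-step linear interpolation of the first drop
below `O_dv`. Between *touching* vessels (profiles max-compose, so the
inter-vessel saddle only exceeds `O_dv` when the ideal surfaces overlap)
the ray would run through the neighbor; valley detection — a dip of
≥ 25 HU below the running maximum followed by a rise back above `M_min` —
pulls the border to the dip. Border radii are smoothed with a circular
moving average (window 5 of 36 rays). Validated thresholds:
`M_min = 150`, `O_dv = 160`, `C_min = 170`, `C_max = 1500` HU.

Systematic effects at these settings: the border sits where HU crosses
160, i.e. `r = R − 0.027 mm` for a = 10 (≈ −0.05 mm on the diameter), and
the 36-gon fan underestimates the disk area by 0.5 %. The diameter
validation (10 random sites per model over the published torus/spiral
grid) lands at mean per-model RMS ≈ 0.11 mm — sub-voxel for D ≥ 1.5 mm,
with accuracy visibly breaking down at D = 1 mm, where the tube is barely
wider than an acquisition voxel.

## Centerline tracking

The tracker crawls over the ridge of the distance map: step
`Δd = M(P)·f`, then the local in-plane maximum of the tricubic-
interpolated map in the plane perpendicular to the current direction
(projected gradient ascent, tolerance 10⁻³ mm), displacement clamped to a
forward cone of half-aperture `dA` (default 3/2π ≈ 0.48 rad; read as the
aperture in radians). The seed direction is the principal axis of the
local mask, signed toward the endpoint. Crawl rates outside [0.5, 1] warn
— large steps can hop between abutting vessels.

Three mechanisms added around the basic crawl, all deterministic:

* **basin selection** — the in-plane disk is sampled on a polar grid
  first; where a vessel divides the ridge has several basins, and the
  candidate best aligned with the endpoint picks the one to ascend.
  Plain ascent from the predicted point collapses into the widest
  sibling's basin, which is fatal for thin branches.
* **turn-adaptive stepping** — when the best-valued candidate rides the
  disk edge, the step is halved (turn rate per mm doubles), so steep
  take-offs are negotiated at finer arc scale (used where sharp turns
  are expected, e.g. tube tracking; the zone pipeline instead widens the
  cone to 1.2 rad because take-offs reach 80°).
* **refinement** — after tracking, every interior point is re-centered
  to the unconstrained in-plane maximum perpendicular to its chord
  tangent (the ridge invariant made exact), after removing any fold-back
  left by a tight turn.

On the 36-model torus/helix set the tracked points sit 0.02–0.05 mm RMS
from the analytic centerlines — noticeably *below* the published
0.061–0.063 mm level, which is parameter-independent and numerically
equal to the RMS of uniform quantization on the 0.2 mm auxiliary grid
(0.2/√12 ≈ 0.058 mm); a test verifies that snapping our tracked points
to that grid degrades the RMS to exactly this quantization floor. We
keep the sub-voxel search rather than coarsening the tracker to match
the published error floor, and the corresponding accuracy test records
this discrepancy.

## Bifurcation zones

Both curves of a division are tracked downstream from the same trunk
seed, so they are bit-identical along the shared ridge; the split point
`T0` is the midpoint of the last points of the *contiguous* within-d stem
(d = 0.2 mm, the auxiliary voxel). The contiguous reading matters:
tracked curves can brush past each other again inside the junction blob,
and a plain "last point within d" would drag `T0` off the trunk axis.
The stem can also end with one or two shared vertices that have already
turned into the wider branch's root (the ridge of the merged lumen
bulges toward it); since a trunk never turns by more than a few degrees
per step while every anatomical take-off exceeds 15°, the stem is
trimmed back past the first vertex whose direction change exceeds 12°,
which keeps `T0` — and with it the trunk directional vector — on the
vessel axis. A zone whose measured vectors contradict the operator's
seed points (any vector more than 35° from the direction to its own
seed) is rejected as a pipeline failure.
`Br_0` is each branch's first point at least d away from its sibling;
later points follow the centerline at 3 local radii per step — the
spacing constant is a free design choice, and short chords put the
directional-vector endpoints on the junction elbow, inflating angle
errors several-fold. Angles: `BA` between the branch vectors
(`Br_0 → Br_1`), `VA` against the downstream trunk vector
(`Tr_1 → Tr_0`); the coplanarity index is implemented literally
(1 for a vessel parallel to the plane normal, 0 for one lying in the
plane), with the opposite convention available as an option.

Divisions whose branches are nearly collinear with a wide trunk
continuation (take-offs ~15–25° with `D_1 ≈ D_T`) keep a single merged
lumen for several millimetres past the apex; there the steered crawl
fails detectably (divergence, or no split found) rather than returning a
displaced split point, and the validation experiment resamples such
zones with a logged count (about 10–25 % of uniform draws). Over 70
measured zones the mean absolute errors are ≈ 0.7° (BA), ≈ 0.5°
(dominant VA, max ≈ 5°) and ≈ 0.7° (non-dominant VA), with the trunk
coplanarity error around 0.03 — the same signature as the published
validation (dominant branch best, coparallel cases worst).

With an aneurysm present, the zone whose split point lies furthest from
the trunk origin marks the dome's departure from the parent vessel; the
returned division is the furthest zone not involving the aneurysm curve
(curve type 1).

## Spline geometry

Centerlines are resampled at `spacing_factor` × local radius (wide
vessels get fewer control points), grouped into degree-6 Bézier segments
(a joint every 20 resampled points, plus any requested split-point
joints), and fitted by equality-constrained linear least squares:
endpoint interpolation plus C0–C3 continuity, solved per dimension by the
null-space method. Degree 6 is the lowest degree admitting C3 splines
with any number of segments, and C3 is what keeps the torsion function
continuous across joints (the C2-only fit shows torsion jumps on a helix;
a regression test pins this). Fitting uses chord-length parameterization;
the arc-length map is built afterwards by Gauss–Legendre quadrature of
the parametric speed. Curvature and torsion come from the analytic
derivatives; below `κ_floor = 10⁻⁶ rad/mm` the Frénet frame is undefined
and torsion is reported as 0. Arc statistics (`Kmax`, `Kav`, `Tav`, with
`Tav` the mean of |τ| — the sign convention of the published statistic is
not stated) are sampled at 0.05 mm. A side effect of the least-squares
fit is smoothing of tracking noise (tested: fitted radial scatter of a
noisy circle is below the injected noise).

## Problem sizes and determinism

The validation experiments run at the published sizes: 70 bifurcation
zones, 36 centerline models (25 torus + 11 helix, two curves each), and
the full diameter grid (412 torus + 1086 spiral models, 10 sites each);
each processes a cropped VOI around the structure at the 0.2 mm auxiliary
resolution, which keeps the whole suite within minutes on one CPU. All
randomness flows from a single seed through `numpy.random.SeedSequence`
spawning (one child per model/zone), so partial reruns reproduce
bit-for-bit.

## Known limitations

* Trifurcations and multi-trunk divisions are out of scope; only
  two-branch zones are described.
* The cross-section border is polygonal (no sub-pixel active-contour
  refinement) and planes are flat.
* Near-collinear wide-branch divisions are rejected rather than measured
  (see above); clinical use would surface these to the operator.
* Phantom realism limits: see the synthetic-volumes section.
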