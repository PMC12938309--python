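# Methods

## The maneuver model

A C-turn is described by the signed midline curvature field κ(s, t) in the
body frame, with arc length s ∈ [0, 1] normalized by body length L and κ
in units of 1/L (positive = bend toward the fish's left).  Shape follows
from curvature alone: integrating κ gives the bending angle α(s, t), and
integrating the unit tangent (cos α, sin α) gives the head-frame midline
with the snout at the origin and the initial tangent along +x.  This
reconstruction is arc-length preserving by construction, which is what
makes curvature the natural deformation descriptor for both measurement
and simulation input.

### Synthetic curvature fields

No closed-form κ(s, t) exists for real maneuvers, so the generator uses a
parametric surrogate chosen to reproduce the qualitative sequence seen in
high-speed video — a "two peak and one valley" curvature mode evolving in
three phases:

1. **Standing wave** (t/T < bend_end): a Gaussian curvature bump of
   amplitude A and width σ (`bump_width`) grows in place at station
   `s_peak`, with a smaller opposite-sign lobe near the tail
   (`tail_lobe` × A at `tail_center`) producing the counter-swing of the
   caudal peduncle during the bend;
2. **Traveling wave** (bend_end ≤ t/T < recover_end): the bump translates
   tailward at `wave_speed` (L per T) while the tail lobe dies out;
3. **Attenuation**: the amplitude decays smoothly to zero by t = T.

All envelopes are cubic smoothsteps, so κ(s, 0) = κ(s, T) = 0 exactly and
rates vanish at both ends.  Key defaults: A = 5.5–6.0 L⁻¹ held nearly
constant across maneuver sizes while σ grows with the turn angle
(0.085–0.175 L) — this is the mechanism behind the observed κ_max
invariance: larger turns recruit more body, they do not bend any segment
harder.  T spans 0.195–0.224 s and L = 3.60 cm, matching adult zebrafish.

### Pose track

The world-frame trajectory is prescribed, not solved — the hydrodynamics
that would produce it is out of scope.  The heading runs from ψ₀ to ψT by
a cubic smoothstep over the bending+recovery window (so the total heading
change is exact and usable as ground truth), and the **planform centroid**
follows a straight-ahead track whose speed ramps linearly from
u₀ · (L/T) to twice that value.  Anchoring the centroid rather than the
head matters: the centroid is what a silhouette experiment tracks, and
pinning the head instead makes the apparent centroid speeds unphysically
large as the body sweeps around it.

### Rendering

Frames are rasterized by thickening the world-frame midline by half the
top-view width w(s)/2 on each side of the local normal and filling the
polygon dark-on-light (foreground 40, background 200, 8-bit, no
anti-aliasing; optional Gaussian sensor noise).  Defaults: 512×512 px at
0.014 cm/px.  The scale is set by the *whole-maneuver* footprint: a 156°
turn sweeps a fan of roughly body-length radius plus the centroid travel
(~6.6 cm), so a finer scale cannot keep all frames of the largest maneuver
inside a 512-px frame with a fixed camera.  The fish spans ~257 px.  A
minimum half-width of 1 px keeps the rasterized peduncle connected — the
four-digit width law has an open trailing edge that would otherwise pinch
to a fraction of a pixel and detach the caudal fin (real silhouettes never
pinch to zero).

## Body geometry

Height h(s) (lateral view): semi-ellipse over the head, linear taper to
the torso plateau h₂, plateau, linear taper to the fin plateau h₃.  The
junction value h₁ is defined as the ellipse value at s₁, so h is
continuous by construction.  Defaults place the ellipse apex at the s₁
junction (a = s₁ = 0.30, b = 0.07) so the profile rises monotonically onto
the torso — setting a < s₁/2 would pinch the profile to zero mid-body.

Width w(s) (top view): the four-digit NACA thickness polynomial
(coefficients 0.2969, −0.1260, −0.3516, +0.2843, −0.1015) on the rescaled
chord s/s₄, scaled by w₁/0.2 (peak width w₁/2 near s = 0.3 s₄); constant
plate width w₂ on the fin s ≥ s₄.  A step at s₄ is permitted — the law's
trailing-edge value need not equal w₂ and the defaults leave a visible
one.  All parameter defaults are package choices (no measured values are
published for them) and are overridable from JSON.

Cross-sections are ellipses with semi-axes w/2 and h/2 on the torso and
peduncle and thin w₂ × h rectangles on the fin.  The volumetric lattice
uses equal-area polar rings per elliptical section (angular phases offset
so the point set is mirror-symmetric in both section axes) and a tensor
grid on the fin plate; per-point weights are section-area quadrature
weights times the slab thickness and sum to the body volume (within ~0.1%
of 1-D quadrature at 60 sections).

## Midline extraction

Per frame: threshold (default "mean-gap": iterated intermeans, i.e. the
threshold midway between the mean gray of background and fish; Otsu and
manual available) → largest connected component → hole filling →
morphological skeleton → longest endpoint-to-endpoint geodesic (Dijkstra
on the 8-connected pixel graph, diagonal steps √2; this prunes spur
branches implicitly) → tangent extension of both ends to the body
extremities (least-squares tangent over the terminal 12 px) → re-centering
of the path onto the silhouette's local symmetry axis (midpoint of the two
boundary crossings along each point's normal, tapered to zero at the tips)
→ cubic smoothing spline (residual budget 0.5 px) resampled at n_s = 100
equal arc-length nodes, converted to a right-handed cm frame.

The re-centering step is what makes heading estimates unbiased: raw
skeletons deflect systematically by ~1° near the wide rounded head, which
otherwise propagates directly into the turning angle.  Head/tail
orientation uses the distance-transform width of the two path ends
(head = wider), overridden by temporal continuity when a previous frame
exists; a near-tie raises a low-confidence flag.

Curvature from extracted midlines differentiates the unwrapped tangent
angle along s (second-order differences), optionally after a cubic
Savitzky–Golay filter on θ(s).  Maneuver-level summaries default to window
21 (of 100 nodes) and evaluate the deformation metrics α_max and κ_max on
the interior s ∈ [0.05, 0.92]: the terminal nodes are tangent
extrapolations whose curvature is measurement artifact, and the thin
caudal fin (rendered only 2–5 px wide) dominates the error budget there.

Measured fidelity on noiseless synthetic video (the tests compute these):
ϕ within ±0.6°, midline Hausdorff distance < 1% of L, measured length
stable within ~1.5%, α_max within ±4°, κ_max within +9% of the generated
amplitude.

## Phase segmentation

Frames are labeled glide / bending / recovery from the α_max(t) track and
the head angular velocity.  Because α_max(t) is nearly flat during the
traveling-wave phase, "peak bend" is defined as the first frame reaching
97% of the track maximum (after a 3-frame moving average), not the strict
argmax; bending ends there.  Glide thresholds: |ω| < 30 deg/s and
α_max < 0.15 rad — the boundary is not sharply defined by the data and
both are configurable.  Disjoint excursions above 80% of the peak
separated by a dip below 60% flag a multi-peak (non-C) maneuver.

## Velocities, Reynolds number, added mass

Centroid speeds use the silhouette area centroid (what the experiment can
measure; a volume-weighted 3D option exists for simulation-side checks),
central differences in time, normalized by U = L/T.  ω_ave = ϕ/T by
definition.  Re = ρL²/(μT) with water defaults ρ = 998 kg/m³,
μ = 1.00 × 10⁻³ Pa·s (20–25 °C); L is converted from cm internally.  The
added-mass force estimate is slender-body: sectional added mass
m(s) = ρπ(h/2)² (cylinder in lateral motion, height as diameter) applied
to the head-frame lateral midline velocity, F = −d/dt ∫ m V ds.  It is a
kinematic order-of-magnitude estimate, not a CFD force.

## Cohort generator and statistics

Each synthetic trial draws ϕ uniformly on [30°, 220°] and sets
α_max = 71° (flat) below 60° and 20° + 0.85ϕ above, with 8° Gaussian
noise; κ_max = 6 L⁻¹ with 2% noise (the ceiling); u₀ means 0.15 / 0.35
below/above 140° with 0.05 noise; u_m and u_e ride 0.25 and 0.10 above u₀.
The linear-law coefficients are package choices shaped to the qualitative
description of the published scatter (flat-then-linear, elevated initial
speed for large turns); no numeric regression coefficients are published
to pin them to.  Inference is resampling-based throughout: OLS slope with
2-SE recovery checks, a 10⁴-permutation test for the κ_max trend, and a
10⁴-resample bootstrap CI for the u₀ regime difference — all seeded and
reproducible.

## Deformation export

The straight lattice (s, η, ζ) maps to midline(s) + η·normal(s) with ζ
unchanged — a planar bend with zero twist, sections exactly perpendicular
to the midline.  Volume weights pick up the bending Jacobian 1 − ηκ;
because sections are symmetric in η the lattice total is conserved
identically, and the per-point weights warn when |κ|·w/2 ≥ 1 (section
planes crossing).

Momentum correction treats the straight-pose weights as material (mass)
weights, constant in time.  Step 1 translates every frame's mass centroid
to the origin (zero linear momentum under any linear differencing).  Step
2 iteratively removes residual rigid rotation: compute the angular
momentum of the centrally differenced motion, integrate the counter
rotation rate −L_z/I_z (trapezoid), rotate the frames, repeat to
tolerance.  Step 3 subtracts the exact remaining rigid velocity field
(solving the 3×3 inertia system) so the stored (positions, velocities)
pairs have net linear and angular momentum at machine zero on every frame.
Pure rigid inputs come back stationary.  Velocity differencing is central
with one-sided ends.  Vertex files are plain text (point count header +
one x y z triple per line, 14 significant digits) with a JSON manifest —
the point-cloud body description an immersed-boundary front end consumes.

## Problem sizes

Defaults are sized for complete desk-side runs: 40-frame maneuvers at
512×512, 100-node midlines, ~3 × 10³-point lattices, 80-trial cohorts,
10⁴ resamples.  All are parameters, not limits.

## Known limitations

- The synthetic trajectory has no hydrodynamic feedback; prescribed
  heading/speed profiles are smooth surrogates, so the pipeline's accuracy
  on real video (occlusions, fin shadows, dorsal-ventral asymmetry,
  camera distortion) is not demonstrated by these tests.
- The curvature surrogate is a single-bump family; real maneuvers show
  richer multi-segment patterns, and S-starts are out of scope.
- Top view only; no 3D reconstruction, no multi-fish tracking.
- The added-mass estimate ignores three-dimensional and vortex effects
  entirely.
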