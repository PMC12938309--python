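# cturnkit

Analysis chain for **C-type turning maneuvers (C-turns)** in small
carangiform swimmers such as adult zebrafish (*Danio rerio*).  A C-turn is
a rotation-dominated escape maneuver (~0.2 s) in which the fish bends into
a "C" and swings back, reorienting by anywhere from 30° to over 200°.

The package covers the full desk-side workflow around such experiments:

1. **Synthesis** — generate top-view silhouette video of a
   curvature-driven body whose bending follows the canonical C-maneuver
   sequence (standing curvature wave → traveling wave → attenuation), so
   every downstream stage has exact ground truth;
2. **Midline extraction** — binarize 8-bit grayscale frames, skeletonize
   the silhouette, re-center and smooth the path, and resample it at equal
   arc-length nodes;
3. **Kinematics** — signed curvature κ(s, t) (units of 1/L, arc length s
   normalized by body length L), the head-frame reconstruction

       α(s, t) = ∫₀ˢ κ(s′, t) ds′,    (x, y)(s, t) = ∫₀ˢ (cos α, sin α) ds′,

   the total turning angle ϕ between initial and final head directions,
   deformation amplitude α_max, curvature ceiling κ_max, normalized
   centroid speeds u₀/u_m/u_e (in units of U = L/T), angular velocities
   ω_ave = ϕ/T and ω_m, and the maneuver Reynolds number
   Re = ρUL/μ = ρL²/(μT);
4. **Cohort statistics** — the population structure of repeated trials:
   α_max is flat for ϕ ∈ [30°, 60°] and linear in ϕ for [60°, 220°], κ_max
   is constant (a physiological ceiling — larger turns engage more of the
   body, not a tighter bend), and initial speed u₀ jumps at the 140°
   boundary between moderate and large turns;
5. **Export** — curvature-prescribed 3D body configurations (parametric
   height/width body model: NACA0016-style width law, elliptical sections,
   trapezoidal caudal-fin plate) with cross-sections perpendicular to the
   midline, volume-conserving weights, momentum/angular-momentum-corrected
   deformation velocities, and plain-text vertex files for
   immersed-boundary solvers.

## Worked example

The numbered scripts under `analysis/` run the chain end to end.
`analysis/02_extract_kinematics.py` synthesizes the three packaged
maneuvers (67.0°, 108.8°, 156.3°), extracts midlines, and prints:

```
turn_small: phi = 67.3 deg (prescribed 67.0), alpha_max = 70.7 deg, kappa_max = 5.55/L, u0 = 0.11, omega_ave = 300 deg/s, Re = 5774
turn_mid: phi = 108.4 deg (prescribed 108.8), alpha_max = 102.5 deg, kappa_max = 6.22/L, u0 = 0.15, omega_ave = 516 deg/s, Re = 6159
turn_large: phi = 156.2 deg (prescribed 156.3), alpha_max = 140.8 deg, kappa_max = 6.52/L, u0 = 0.33, omega_ave = 801 deg/s, Re = 6633
```

Each line is one maneuver measured purely from its rendered video: the
recovered yaw angle ϕ lands within half a degree of the prescribed truth,
the bending amplitude α_max grows with ϕ while the curvature ceiling
κ_max stays near 6/L, the large turn starts ~2× faster (u₀ = 0.33 vs
0.11–0.15), and Re ≈ 6 × 10³ sits in the inertial regime typical of such
maneuvers (10³–3 × 10⁴).

`analysis/03_cohort_statistics.py` repeats the logic at population scale
(80 trials): an OLS fit over ϕ ∈ [60°, 220°] recovers the generator's
α_max–ϕ slope (0.830 vs 0.85, R² = 0.97), the κ_max trend is not
significant (permutation p = 0.09), and the u₀ difference across the 140°
split is 0.19 with a bootstrap CI well clear of zero.

The same calls are available as library functions:

```python
import cturnkit as ck

tpl = ck.maneuver_template("turn_large")      # 156.3 deg fixture
fld, pose, seq = ck.synthesize_maneuver(tpl)  # curvature, pose, video
midlines, masks, _ = ck.extract_midlines(seq)
phi, sign = ck.turning_angle(midlines)        # 156.2, +1
```

## Layout

- `src/cturnkit/` — the library: `synthetic` (generator), `geometry`
  (body model), `midline` (image pipeline), `kinematics` (maneuver
  metrics), `cohort` (population statistics), `export` (IB hand-off),
  `fixtures` (packaged maneuvers), `io` (stacks/CSV).
- `analysis/` — numbered drivers writing tables under `results/`.
- `docs/methods.md` — models, parameter choices, numerical details and
  known limitations.
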