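"""Forward generator for C-maneuver test data.

Because no recorded video ships with the package, every downstream stage is
exercised against synthetic maneuvers built from first principles:

* a parametric curvature field kappa(s, t) reproducing the canonical
  C-maneuver sequence — a standing curvature wave growing at a fixed
  mid-body station, a traveling wave whose peak propagates tailward, and
  final attenuation back to a straight body — with a tail counter-swing
  lobe of opposite sign during the bend;
* a prescribed world-frame pose track (smoothstep heading, ramped speed);
  the fluid dynamics that would produce it in reality are out of scope, so
  the trajectory is an input, not an output;
* a silhouette renderer that sweeps the top-view half-width along the
  reconstructed midline and rasterizes it dark-on-light at 8 bit;
* a cohort generator emulating the population structure of repeated trials
  (bending amplitude flat below a 60 deg yaw, linear above; elevated
  initial speed above a 140 deg yaw; near-constant curvature ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .geometry import BodyGeometry, width_profile
from .kinematics import CurvatureField, integrate_curvature
from .midline import FrameSequence

__all__ = [
    "ManeuverTemplate",
    "WorldPoseTrack",
    "CohortSpec",
    "ImageConfig",
    "make_cturn_curvature",
    "make_pose_track",
    "render_silhouette",
    "make_cohort",
    "synthesize_maneuver",
    "true_midline_world",
]


def smoothstep(x):
    """Cubic smoothstep 3x^2 - 2x^3, clamped; zero slope at both ends."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class ManeuverTemplate:
    """Parameters of one synthetic C-maneuver.

    Lengths in cm, times in s, curvature amplitude in 1/L.  The curvature
    bump is a Gaussian in s of width ``bump_width``; larger turns engage a
    wider stretch of the body (wider bump) rather than a higher amplitude,
    consistent with a physiological curvature ceiling.
    """

    L: float = 3.60            # body length, cm
    T: float = 0.195           # maneuver duration, s
    n_s: int = 200             # midline samples
    n_t: int = 40              # frames
    A: float = 6.0             # peak dimensionless curvature amplitude, 1/L
    s_peak: float = 0.45       # arc-length station of the curvature peak
    bump_width: float = 0.14   # Gaussian sigma of the curvature bump, L units
    wave_speed: float = 1.2    # tailward peak speed, L per T
    phase_fractions: Tuple[float, float] = (0.35, 0.65)  # (bend_end, recover_end)/T
    psi0: float = 0.0          # initial head heading, deg
    psiT: float = 156.3        # final head heading, deg
    u0_frac: float = 0.25      # initial centroid speed / (L/T)
    tail_lobe: float = 0.35    # counter-swing lobe amplitude, fraction of A
    tail_center: float = 0.88  # counter-swing lobe station
    tail_width: float = 0.06   # counter-swing lobe sigma
    seed: int = 0

    def __post_init__(self):
        b, r = self.phase_fractions
        if not (0.0 < b < r <= 1.0):
            raise ValueError("phase fractions must satisfy 0 < bend_end < recover_end <= 1")
        if self.A < 0:
            raise ValueError("curvature amplitude A must be >= 0")
        if self.n_s < 50 or self.n_t < 30:
            raise ValueError("need n_s >= 50 and n_t >= 30")
        if min(self.L, self.T) <= 0:
            raise ValueError("L and T must be positive")

    @property
    def turn_sign(self) -> int:
        """+1 for a left (CCW, psiT > psi0) turn; the bend sign follows it."""
        return 1 if self.psiT >= self.psi0 else -1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WorldPoseTrack:
    """Prescribed world-frame pose: centroid position (cm) and heading (deg).

    The position track anchors the body's planform (area) centroid — the
    quantity a silhouette experiment actually tracks — not the head; the
    head sweeps around it as the body bends.
    """

    t: np.ndarray               # (n_t,) s
    position: np.ndarray        # (n_t, 2) cm, planform centroid
    heading: np.ndarray         # (n_t,) deg, unwrapped

    def __post_init__(self):
        step = np.abs(np.diff(self.heading))
        if step.size and step.max() >= 90.0:
            raise ValueError("heading track has wrap artifacts (step >= 90 deg)")


def make_cturn_curvature(template: ManeuverTemplate) -> CurvatureField:
    """Curvature field kappa(s, t) for one C-maneuver.

    Three phases over normalized time tau = t/T with phase fractions
    (tau1, tau2): (i) tau < tau1 the bump amplitude grows in place at
    ``s_peak`` (standing wave) while a counter-swing lobe of opposite sign
    grows near the tail; (ii) tau1 <= tau < tau2 the bump translates
    tailward at ``wave_speed`` and the tail lobe dies out (traveling wave);
    (iii) tau >= tau2 the amplitude decays smoothly to zero by t = T
    (attenuation).  Peak |kappa| over the field equals A (up to grid
    sampling); kappa(s, 0) = kappa(s, T) = 0.
    """
    tp = template
    tau1, tau2 = tp.phase_fractions
    s = np.linspace(0.0, 1.0, tp.n_s)
    t = np.linspace(0.0, tp.T, tp.n_t)
    tau = t / tp.T

    amp = np.where(
        tau < tau1,
        smoothstep(tau / tau1),
        np.where(tau <= tau2, 1.0, smoothstep((1.0 - tau) / (1.0 - tau2))),
    )
    center = np.where(
        tau < tau1,
        tp.s_peak,
        np.minimum(tp.s_peak + tp.wave_speed * (tau - tau1), 0.92),
    )
    # tail counter-swing: present during the bend, gone before the main
    # peak arrives in the caudal region
    tail_env = amp * (1.0 - smoothstep((tau - tau1) / max(tau2 - tau1, 1e-9)))

    S = s[None, :]
    main = amp[:, None] * np.exp(-0.5 * ((S - center[:, None]) / tp.bump_width) ** 2)
    tail = (tp.tail_lobe * tail_env[:, None]
            * np.exp(-0.5 * ((S - tp.tail_center) / tp.tail_width) ** 2))
    kappa = tp.turn_sign * tp.A * (main - tail)
    return CurvatureField(s_grid=s, t_grid=t, kappa=kappa)


def make_pose_track(template: ManeuverTemplate) -> WorldPoseTrack:
    """Prescribed centroid pose: smoothstep heading, linearly ramped speed.

    The heading goes from psi0 to psiT via a cubic smoothstep over the
    bending+recovery window [0, recover_end*T], so psi(T) - psi(0) equals
    psiT - psi0 exactly and the angular rate vanishes at both ends.  The
    centroid speed ramps linearly from ``u0_frac * L/T`` to twice that
    value; position integrates speed along the instantaneous heading.
    """
    tp = template
    _, tau2 = tp.phase_fractions
    t = np.linspace(0.0, tp.T, tp.n_t)
    tau = t / tp.T
    psi = tp.psi0 + (tp.psiT - tp.psi0) * smoothstep(tau / tau2)
    U = tp.L / tp.T
    speed = tp.u0_frac * U * (1.0 + tau)
    psi_rad = np.radians(psi)
    vel = speed[:, None] * np.column_stack([np.cos(psi_rad), np.sin(psi_rad)])
    pos = np.zeros_like(vel)
    dt = t[1] - t[0]
    pos[1:] = np.cumsum(0.5 * (vel[1:] + vel[:-1]) * dt, axis=0)
    return WorldPoseTrack(t=t, position=pos, heading=psi)


def true_midline_world(fld: CurvatureField, pose: WorldPoseTrack,
                       L: float, frame: int,
                       geom: Optional[BodyGeometry] = None) -> np.ndarray:
    """Ground-truth world-frame midline (cm) for one frame.

    The head-frame midline (head at origin, tangent along +x pointing
    tailward) is rotated so the fish faces the heading direction — the body
    trails opposite the heading — and translated so the planform (width-
    weighted) centroid sits on the pose track.
    """
    if geom is None:
        geom = BodyGeometry(L=L)
    _, x, y = integrate_curvature(fld.kappa[frame], fld.s_grid)
    w = width_profile(geom, fld.s_grid)
    cx = np.trapezoid(w * x, fld.s_grid) / np.trapezoid(w, fld.s_grid)
    cy = np.trapezoid(w * y, fld.s_grid) / np.trapezoid(w, fld.s_grid)
    psi = np.radians(pose.heading[frame])
    c, si = np.cos(psi), np.sin(psi)
    # facing psi means the tailward body axis points along psi + pi
    bx = -(c * (x - cx) - si * (y - cy)) * L
    by = -(si * (x - cx) + c * (y - cy)) * L
    return pose.position[frame] + np.column_stack([bx, by])


@dataclass(frozen=True)
class ImageConfig:
    """Rasterization settings for silhouette rendering."""

    shape: Tuple[int, int] = (512, 512)   # (H, W) px
    scale: float = 0.014                  # cm per px (frame ~7.2 cm across)
    fg: int = 40                          # fish gray level
    bg: int = 200                         # background gray level
    noise_sd: float = 0.0                 # Gaussian sensor noise, gray levels
    seed: int = 0
    auto_center: bool = True              # center the maneuver in the frame
    min_halfwidth_px: float = 1.0         # silhouette floor; keeps the thin
                                          # peduncle connected when rasterized


def _ribbon_polygon(mid: np.ndarray, half_width: np.ndarray) -> np.ndarray:
    """Closed planform polygon: midline offset by +-half_width along normals."""
    d = np.gradient(mid, axis=0)
    nrm = np.linalg.norm(d, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    tang = d / nrm
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    left = mid + half_width[:, None] * normal
    right = mid - half_width[:, None] * normal
    return np.vstack([left, right[::-1]])


def render_silhouette(fld: CurvatureField, pose: WorldPoseTrack,
                      geom: BodyGeometry, cfg: ImageConfig = ImageConfig(),
                      dt: Optional[float] = None) -> FrameSequence:
    """Rasterize a maneuver into an 8-bit top-view silhouette stack.

    Each frame reconstructs the midline from kappa(., t), places it rigidly
    by the pose track, thickens it by half the top-view width on each side
    of the local normal, and fills the resulting polygon dark-on-light
    (no anti-aliasing, so noiseless output is two-level).  Raises if the
    body leaves the image bounds, reporting the frame index.
    """
    n_t = fld.t_grid.size
    if pose.t.size != n_t:
        raise ValueError("pose track and curvature field frame counts differ")
    hw = 0.5 * width_profile(geom, fld.s_grid) * geom.L
    hw = np.maximum(hw, cfg.min_halfwidth_px * cfg.scale)
    polys = [
        _ribbon_polygon(true_midline_world(fld, pose, geom.L, i, geom=geom), hw)
        for i in range(n_t)
    ]
    H, W = cfg.shape
    allpts = np.vstack(polys)
    if cfg.auto_center:
        lo, hi = allpts.min(axis=0), allpts.max(axis=0)
        mid_cm = 0.5 * (lo + hi)
        # world point mapping: col = (x - x0)/scale, row = (y0 - y)/scale
        x0 = mid_cm[0] - 0.5 * W * cfg.scale
        y0 = mid_cm[1] + 0.5 * H * cfg.scale
    else:
        x0, y0 = 0.0, H * cfg.scale

    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((n_t, H, W), dtype=np.uint8)
    for i, poly in enumerate(polys):
        cols = (poly[:, 0] - x0) / cfg.scale
        rows = (y0 - poly[:, 1]) / cfg.scale
        if (cols.min() < 0 or cols.max() > W - 1
                or rows.min() < 0 or rows.max() > H - 1):
            raise ValueError(f"body exits image bounds at frame {i}")
        img = np.full((H, W), float(cfg.bg))
        rr, cc = draw_polygon(rows, cols, shape=(H, W))
        img[rr, cc] = cfg.fg
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    if dt is None:
        dt = float(fld.t_grid[1] - fld.t_grid[0])
    # origin: world point mapping to image-frame (x, y-up) coordinate zero,
    # i.e. extracted_cm = world_cm - origin
    return FrameSequence(frames=frames, dt=dt, scale=cfg.scale,
                         meta={"fg": cfg.fg, "bg": cfg.bg,
                               "noise_sd": cfg.noise_sd,
                               "origin": (float(x0), float(y0))})


def synthesize_maneuver(template: ManeuverTemplate,
                        geom: Optional[BodyGeometry] = None,
                        cfg: ImageConfig = ImageConfig()):
    """Template -> (curvature field, pose track, silhouette frames)."""
    if geom is None:
        geom = BodyGeometry(L=template.L)
    fld = make_cturn_curvature(template)
    pose = make_pose_track(template)
    seq = render_silhouette(fld, pose, geom, cfg)
    return fld, pose, seq


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a repeated-trials cohort.

    Yaw angles are uniform over ``phi_range``; the bending amplitude is
    flat (``alpha_flat``) below 60 deg and linear (``alpha_intercept +
    alpha_slope * phi``) above; the normalized initial speed jumps from
    ``u0_small`` to ``u0_large`` at a 140 deg yaw; the curvature ceiling is
    constant up to small noise.
    """

    n_trials: int = 80
    phi_range: Tuple[float, float] = (30.0, 220.0)
    alpha_slope: float = 0.85          # deg alpha per deg phi
    alpha_intercept: float = 20.0      # deg
    alpha_flat: float = 71.0           # deg, constant below the 60 deg split
    noise_sd_alpha: float = 8.0        # deg
    u0_small: float = 0.15             # mean u0 below 140 deg, L/T units
    u0_large: float = 0.35             # mean u0 at/above 140 deg
    noise_sd_u: float = 0.05
    kappa_ceiling: float = 6.0         # 1/L
    kappa_cv: float = 0.02             # relative sd of the ceiling
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        lo, hi = self.phi_range
        if not (30.0 <= lo < hi <= 220.0):
            raise ValueError("phi_range must lie within [30, 220]")
        if min(self.noise_sd_alpha, self.noise_sd_u, self.kappa_cv) < 0:
            raise ValueError("noise SDs must be >= 0")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per trial: phi, alpha_max, kappa_max, speeds, angular rates,
    and the moderate/large regime label (140 deg split).  Reproducible under
    a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    phi = rng.uniform(*spec.phi_range, size=spec.n_trials)
    alpha = np.where(
        phi < 60.0,
        spec.alpha_flat,
        spec.alpha_intercept + spec.alpha_slope * phi,
    ) + rng.normal(0.0, spec.noise_sd_alpha, size=spec.n_trials)
    u0 = np.where(phi < 140.0, spec.u0_small, spec.u0_large)
    u0 = np.abs(u0 + rng.normal(0.0, spec.noise_sd_u, size=spec.n_trials))
    um = u0 + 0.25 + np.abs(rng.normal(0.0, spec.noise_sd_u, size=spec.n_trials))
    ue = u0 + 0.10 + np.abs(rng.normal(0.0, spec.noise_sd_u, size=spec.n_trials))
    T = np.clip(rng.normal(0.21, 0.012, size=spec.n_trials), 0.19, 0.23)
    omega_ave = phi / T
    omega_m = omega_ave * (1.8 + rng.normal(0.0, 0.1, size=spec.n_trials))
    kappa_max = spec.kappa_ceiling * (
        1.0 + rng.normal(0.0, spec.kappa_cv, size=spec.n_trials))
    return pd.DataFrame({
        "phi": phi,
        "alpha_max": alpha,
        "kappa_max": kappa_max,
        "u0": u0,
        "um": um,
        "ue": ue,
        "omega_ave": omega_ave,
        "omega_m": omega_m,
        "regime": np.where(phi >= 140.0, "large", "moderate"),
    })
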