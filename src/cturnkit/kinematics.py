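"""Turning-maneuver kinematics.

Quantities are built around the dimensionless midline description: arc
length ``s`` in [0, 1] (normalized by body length L) and signed curvature
``kappa(s, t)`` in units of 1/L, positive for a bend toward the fish's left.
The bending angle is the running integral

    alpha(s, t) = integral_0^s kappa ds',

and the head-frame midline follows by integrating the unit tangent
``(cos alpha, sin alpha)``.  The maneuver-level metrics are the total
turning (yaw) angle ``phi`` between initial and final head directions, the
deformation amplitude ``alpha_max``, the curvature ceiling ``kappa_max``,
centroid speeds normalized by the characteristic velocity ``U = L/T``, head
angular velocities, and the maneuver Reynolds number
``Re = rho U L / mu = rho L^2 / (mu T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import savgol_filter

from .geometry import BodyGeometry, height_profile

__all__ = [
    "CurvatureField",
    "ManeuverKinematics",
    "curvature_from_midline",
    "integrate_curvature",
    "turning_angle",
    "head_heading",
    "heading_track",
    "alpha_max_track",
    "kappa_max_of",
    "summarize_maneuver",
    "segment_phases",
    "centroid_velocities",
    "angular_metrics",
    "reynolds",
    "added_mass_force",
]

RHO_WATER = 998.0      # kg/m^3, fresh water at ~21 C
MU_WATER = 1.00e-3     # Pa s


@dataclass
class CurvatureField:
    """Signed midline curvature kappa(s, t) on a regular (s, t) grid.

    ``s_grid`` is normalized arc length in [0, 1]; ``t_grid`` is in seconds;
    ``kappa`` has shape (n_t, n_s) in units of 1/L, left-positive.
    """

    s_grid: np.ndarray
    t_grid: np.ndarray
    kappa: np.ndarray

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.shape != (self.t_grid.size, self.s_grid.size):
            raise ValueError("kappa must have shape (n_t, n_s)")
        if not np.all(np.isfinite(self.kappa)):
            raise ValueError("kappa must be finite everywhere")

    @property
    def kappa_max(self) -> float:
        return float(np.abs(self.kappa).max())


@dataclass
class ManeuverKinematics:
    """Per-trial derived quantities for one C-maneuver."""

    phi: float                      # total turning angle, deg (magnitude)
    phi_sign: int                   # +1 = CCW (left) turn, -1 = CW
    alpha_max: float                # max |alpha(s,t)|, deg
    kappa_max: float                # max |kappa|, 1/L
    T: float                        # maneuver duration, s
    u0: float                       # initial centroid speed / (L/T)
    um: float                       # max centroid speed / (L/T)
    ue: float                       # final centroid speed / (L/T)
    omega_ave: float                # phi / T, deg/s
    omega_m: float                  # max |omega(t)|, deg/s
    Re: float                       # Reynolds number rho L^2 / (mu T)
    omega: np.ndarray = field(default=None, repr=False)     # deg/s per frame
    centroid: np.ndarray = field(default=None, repr=False)  # (n_t, 2) cm
    phases: np.ndarray = field(default=None, repr=False)    # per-frame labels


def curvature_from_midline(midline, smooth_window: int = 0) -> np.ndarray:
    """Signed curvature profile kappa(s) in 1/L units from a smoothed midline.

    Computed as the arc-length derivative of the unwrapped tangent angle on
    the midline's normalized s-grid (so the result is dimensionless in L).
    Left-positive in the right-handed (x, y-up) frame.  ``smooth_window``
    (odd, >= 5) applies a cubic Savitzky-Golay filter to the tangent angle
    before differentiating — useful for image-extracted midlines where the
    double differencing amplifies residual pixel noise.
    """
    pts = np.asarray(midline.points, dtype=float)
    s = np.asarray(midline.s_grid, dtype=float)
    d = np.gradient(pts, s, axis=0, edge_order=2)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    if smooth_window and smooth_window >= 5 and theta.size > smooth_window:
        theta = savgol_filter(theta, smooth_window, 3, mode="interp")
    return np.gradient(theta, s, edge_order=2)


def integrate_curvature(kappa: np.ndarray, s_grid: Optional[np.ndarray] = None):
    """Head-frame reconstruction from a curvature profile.

    Returns ``(alpha, x, y)`` on the same s-grid: the bending angle
    ``alpha(s)`` (rad) and the midline coordinates in units of L, with the
    head at the origin and the initial tangent along +x.  Cumulative
    trapezoidal integration; the reconstruction is arc-length preserving
    because the integrand ``(cos alpha, sin alpha)`` is a unit vector.
    """
    kappa = np.asarray(kappa, dtype=float)
    if s_grid is None:
        s_grid = np.linspace(0.0, 1.0, kappa.size)
    alpha = cumulative_trapezoid(kappa, s_grid, initial=0.0)
    x = cumulative_trapezoid(np.cos(alpha), s_grid, initial=0.0)
    y = cumulative_trapezoid(np.sin(alpha), s_grid, initial=0.0)
    return alpha, x, y


def head_heading(midline, head_frac: float = 0.1) -> float:
    """Facing direction of the head, radians, from the anterior midline.

    The mean tangent over the anterior ``head_frac`` of arc length, reversed
    (points are ordered head->tail, the fish faces the other way).
    """
    pts = np.asarray(midline.points, dtype=float)
    s = np.asarray(midline.s_grid, dtype=float)
    k = max(2, int(np.searchsorted(s, head_frac)))
    t = pts[k] - pts[0]
    return float(np.arctan2(-t[1], -t[0]))


def heading_track(midlines: Sequence, head_frac: float = 0.1) -> np.ndarray:
    """Unwrapped per-frame head heading (rad) for a midline sequence."""
    raw = np.array([head_heading(m, head_frac) for m in midlines])
    return np.unwrap(raw)


def turning_angle(midlines: Sequence, head_frac: float = 0.1):
    """Total turning angle phi of a maneuver, degrees.

    Head direction per frame is the mean anterior tangent (anterior
    ``head_frac`` of arc length); phi is the unwrapped heading change
    between the first and last frames.  Returns ``(phi_magnitude_deg,
    sign)`` with sign +1 for a counter-clockwise (left) turn.
    """
    if len(midlines) < 2:
        raise ValueError("turning_angle requires at least 2 frames")
    psi = heading_track(midlines, head_frac)
    dpsi = np.degrees(psi[-1] - psi[0])
    sign = 1 if dpsi >= 0 else -1
    return abs(dpsi), sign


def alpha_max_track(midlines: Sequence, smooth_window: int = 0,
                    trim: tuple = (0.0, 1.0)) -> np.ndarray:
    """Per-frame max |alpha(s)| (rad) from each midline's curvature.

    ``trim`` restricts the max to an interior arc-length window — for
    image-extracted midlines the terminal few percent are tangent
    extrapolations whose curvature is unreliable.
    """
    out = np.empty(len(midlines))
    for i, m in enumerate(midlines):
        s = np.asarray(m.s_grid, float)
        kap = curvature_from_midline(m, smooth_window=smooth_window)
        alpha, _, _ = integrate_curvature(kap, s)
        sel = (s >= trim[0]) & (s <= trim[1])
        out[i] = np.abs(alpha[sel]).max()
    return out


def kappa_max_of(midlines: Sequence, smooth_window: int = 0,
                 trim: tuple = (0.0, 1.0)) -> float:
    """Max |kappa| (1/L) over frames, restricted to the interior window."""
    best = 0.0
    for m in midlines:
        s = np.asarray(m.s_grid, float)
        kap = curvature_from_midline(m, smooth_window=smooth_window)
        sel = (s >= trim[0]) & (s <= trim[1])
        best = max(best, float(np.abs(kap[sel]).max()))
    return best


def segment_phases(
    alpha_track: np.ndarray,
    omega: np.ndarray,
    omega_glide: float = 30.0,
    alpha_glide: float = 0.15,
):
    """Per-frame phase labels for a C-maneuver.

    Labels are 'glide' / 'bending' / 'recovery'.  Frames before the global
    peak of the bending amplitude are 'bending' once either the body bend or
    the head rotation rate exceeds its glide threshold (``alpha_glide`` rad,
    ``omega_glide`` deg/s); frames after the peak are 'recovery' while the
    body is still appreciably bent, 'glide' once straightened.  A clean
    C-maneuver has exactly one bending->recovery transition, at the peak;
    multi-peak bends are flagged.

    Returns ``(labels, flags)`` where flags is a dict with ``multi_peak``.
    """
    a = np.asarray(alpha_track, dtype=float)
    w = np.abs(np.asarray(omega, dtype=float))
    n = a.size
    labels = np.array(["glide"] * n, dtype=object)
    if a.max() <= alpha_glide:
        return labels, {"multi_peak": False}
    # light temporal smoothing so measurement noise does not split the peak
    a_s = np.convolve(a, np.ones(3) / 3.0, mode="same") if n >= 3 else a
    a_s[0], a_s[-1] = a[0], a[-1]
    # the bend ends when the amplitude first reaches its plateau: a
    # traveling-wave phase holds alpha_max nearly constant, so the strict
    # argmax is ill-defined there
    peak = int(np.argmax(a_s >= 0.97 * a_s.max()))
    active = (a > alpha_glide) | (w > omega_glide)
    # bending: first active frame up to the amplitude peak
    start = int(np.argmax(active)) if active.any() else peak
    labels[start : peak + 1] = "bending"
    after = np.arange(peak + 1, n)
    labels[after[(a[after] > alpha_glide)]] = "recovery"
    # multi-peak: disjoint runs above 80% of the peak separated by a dip
    # below 60% indicate a double bend rather than one clean C
    high = a_s >= 0.8 * a_s.max()
    runs = np.flatnonzero(np.diff(high.astype(int)) == 1).size + int(high[0])
    dips = a_s[np.flatnonzero(high)[0]: np.flatnonzero(high)[-1] + 1].min()
    multi = runs > 1 and dips < 0.6 * a_s.max()
    return labels, {"multi_peak": bool(multi)}


def _speeds(track: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Speed magnitude from a 2D track: central differences, one-sided ends."""
    v = np.gradient(np.asarray(track, float), t, axis=0)
    return np.hypot(v[:, 0], v[:, 1])


def centroid_velocities(track: np.ndarray, t: np.ndarray, L: float, T: float):
    """Normalized initial / max / final centroid speeds (u0, um, ue).

    ``track`` is the centroid path in cm, speeds by central differences,
    normalized by the characteristic velocity U = L/T.
    """
    sp = _speeds(track, t) / (L / T)
    return float(sp[0]), float(sp.max()), float(sp[-1])


def mask_centroid_track(frames, scale: float) -> np.ndarray:
    """Area-centroid path (cm, y-up) of a sequence of binary masks."""
    out = np.empty((len(frames), 2))
    for i, m in enumerate(frames):
        r, c = np.nonzero(m)
        if r.size == 0:
            raise ValueError(f"empty mask at frame {i}")
        out[i] = (c.mean() * scale, -(r.mean() * scale))
    return out


def angular_metrics(psi: np.ndarray, t: np.ndarray):
    """Head angular velocity metrics from an unwrapped heading track (rad).

    Returns ``(omega, omega_ave, omega_m)`` in deg/s: the per-frame angular
    velocity by central differences, the definitional mean ``phi/T``, and
    the peak |omega|.
    """
    psi = np.asarray(psi, dtype=float)
    t = np.asarray(t, dtype=float)
    omega = np.degrees(np.gradient(psi, t))
    phi = abs(np.degrees(psi[-1] - psi[0]))
    omega_ave = phi / (t[-1] - t[0])
    return omega, float(omega_ave), float(np.abs(omega).max())


def reynolds(L_cm: float, T: float, rho: float = RHO_WATER, mu: float = MU_WATER) -> float:
    """Maneuver Reynolds number Re = rho U L / mu = rho L^2 / (mu T).

    ``L_cm`` in cm (converted to m internally), ``T`` in s, ``rho`` in
    kg/m^3, ``mu`` in Pa s.
    """
    if min(L_cm, T, rho, mu) <= 0:
        raise ValueError("all Reynolds inputs must be positive")
    L_m = L_cm / 100.0
    return rho * L_m**2 / (mu * T)


def added_mass_force(
    fld: CurvatureField,
    geom: BodyGeometry,
    rho: float = RHO_WATER,
) -> np.ndarray:
    """Slender-body added-mass force estimate F(t) = -d/dt int m(s) V(s,t) ds.

    The sectional added mass per unit length is that of a cylinder in
    lateral motion, ``m(s) = rho * pi * (h(s)/2)^2`` with the lateral-view
    height as diameter.  ``V(s, t)`` is the body-frame lateral midline
    velocity obtained by differencing the head-frame reconstruction in time.
    Returns the lateral force per frame in SI units (N); an order-of-
    magnitude kinematic estimate, not a substitute for a fluid solve.
    """
    s = fld.s_grid
    t = fld.t_grid
    L_m = geom.L / 100.0
    # head-frame midlines per frame, in meters
    ys = np.empty((t.size, s.size))
    for i in range(t.size):
        _, _, y = integrate_curvature(fld.kappa[i], s)
        ys[i] = y * L_m
    v_lat = np.gradient(ys, t, axis=0)                 # m/s
    h = height_profile(geom, s) * L_m                  # m
    m_add = rho * np.pi * (h / 2.0) ** 2               # kg/m
    momentum = np.trapezoid(m_add[None, :] * v_lat, s * L_m, axis=1)  # kg m/s
    return -np.gradient(momentum, t)


def summarize_maneuver(
    midlines: Sequence,
    centroid_track: np.ndarray,
    L: float,
    T: float,
    head_frac: float = 0.1,
    rho: float = RHO_WATER,
    mu: float = MU_WATER,
    smooth_window: int = 21,
    trim: tuple = (0.05, 0.92),
) -> ManeuverKinematics:
    """Assemble the per-trial kinematic summary from extracted midlines.

    Defaults (tangent-angle Savitzky-Golay window 21, deformation metrics
    over the interior s in [0.05, 0.92]) are tuned for image-extracted
    midlines; pass ``smooth_window=0, trim=(0, 1)`` for analytic ones.
    """
    t = np.array([m.t for m in midlines], dtype=float)
    psi = heading_track(midlines, head_frac)
    phi, sign = turning_angle(midlines, head_frac)
    omega, omega_ave, omega_m = angular_metrics(psi, t)
    a_track = alpha_max_track(midlines, smooth_window=smooth_window, trim=trim)
    kmax = kappa_max_of(midlines, smooth_window=smooth_window, trim=trim)
    u0, um, ue = centroid_velocities(centroid_track, t, L, T)
    labels, _ = segment_phases(a_track, omega)
    return ManeuverKinematics(
        phi=phi,
        phi_sign=sign,
        alpha_max=float(np.degrees(a_track.max())),
        kappa_max=kmax,
        T=T,
        u0=u0,
        um=um,
        ue=ue,
        omega_ave=omega_ave,
        omega_m=omega_m,
        Re=reynolds(L, T, rho, mu),
        omega=omega,
        centroid=np.asarray(centroid_track, float),
        phases=labels,
    )
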