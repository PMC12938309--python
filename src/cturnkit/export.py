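"""Curvature-prescribed body configurations for immersed-boundary solvers.

Turns a midline curvature field kappa(s, t) into a time series of 3D
Lagrangian body configurations: the midline is rebuilt by integrating the
curvature, each cross-section is placed in the plane perpendicular to the
local midline tangent (planar bend, zero twist), and per-point volume
weights pick up the bending Jacobian ``1 - eta * kappa`` so the discrete
body volume is conserved under deformation.

Because the prescription is purely kinematic, the deformation carries
spurious net linear and angular momentum; :func:`momentum_correct` removes
the rigid-body component so the exported motion injects no net momentum
into a fluid solve.  :func:`write_vertex_series` writes plain-text vertex
files (point count header + one ``x y z`` line per point) plus a JSON
manifest — the hand-off format for IB front ends.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .geometry import (BodyGeometry, StraightMesh, build_straight_mesh,
                       width_profile)
from .kinematics import CurvatureField, integrate_curvature

__all__ = [
    "DeformedConfiguration",
    "configure_from_curvature",
    "configure_sequence",
    "momentum_correct",
    "momentum_residuals",
    "write_vertex_series",
    "read_vertex_file",
]


@dataclass
class DeformedConfiguration:
    """One frame of the prescribed body motion."""

    t: float                      # time, s
    points: np.ndarray            # (N, 3) Lagrangian positions, cm
    weights: np.ndarray           # (N,) volume weights, cm^3
    velocity: Optional[np.ndarray] = None   # (N, 3) cm/s, after correction

    @property
    def volume(self) -> float:
        return float(self.weights.sum())


def configure_from_curvature(fld: CurvatureField, geom: BodyGeometry,
                             frame: int,
                             mesh: Optional[StraightMesh] = None
                             ) -> DeformedConfiguration:
    """Deform the straight lattice by the curvature profile of one frame.

    The midline comes from integrating kappa(., t); lattice point
    (s, eta, zeta) maps to ``midline(s) + eta * normal(s)`` in the bending
    plane with zeta (the vertical offset) unchanged — each cross-section
    stays perpendicular to the midline by construction.  Volume weights are
    scaled by the bending Jacobian ``1 - eta*kappa(s)``; a warning (with
    the frame index) is raised when section planes cross, i.e. when
    ``|kappa| * half_width >= 1`` anywhere.
    """
    if mesh is None:
        mesh = build_straight_mesh(geom)
    kap = fld.kappa[frame]
    s_grid = fld.s_grid
    alpha, x, y = integrate_curvature(kap, s_grid)

    s = mesh.lattice[:, 0]
    eta = mesh.lattice[:, 1]
    zeta = mesh.lattice[:, 2]
    a = np.interp(s, s_grid, alpha)
    mx = np.interp(s, s_grid, x)
    my = np.interp(s, s_grid, y)
    k = np.interp(s, s_grid, kap)

    jac = 1.0 - eta * k
    halfw = 0.5 * width_profile(geom, mesh.stations)
    k_st = np.interp(mesh.stations, s_grid, kap)
    if np.any(np.abs(k_st) * halfw >= 1.0):
        n_bad = int((np.abs(k_st) * halfw >= 1.0).sum())
        warnings.warn(
            f"section planes cross at frame {frame} "
            f"(|kappa|*half_width >= 1 at {n_bad} stations)"
        )
    nx, ny = -np.sin(a), np.cos(a)
    pts = np.column_stack([
        (mx + eta * nx) * geom.L,
        (my + eta * ny) * geom.L,
        zeta * geom.L,
    ])
    return DeformedConfiguration(
        t=float(fld.t_grid[frame]),
        points=pts,
        weights=mesh.weights * jac,
    )


def configure_sequence(fld: CurvatureField, geom: BodyGeometry,
                       mesh: Optional[StraightMesh] = None
                       ) -> List[DeformedConfiguration]:
    """Deformed configurations for every frame of a curvature field."""
    if mesh is None:
        mesh = build_straight_mesh(geom)
    return [configure_from_curvature(fld, geom, i, mesh=mesh)
            for i in range(fld.t_grid.size)]


def _diff_time(P: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Central time differences, one-sided at the endpoints."""
    return np.gradient(P, t, axis=0)


def _rigid_part(r: np.ndarray, v: np.ndarray, m: np.ndarray):
    """Rigid translation + rotation carrying the lattice's net momenta.

    Returns the velocity field ``V + Omega x (r - c)`` whose subtraction
    zeroes both Sum(m v) and Sum(m (r-c) x v) to solver precision.
    """
    M = m.sum()
    c = (m[:, None] * r).sum(axis=0) / M
    V = (m[:, None] * v).sum(axis=0) / M
    rc = r - c
    vrel = v - V
    Lm = (m[:, None] * np.cross(rc, vrel)).sum(axis=0)
    r2 = (rc * rc).sum(axis=1)
    # inertia tensor I = sum m (|r|^2 I3 - r r^T)
    I3 = np.eye(3)
    inertia = (m[:, None, None] * (r2[:, None, None] * I3[None]
               - rc[:, :, None] * rc[:, None, :])).sum(axis=0)
    Omega = np.linalg.solve(inertia, Lm)
    return V + np.cross(Omega[None, :], rc), c


def momentum_correct(configs: Sequence[DeformedConfiguration],
                     mass_weights: Optional[np.ndarray] = None,
                     tol: float = 1e-13, max_iter: int = 60
                     ) -> List[DeformedConfiguration]:
    """Remove the net rigid-body motion of a prescribed deformation.

    Material (mass) weights are the straight-pose volume weights times a
    uniform density, so they are constant in time; by default the first
    frame's volume weights are used.  The procedure: (1) translate every
    frame so the mass centroid sits at the origin (zero linear momentum for
    any linear differencing); (2) iteratively rotate each frame by the
    integral of the residual rigid rotation rate until the angular momentum
    of the centrally differenced motion vanishes; (3) subtract the exact
    remaining rigid velocity field so the stored (positions, velocities)
    pair has machine-zero net linear and angular momentum at every frame.

    Pure rigid translations or rotations are corrected to a stationary
    sequence.  Requires at least 3 frames.
    """
    if len(configs) < 3:
        raise ValueError("momentum correction needs at least 3 frames")
    t = np.array([c.t for c in configs])
    P = np.stack([c.points for c in configs])          # (n_t, N, 3)
    m = (np.asarray(mass_weights, float) if mass_weights is not None
         else configs[0].weights.copy())
    M = m.sum()

    # (1) zero linear momentum: mass centroid to the origin in every frame
    cent = (m[None, :, None] * P).sum(axis=1) / M
    P = P - cent[:, None, :]

    # (2) iterative de-rotation (planar fields only carry z angular momentum,
    # but the general 3-component form costs nothing)
    n_t = len(t)
    for _ in range(max_iter):
        V = _diff_time(P, t)
        Lz = np.empty(n_t)
        Iz = np.empty(n_t)
        for k in range(n_t):
            r = P[k]
            Lz[k] = (m * (r[:, 0] * V[k][:, 1] - r[:, 1] * V[k][:, 0])).sum()
            Iz[k] = (m * (r[:, 0] ** 2 + r[:, 1] ** 2)).sum()
        scale = M * max(np.abs(P).max(), 1e-300) ** 2 / (t[-1] - t[0])
        if np.abs(Lz).max() < tol * scale:
            break
        omega = -Lz / Iz
        theta = np.concatenate([[0.0], np.cumsum(
            0.5 * (omega[1:] + omega[:-1]) * np.diff(t))])
        cth, sth = np.cos(theta), np.sin(theta)
        Px = cth[:, None] * P[:, :, 0] - sth[:, None] * P[:, :, 1]
        Py = sth[:, None] * P[:, :, 0] + cth[:, None] * P[:, :, 1]
        P = np.stack([Px, Py, P[:, :, 2]], axis=2)

    # (3) exact velocity-level correction at the final positions
    V = _diff_time(P, t)
    out = []
    for k, cfg in enumerate(configs):
        rigid, _ = _rigid_part(P[k], V[k], m)
        out.append(DeformedConfiguration(
            t=cfg.t, points=P[k], weights=cfg.weights,
            velocity=V[k] - rigid,
        ))
    return out


def momentum_residuals(configs: Sequence[DeformedConfiguration],
                       mass_weights: Optional[np.ndarray] = None,
                       L: float = 1.0, T: float = 1.0):
    """Relative net linear / angular momentum per frame.

    Normalized by ``V_total * L/T`` (linear) and ``V_total * L^2/T``
    (angular) so both are dimensionless.
    """
    m = (np.asarray(mass_weights, float) if mass_weights is not None
         else configs[0].weights)
    M = m.sum()
    lin, ang = [], []
    for cfg in configs:
        if cfg.velocity is None:
            raise ValueError("configurations carry no velocities; run momentum_correct")
        r, v = cfg.points, cfg.velocity
        c = (m[:, None] * r).sum(axis=0) / M
        p = (m[:, None] * v).sum(axis=0)
        Lm = (m[:, None] * np.cross(r - c, v)).sum(axis=0)
        lin.append(np.linalg.norm(p) / (M * L / T))
        ang.append(np.linalg.norm(Lm) / (M * L**2 / T))
    return np.array(lin), np.array(ang)


def write_vertex_series(configs: Sequence[DeformedConfiguration],
                        out_dir, L: float, T: float,
                        basename: str = "body") -> List[Path]:
    """Write one plain-text vertex file per frame plus a JSON manifest.

    File format: first line the integer point count, then one
    ``x y z`` triple per line at 12+ significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, cfg in enumerate(configs):
        path = out_dir / f"{basename}.{i:04d}.vertex"
        with open(path, "w") as fh:
            fh.write(f"{len(cfg.points)}\n")
            for x, y, z in cfg.points:
                fh.write(f"{x:.14e} {y:.14e} {z:.14e}\n")
        paths.append(path)
    manifest = {
        "frames": len(configs),
        "times": [c.t for c in configs],
        "L_cm": L,
        "T_s": T,
        "units": "cm",
        "files": [p.name for p in paths],
    }
    with open(out_dir / f"{basename}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def read_vertex_file(path) -> np.ndarray:
    """Read one vertex file back into an (N, 3) array."""
    with open(path) as fh:
        n = int(fh.readline())
        pts = np.loadtxt(fh)
    pts = np.atleast_2d(pts)
    if pts.shape != (n, 3):
        raise ValueError(f"{path}: expected {n} points, found {pts.shape}")
    return pts
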