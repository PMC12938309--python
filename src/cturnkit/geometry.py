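"""Parametric carangiform body model.

The body is described by two planform profiles over normalized arc length
``s`` in [0, 1] (head at 0, tail tip at 1):

* a lateral-view height profile ``h(s)`` — a semi-elliptical head, a linear
  taper onto the torso plateau, and a second taper onto the caudal-fin
  plateau;
* a top-view width profile ``w(s)`` — the four-digit NACA thickness law
  (NACA0016-style) on a chord ending at the peduncle/fin junction ``s4``,
  followed by a constant fin width (the caudal fin is a thin plate of fixed
  width, trapezoidal in lateral view because of the ``h`` taper).

Cross-sections are symmetric ellipses with semi-axes ``w/2`` and ``h/2`` on
the torso/peduncle and thin rectangles (plates) on the fin.  All lengths are
fractions of the body length ``L`` unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

__all__ = [
    "BodyGeometry",
    "height_profile",
    "width_profile",
    "cross_section",
    "build_straight_mesh",
    "StraightMesh",
]

# Four-digit NACA thickness polynomial coefficients (half-thickness for a
# t/c = 0.20 section; scaled by w1/0.2 for other maximum widths).
_NACA = (0.2969, -0.1260, -0.3516, 0.2843, -0.1015)


@dataclass(frozen=True)
class BodyGeometry:
    """Parameter set for the piecewise height/width body model.

    Defaults are a hand-tuned adult-zebrafish-like parameterization (all
    fractions of body length L); they are not measured values and every
    field can be overridden from JSON via :meth:`from_json`.
    """

    L: float = 3.60          # body length, cm (normalization unit)
    a: float = 0.30          # head semi-ellipse half-chord (apex at s=a=s1, so
                             # the head rises monotonically onto the torso)
    b: float = 0.07          # head semi-ellipse apex height
    s1: float = 0.30         # end of head ellipse / start of first taper
    s2: float = 0.45         # start of torso height plateau
    s3: float = 0.60         # end of torso plateau / start of caudal taper
    s4: float = 0.70         # chord end of the NACA width law (fin start)
    s5: float = 0.80         # end of caudal height taper
    h2: float = 0.08         # torso plateau height
    h3: float = 0.04         # caudal-fin plateau height
    w1: float = 0.112        # NACA thickness parameter; max width = w1/2 (0.16*s4)
    w2: float = 0.02         # constant caudal-fin plate width
    n_s: int = 200           # default profile sampling count

    def __post_init__(self):
        if not (0 < self.s1 < self.s2 < self.s3 < self.s4 <= self.s5 < 1):
            raise ValueError(
                "breakpoints must satisfy 0 < s1 < s2 < s3 < s4 <= s5 < 1"
            )
        if min(self.a, self.b, self.h2, self.h3, self.w1, self.w2, self.L) <= 0:
            raise ValueError("all geometric parameters must be positive")

    @property
    def h1(self) -> float:
        """Height at s1, derived from the ellipse branch so h is continuous."""
        return _ellipse_height(self, self.s1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BodyGeometry":
        with open(path) as fh:
            return cls(**json.load(fh))


def _ellipse_height(geom: BodyGeometry, s):
    arg = 1.0 - ((np.asarray(s, float) - geom.a) / geom.a) ** 2
    return geom.b * np.sqrt(np.clip(arg, 0.0, None))


def _check_domain(s):
    s = np.asarray(s, dtype=float)
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ValueError("arc-length fraction s must lie in [0, 1]")
    return s


def height_profile(geom: BodyGeometry, s):
    """Lateral-view height h(s) (fraction of L), vectorized over ``s``.

    Piecewise: semi-ellipse on [0, s1), linear h1->h2 on [s1, s2), plateau h2
    on [s2, s3), linear h2->h3 on [s3, s5), plateau h3 on [s5, 1].
    """
    s = _check_domain(s)
    h1 = geom.h1
    conds = [
        s < geom.s1,
        (s >= geom.s1) & (s < geom.s2),
        (s >= geom.s2) & (s < geom.s3),
        (s >= geom.s3) & (s < geom.s5),
        s >= geom.s5,
    ]
    funcs = [
        lambda x: _ellipse_height(geom, x),
        lambda x: h1 + (geom.h2 - h1) * (x - geom.s1) / (geom.s2 - geom.s1),
        lambda x: np.full_like(x, geom.h2),
        lambda x: geom.h2 + (geom.h3 - geom.h2) * (x - geom.s3) / (geom.s5 - geom.s3),
        lambda x: np.full_like(x, geom.h3),
    ]
    return np.piecewise(s, conds, funcs)


def naca_poly(x):
    """Four-digit thickness polynomial (half-thickness of a t/c=0.2 section).

    Maximum value ~0.1003 at chord fraction x ~ 0.300; small but nonzero at
    x = 1 (the open trailing edge of the four-digit family).
    """
    x = np.asarray(x, dtype=float)
    c0, c1, c2, c3, c4 = _NACA
    return c0 * np.sqrt(x) + c1 * x + c2 * x**2 + c3 * x**3 + c4 * x**4


def width_profile(geom: BodyGeometry, s):
    """Top-view width w(s) (fraction of L).

    For s < s4: ``(w1 / 0.2) * naca_poly(s / s4)`` — the four-digit thickness
    law on the rescaled chord coordinate, peak width w1/2 near s = 0.3*s4.
    For s >= s4: the constant fin plate width w2.  The torso->fin transition
    at s4 is allowed a step (the law's trailing-edge value need not equal w2).
    """
    s = _check_domain(s)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    out = np.full(s.shape, geom.w2, dtype=float)
    torso = s < geom.s4
    out[torso] = (geom.w1 / 0.2) * naca_poly(s[torso] / geom.s4)
    return out[0] if scalar else out


def cross_section(geom: BodyGeometry, s: float, n_theta: int = 64) -> np.ndarray:
    """Closed cross-section curve at station s, in the (width, height) plane.

    Returns an (n_theta, 2) array of (eta, zeta) vertices, counter-clockwise,
    fractions of L.  Ellipse with semi-axes w/2, h/2 on the torso/peduncle;
    a thin rectangle (plate) of width w2 on the fin.
    """
    if n_theta < 8:
        raise ValueError("n_theta must be at least 8")
    s = float(s)
    _check_domain(s)
    h = float(height_profile(geom, s))
    w = float(width_profile(geom, s))
    if s < geom.s4:
        theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        return np.column_stack([0.5 * w * np.cos(theta), 0.5 * h * np.sin(theta)])
    # fin plate: rectangle w2 x h, vertices distributed along the perimeter
    return _rectangle_curve(w, h, n_theta)


def _rectangle_curve(w: float, h: float, n: int) -> np.ndarray:
    """n points on the perimeter of a w x h axis-aligned rectangle, CCW."""
    per = 2.0 * (w + h)
    d = np.linspace(0.0, per, n, endpoint=False)
    pts = np.empty((n, 2))
    for i, t in enumerate(d):
        if t < w:
            pts[i] = (t - w / 2, -h / 2)
        elif t < w + h:
            pts[i] = (w / 2, t - w - h / 2)
        elif t < 2 * w + h:
            pts[i] = (w / 2 - (t - w - h), h / 2)
        else:
            pts[i] = (-w / 2, h / 2 - (t - 2 * w - h))
    return pts


@dataclass
class StraightMesh:
    """Straight-pose surface mesh and volumetric Lagrangian lattice.

    ``lattice`` columns are (s, eta, zeta): arc-length station and in-section
    offsets, fractions of L.  ``weights`` are per-point volumes (cm^3)
    summing to the body volume.  ``vertices``/``faces`` triangulate the outer
    surface (cm).
    """

    lattice: np.ndarray          # (N, 3) material coordinates (s, eta, zeta), L units
    weights: np.ndarray          # (N,) straight-pose volume weights, cm^3
    section_of: np.ndarray       # (N,) station index of each lattice point
    stations: np.ndarray         # (n_s,) station s values
    vertices: np.ndarray         # (M, 3) surface vertices, cm
    faces: np.ndarray            # (F, 3) triangle indices
    geometry: BodyGeometry = field(repr=False, default=None)

    @property
    def volume(self) -> float:
        return float(self.weights.sum())

    def points_cm(self) -> np.ndarray:
        """Straight-pose lattice in cm: x along the midline, y=eta, z=zeta."""
        return self.lattice * self.geometry.L


def _section_points(geom: BodyGeometry, s: float, n_r: int, n_phi: int):
    """Interior quadrature points + weights for one cross-section.

    Elliptical sections use a polar product rule (equal-area rings, offset
    angular phases so the set is mirror-symmetric in both eta and zeta);
    fin-plate sections use a small tensor grid.  Weights sum to the section
    area (L^2 units).
    """
    h = float(height_profile(geom, s))
    w = float(width_profile(geom, s))
    if h <= 0 or w <= 0:
        return np.zeros((0, 2)), np.zeros(0)
    if s < geom.s4:
        area = np.pi * (w / 2) * (h / 2)
        # equal-area annuli: outer radii fractions r_k = sqrt(k/n_r)
        pts, wts = [], []
        for k in range(n_r):
            r_mid = np.sqrt((k + 0.5) / n_r)
            phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
            ring = np.column_stack(
                [0.5 * w * r_mid * np.cos(phi), 0.5 * h * r_mid * np.sin(phi)]
            )
            pts.append(ring)
            wts.append(np.full(n_phi, area / (n_r * n_phi)))
        return np.vstack(pts), np.concatenate(wts)
    # fin plate: symmetric tensor grid
    nx, nz = 4, max(4, n_r)
    xe = (np.arange(nx) + 0.5) / nx - 0.5
    ze = (np.arange(nz) + 0.5) / nz - 0.5
    X, Z = np.meshgrid(xe * w, ze * h)
    pts = np.column_stack([X.ravel(), Z.ravel()])
    wts = np.full(pts.shape[0], w * h / pts.shape[0])
    return pts, wts


def build_straight_mesh(
    geom: BodyGeometry,
    n_s: int = 60,
    n_theta: int = 32,
    n_r: int = 4,
) -> StraightMesh:
    """Discretize the straight body into a surface mesh and a volume lattice.

    Stations are section midpoints so each carries a well-defined slab
    thickness; per-point weights are (section-area quadrature weight) x
    (slab thickness), summing to the body volume.
    """
    if n_s < 30:
        raise ValueError("n_s must be at least 30")
    edges = np.linspace(0.0, 1.0, n_s + 1)
    stations = 0.5 * (edges[:-1] + edges[1:])
    ds = np.diff(edges)

    lat, wts, sec = [], [], []
    for j, (s, d) in enumerate(zip(stations, ds)):
        pts, w2d = _section_points(geom, s, n_r=n_r, n_phi=n_theta // 2)
        if pts.shape[0] == 0:
            continue
        lat.append(np.column_stack([np.full(pts.shape[0], s), pts]))
        wts.append(w2d * d * geom.L**3)   # L^2 area x L ds -> cm^3
        sec.append(np.full(pts.shape[0], j, dtype=int))
    lattice = np.vstack(lat)
    weights = np.concatenate(wts)
    section_of = np.concatenate(sec)

    vertices, faces = _surface_mesh(geom, stations, n_theta)
    return StraightMesh(
        lattice=lattice,
        weights=weights,
        section_of=section_of,
        stations=stations,
        vertices=vertices,
        faces=faces,
        geometry=geom,
    )


def _surface_mesh(geom: BodyGeometry, stations: np.ndarray, n_theta: int):
    """Triangulated surface: section rings stitched along s plus end caps."""
    rings = []
    for s in stations:
        sec = cross_section(geom, float(s), n_theta=n_theta)
        ring = np.column_stack([np.full(n_theta, s), sec]) * geom.L
        rings.append(ring)
    verts = np.vstack(rings)
    faces = []
    for j in range(len(rings) - 1):
        base0, base1 = j * n_theta, (j + 1) * n_theta
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            faces.append((base0 + k, base1 + k, base1 + k2))
            faces.append((base0 + k, base1 + k2, base0 + k2))
    # end caps: snout tip and tail-tip fans
    nose = np.array([[0.0, 0.0, 0.0]])
    tail = np.array([[geom.L, 0.0, 0.0]])
    verts = np.vstack([verts, nose, tail])
    i_nose, i_tail = len(verts) - 2, len(verts) - 1
    for k in range(n_theta):
        k2 = (k + 1) % n_theta
        faces.append((i_nose, k2, k))
        base = (len(rings) - 1) * n_theta
        faces.append((i_tail, base + k, base + k2))
    return verts, np.asarray(faces, dtype=int)


def write_obj(mesh: StraightMesh, path) -> None:
    """Write the surface mesh as a Wavefront OBJ file."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
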