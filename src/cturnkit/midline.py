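"""Midline extraction from top-view silhouette video.

The pipeline mirrors a standard high-speed-video workflow for swimming
fish: binarize each 8-bit grayscale frame (the fish is the dark region),
keep the largest connected component and fill holes, detect the outer
contour, reduce the mask to its morphological skeleton, prune the skeleton
to its single longest geodesic path, extend the path along its end tangents
to the true snout/tail extremities, orient it head->tail, and fit a
smoothing spline resampled at equal arc-length nodes.

Conventions: images are row-major with pixel (0, 0) at the top-left; pixel
paths are (x=col, y=row) arrays; finished midlines are converted to a
right-handed (x, y-up) frame in cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.interpolate import splev, splprep, interp1d
from scipy.sparse.csgraph import dijkstra
from skimage import measure, morphology

__all__ = [
    "FrameSequence",
    "Midline",
    "binarize",
    "compute_threshold",
    "extract_contour",
    "skeletonize_midline",
    "extend_to_tips",
    "recenter_on_mask",
    "orient_head_tail",
    "resample_smooth",
    "extract_midlines",
]


@dataclass
class FrameSequence:
    """Timestamped 8-bit grayscale image stack with a pixel scale."""

    frames: np.ndarray      # (n_t, H, W) uint8
    dt: float               # frame interval, s
    scale: float            # cm per pixel
    meta: dict = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_t, H, W) stack")
        if self.dt <= 0 or self.scale <= 0:
            raise ValueError("dt and scale must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.dt


@dataclass
class Midline:
    """Ordered head->tail midline for one frame, in cm (y-up)."""

    t: float                # time, s
    points: np.ndarray      # (n_s, 2) cm
    s_grid: np.ndarray      # cumulative arc length / L_measured, in [0, 1]
    L_measured: float       # arc length of this frame's midline, cm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if self.s_grid[0] != 0.0 or abs(self.s_grid[-1] - 1.0) > 1e-9:
            raise ValueError("s_grid must run from 0 to 1")
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")


def compute_threshold(frame: np.ndarray, method: str = "mean-gap",
                      manual_threshold: Optional[float] = None) -> float:
    """Binarization threshold for one frame.

    ``mean-gap`` places the threshold midway between the mean gray level of
    the background and of the fish (iterated intermeans); ``otsu`` and
    ``manual`` are alternatives.
    """
    frame = np.asarray(frame)
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method requires manual_threshold")
        return float(manual_threshold)
    if method == "otsu":
        from skimage.filters import threshold_otsu
        return float(threshold_otsu(frame))
    if method != "mean-gap":
        raise ValueError(f"unknown binarization method {method!r}")
    f = frame.astype(float)
    thr = f.mean()
    for _ in range(100):
        lo, hi = f[f < thr], f[f >= thr]
        if lo.size == 0 or hi.size == 0:
            raise ValueError("no fish detected")
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - thr) < 1e-6:
            break
        thr = new
    return float(thr)


def binarize(frame: np.ndarray, method: str = "mean-gap",
             manual_threshold: Optional[float] = None) -> np.ndarray:
    """Foreground (fish) mask: darker-than-threshold region, largest
    connected component, holes filled."""
    thr = compute_threshold(frame, method, manual_threshold)
    fg = np.asarray(frame).astype(float) < thr
    if not fg.any():
        raise ValueError("no fish detected")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        fg = lab == sizes.argmax()
    return ndimage.binary_fill_holes(fg)


def extract_contour(mask: np.ndarray, smooth: int = 5) -> np.ndarray:
    """Outer contour of a single-component mask as an (N, 2) closed (x, y)
    pixel polyline, counter-clockwise in the y-up sense.

    ``smooth`` applies a circular moving average (window in vertices) to
    remove the half-pixel staircase of the marching-squares contour, which
    otherwise inflates perimeter estimates by several percent.
    """
    _, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"mask must have exactly one component, found {n}")
    contours = measure.find_contours(mask.astype(float), 0.5)
    rc = max(contours, key=len)              # (row, col), closed
    rc = rc[:-1] if np.allclose(rc[0], rc[-1]) else rc
    if smooth and smooth > 1 and len(rc) > smooth:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        wrapped = np.vstack([rc[-pad:], rc, rc[:pad]])
        rc = np.column_stack([
            np.convolve(wrapped[:, k], kernel, mode="valid") for k in (0, 1)])
    xy = rc[:, ::-1].copy()                  # (x=col, y=row)
    # shoelace in y-up coordinates: enforce CCW
    x, y = xy[:, 0], -xy[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    if area2 < 0:
        xy = xy[::-1]
    return xy


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeletonize_midline(mask: np.ndarray,
                        expected_length: Optional[float] = None) -> np.ndarray:
    """Raw midline pixel path from the morphological skeleton.

    The skeleton is pruned to its single longest endpoint-to-endpoint
    geodesic (8-connected, diagonal steps weighted sqrt(2)), which drops
    spur branches.  Raises ``skeleton degenerate`` if no path reaches half
    of the expected body length (default: the mask's major axis length).
    """
    if expected_length is None:
        props = measure.regionprops(mask.astype(np.uint8))
        expected_length = props[0].axis_major_length if props else 0.0

    skel = morphology.skeletonize(mask)
    rr, cc = np.nonzero(skel)
    if rr.size < 2:
        raise ValueError("skeleton degenerate")
    index = {(r, c): i for i, (r, c) in enumerate(zip(rr, cc))}
    rows_i, cols_j, wts = [], [], []
    for (r, c), i in index.items():
        for dr, dc in _OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows_i.append(i)
                cols_j.append(j)
                wts.append(np.hypot(dr, dc))
    adj = sparse.csr_matrix((wts, (rows_i, cols_j)), shape=(rr.size, rr.size))
    degree = np.diff(adj.indptr)
    endpoints = np.flatnonzero(degree == 1)
    if endpoints.size < 2:
        raise ValueError("skeleton degenerate")

    best = (-1.0, None, None)
    dists, preds = dijkstra(adj, indices=endpoints, return_predecessors=True)
    for k, e in enumerate(endpoints):
        d = dists[k][endpoints]
        d[~np.isfinite(d)] = -1
        j = int(d.argmax())
        if d[j] > best[0]:
            best = (d[j], k, int(endpoints[j]))
    length, k, target = best
    if length < 0.5 * expected_length:
        raise ValueError("skeleton degenerate")
    path_idx = [target]
    while path_idx[-1] != endpoints[k]:
        path_idx.append(preds[k][path_idx[-1]])
    path = np.array([(cc[i], rr[i]) for i in path_idx], dtype=float)
    return path


def extend_to_tips(path: np.ndarray, mask: np.ndarray, tangent_pts: int = 12,
                   step: float = 0.7) -> np.ndarray:
    """Extend both path ends along their local tangents to the mask boundary.

    Skeletons systematically stop short of the snout and tail tip; marching
    along the end tangents until leaving the foreground places s=0 and s=1
    at the body extremities.  The march direction is a least-squares line
    fit over the terminal ``tangent_pts`` path pixels, which is much less
    sensitive to pixelation than a two-point difference.
    """
    H, W = mask.shape

    def march(segment: np.ndarray) -> np.ndarray:
        """segment is ordered inward -> end; returns extension points."""
        end = segment[-1]
        centered = segment - segment.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        if np.dot(direction, end - segment[0]) < 0:
            direction = -direction
        pts = []
        p = end.copy()
        for _ in range(int(max(H, W) / step)):
            p = p + step * direction
            r, c = int(round(p[1])), int(round(p[0]))
            if not (0 <= r < H and 0 <= c < W) or not mask[r, c]:
                break
            pts.append(p.copy())
        return np.asarray(pts).reshape(-1, 2)

    k = min(tangent_pts, len(path) - 1)
    head_ext = march(path[k::-1])
    tail_ext = march(path[-1 - k:])
    return np.vstack([head_ext[::-1], path, tail_ext])


def recenter_on_mask(path: np.ndarray, mask: np.ndarray, step: float = 0.25,
                     max_halfwidth: float = 30.0, iterations: int = 2
                     ) -> np.ndarray:
    """Snap a pixel path onto the silhouette's local symmetry axis.

    For every point, march along +-normal to the two mask boundary
    crossings and shift the point to their midpoint.  Corrects the small
    systematic deflections that morphological skeletons exhibit near wide
    rounded regions (e.g. the head), which otherwise bias the head-
    direction estimate.
    """
    H, W = mask.shape
    path = np.asarray(path, dtype=float).copy()
    n_steps = int(max_halfwidth / step)

    def inside(p):
        r = np.clip(np.round(p[:, 1]).astype(int), 0, H - 1)
        c = np.clip(np.round(p[:, 0]).astype(int), 0, W - 1)
        return mask[r, c]

    for _ in range(iterations):
        d = np.gradient(path, axis=0)
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        tang = d / nrm
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        dist = {}
        for sign in (+1.0, -1.0):
            out = np.full(len(path), np.nan)
            alive = inside(path)
            for k in range(1, n_steps + 1):
                probe = path + sign * (k * step) * normal
                now_in = inside(probe) & alive
                crossed = alive & ~now_in
                out[crossed & np.isnan(out)] = (k - 0.5) * step
                alive = now_in
                if not alive.any():
                    break
            out[np.isnan(out)] = 0.0
            dist[sign] = out
        shift = 0.5 * (dist[+1.0] - dist[-1.0])
        # taper to zero at the tips, where normals degenerate and a hard
        # cutoff would kink the path
        n = len(path)
        ramp = np.minimum(np.minimum(np.arange(n), np.arange(n)[::-1])
                          / max(1, int(0.05 * n)), 1.0)
        path = path + (ramp * shift)[:, None] * normal
    return path


def orient_head_tail(path: np.ndarray, mask: np.ndarray,
                     previous_head: Optional[np.ndarray] = None,
                     tip_frac: float = 0.1):
    """Orient a pixel path head-first.

    The head end is the one with the larger local body width (mean distance-
    transform value over the terminal ``tip_frac`` of the path).  If the
    previous frame's head position (px) is given, temporal continuity
    overrides the width cue.  Returns ``(oriented_path, low_confidence)``.
    """
    edt = ndimage.distance_transform_edt(mask)
    n = max(2, int(len(path) * tip_frac))

    def mean_width(segment):
        r = np.clip(np.round(segment[:, 1]).astype(int), 0, mask.shape[0] - 1)
        c = np.clip(np.round(segment[:, 0]).astype(int), 0, mask.shape[1] - 1)
        return float(edt[r, c].mean())

    w_start, w_end = mean_width(path[:n]), mean_width(path[-n:])
    low_confidence = abs(w_start - w_end) < 0.1 * max(w_start, w_end, 1e-9)
    head_first = w_start >= w_end
    if previous_head is not None:
        prev = np.asarray(previous_head, dtype=float)
        head_first = (np.linalg.norm(path[0] - prev)
                      <= np.linalg.norm(path[-1] - prev))
        low_confidence = False
    return (path if head_first else path[::-1]), low_confidence


def resample_smooth(path: np.ndarray, n_s: int, scale: float, t: float = 0.0,
                    expected_noise_px: float = 0.5,
                    smoothing: Optional[float] = None) -> Midline:
    """Smoothing-spline fit and equal-arc-length resampling of a pixel path.

    The cubic smoothing parameter defaults to ``m * expected_noise_px**2``
    (residual budget for ~0.5 px pixelation noise).  Output is a
    :class:`Midline` in cm, y-up, with ``n_s`` equally spaced arc-length
    nodes.
    """
    if n_s < 20:
        raise ValueError("insufficient resolution: n_s must be >= 20")
    path = np.asarray(path, dtype=float)
    if len(path) < 20:
        raise ValueError("path too short (need >= 20 px)")
    # drop consecutive duplicates (splprep requires strictly increasing u)
    keep = np.ones(len(path), bool)
    keep[1:] = np.linalg.norm(np.diff(path, axis=0), axis=1) > 1e-9
    path = path[keep]
    if smoothing is None:
        smoothing = len(path) * expected_noise_px**2
    tck, _ = splprep([path[:, 0], path[:, 1]], s=smoothing, k=3)
    u_dense = np.linspace(0.0, 1.0, max(1000, 8 * n_s))
    xd, yd = splev(u_dense, tck)
    dense = np.column_stack([xd, yd])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.linspace(0.0, total, n_s)
    pts_px = interp1d(arc, dense, axis=0)(targets)
    pts_cm = np.column_stack([pts_px[:, 0] * scale, -pts_px[:, 1] * scale])
    L_measured = total * scale
    return Midline(t=t, points=pts_cm, s_grid=targets / total,
                   L_measured=L_measured)


def extract_midlines(seq: FrameSequence, n_s: int = 100,
                     method: str = "mean-gap",
                     manual_threshold: Optional[float] = None,
                     expected_noise_px: float = 0.5):
    """Full per-frame pipeline: binarize -> skeletonize -> extend -> orient
    -> resample.

    Returns ``(midlines, masks, report)``; the report records per-frame
    thresholds and orientation confidence flags.
    """
    midlines, masks = [], []
    report = {"threshold": [], "low_confidence": []}
    prev_head = None
    expected_len = None
    for i, frame in enumerate(seq.frames):
        thr = compute_threshold(frame, method, manual_threshold)
        mask = binarize(frame, method, manual_threshold)
        raw = skeletonize_midline(mask, expected_length=expected_len)
        raw = extend_to_tips(raw, mask)
        raw = recenter_on_mask(raw, mask)
        oriented, lowconf = orient_head_tail(raw, mask, previous_head=prev_head)
        prev_head = oriented[0]
        m = resample_smooth(oriented, n_s=n_s, scale=seq.scale,
                            t=i * seq.dt, expected_noise_px=expected_noise_px)
        if expected_len is None:
            expected_len = m.L_measured / seq.scale
        midlines.append(m)
        masks.append(mask)
        report["threshold"].append(thr)
        report["low_confidence"].append(bool(lowconf))
    return midlines, masks, report
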