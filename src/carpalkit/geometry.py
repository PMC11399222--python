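"""Low-level 2-D polyline and polygon utilities.

Coordinate convention throughout the package: x rightward, y downward
(image convention), origin at the top-left pixel centre, units are
millimetres once an image has been calibrated.  "Proximal" corresponds to
larger y on AP/PA canvases.  A contour is "counter-clockwise" when its
shoelace area is positive in these stored coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import directed_hausdorff


def as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    return pts


def shoelace_area(points) -> float:
    """Signed polygon area (positive = counter-clockwise in stored coords)."""
    p = as_points(points)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points) -> np.ndarray:
    p = as_points(points)
    if shoelace_area(p) < 0:
        p = p[::-1].copy()
    return p


def cumulative_arclength(points, closed: bool = False) -> np.ndarray:
    """Cumulative arc length; includes the closing segment when ``closed``."""
    p = as_points(points)
    seg = p[1:] - p[:-1]
    d = np.hypot(seg[:, 0], seg[:, 1])
    if closed:
        back = p[0] - p[-1]
        d = np.append(d, np.hypot(back[0], back[1]))
    return np.concatenate([[0.0], np.cumsum(d)])


def polyline_length(points, closed: bool = False) -> float:
    return float(cumulative_arclength(points, closed=closed)[-1])


def resample_polyline(points, n: int, closed: bool = False,
                      max_iter: int = 30, tol: float = 1e-13) -> np.ndarray:
    """Resample a polyline to ``n`` points equally spaced along it.

    Open polylines keep both endpoints; closed contours keep the start
    point and return ``n`` points without repeating it.  Points start at
    arc-length-uniform positions and are then relaxed (staying on the
    source polyline) until the output's own segments are equal, which
    makes resampling at a fixed ``n`` exactly idempotent.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p = as_points(points)
    s = cumulative_arclength(p, closed=closed)
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length polyline")
    p_ext = np.vstack([p, p[:1]]) if closed else p

    def sample(t):
        return np.column_stack([np.interp(t, s, p_ext[:, 0]),
                                np.interp(t, s, p_ext[:, 1])])

    if closed:
        t = np.linspace(0.0, total, n, endpoint=False)
    else:
        t = np.linspace(0.0, total, n)
    for _ in range(max_iter):
        out = sample(t)
        loop = np.vstack([out, out[:1]]) if closed else out
        seg = np.hypot(*np.diff(loop, axis=0).T)
        c = np.concatenate([[0.0], np.cumsum(seg)])
        m = len(seg)
        target = c[-1] * np.arange(len(t)) / m
        t_ext = np.append(t, total) if closed else t
        t_new = np.interp(target, c, t_ext)
        t_new[0] = 0.0
        if not closed:
            t_new[-1] = total
        if np.max(np.abs(t_new - t)) < tol * max(total, 1.0):
            t = t_new
            break
        t = t_new
    return sample(t)


def point_at_arclength(points, t: float) -> np.ndarray:
    """Point at cumulative arc length ``t`` along an open polyline."""
    p = as_points(points)
    s = cumulative_arclength(p)
    t = float(np.clip(t, 0.0, s[-1]))
    return np.array([np.interp(t, s, p[:, 0]), np.interp(t, s, p[:, 1])])


def arclength_midpoint(points) -> np.ndarray:
    """The point at half the cumulative arc length of an open polyline."""
    p = as_points(points)
    if len(p) == 1:
        return p[0].copy()
    return point_at_arclength(p, 0.5 * polyline_length(p))


def hausdorff_distance(a, b) -> float:
    """Pointwise (vertex-set) Hausdorff distance."""
    a, b = as_points(a), as_points(b)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def curve_hausdorff(a, b, closed: bool = True, densify_mm: float = 0.05) -> float:
    """Hausdorff distance between two polylines as *curves* (densified),
    so sparse vertex sampling does not inflate the distance."""
    import shapely

    a, b = as_points(a), as_points(b)
    if closed:
        a, b = np.vstack([a, a[:1]]), np.vstack([b, b[:1]])
    la, lb = shapely.LineString(a), shapely.LineString(b)
    frac = max(min(densify_mm / max(la.length, 1e-9), 1.0), 1e-4)
    return float(shapely.hausdorff_distance(la, lb, densify=frac))


def facet_indices(facet_range, n: int) -> np.ndarray:
    """Indices of a (possibly wrapping) half-open facet range on an
    n-point closed contour."""
    start, stop = int(facet_range[0]), int(facet_range[1])
    if not (0 <= start < n) or stop <= start or stop - start > n:
        raise ValueError(f"invalid facet range {facet_range} for n={n}")
    return np.arange(start, stop) % n


def rotation_matrix(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def project_points_to_polyline(query, polyline) -> np.ndarray:
    """Closest point on an open polyline for every query point (vectorised)."""
    q = as_points(query)
    p = as_points(polyline)
    a, b = p[:-1], p[1:]
    ab = b - a                                # (m, 2)
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    # t for every (query, segment) pair
    diff = q[:, None, :] - a[None, :, :]       # (n, m, 2)
    t = np.einsum("nmj,mj->nm", diff, ab) / denom[None, :]
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = np.sum((q[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    return proj[np.arange(len(q)), best]
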