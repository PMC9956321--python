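"""Bagplot outlier detection built on exact Tukey halfspace depth.

The bagplot is the bivariate analogue of the boxplot: the *bag* is a
convex region covering the central half of the points, the *fence* is the
bag inflated about the Tukey median by a constant factor (2 by default),
and points strictly outside the fence are flagged as outliers.

Depth machinery
---------------
For a query point q, the Tukey (halfspace) depth is the minimum, over all
closed halfplanes containing q, of the number of data points in the
halfplane.  Writing each non-coincident point as an angle around q it
equals

    depth(q) = (#points coincident with q) + m - max_open_semicircle,

where m is the number of non-coincident points and ``max_open_semicircle``
is the largest number of angles in an open semicircle — an exact O(m^2)
count with no tolerance beyond the angle computation.

The *depth region* D_k = {x : depth(x) >= k} is the intersection of the
halfplanes  u.x <= s_k(u)  over all unit directions u, where s_k(u) is the
k-th largest projection of the data onto u.  Its edges lie on lines
through pairs of data points, so intersecting over the pair-normal
directions is exact.  The Tukey median is the centroid of the deepest
nonempty region.

The bag interpolates between the last region containing at least half the
points (D_k*) and the next one (D_{k*+1}): the support offsets are blended
with lambda = (n_k - n/2)/(n_k - n_{k+1}), n_j being the number of data
points of depth >= j.  The bag is therefore sandwiched between the two
regions and covers roughly half the points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "DegenerateGeometryError",
    "BagplotResult",
    "halfspace_depth",
    "depth_median",
    "depth_region",
    "compute_bag",
    "detect_outliers_bagplot",
    "BagplotOutlierDetector",
]


class DegenerateGeometryError(ValueError):
    """Raised when a point cloud is too degenerate for a bagplot (fewer
    than 3 points, or all points collinear)."""


def _as_cloud(points) -> np.ndarray:
    pts = check_array(points, ensure_2d=True, dtype=float)
    if pts.shape[1] != 2:
        raise ValueError("bagplot point clouds must be two-dimensional")
    return pts


# --------------------------------------------------------------------- #
# exact depth of a point
# --------------------------------------------------------------------- #
def halfspace_depth(query, cloud) -> int:
    """Exact Tukey (halfspace) depth of ``query`` with respect to ``cloud``.

    Coincident points count with multiplicity; a point far outside the
    convex hull has depth 0, the innermost points approach depth n/2.
    """
    pts = _as_cloud(cloud)
    q = np.asarray(query, dtype=float).ravel()
    if q.shape != (2,) or not np.all(np.isfinite(q)):
        raise ValueError("query must be a finite 2-D point")
    diff = pts - q
    coincident = np.all(diff == 0.0, axis=1)
    c = int(coincident.sum())
    rest = diff[~coincident]
    m = rest.shape[0]
    if m == 0:
        return c
    ang = np.arctan2(rest[:, 1], rest[:, 0])
    # largest number of angles in an open semicircle (s, s+pi): the optimum
    # is attained with the interval anchored just below some data angle a_i,
    # i.e. counting angles with (a_j - a_i) mod 2pi in [0, pi)
    off = np.mod(ang[None, :] - ang[:, None], 2.0 * np.pi)
    counts = (off < np.pi).sum(axis=1)
    return c + m - int(counts.max())


def _all_depths(pts: np.ndarray) -> np.ndarray:
    return np.array([halfspace_depth(p, pts) for p in pts], dtype=int)


def _is_collinear(pts: np.ndarray, tol: float = 1e-12) -> bool:
    if pts.shape[0] < 3:
        return True
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[-1] <= tol * max(1.0, s[0])


# --------------------------------------------------------------------- #
# depth regions (halfplane intersections)
# --------------------------------------------------------------------- #
def _pair_normals(pts: np.ndarray) -> np.ndarray:
    """Unit normals (both orientations) of all point-pair differences."""
    n = pts.shape[0]
    i, j = np.triu_indices(n, k=1)
    d = pts[j] - pts[i]
    keep = np.einsum("ij,ij->i", d, d) > 0
    d = d[keep]
    normals = np.c_[-d[:, 1], d[:, 0]]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return np.vstack([normals, -normals])


def _clip_halfplane(poly: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex polygon with {x : a.x <= b}."""
    if poly.shape[0] == 0:
        return poly
    s = poly @ a - b
    inside = s <= 1e-12
    if inside.all():
        return poly
    if not inside.any():
        return poly[:0]
    out = []
    n = poly.shape[0]
    for k in range(n):
        k2 = (k + 1) % n
        if inside[k]:
            out.append(poly[k])
        if inside[k] != inside[k2]:
            t = s[k] / (s[k] - s[k2])
            out.append(poly[k] + t * (poly[k2] - poly[k]))
    return np.asarray(out)


def _bounding_box(pts: np.ndarray) -> np.ndarray:
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    c = (lo + hi) / 2.0
    r = float(np.max(hi - lo)) + 1.0
    return np.array(
        [c + [-2 * r, -2 * r], c + [2 * r, -2 * r], c + [2 * r, 2 * r], c + [-2 * r, 2 * r]]
    )


def _intersect(pts: np.ndarray, normals: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    poly = _bounding_box(pts)
    for a, b in zip(normals, offsets):
        poly = _clip_halfplane(poly, a, b)
        if poly.shape[0] == 0:
            break
    return poly


def _kth_largest_projections(pts: np.ndarray, normals: np.ndarray, k: int) -> np.ndarray:
    proj = normals @ pts.T  # (m, n)
    return np.partition(proj, proj.shape[1] - k, axis=1)[:, proj.shape[1] - k]


def depth_region(cloud, k: int, normals: np.ndarray | None = None) -> np.ndarray:
    """Vertices of the convex region of plane points with depth >= ``k``.

    Returns an empty array when the region is empty.  Exact: the region is
    the intersection of the halfplanes u.x <= s_k(u) over the pair-normal
    directions u.
    """
    pts = _as_cloud(cloud)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if normals is None:
        normals = _pair_normals(pts)
    if normals.shape[0] == 0:  # all points coincident
        return pts[:1].copy()
    offsets = _kth_largest_projections(pts, normals, k)
    return _intersect(pts, normals, offsets)


def _polygon_centroid(poly: np.ndarray) -> np.ndarray:
    if poly.shape[0] < 3:
        return poly.mean(axis=0)
    x, y = poly[:, 0], poly[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return poly.mean(axis=0)
    cx = ((x + xs) * cross).sum() / (6.0 * area)
    cy = ((y + ys) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def depth_median(cloud) -> np.ndarray:
    """The Tukey median: centroid of the deepest nonempty depth region.

    Falls back to the centroid of the deepest data points when the region
    degenerates numerically (e.g. all points coincident or collinear).
    """
    pts = _as_cloud(cloud)
    depths = _all_depths(pts)
    dmax = int(depths.max())
    if _is_collinear(pts):
        return pts[depths == dmax].mean(axis=0)
    normals = _pair_normals(pts)
    n = pts.shape[0]
    # the deepest region has level between the max data depth and ceil(n/2)
    lo, hi = dmax, int(np.ceil(n / 2))
    best = depth_region(pts, lo, normals)
    k = lo + 1
    while k <= hi:
        reg = depth_region(pts, k, normals)
        if reg.shape[0] == 0:
            break
        best = reg
        k += 1
    if best.shape[0] == 0:
        return pts[depths == dmax].mean(axis=0)
    return _polygon_centroid(best)


# --------------------------------------------------------------------- #
# bag / fence
# --------------------------------------------------------------------- #
def _bag_geometry(pts: np.ndarray):
    """Bag polygon, Tukey median, and the data depths (internal)."""
    n = pts.shape[0]
    if n < 3 or _is_collinear(pts):
        raise DegenerateGeometryError("bag requires >= 3 non-collinear points")
    depths = _all_depths(pts)
    normals = _pair_normals(pts)
    median = depth_median(pts)

    need = np.ceil(n / 2.0)
    levels = np.array([(depths >= k).sum() for k in range(1, depths.max() + 2)])
    k_star = int(np.max(np.flatnonzero(levels[: depths.max()] >= need))) + 1
    n_k = int((depths >= k_star).sum())
    n_k1 = int((depths >= k_star + 1).sum())

    s_k = _kth_largest_projections(pts, normals, k_star)
    if k_star + 1 <= n:
        inner = depth_region(pts, k_star + 1, normals)
    else:
        inner = np.empty((0, 2))
    if inner.shape[0] == 0:
        s_k1 = normals @ median  # degenerate inner contour: the median itself
    else:
        s_k1 = _kth_largest_projections(pts, normals, k_star + 1)

    lam = 0.0 if n_k <= n_k1 else (n_k - n / 2.0) / (n_k - n_k1)
    lam = float(np.clip(lam, 0.0, 1.0))
    offsets = (1.0 - lam) * s_k + lam * s_k1
    bag = _intersect(pts, normals, offsets)
    if bag.shape[0] < 3:
        raise DegenerateGeometryError("bag degenerated to a point or segment")
    return bag, median, depths


def compute_bag(cloud) -> np.ndarray:
    """Vertices of the bag: the depth contour covering the central half.

    The bag is the support-function interpolation between the depth
    regions D_k* (holding at least half the points) and D_{k*+1}; it
    contains every point of depth >= k*+1, no point of depth < k*, and the
    Tukey median.  Degenerate clouds (collinear or n < 3) raise
    DegenerateGeometryError.
    """
    pts = _as_cloud(cloud)
    bag, _median, _depths = _bag_geometry(pts)
    return bag


@dataclass
class BagplotResult:
    """Outcome of one bagplot run on a 2-D point cloud."""

    depths: np.ndarray  # integer Tukey depth per point
    depth_median: np.ndarray  # 2-D inflation center (Tukey median)
    bag: np.ndarray | None  # CCW vertices, None when degenerate
    fence: np.ndarray | None  # CCW vertices of bag scaled by `factor`
    is_outlier: np.ndarray  # boolean flag per point
    factor: float


def detect_outliers_bagplot(cloud, factor: float = 2.0) -> BagplotResult:
    """Run the bagplot on ``cloud`` and flag points strictly outside the fence.

    ``factor`` scales the bag about the Tukey median to build the fence;
    larger factors flag fewer points.  Degenerate clouds (collinear or
    fewer than 3 points) yield no flags and a warning.
    """
    pts = _as_cloud(cloud)
    if factor <= 0:
        raise ValueError("factor must be positive")
    n = pts.shape[0]
    try:
        bag, median, depths = _bag_geometry(pts)
    except DegenerateGeometryError:
        warnings.warn(
            "degenerate point cloud (collinear or n < 3): no outliers flagged",
            stacklevel=2,
        )
        depths = _all_depths(pts)
        med = pts[depths == depths.max()].mean(axis=0)
        return BagplotResult(
            depths=depths,
            depth_median=med,
            bag=None,
            fence=None,
            is_outlier=np.zeros(n, dtype=bool),
            factor=float(factor),
        )
    fence = median + factor * (bag - median)
    poly = Polygon(fence)
    flags = np.array([not poly.covers(Point(p)) for p in pts], dtype=bool)
    return BagplotResult(
        depths=depths,
        depth_median=median,
        bag=bag,
        fence=fence,
        is_outlier=flags,
        factor=float(factor),
    )


class BagplotOutlierDetector(OutlierMixin, BaseEstimator):
    """Scikit-learn style wrapper around the bagplot detector.

    ``fit(X)`` computes the bagplot of the 2-D rows of ``X``; ``predict``
    follows the sklearn outlier convention (-1 outlier, +1 inlier) for the
    fitted points.

    Attributes
    ----------
    result_ : BagplotResult
    depth_median_ : ndarray of shape (2,)
    """

    def __init__(self, factor: float = 2.0):
        self.factor = factor

    def fit(self, X, y=None):
        X = _as_cloud(X)
        self.result_ = detect_outliers_bagplot(X, factor=self.factor)
        self.depth_median_ = self.result_.depth_median
        self.n_features_in_ = 2
        return self

    def predict(self, X=None):
        check_is_fitted(self, "result_")
        if X is not None:
            res = detect_outliers_bagplot(_as_cloud(X), factor=self.factor)
            return np.where(res.is_outlier, -1, 1)
        return np.where(self.result_.is_outlier, -1, 1)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict()
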