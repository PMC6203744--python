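"""Independent reference implementations used only to cross-check metrics.

These deliberately take different computational routes from the package:
shapely geometry for corridor clipping, dense resampling for occupancies
and zone lengths, and brute-force enumeration for the rank statistics.
"""

import itertools
import math

import numpy as np
from shapely.geometry import LineString, Point, Polygon


def polyline_length_m(points) -> float:
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        total = math.fsum([total, math.dist(a, b)])
    return total / 100.0


def corridor_rectangle(start, platform, width_cm=20.0) -> Polygon:
    s = np.asarray(start, float)
    p = np.asarray(platform, float)
    u = (p - s) / np.linalg.norm(p - s)
    n = np.array([-u[1], u[0]]) * (width_cm / 2.0)
    return Polygon([s + n, p + n, p - n, s - n])


def corridor_percent_shapely(points, start, platform, width_cm=20.0) -> float:
    line = LineString(points)
    rect = corridor_rectangle(start, platform, width_cm)
    return 100.0 * line.intersection(rect).length / line.length


def central_zone_path_shapely(points, radius_cm) -> float:
    line = LineString(points)
    disk = Point(0.0, 0.0).buffer(radius_cm, quad_segs=4096)
    return line.intersection(disk).length / 100.0


def densify(times, points, factor=200):
    """Piecewise-linear resampling: each interval split into ``factor``."""
    ts, ps = [], []
    for i in range(len(times) - 1):
        f = np.linspace(0.0, 1.0, factor, endpoint=False)
        ts.append(times[i] + f * (times[i + 1] - times[i]))
        ps.append(points[i] + f[:, None] * (points[i + 1] - points[i]))
    ts.append(times[-1:])
    ps.append(points[-1:])
    return np.concatenate(ts), np.concatenate(ps)


def quadrant_occupancy_dense(times, points, factor=200):
    """Occupancy shares from midpoint classification of dense substeps."""
    ts, ps = densify(times, points, factor)
    mid = (ps[:-1] + ps[1:]) / 2.0
    dt = np.diff(ts)
    ang = np.arctan2(mid[:, 1], mid[:, 0]) % (2 * math.pi)
    q = (ang // (math.pi / 2)).astype(int)
    occ = np.array([dt[q == k].sum() for k in range(4)])
    return 100.0 * occ / occ.sum()


def first_crossing_dense(times, points, center, radius, factor=200):
    """First platform-contact time from dense resampling; None if never."""
    ts, ps = densify(times, points, factor)
    d = np.hypot(ps[:, 0] - center[0], ps[:, 1] - center[1])
    hit = np.nonzero(d <= radius)[0]
    if len(hit) == 0:
        return None
    return ts[hit[0]] - ts[0]


# ---------------------------------------------------------------------------
# rank-statistic enumeration


def mwu_enumeration(a, b):
    """U = min(U1, U2) and the exact two-tailed p by enumerating all
    ways of labeling the pooled sample (no ties assumed)."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    pooled = a + b

    def u_stat(group_a):
        u1 = sum(1 for x in group_a for y in pooled if y not in group_a and x > y)
        return u1

    u1_obs = sum(1 for x in a for y in b if x > y)
    u_obs = min(u1_obs, n1 * n2 - u1_obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        sel = [pooled[i] for i in combo]
        rest = [pooled[i] for i in range(n1 + n2) if i not in combo]
        u1 = sum(1 for x in sel for y in rest if x > y)
        if min(u1, n1 * n2 - u1) <= u_obs:
            count += 1
        total += 1
    return u_obs, count / total


def kruskal_h_formula(groups):
    """H from the textbook rank formula with midrank ties correction."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = rankdata(pooled)
    n = len(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i:i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie if tie > 0 else float("nan")


def spearman_enumeration(x, y):
    """rho by the d^2 formula (no ties) and the exact two-tailed p by
    enumerating all n! orderings of y's ranks."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    n = len(x)

    def rho_of(r):
        d = rx - np.asarray(r)
        return 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))

    rho = rho_of(ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        if abs(rho_of(perm)) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total
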