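"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Python loops, direct
per-pixel summation, dense grid searches — so that each oracle shares no
code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# morphometry oracles: direct per-pixel computation
# ---------------------------------------------------------------------------

def pixel_moments(mask: np.ndarray) -> dict:
    """Area, centroid, second-moment axes and aspect ratio by direct
    summation over pixels."""
    rs, cs = np.nonzero(mask)
    n = rs.size
    r0 = rs.mean()
    c0 = cs.mean()
    mu20 = float(((rs - r0) ** 2).sum()) / n
    mu02 = float(((cs - c0) ** 2).sum()) / n
    mu11 = float(((rs - r0) * (cs - c0)).sum()) / n
    t = mu20 + mu02
    d = math.sqrt((mu20 - mu02) ** 2 + 4 * mu11 ** 2)
    l1 = (t + d) / 2.0
    l2 = (t - d) / 2.0
    major = 4.0 * math.sqrt(l1)
    minor = 4.0 * math.sqrt(max(l2, 0.0))
    return {"area": n, "centroid": (r0, c0), "major": major, "minor": minor,
            "aspect_ratio": major / minor if minor > 0 else np.inf}


_CROFTON4 = [0.0, math.pi / 4 * (1 + 1 / math.sqrt(2)),
             math.pi / (4 * math.sqrt(2)), math.pi / (2 * math.sqrt(2)), 0.0,
             math.pi / 4 * (1 + 1 / math.sqrt(2)), 0.0,
             math.pi / (4 * math.sqrt(2)), math.pi / 4, math.pi / 2,
             math.pi / (4 * math.sqrt(2)), math.pi / (4 * math.sqrt(2)),
             math.pi / 4, math.pi / 2, 0.0, 0.0]


def crofton_perimeter(mask: np.ndarray) -> float:
    """4-direction Crofton perimeter evaluated by looping over every pixel
    of the 1-padded mask and classifying its 2x2 backward neighbourhood
    (bits: self=1, left=4, up=2, up-left=8)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    pad = np.zeros((h + 2, w + 2), dtype=bool)
    pad[1:-1, 1:-1] = m

    def at(r, c):
        return pad[r, c] if 0 <= r < h + 2 and 0 <= c < w + 2 else False

    total = 0.0
    for r in range(h + 2):
        for c in range(w + 2):
            code = (1 * at(r, c) + 4 * at(r, c - 1)
                    + 2 * at(r - 1, c) + 8 * at(r - 1, c - 1))
            total += _CROFTON4[code]
    return total


def crack_perimeter(mask: np.ndarray) -> float:
    """Unit object/background boundary edges counted one by one."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    total = 0
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    total += 1
    return float(total)


def convex_area(mask: np.ndarray) -> int:
    """Convex area: hull of pixel edge-midpoints, rasterised by
    centre-in-polygon testing."""
    from matplotlib.path import Path as MplPath
    from scipy.spatial import ConvexHull

    rs, cs = np.nonzero(mask)
    pts = []
    for dr, dc in ((0.5, 0.0), (-0.5, 0.0), (0.0, 0.5), (0.0, -0.5)):
        pts.append(np.column_stack([rs + dr, cs + dc]))
    pts = np.vstack(pts)
    hull = ConvexHull(pts)
    path = MplPath(pts[hull.vertices])
    rr, cc = np.meshgrid(np.arange(mask.shape[0]),
                         np.arange(mask.shape[1]), indexing="ij")
    inside = path.contains_points(np.column_stack([rr.ravel(), cc.ravel()]))
    return int(inside.sum())


# ---------------------------------------------------------------------------
# radial split oracle: exhaustive distance ranking
# ---------------------------------------------------------------------------

def fill_holes_by_flood(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes: background pixels not 4-connected to the array
    border become foreground (breadth-first flood from the border)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    outside = np.zeros_like(m)
    stack = [(r, c) for r in range(h) for c in (0, w - 1) if not m[r, c]]
    stack += [(r, c) for c in range(w) for r in (0, h - 1) if not m[r, c]]
    for r, c in stack:
        outside[r, c] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not m[rr, cc] \
                    and not outside[rr, cc]:
                outside[rr, cc] = True
                stack.append((rr, cc))
    return ~outside


def brute_distance_transform(mask: np.ndarray) -> np.ndarray:
    """Distance of each mask pixel to the nearest non-mask pixel, by
    exhaustive pairwise search (O(n^2); small masks only)."""
    m = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~m)
    # pixels on the array edge see implicit background just outside
    h, w = m.shape
    halo = []
    for r in range(-1, h + 1):
        halo.append((r, -1))
        halo.append((r, w))
    for c in range(w):
        halo.append((-1, c))
        halo.append((h, c))
    bg = np.vstack([bg, np.array(halo)]) if bg.size else np.array(halo)
    out = np.zeros(m.shape)
    for r, c in np.argwhere(m):
        d2 = (bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2
        out[r, c] = math.sqrt(d2.min())
    return out


def sorted_bottom_quantile_split(mask: np.ndarray, fraction: float):
    """Periphery = exact bottom quantile of pixels sorted by boundary
    distance (stable in scan order), from the brute-force transform on the
    hole-filled mask; the partition covers only original mask pixels."""
    m = np.asarray(mask, dtype=bool)
    dist = brute_distance_transform(fill_holes_by_flood(m))
    flat = np.flatnonzero(m.ravel())
    order = sorted(flat.tolist(), key=lambda i: (dist.ravel()[i], i))
    take = int(round(fraction * len(order)))
    peri = np.zeros_like(m)
    peri.ravel()[order[:take]] = True
    return peri, m & ~peri


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def pearson_by_summation(x, y) -> float:
    """Covariance / product of standard deviations by explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / math.sqrt(sxx * syy)


def gamma_loglik_grid_search(x: np.ndarray, k_lo=0.1, k_hi=20.0,
                             step=0.001) -> float:
    """Maximise the unit-mean gamma log-likelihood over a dense k grid.

    Uses the sufficient statistics directly:
    l(k)/n = k ln k - ln Gamma(k) + (k-1) <ln x> - k <x>.
    """
    from scipy.special import gammaln

    mean_x = float(np.mean(x))
    mean_lnx = float(np.mean(np.log(x)))
    ks = np.arange(k_lo, k_hi + step / 2, step)
    ll = (ks * np.log(ks) - gammaln(ks) + (ks - 1) * mean_lnx - ks * mean_x)
    return float(ks[np.argmax(ll)])


def multiplicative_division_paths(n_paths: int, generations: int, sd: float,
                                  seed: int) -> np.ndarray:
    """ln(area) after g divisions for independent lineage paths, resampling
    the same truncated-normal multiplicative process via scipy.

    Returns an (n_paths, generations + 1) array of ln areas (initial area 1).
    """
    from scipy.stats import truncnorm

    a, b = (0.05 - 0.5) / sd, (0.95 - 0.5) / sd
    rng = np.random.default_rng(seed)
    f = truncnorm.rvs(a, b, loc=0.5, scale=sd,
                      size=(n_paths, generations), random_state=rng)
    # each path keeps one daughter at random: f or 1-f, symmetric
    pick = rng.integers(0, 2, size=f.shape).astype(bool)
    f = np.where(pick, f, 1.0 - f)
    lnA = np.concatenate([np.zeros((n_paths, 1)), np.cumsum(np.log(f), axis=1)],
                         axis=1)
    return lnA
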