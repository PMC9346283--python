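"""Independent brute-force oracles (numpy-only, no sklearn / scipy.cluster).

Each routine recomputes, by direct enumeration, a quantity the library
implements with a faster algorithm.  They are deliberately naive.
"""

from __future__ import annotations

import numpy as np


def pairwise_distances(xy: np.ndarray) -> np.ndarray:
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def brute_dbscan_noise(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Boolean noise mask per classical DBSCAN (a point counts itself)."""
    n = len(xy)
    d = pairwise_distances(xy)
    neighbours = d <= eps
    core = neighbours.sum(axis=1) >= min_pts
    # expand: a point is non-noise iff it is core or within eps of a core
    reachable = core.copy()
    for i in range(n):
        if not core[i] and neighbours[i][core].any():
            reachable[i] = True
    return ~reachable


def brute_complete_linkage(xy: np.ndarray, cutoff: float) -> np.ndarray:
    """Labels from naive agglomerative complete linkage cut at ``cutoff``.

    Repeatedly merges the pair of clusters with the smallest complete-linkage
    (maximum pairwise) distance until that distance exceeds the cutoff.
    """
    n = len(xy)
    d = pairwise_distances(xy)
    np.fill_diagonal(d, np.inf)
    clusters = {i: [i] for i in range(n)}
    cd = d.copy()  # complete-linkage distance between live clusters
    alive = list(range(n))
    while len(alive) > 1:
        sub = cd[np.ix_(alive, alive)]
        k = np.argmin(sub)
        i_, j_ = divmod(k, len(alive))
        if sub[i_, j_] > cutoff:
            break
        a, b = alive[i_], alive[j_]
        clusters[a].extend(clusters.pop(b))
        for c in alive:
            if c not in (a, b):
                cd[a, c] = cd[c, a] = max(cd[a, c], cd[b, c])
        alive.remove(b)
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters.values()):
        labels[members] = lab
    return labels


def brute_min_distance_components(
    groups: list[np.ndarray], eps: float
) -> np.ndarray:
    """Connected components of groups linked by min point-to-point distance ≤ eps."""
    n = len(groups)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            dmin = np.min(
                np.sqrt(
                    ((groups[i][:, None, :] - groups[j][None, :, :]) ** 2).sum(-1)
                )
            )
            if dmin <= eps:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def brute_suffix_k(
    frames: np.ndarray, area: float, target: float
) -> tuple[int, float]:
    """Exhaustive scan over all frame suffixes; smallest k on ties."""
    max_frame = int(frames.max())
    best_k, best_dev, best_density = None, np.inf, 0.0
    for k in range(1, max_frame + 1):
        count = int((frames >= max_frame - k + 1).sum())
        density = count / area
        dev = abs(density - target)
        if dev < best_dev:
            best_k, best_dev, best_density = k, dev, density
    return best_k, best_density


def brute_proximity(polygons: list, n_neighbours: int = 10) -> np.ndarray:
    """All-pairs polygon distances + sort; mean over min(k, n-1) nearest."""
    n = len(polygons)
    out = np.empty(n)
    for i in range(n):
        ds = sorted(
            polygons[i].distance(polygons[j]) for j in range(n) if j != i
        )
        out[i] = float(np.mean(ds[: min(n_neighbours, n - 1)]))
    return out


def winding_number_inside(poly: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Point-in-polygon by winding number; boundary points count as inside."""
    out = np.zeros(len(pts), dtype=bool)
    v = np.vstack([poly, poly[0]])
    for k, (px, py) in enumerate(pts):
        wn = 0
        on_edge = False
        for a, b in zip(v[:-1], v[1:]):
            cross = (b[0] - a[0]) * (py - a[1]) - (px - a[0]) * (b[1] - a[1])
            dot = (px - a[0]) * (px - b[0]) + (py - a[1]) * (py - b[1])
            if abs(cross) < 1e-9 and dot <= 1e-9:
                on_edge = True
                break
            if a[1] <= py:
                if b[1] > py and cross > 0:
                    wn += 1
            elif b[1] <= py and cross < 0:
                wn -= 1
        out[k] = on_edge or wn != 0
    return out


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper/improper intersection of segments p1p2 and p3p4."""

    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12
            and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12
        )

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    if o1 != o2 and o3 != o4:
        return True
    for (a, b, c), o in (
        ((p1, p2, p3), o1),
        ((p1, p2, p4), o2),
        ((p3, p4, p1), o3),
        ((p3, p4, p2), o4),
    ):
        if o == 0 and on_seg(a, b, c):
            return True
    return False


def polygon_is_simple(vertices: np.ndarray) -> bool:
    """O(n²) all-pairs edge intersection check (non-adjacent edges only)."""
    n = len(vertices)
    edges = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True
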