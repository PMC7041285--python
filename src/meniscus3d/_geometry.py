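"""Low-level geometric primitives.

Exact point-to-triangle closest points, an AABB-BVH accelerated exact
point-to-surface distance query, and the closed-form (Kabsch/SVD) rigid
alignment solve. Everything here is plain numpy plus an optional
numba-compiled traversal kernel; no mesh semantics.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = ["closest_point_on_triangles", "SurfaceQuery", "kabsch"]


def _dot(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", u, v)


def closest_point_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest point on triangle (a, b, c) to p, rowwise.

    All inputs are (n, 3); returns (n, 3). Barycentric region
    classification; regions are applied in increasing priority so the
    vertex/edge cases override the interior solution.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = _dot(ab, ap)
    d2 = _dot(ac, ap)
    bp = p - b
    d3 = _dot(ab, bp)
    d4 = _dot(ac, bp)
    cp = p - c
    d5 = _dot(ab, cp)
    d6 = _dot(ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    def safe_div(num, den):
        den = np.where(np.abs(den) < 1e-300, 1.0, den)
        return num / den

    # face interior (default)
    denom = safe_div(np.ones_like(va), va + vb + vc)
    v = vb * denom
    w = vc * denom
    out = a + ab * v[:, None] + ac * w[:, None]

    # edge BC
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    w_bc = safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
    out = np.where(m[:, None], b + (c - b) * w_bc[:, None], out)
    # edge AC
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w_ac = safe_div(d2, d2 - d6)
    out = np.where(m[:, None], a + ac * w_ac[:, None], out)
    # edge AB
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v_ab = safe_div(d1, d1 - d3)
    out = np.where(m[:, None], a + ab * v_ab[:, None], out)
    # vertices
    out = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, out)
    return out


@njit(cache=False, inline="always")
def _pt_tri_sq(px, py, pz, tri, f):  # pragma: no cover - numba kernel
    """Squared distance from point to triangle f (scalar Ericson)."""
    ax = tri[f, 0, 0]; ay = tri[f, 0, 1]; az = tri[f, 0, 2]
    bx = tri[f, 1, 0]; by = tri[f, 1, 1]; bz = tri[f, 1, 2]
    cx = tri[f, 2, 0]; cy = tri[f, 2, 1]; cz = tri[f, 2, 2]
    abx = bx - ax; aby = by - ay; abz = bz - az
    acx = cx - ax; acy = cy - ay; acz = cz - az
    apx = px - ax; apy = py - ay; apz = pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        qx = ax; qy = ay; qz = az
    else:
        bpx = px - bx; bpy = py - by; bpz = pz - bz
        d3 = abx * bpx + aby * bpy + abz * bpz
        d4 = acx * bpx + acy * bpy + acz * bpz
        if d3 >= 0.0 and d4 <= d3:
            qx = bx; qy = by; qz = bz
        else:
            vc = d1 * d4 - d3 * d2
            if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                den = d1 - d3
                v = d1 / den if den != 0.0 else 0.0
                qx = ax + v * abx; qy = ay + v * aby; qz = az + v * abz
            else:
                cpx = px - cx; cpy = py - cy; cpz = pz - cz
                d5 = abx * cpx + aby * cpy + abz * cpz
                d6 = acx * cpx + acy * cpy + acz * cpz
                if d6 >= 0.0 and d5 <= d6:
                    qx = cx; qy = cy; qz = cz
                else:
                    vb = d5 * d2 - d1 * d6
                    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                        den = d2 - d6
                        w = d2 / den if den != 0.0 else 0.0
                        qx = ax + w * acx; qy = ay + w * acy; qz = az + w * acz
                    else:
                        va = d3 * d6 - d5 * d4
                        if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                            den = (d4 - d3) + (d5 - d6)
                            w = (d4 - d3) / den if den != 0.0 else 0.0
                            qx = bx + w * (cx - bx)
                            qy = by + w * (cy - by)
                            qz = bz + w * (cz - bz)
                        else:
                            den = va + vb + vc
                            inv = 1.0 / den if den != 0.0 else 0.0
                            v = vb * inv
                            w = vc * inv
                            qx = ax + abx * v + acx * w
                            qy = ay + aby * v + acy * w
                            qz = az + abz * v + acz * w
    dx = px - qx; dy = py - qy; dz = pz - qz
    return dx * dx + dy * dy + dz * dz


@njit(cache=False)
def _bvh_query(points, tri, node_min, node_max, node_left, node_right,
               node_start, node_count, face_order):  # pragma: no cover
    """Exact squared surface distance per point via branch-and-bound
    traversal of the AABB BVH (numba-compiled)."""
    n = points.shape[0]
    out = np.empty(n)
    stack = np.empty(128, dtype=np.int64)
    prev_d = 1e150
    prev_x = 1e150
    prev_y = 0.0
    prev_z = 0.0
    for i in range(n):
        px = points[i, 0]; py = points[i, 1]; pz = points[i, 2]
        # warm start: d(p) <= d(p_prev) + |p - p_prev| (triangle inequality);
        # consecutive sample points are spatially coherent, so this is tight
        hx = px - prev_x; hy = py - prev_y; hz = pz - prev_z
        hop = np.sqrt(hx * hx + hy * hy + hz * hz)
        ub = prev_d + hop
        best = ub * ub if ub < 1e140 else 1e300
        top = 0
        stack[0] = 0
        top = 1
        while top > 0:
            top -= 1
            node = stack[top]
            # squared distance from point to node AABB
            dx = max(node_min[node, 0] - px, 0.0, px - node_max[node, 0])
            dy = max(node_min[node, 1] - py, 0.0, py - node_max[node, 1])
            dz = max(node_min[node, 2] - pz, 0.0, pz - node_max[node, 2])
            if dx * dx + dy * dy + dz * dz >= best:
                continue
            left = node_left[node]
            if left < 0:  # leaf
                for jj in range(node_start[node],
                                node_start[node] + node_count[node]):
                    d2 = _pt_tri_sq(px, py, pz, tri, face_order[jj])
                    if d2 < best:
                        best = d2
            else:
                right = node_right[node]
                # near child on top of the stack (popped first)
                dlx = max(node_min[left, 0] - px, 0.0, px - node_max[left, 0])
                dly = max(node_min[left, 1] - py, 0.0, py - node_max[left, 1])
                dlz = max(node_min[left, 2] - pz, 0.0, pz - node_max[left, 2])
                drx = max(node_min[right, 0] - px, 0.0, px - node_max[right, 0])
                dry = max(node_min[right, 1] - py, 0.0, py - node_max[right, 1])
                drz = max(node_min[right, 2] - pz, 0.0, pz - node_max[right, 2])
                dl = dlx * dlx + dly * dly + dlz * dlz
                dr = drx * drx + dry * dry + drz * drz
                if dl <= dr:
                    stack[top] = right
                    stack[top + 1] = left
                else:
                    stack[top] = left
                    stack[top + 1] = right
                top += 2
        out[i] = best
        prev_d = np.sqrt(best)
        prev_x = px; prev_y = py; prev_z = pz
    return out


def _bvh_query_python(points, tri, node_min, node_max, node_left, node_right,
                      node_start, node_count, face_order):
    """Pure-python/numpy fallback: brute per-point over leaf candidates
    collected by the same traversal (used only without numba)."""
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        stack = [0]
        while stack:
            node = stack.pop()
            d = np.maximum(node_min[node] - p, 0.0)
            d = np.maximum(d, p - node_max[node])
            if float(d @ d) >= best:
                continue
            if node_left[node] < 0:
                faces = face_order[
                    node_start[node]: node_start[node] + node_count[node]]
                t = tri[faces]
                cp = closest_point_on_triangles(
                    np.broadcast_to(p, (len(t), 3)), t[:, 0], t[:, 1], t[:, 2]
                )
                d2 = np.sum((p - cp) ** 2, axis=1).min()
                if d2 < best:
                    best = float(d2)
            else:
                stack.append(node_left[node])
                stack.append(node_right[node])
        out[i] = best
    return out


class SurfaceQuery:
    """Exact unsigned distance from points to a triangulated surface.

    A median-split AABB BVH over the faces (leaf size 4) is traversed
    per query point with branch-and-bound on the exact point-triangle
    distance; exact to floating-point round-off.
    """

    _LEAF_SIZE = 4

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.ascontiguousarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        self.triangles = np.ascontiguousarray(vertices[faces])  # (F, 3, 3)
        self._build()

    def _build(self) -> None:
        tri = self.triangles
        F = len(tri)
        fmin = tri.min(axis=1)
        fmax = tri.max(axis=1)
        cent = tri.mean(axis=1)
        order = np.arange(F, dtype=np.int64)

        node_min, node_max = [], []
        node_left, node_right = [], []
        node_start, node_count = [], []

        def build(lo: int, hi: int) -> int:
            idx = len(node_min)
            sub = order[lo:hi]
            node_min.append(fmin[sub].min(axis=0))
            node_max.append(fmax[sub].max(axis=0))
            node_left.append(-1)
            node_right.append(-1)
            node_start.append(lo)
            node_count.append(hi - lo)
            if hi - lo > self._LEAF_SIZE:
                axis = int(np.argmax(cent[sub].max(axis=0) - cent[sub].min(axis=0)))
                mid = (lo + hi) // 2
                part = np.argpartition(cent[sub, axis], mid - lo)
                order[lo:hi] = sub[part]
                left = build(lo, mid)
                right = build(mid, hi)
                node_left[idx] = left
                node_right[idx] = right
                node_count[idx] = 0
            return idx

        import sys

        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 10000))
        try:
            build(0, F)
        finally:
            sys.setrecursionlimit(limit)
        self._node_min = np.ascontiguousarray(node_min, dtype=float)
        self._node_max = np.ascontiguousarray(node_max, dtype=float)
        self._node_left = np.asarray(node_left, dtype=np.int64)
        self._node_right = np.asarray(node_right, dtype=np.int64)
        self._node_start = np.asarray(node_start, dtype=np.int64)
        self._node_count = np.asarray(node_count, dtype=np.int64)
        self._face_order = order

    def distance(self, points: np.ndarray) -> np.ndarray:
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=float)
        fn = _bvh_query if _HAVE_NUMBA else _bvh_query_python
        d2 = fn(points, self.triangles, self._node_min, self._node_max,
                self._node_left, self._node_right, self._node_start,
                self._node_count, self._face_order)
        return np.sqrt(d2)

    def brute_distance(self, points: np.ndarray) -> np.ndarray:
        """Unpruned all-points-to-all-triangles minimum (oracle path)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tri = self.triangles
        out = np.empty(len(points))
        for i, p in enumerate(points):
            cp = closest_point_on_triangles(
                np.broadcast_to(p, (len(tri), 3)), tri[:, 0], tri[:, 1], tri[:, 2]
            )
            out[i] = np.sqrt(np.sum((p - cp) ** 2, axis=1).min())
        return out


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid (R, t) minimizing ||R P_i + t - Q_i||^2, det(R) = +1."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    return R, t
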