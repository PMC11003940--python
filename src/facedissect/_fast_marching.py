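"""First-order fast marching on triangle meshes (Eikonal solver, unit speed).

Solves the surface Eikonal equation |grad U| = 1 outward from a source
vertex, giving on-surface geodesic distance fields.  Per-triangle updates use
the planar two-point scheme: assume a locally planar wavefront with unit
gradient, solve the resulting quadratic for the arrival time at the unknown
corner, and accept the solution only when the characteristic enters through
the triangle's interior (both barycentric gradient coefficients negative);
otherwise fall back to the one-sided edge update.  Obtuse corners simply fail
the interior test and take the edge fallback, which overestimates slightly —
adequate for the near-uniform triangulations produced in this package.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["MeshGeodesics"]

_FAR, _NARROW, _ACCEPTED = 0, 1, 2


class MeshGeodesics:
    """Precomputed fast-marching solver for one mesh.

    Building the per-corner geometry once lets repeated source queries (one
    per landmark) reuse the same tables.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.asarray(vertices, float)
        faces = np.asarray(faces, np.int64)
        self.n_vertices = len(vertices)
        # corner (f, c) has unknown vertex C = faces[f, c], knowns A, B
        ia = faces[:, [1, 2, 0]]  # A for corner c
        ib = faces[:, [2, 0, 1]]  # B for corner c
        ic = faces
        pa = vertices[ia] - vertices[ic]
        pb = vertices[ib] - vertices[ic]
        b2 = (pa**2).sum(-1)
        a2 = (pb**2).sum(-1)
        dot = (pa * pb).sum(-1)
        det = b2 * a2 - dot**2
        det = np.where(det <= 1e-18, 1e-18, det)
        q11 = a2 / det
        q12 = -dot / det
        q22 = b2 / det

        self._corner = {}  # vertex -> list of per-corner tuples
        blen = np.sqrt(b2)
        alen = np.sqrt(a2)
        p1 = q11 + 2 * q12 + q22
        for f in range(len(faces)):
            for c in range(3):
                v = int(ic[f, c])
                self._corner.setdefault(v, []).append(
                    (
                        int(ia[f, c]),
                        int(ib[f, c]),
                        float(blen[f, c]),
                        float(alen[f, c]),
                        float(q11[f, c]),
                        float(q12[f, c]),
                        float(q22[f, c]),
                        float(p1[f, c]),
                    )
                )
        # simple vertex adjacency for the final sweep of edge updates
        self._neighbors: dict[int, set[int]] = {}
        for f in faces:
            for i in range(3):
                self._neighbors.setdefault(int(f[i]), set()).update(
                    (int(f[(i + 1) % 3]), int(f[(i + 2) % 3]))
                )

    def distance_field(self, source: int) -> np.ndarray:
        """Geodesic distance from ``source`` to every vertex (inf if unreachable)."""
        n = self.n_vertices
        u = np.full(n, np.inf)
        status = np.zeros(n, dtype=np.int8)
        u[source] = 0.0
        heap = [(0.0, source)]
        corner = self._corner
        while heap:
            d, v = heapq.heappop(heap)
            if status[v] == _ACCEPTED:
                continue
            status[v] = _ACCEPTED
            # relax every corner whose triangle touches v
            for w in self._neighbors.get(v, ()):  # vertices sharing a face with v
                if status[w] == _ACCEPTED:
                    continue
                best = u[w]
                for (a, b, blen, alen, q11, q12, q22, p1) in corner[w]:
                    ua = u[a] if status[a] == _ACCEPTED else np.inf
                    ub = u[b] if status[b] == _ACCEPTED else np.inf
                    if np.isfinite(ua) and np.isfinite(ub):
                        p2 = q11 * ua + q12 * (ua + ub) + q22 * ub
                        p3 = q11 * ua * ua + 2 * q12 * ua * ub + q22 * ub * ub - 1.0
                        disc = p2 * p2 - p1 * p3
                        if disc >= 0.0:
                            t = (p2 + disc**0.5) / p1
                            if t >= ua and t >= ub:
                                alpha = q11 * (ua - t) + q12 * (ub - t)
                                beta = q12 * (ua - t) + q22 * (ub - t)
                                if alpha <= 0.0 and beta <= 0.0 and t < best:
                                    best = t
                                    continue
                    # one-sided fallbacks along the triangle's edges
                    if np.isfinite(ua) and ua + blen < best:
                        best = ua + blen
                    if np.isfinite(ub) and ub + alen < best:
                        best = ub + alen
                if best < u[w]:
                    u[w] = best
                    heapq.heappush(heap, (best, w))
        return u
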