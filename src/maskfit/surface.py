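"""Exact closest-point queries against a triangulated surface.

Candidate triangles come from a KD-tree over the mesh vertices (the
faces incident to the ``k`` nearest vertices of each query); the exact
closest point on each candidate is found with the standard barycentric
clamp, and the best candidate wins. For well-shaped meshes the true
closest triangle is incident to one of the nearest vertices, so the
result matches an exhaustive scan over all triangles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_on_surface"]


def closest_on_surface(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    k: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest surface point for each query point.

    Returns ``(closest_points, distances, triangle_indices)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if len(faces) == 0:
        raise ValueError("surface has no triangles")
    tree = cKDTree(vertices)
    k = min(k, len(vertices))
    _, knn = tree.query(points, k=k)
    knn = np.atleast_2d(knn)
    indptr, incident = _vertex_face_csr(faces, len(vertices))
    n = len(points)
    cand_lists = [
        np.unique(
            np.concatenate([incident[indptr[v] : indptr[v + 1]] for v in row])
        )
        for row in knn
    ]
    lens = np.array([len(c) for c in cand_lists])
    flat_q = np.repeat(np.arange(n), lens)
    flat_f = np.concatenate(cand_lists)
    cp = _closest_point_triangle(points[flat_q], vertices[faces[flat_f]])
    d2 = np.sum((points[flat_q] - cp) ** 2, axis=1)
    # min-reduce per query; stable lexsort keeps the lowest triangle
    # index among exact ties deterministic
    order = np.lexsort((flat_f, d2, flat_q))
    first = np.ones(len(order), dtype=bool)
    first[1:] = flat_q[order][1:] != flat_q[order][:-1]
    sel = order[first]
    best_pt = np.zeros((n, 3))
    best_tri = np.zeros(n, dtype=np.int64)
    best_d2 = np.full(n, np.inf)
    best_pt[flat_q[sel]] = cp[sel]
    best_tri[flat_q[sel]] = flat_f[sel]
    best_d2[flat_q[sel]] = d2[sel]
    return best_pt, np.sqrt(best_d2), best_tri


def _vertex_face_csr(
    faces: np.ndarray, n_vertices: int
) -> tuple[np.ndarray, np.ndarray]:
    """CSR map vertex -> incident face indices."""
    flat_v = faces.ravel()
    flat_f = np.repeat(np.arange(len(faces)), 3)
    order = np.argsort(flat_v, kind="stable")
    incident = flat_f[order]
    counts = np.bincount(flat_v, minlength=n_vertices)
    indptr = np.zeros(n_vertices + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, incident


def _closest_point_triangle(P: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle (a, b, c) to each P (vectorized
    Voronoi-region case analysis)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, P - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = P - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = P - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)
    out = np.empty_like(P)
    done = np.zeros(len(P), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    def safe_div(num, den):
        return num / np.where(den == 0.0, 1.0, den)

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex b
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex c
    vc = d1 * d4 - d3 * d2
    v = safe_div(d1, d1 - d3)[:, None]
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v * ab)  # edge ab
    vb = d5 * d2 - d1 * d6
    w = safe_div(d2, d2 - d6)[:, None]
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    w = safe_div(d4 - d3, (d4 - d3) + (d5 - d6))[:, None]
    assign(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w * (c - b)
    )  # edge bc
    denom = va + vb + vc
    v = safe_div(vb, denom)[:, None]
    w = safe_div(vc, denom)[:, None]
    assign(np.ones(len(P), dtype=bool), a + v * ab + w * ac)  # interior
    return out
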