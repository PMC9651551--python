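"""Signed nearest-neighbour distance fields and distribution summaries.

Fit quality is read off the signed distance from each respirator vertex
to the facial surface: positive distances are gaps (respirator stands
off the skin), negative distances are indentation (respirator inside the
skin envelope). The same machinery quantifies soft-tissue displacement
between loaded and unloaded facial scans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import EmptyMeshError, SurfaceMesh, vertex_area_weights

__all__ = [
    "SignedDistanceMap",
    "DistanceSummary",
    "exhaustive_nearest",
    "signed_distances",
    "weighted_percentile",
    "summarize_distances",
    "export_distance_csv",
    "export_colored_ply",
]


@dataclass
class SignedDistanceMap:
    """Per-vertex signed distances of a query mesh to a reference surface.

    ``distances`` are in mm; negative means the query vertex lies on the
    inward side of the reference surface (indentation), positive on the
    outward side (gap). ``weights`` are per-vertex area weights in mm^2
    (or all ones for count weighting).
    """

    distances: np.ndarray
    weights: np.ndarray
    query: SurfaceMesh

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.distances.shape != self.weights.shape:
            raise ValueError("distances and weights must have equal length")
        if len(self.distances) != self.query.n_vertices:
            raise ValueError("map cardinality must equal query vertex count")
        if not np.isfinite(self.distances).all():
            raise ValueError("distances contain NaN/Inf")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")


@dataclass
class DistanceSummary:
    """Central 95% interval and histogram of a signed-distance map.

    ``p_low`` / ``p_high`` are the weighted 2.5th / 97.5th percentiles;
    ``ci_width`` is their difference — the width of the central interval
    holding 95% of the (area-weighted) distances, the scalar used to rank
    deformation levels.
    """

    p_low: float
    p_high: float
    ci_width: float
    bin_edges: np.ndarray
    density: np.ndarray

    def as_dict(self) -> dict:
        return {
            "p_low": self.p_low,
            "p_high": self.p_high,
            "ci_width": self.ci_width,
        }


def exhaustive_nearest(
    query_points: np.ndarray, reference_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force nearest neighbour (the oracle for tree-based search).

    Returns ``(indices, distances)``; ties resolve to the lowest
    reference index (argmin order).
    """
    Q = np.atleast_2d(np.asarray(query_points, dtype=np.float64))
    R = np.atleast_2d(np.asarray(reference_points, dtype=np.float64))
    if len(Q) == 0 or len(R) == 0:
        raise ValueError("empty point set")
    # chunked to keep the n_q x n_r matrix small
    idx = np.empty(len(Q), dtype=np.int64)
    dist = np.empty(len(Q))
    chunk = max(1, int(4e6) // max(1, len(R)))
    for start in range(0, len(Q), chunk):
        block = Q[start : start + chunk]
        d2 = (
            np.sum(block**2, axis=1)[:, None]
            + np.sum(R**2, axis=1)[None, :]
            - 2.0 * block @ R.T
        )
        # recompute exactly for the winners to avoid catastrophic cancellation
        i = np.argmin(d2, axis=1)
        idx[start : start + chunk] = i
        dist[start : start + chunk] = np.linalg.norm(block - R[i], axis=1)
    return idx, dist


def signed_distances(
    query: SurfaceMesh,
    reference: SurfaceMesh,
    weighting: str = "area",
    mode: str = "vertex",
) -> SignedDistanceMap:
    """Signed distance from each query vertex to the reference surface.

    ``mode="vertex"`` (default, and what the sweep uses) measures to the
    nearest reference *vertex*; ``mode="surface"`` projects onto the
    reference triangles instead. The sign comes from the outward normal
    at the nearest reference point: negative = query inside the reference
    envelope (indentation), positive = outside (gap).
    """
    if reference.n_faces == 0:
        raise EmptyMeshError(
            "reference mesh has no faces; outward normals are not orientable"
        )
    if weighting not in ("area", "count"):
        raise ValueError("weighting must be 'area' or 'count'")
    if mode == "vertex":
        tree = cKDTree(reference.vertices)
        dist, idx = tree.query(query.vertices)
        normals = reference.outward_normals[idx]
        offset = query.vertices - reference.vertices[idx]
    elif mode == "surface":
        from .surface import closest_on_surface

        closest, dist, tri = closest_on_surface(
            query.vertices, reference.vertices, reference.faces
        )
        normals = np.asarray(reference.to_trimesh().face_normals)[tri]
        offset = query.vertices - closest
    else:
        raise ValueError("mode must be 'vertex' or 'surface'")
    sign = np.where(np.einsum("ij,ij->i", offset, normals) < 0.0, -1.0, 1.0)
    signed = sign * dist
    if weighting == "area":
        weights = vertex_area_weights(query)
        if (weights <= 0).any():
            # boundary-isolated vertices would get zero weight on dirty
            # meshes; distances on a clean mesh always have positive area
            weights = np.maximum(weights, np.finfo(float).tiny)
    else:
        weights = np.ones(query.n_vertices)
    return SignedDistanceMap(distances=signed, weights=weights, query=query)


def weighted_percentile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> np.ndarray:
    """Weighted percentile by linear interpolation of the empirical CDF.

    Each sorted value ``v_i`` sits at cumulative position
    ``(c_i - w_i / 2) / W``; percentiles interpolate linearly between
    positions and clamp at the extremes. Invariant to uniform rescaling
    of the weights and to input ordering.
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    positions = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.asarray(q, dtype=np.float64) / 100.0, positions, v)


def summarize_distances(
    dmap: SignedDistanceMap, n_bins: int = 100
) -> DistanceSummary:
    """Central-95% percentiles and a density-normalized histogram."""
    if len(dmap.distances) == 0:
        raise ValueError("cannot summarize an empty distance map")
    p_low, p_high = weighted_percentile(
        dmap.distances, dmap.weights, np.array([2.5, 97.5])
    )
    lo, hi = float(dmap.distances.min()), float(dmap.distances.max())
    if hi <= lo:  # constant input: give the histogram a token width
        lo, hi = lo - 0.5, hi + 0.5
    density, edges = np.histogram(
        dmap.distances,
        bins=n_bins,
        range=(lo, hi),
        weights=dmap.weights,
        density=True,
    )
    return DistanceSummary(
        p_low=float(p_low),
        p_high=float(p_high),
        ci_width=float(p_high - p_low),
        bin_edges=edges,
        density=density,
    )


def export_distance_csv(dmap: SignedDistanceMap, path: str | os.PathLike) -> None:
    """Write (vertex index, signed distance, area weight) rows as CSV."""
    import pandas as pd

    pd.DataFrame(
        {
            "vertex": np.arange(len(dmap.distances)),
            "distance_mm": dmap.distances,
            "weight_mm2": dmap.weights,
        }
    ).to_csv(path, index=False)


def export_colored_ply(
    dmap: SignedDistanceMap,
    path: str | os.PathLike,
    vmin: float = -5.0,
    vmax: float = 5.0,
) -> None:
    """Write the query mesh as PLY with a blue-white-red distance colouring.

    Blue = indentation, white = contact, red = gap; saturation at
    ``vmin``/``vmax`` mm. Reproduces the usual contour-plot reading of a
    registration shape.
    """
    t = np.clip((dmap.distances - vmin) / (vmax - vmin), 0.0, 1.0)
    rgb = np.empty((len(t), 3))
    lower = t < 0.5
    s = np.where(lower, t * 2.0, (t - 0.5) * 2.0)
    rgb[lower] = np.column_stack(
        [s[lower], s[lower], np.ones(lower.sum())]
    )  # blue -> white
    rgb[~lower] = np.column_stack(
        [
            np.ones((~lower).sum()),
            1.0 - s[~lower],
            1.0 - s[~lower],
        ]
    )  # white -> red
    tm = dmap.query.to_trimesh()
    tm.visual.vertex_colors = (rgb * 255).astype(np.uint8)
    tm.export(os.fspath(path), file_type="ply")
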