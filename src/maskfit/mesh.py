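"""Triangulated surface meshes, STL I/O, cleaning and rigid transforms.

All geometry is in millimetres. STL carries no unit metadata, so this is a
package-wide convention: faces are assumed to have been exported at mm scale
(the native scale of clinical surface scans).

The coordinate convention is right-handed with the face looking along +z
after :func:`pre_rotate` has been applied to scanner output.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "RigidTransform",
    "MeshFormatError",
    "EmptyMeshError",
    "read_stl",
    "write_stl",
    "clean_mesh",
    "pre_rotate",
    "vertex_area_weights",
    "apply_transform",
]

#: Vertices closer than this (mm) are merged into one index on STL read.
#: STL duplicates shared vertices per facet, so welding is required to
#: recover mesh adjacency.
WELD_TOLERANCE = 1e-6


class MeshFormatError(ValueError):
    """Raised for unreadable or truncated mesh files."""


class EmptyMeshError(ValueError):
    """Raised when an operation would produce or consume an empty mesh."""


@dataclass
class SurfaceMesh:
    """A triangulated 3D surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Triangles as triples of vertex indices.
    vertex_normals : (n, 3) float array, optional
        Outward unit normals.  Computed lazily from face winding when not
        supplied (see :attr:`outward_normals`).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {self.faces.shape}")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates contain NaN/Inf")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.vertex_normals is not None:
            self.vertex_normals = np.ascontiguousarray(
                self.vertex_normals, dtype=np.float64
            )
            if self.vertex_normals.shape != self.vertices.shape:
                raise ValueError("vertex_normals shape mismatch")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def outward_normals(self) -> np.ndarray:
        """Per-vertex outward unit normals (area-weighted from face winding)."""
        if self.vertex_normals is None:
            if len(self.faces) == 0:
                raise EmptyMeshError(
                    "mesh has no faces; outward normals are undefined"
                )
            self.vertex_normals = np.asarray(
                self.to_trimesh().vertex_normals, dtype=np.float64
            ).copy()
        return self.vertex_normals

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(_triangle_areas(self.vertices, self.faces).sum())


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body transform ``v' = R v + t``.

    ``rotation`` must be orthonormal with determinant +1 (tolerance 1e-8);
    reflections are rejected.  Composition and inversion stay within the
    type.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis: str, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        return cls(_axis_rotation_matrix(axis, angle_deg), np.asarray(translation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equal to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def _axis_rotation_matrix(axis: str, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=np.float64)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=np.float64)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=np.float64)
    raise ValueError(f"axis must be 'x', 'y' or 'z', got {axis!r}")


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if len(faces) == 0:
        return np.zeros(0)
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def _weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOLERANCE
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (grid-rounding weld).

    Deterministic: the kept representative for each cell is the first
    occurrence in input order.
    """
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)  # keep first-occurrence ordering
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse][faces]
    return new_vertices, new_faces


def read_stl(path: str | os.PathLike) -> SurfaceMesh:
    """Read a binary or ASCII STL file and weld duplicated vertices.

    STL stores three independent vertices per facet; on read they are
    welded (tolerance :data:`WELD_TOLERANCE` mm) so that shared vertices
    get one index and mesh adjacency is recoverable.  Face winding is
    preserved.  Units are taken as mm.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(84)
    is_binary = True
    if head[:5].lower() == b"solid":
        # ASCII unless the binary facet count matches the file size exactly.
        if size >= 84:
            (count,) = struct.unpack("<I", head[80:84])
            is_binary = size == 84 + 50 * count
        else:
            is_binary = False
    if is_binary:
        if size < 84:
            raise MeshFormatError(
                f"{path}: truncated binary STL, only {size} bytes "
                f"(header needs 84, truncation at byte offset {size})"
            )
        (count,) = struct.unpack("<I", head[80:84])
        expected = 84 + 50 * count
        if size != expected:
            raise MeshFormatError(
                f"{path}: binary STL declares {count} facets "
                f"({expected} bytes) but file has {size} bytes; "
                f"truncation/overrun at byte offset {min(size, expected)}"
            )
    try:
        tm = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - rewrap parser failures
        raise MeshFormatError(f"{path}: unparseable STL ({exc})") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(faces) == 0:
        raise MeshFormatError(f"{path}: STL contains no facets")
    vertices, faces = _weld_vertices(vertices, faces)
    return SurfaceMesh(vertices, faces)


def write_stl(
    mesh: SurfaceMesh, path: str | os.PathLike, dialect: str = "binary"
) -> None:
    """Write ``mesh`` as STL (``dialect`` is ``"binary"`` or ``"ascii"``)."""
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write an STL with zero facets")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    tm = mesh.to_trimesh()
    if dialect == "binary":
        data = tm.export(file_type="stl")
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        text = tm.export(file_type="stl_ascii")
        with open(path, "w") as fh:
            fh.write(text)


def clean_mesh(
    mesh: SurfaceMesh, min_component_fraction: float = 0.01
) -> SurfaceMesh:
    """Remove duplicate faces, zero-area faces, small floating components
    and unreferenced vertices; reindex.

    Connected components whose total area is below
    ``min_component_fraction`` times the largest component's area are
    discarded (scan debris such as detached slivers).  Idempotent.
    """
    tm = mesh.to_trimesh()
    # duplicate faces (regardless of winding), then degenerate faces
    keep = np.zeros(len(tm.faces), dtype=bool)
    _, first = np.unique(np.sort(tm.faces, axis=1), axis=0, return_index=True)
    keep[first] = True
    tm.update_faces(keep)
    areas = _triangle_areas(np.asarray(tm.vertices), np.asarray(tm.faces))
    tm.update_faces(areas > 0.0)
    if len(tm.faces) == 0:
        raise EmptyMeshError("mesh empty after cleaning")
    # face_adjacency misses isolated faces; label faces via shared vertices
    labels = _face_component_labels(np.asarray(tm.faces))
    areas = _triangle_areas(np.asarray(tm.vertices), np.asarray(tm.faces))
    comp_area = np.bincount(labels, weights=areas)
    cutoff = min_component_fraction * comp_area.max()
    tm.update_faces(comp_area[labels] >= cutoff)
    if len(tm.faces) == 0:
        raise EmptyMeshError("mesh empty after cleaning")
    tm.remove_unreferenced_vertices()
    return SurfaceMesh.from_trimesh(tm)


def _face_component_labels(faces: np.ndarray) -> np.ndarray:
    """Label faces by vertex-connected component (union-find over edges)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = int(faces.max()) + 1
    rows = faces[:, [0, 1, 2]].ravel()
    cols = faces[:, [1, 2, 0]].ravel()
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, vertex_labels = connected_components(adj, directed=False)
    return vertex_labels[faces[:, 0]]


def pre_rotate(mesh: SurfaceMesh, axis: str, angle_deg: float) -> SurfaceMesh:
    """Rotate the whole mesh about a coordinate axis through the origin.

    Scanner exports are commonly supine; a 90 degree rotation brings the
    face into the canonical x-y frame looking along +z.
    """
    T = RigidTransform.from_axis_angle(axis, angle_deg)
    return apply_transform(mesh, T)


def vertex_area_weights(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex area weights in mm^2 (one third of incident triangle area).

    The weights sum to the total surface area, so area-weighted statistics
    over vertices equal statistics over the surface measure for piecewise
    linear fields.
    """
    areas = _triangle_areas(mesh.vertices, mesh.faces)
    w = np.zeros(mesh.n_vertices)
    for c in range(3):
        np.add.at(w, mesh.faces[:, c], areas / 3.0)
    return w


def apply_transform(mesh: SurfaceMesh, T: RigidTransform) -> SurfaceMesh:
    """Apply a rigid transform to every vertex (and rotate stored normals)."""
    normals = None
    if mesh.vertex_normals is not None:
        normals = mesh.vertex_normals @ T.rotation.T
    return SurfaceMesh(T.apply(mesh.vertices), mesh.faces.copy(), normals)
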