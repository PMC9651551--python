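"""Deterministic synthetic face / respirator / loaded-face scenes.

No facial scans ship with the package, so every pipeline stage is
exercised on generated scenes with known ground truth: a smooth
height-field face (dome base, Gaussian nose ridge, two cheek mounds), an
internal respirator shell built as a normal-offset of the nose-and-mouth
region with a sealing rim, a loaded face carrying a prescribed
indentation and lateral bulge, and recorded rigid misalignments between
the "scans".

Height-field faces have no undercuts, which keeps signed-distance signs
unambiguous; scene defaults put the prescribed indentation and bulge
peaks in the 3-6 mm range observed for real respirator donning, and the
respirator standoff in the low millimetres so that fit improves visibly
as the deformation ladder loosens.

Ground-truth displacement percentiles are computed from the prescribed
field and the face's area weights — never from any registration output —
so they can serve as an independent oracle for the pipeline.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .anthro import LandmarkSet
from .distances import weighted_percentile
from .mesh import (
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    vertex_area_weights,
    write_stl,
)

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "GroundTruth",
    "make_face",
    "make_mask",
    "make_loaded_face",
    "make_scene",
    "write_scene",
]

MIN_RESOLUTION = 20


def _default_perturb_unloaded() -> RigidTransform:
    return RigidTransform.from_axis_angle("z", 10.0, (5.0, 2.0, -3.0))


def _default_perturb_loaded() -> RigidTransform:
    return RigidTransform.from_axis_angle("y", 7.0, (-4.0, 3.0, 2.0))


def _default_perturb_respirator() -> RigidTransform:
    # the respirator scans come from one tomography session on the same
    # phantom, so their misalignment to the reference is sub-millimetre;
    # facial scans are separate sessions and get the large misalignments
    return RigidTransform.from_axis_angle("z", -0.4, (0.3, -0.3, 0.2))


@dataclass
class SceneParams:
    """Geometry, loading and perturbation parameters of one scene (mm).

    The defaults describe an adult-scale face (160 x 180 mm extent,
    35 mm of facial convexity, a 12 mm nose ridge, 6 mm cheek mounds), a
    respirator shell standing 0.5 mm off the skin with a 2.5 mm bridge
    gap and a slightly pre-indented sealing rim, and a loaded face with
    a 5 mm deep cheek indentation and a 4 mm lateral bulge — the
    magnitude range seen when a filtering facepiece is strapped on.
    """

    # face
    face_width: float = 160.0
    face_height: float = 180.0
    dome_height: float = 35.0
    nose_height: float = 12.0
    nose_width: float = 18.0
    nose_length: float = 30.0
    nose_center_y: float = 10.0
    cheek_amplitude: float = 6.0
    cheek_sigma: float = 18.0
    alar_half_width: float = 11.0
    exo_half_width: float = 33.5
    eye_line_y: float = 45.0
    menton_y: float = -70.0
    # respirator
    mask_half_width: float = 45.0
    mask_y_min: float = -60.0
    mask_y_max: float = 25.0
    mask_offset: float = 0.5
    mask_bridge_gap: float = 2.5
    bridge_center: tuple[float, float] = (0.0, 20.0)
    bridge_sigma: float = 18.0
    rim_width: float = 8.0
    rim_offset: float | None = -0.5
    shell_thickness: float = 4.0
    # loading
    indent_depth: float = 5.0
    indent_center: tuple[float, float] = (50.0, -42.0)
    indent_sigma: float = 30.0
    bulge_height: float = 4.0
    bulge_center: tuple[float, float] = (-56.0, 36.0)
    bulge_sigma: float = 30.0
    # discretization / misalignment / noise
    resolution: int = 80
    perturb_unloaded: RigidTransform = field(
        default_factory=_default_perturb_unloaded
    )
    perturb_loaded: RigidTransform = field(
        default_factory=_default_perturb_loaded
    )
    perturb_respirator: RigidTransform = field(
        default_factory=_default_perturb_respirator
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < MIN_RESOLUTION:
            raise ValueError(
                f"resolution must be >= {MIN_RESOLUTION} vertices per axis"
            )
        for name in ("indent_depth", "bulge_height", "noise_sd", "nose_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_(self, **kwargs) -> "SceneParams":
        return replace(self, **kwargs)


def _face_height_function(params: SceneParams):
    ax = 0.75 * params.face_width
    ay = 0.75 * params.face_height
    sx = params.nose_width / 2.0
    sy = params.nose_length / 2.0
    cx, cy = 0.35 * params.face_width / 1.6, -15.0  # cheek mound centers

    def f(x, y):
        dome = params.dome_height * (1.0 - (x / ax) ** 2 - (y / ay) ** 2)
        nose = params.nose_height * np.exp(
            -(x**2) / (2 * sx**2)
            - ((y - params.nose_center_y) ** 2) / (2 * sy**2)
        )
        cheeks = params.cheek_amplitude * (
            np.exp(
                -(((x - cx) ** 2 + (y - cy) ** 2)) / (2 * params.cheek_sigma**2)
            )
            + np.exp(
                -(((x + cx) ** 2 + (y - cy) ** 2)) / (2 * params.cheek_sigma**2)
            )
        )
        return dome + nose + cheeks

    return f


def _grid_mesh(params: SceneParams, zfunc) -> SurfaceMesh:
    n = params.resolution
    xs = np.linspace(-params.face_width / 2, params.face_width / 2, n)
    ys = np.linspace(-params.face_height / 2, params.face_height / 2, n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = zfunc(X, Y)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    # winding chosen so normals point along +z (out of the face)
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    return SurfaceMesh(vertices, faces)


def make_face(params: SceneParams) -> tuple[SurfaceMesh, LandmarkSet]:
    """Generate the canonical unloaded face and its analytic landmarks."""
    f = _face_height_function(params)
    mesh = _grid_mesh(params, f)

    def on_surface(x, y):
        return np.array([x, y, float(f(np.float64(x), np.float64(y)))])

    y0 = params.nose_center_y
    landmarks = LandmarkSet(
        {
            "exocanthion_left": on_surface(-params.exo_half_width, params.eye_line_y),
            "exocanthion_right": on_surface(params.exo_half_width, params.eye_line_y),
            "alare_left": on_surface(-params.alar_half_width, y0),
            "alare_right": on_surface(params.alar_half_width, y0),
            "nasion": on_surface(0.0, y0 + params.nose_length * 0.75),
            "pronasale": on_surface(0.0, y0),
            "subnasale": on_surface(0.0, y0 - params.nose_length * 0.75),
            "menton": on_surface(0.0, params.menton_y),
        }
    )
    return mesh, landmarks


def _submesh(mesh: SurfaceMesh, face_keep: np.ndarray) -> SurfaceMesh:
    """Faces selected by mask, with unreferenced vertices dropped."""
    kept = mesh.faces[face_keep]
    used = np.unique(kept)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[kept])


def _mask_region_mask(params: SceneParams, vertices: np.ndarray) -> np.ndarray:
    x, y = vertices[:, 0], vertices[:, 1]
    return (
        (np.abs(x) <= params.mask_half_width)
        & (y >= params.mask_y_min)
        & (y <= params.mask_y_max)
    )


def _mask_offset_field(params: SceneParams, vertices: np.ndarray) -> np.ndarray:
    """Standoff of the internal shell from the skin, per vertex (mm)."""
    x, y = vertices[:, 0], vertices[:, 1]
    bx, by = params.bridge_center
    interior = params.mask_offset + params.mask_bridge_gap * np.exp(
        -((x - bx) ** 2 + (y - by) ** 2) / (2 * params.bridge_sigma**2)
    )
    rim_target = (
        params.mask_offset if params.rim_offset is None else params.rim_offset
    )
    boundary_distance = np.minimum.reduce(
        [
            params.mask_half_width - np.abs(x),
            y - params.mask_y_min,
            params.mask_y_max - y,
        ]
    )
    t = np.clip(boundary_distance / params.rim_width, 0.0, 1.0)
    return (1.0 - t) * rim_target + t * interior


def make_mask(
    face: SurfaceMesh, params: SceneParams
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Build (internal surface, whole geometry) of the respirator.

    The internal surface is the nose-and-mouth region of the face offset
    along the face normals by the configured standoff field (negative =
    pre-indented, 0 = coincident, positive = gapped), with the sealing
    rim offset separately near the region boundary. The whole geometry
    adds an outer shell one thickness further out.
    """
    if (
        params.mask_half_width > params.face_width / 2
        or params.mask_y_min < -params.face_height / 2
        or params.mask_y_max > params.face_height / 2
    ):
        raise ValueError("mask region extends outside the face extent")
    in_region = _mask_region_mask(params, face.vertices)
    face_keep = in_region[face.faces].all(axis=1)
    if not face_keep.any():
        raise ValueError("mask region contains no face triangles")
    used = np.unique(face.faces[face_keep])
    remap = np.full(face.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    region_faces = remap[face.faces[face_keep]]
    normals = face.outward_normals[used]
    offsets = _mask_offset_field(params, face.vertices[used])
    internal_vertices = face.vertices[used] + offsets[:, None] * normals
    internal = SurfaceMesh(internal_vertices, region_faces)
    shell_vertices = internal_vertices + params.shell_thickness * normals
    shell_faces = region_faces[:, ::-1] + len(internal_vertices)
    whole = SurfaceMesh(
        np.vstack([internal_vertices, shell_vertices]),
        np.vstack([region_faces, shell_faces]),
    )
    return internal, whole


def prescribed_displacement(
    params: SceneParams, vertices: np.ndarray
) -> np.ndarray:
    """Signed normal displacement (mm) the loading applies at each vertex.

    Flat-topped (eighth-order super-Gaussian) profiles so that a
    measurable fraction of the face area experiences the full peak
    indentation / bulge, making the prescribed 2.5th / 97.5th percentiles
    sit at (nearly) the peak values.
    """
    x, y = vertices[:, 0], vertices[:, 1]

    def flat_top(center, sigma):
        r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
        return np.exp(-((r2 / sigma**2) ** 4))

    return -params.indent_depth * flat_top(
        params.indent_center, params.indent_sigma
    ) + params.bulge_height * flat_top(params.bulge_center, params.bulge_sigma)


def make_loaded_face(
    face: SurfaceMesh, params: SceneParams
) -> tuple[SurfaceMesh, tuple[float, float], np.ndarray]:
    """Apply the prescribed loading field to the face.

    Returns ``(loaded_face, (p_low, p_high), displacement_field)`` where
    the percentiles are the area-weighted 2.5th / 97.5th percentiles of
    the *prescribed* normal displacement — the analytic ground truth the
    registration pipeline is later asked to recover. Optional Gaussian
    vertex noise is seeded and reproducible.
    """
    disp = prescribed_displacement(params, face.vertices)
    weights = vertex_area_weights(face)
    p_low, p_high = weighted_percentile(disp, weights, np.array([2.5, 97.5]))
    vertices = face.vertices + disp[:, None] * face.outward_normals
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        vertices = vertices + rng.normal(
            0.0, params.noise_sd, size=vertices.shape
        )
    loaded = SurfaceMesh(vertices, face.faces.copy())
    return loaded, (float(p_low), float(p_high)), disp


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    perturb_unloaded: RigidTransform
    perturb_loaded: RigidTransform
    perturb_respirator: RigidTransform
    displacement_field: np.ndarray
    p_low: float
    p_high: float
    landmarks: LandmarkSet
    params: SceneParams


@dataclass
class SyntheticScene:
    """The six scene meshes plus ground truth.

    Subject meshes carry their recorded misalignments; the reference
    head (playing the standardized-head-form role of the alignment
    cascade) and its with-respirator counterpart stay in the canonical
    frame.
    """

    unloaded_face: SurfaceMesh
    loaded_face: SurfaceMesh
    respirator_whole: SurfaceMesh
    respirator_internal: SurfaceMesh
    reference_head: SurfaceMesh
    reference_head_with_respirator: SurfaceMesh
    ground_truth: GroundTruth

    def mesh_dict(self) -> dict[str, SurfaceMesh]:
        return {
            "unloaded_face": self.unloaded_face,
            "loaded_face": self.loaded_face,
            "respirator_whole": self.respirator_whole,
            "respirator_internal": self.respirator_internal,
            "reference_head": self.reference_head,
            "reference_head_with_respirator": self.reference_head_with_respirator,
        }


def make_scene(params: SceneParams | None = None) -> SyntheticScene:
    """Compose face, respirator and loaded face into a full scene."""
    params = params or SceneParams()
    face, landmarks = make_face(params)
    internal, whole = make_mask(face, params)
    loaded, (p_low, p_high), disp = make_loaded_face(face, params)
    reference_head = face.copy()
    # the respirator occludes the skin it covers, so the "head with
    # respirator in situ" scan shows the mask surface instead of that
    # face region
    covered = _mask_region_mask(params, face.vertices)[face.faces].all(axis=1)
    visible = _submesh(face, ~covered)
    ref_with_resp = SurfaceMesh(
        np.vstack([visible.vertices, whole.vertices]),
        np.vstack([visible.faces, whole.faces + visible.n_vertices]),
    )
    Tu, Tl, Tr = (
        params.perturb_unloaded,
        params.perturb_loaded,
        params.perturb_respirator,
    )
    return SyntheticScene(
        unloaded_face=apply_transform(face, Tu),
        loaded_face=apply_transform(loaded, Tl),
        respirator_whole=apply_transform(whole, Tr),
        respirator_internal=apply_transform(internal, Tr),
        reference_head=reference_head,
        reference_head_with_respirator=ref_with_resp,
        ground_truth=GroundTruth(
            perturb_unloaded=Tu,
            perturb_loaded=Tl,
            perturb_respirator=Tr,
            displacement_field=disp,
            p_low=p_low,
            p_high=p_high,
            landmarks=landmarks.transformed(Tu),
            params=params,
        ),
    )


def write_scene(scene: SyntheticScene, out_dir: str | os.PathLike) -> None:
    """Write the six meshes as binary STL plus a ground-truth sidecar."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for name, mesh in scene.mesh_dict().items():
        write_stl(mesh, os.path.join(out_dir, f"{name}.stl"))
    gt = scene.ground_truth
    sidecar = {
        "seed": gt.params.seed,
        "p_low": gt.p_low,
        "p_high": gt.p_high,
        "landmarks": {k: v.tolist() for k, v in gt.landmarks.points.items()},
        "transforms": {
            name: T.as_matrix().tolist()
            for name, T in (
                ("unloaded", gt.perturb_unloaded),
                ("loaded", gt.perturb_loaded),
                ("respirator", gt.perturb_respirator),
            )
        },
        "params": {
            k: v
            for k, v in gt.params.__dict__.items()
            if isinstance(v, (int, float, str, tuple, type(None)))
        },
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
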