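"""Rigid iterative-closest-point (ICP) registration.

The pipeline aligns every scan into a common reference frame before any
fit analysis: both facial scans to a reference head, the respirator's
whole geometry to the reference head with the respirator in situ, and the
respirator's internal surface by reusing that second transform.

The core estimator :class:`RigidICP` follows the scikit-learn protocol
(``fit`` / ``transform`` / ``get_params``); module-level functions wrap it
for mesh inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .mesh import RigidTransform, SurfaceMesh, apply_transform

__all__ = [
    "ICPSettings",
    "ICPResult",
    "CascadeResult",
    "SingularConfigurationError",
    "kabsch_fit",
    "RigidICP",
    "icp_align",
    "align_cascade",
]


class SingularConfigurationError(ValueError):
    """Point configuration too degenerate for a unique rigid fit."""


@dataclass
class ICPSettings:
    """Control parameters for rigid ICP.

    max_iterations : hard cap on correspondence/update rounds.
    rms_tolerance : stop when the RMS correspondence distance changes by
        less than this many mm between rounds.
    correspondence_trim_fraction : fraction of the worst matches dropped
        each round (robustness to outliers / partial overlap).
    initial_transform : applied to the source before iteration begins.
    """

    max_iterations: int = 100
    rms_tolerance: float = 1e-4
    correspondence_trim_fraction: float = 0.0
    initial_transform: RigidTransform = field(
        default_factory=RigidTransform.identity
    )

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rms_tolerance <= 0:
            raise ValueError("rms_tolerance must be > 0")
        if not 0.0 <= self.correspondence_trim_fraction < 1.0:
            raise ValueError("correspondence_trim_fraction must be in [0, 1)")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_history: np.ndarray
    converged: bool

    @property
    def final_rms(self) -> float:
        return float(self.rms_history[-1])


def kabsch_fit(
    source_points: np.ndarray, target_points: np.ndarray
) -> RigidTransform:
    """Closed-form least-squares rigid transform between matched point sets.

    Solves ``argmin_{R,t} sum_i ||R s_i + t - g_i||^2`` over proper
    rotations via SVD of the cross-covariance, with the determinant sign
    fixed so reflections are excluded.
    """
    S = np.asarray(source_points, dtype=np.float64)
    G = np.asarray(target_points, dtype=np.float64)
    if S.shape != G.shape or S.ndim != 2 or S.shape[1] != 3:
        raise ValueError("source and target must be matched (n, 3) arrays")
    if len(S) < 3:
        raise SingularConfigurationError("need at least 3 point pairs")
    cs, cg = S.mean(axis=0), G.mean(axis=0)
    H = (S - cs).T @ (G - cg)
    U, sing, Vt = np.linalg.svd(H)
    # collinear source points leave the rotation about their axis free
    scale = max(np.ptp(S, axis=0).max(), 1.0)
    if sing[1] <= 1e-12 * scale * len(S):
        raise SingularConfigurationError(
            "point configuration is (nearly) collinear; rotation not unique"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cg - R @ cs
    return RigidTransform(R, t)


class RigidICP(BaseEstimator, TransformerMixin):
    """Rigid point-to-point ICP as a scikit-learn style transformer.

    ``fit(X, y)`` aligns the source point cloud ``X`` onto the target
    cloud ``y`` (unmatched; correspondences are nearest neighbours in the
    target, recomputed every round and solved with :func:`kabsch_fit`).
    ``transform`` then maps points with the fitted rigid transform.

    Parameters
    ----------
    max_iterations, rms_tolerance, trim_fraction
        See :class:`ICPSettings`.
    center_init : bool
        Start from the centroid-difference translation. The pipeline's
        meshes are pre-rotated into a common frame, so the centroid shift
        is the dominant initial misalignment.
    initial_transform : RigidTransform or None
        Applied before iteration (after centering is disabled if given).

    Attributes
    ----------
    transform_ : RigidTransform
        Cumulative source-to-target transform.
    rotation_, translation_ : ndarray
        Components of ``transform_``.
    rms_history_ : ndarray
        RMS correspondence distance after each round's update
        (non-increasing).
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        max_iterations: int = 100,
        rms_tolerance: float = 1e-4,
        trim_fraction: float = 0.0,
        center_init: bool = True,
        initial_transform: RigidTransform | None = None,
    ):
        self.max_iterations = max_iterations
        self.rms_tolerance = rms_tolerance
        self.trim_fraction = trim_fraction
        self.center_init = center_init
        self.initial_transform = initial_transform

    #: iterations given to each starting candidate before the best one
    #: is singled out and run to convergence
    _CANDIDATE_ITERATIONS = 20

    def fit(self, X, y):
        src = check_array(X, dtype=np.float64)
        tgt = check_array(y, dtype=np.float64)
        if src.shape[1] != 3 or tgt.shape[1] != 3:
            raise ValueError("point clouds must be (n, 3)")
        ICPSettings(  # validate control parameters
            max_iterations=self.max_iterations,
            rms_tolerance=self.rms_tolerance,
            correspondence_trim_fraction=self.trim_fraction,
        )
        tree = cKDTree(tgt)
        if self.initial_transform is not None:
            candidates = [self.initial_transform]
        else:
            candidates = _initial_candidates(src, tgt, self.center_init)
        best = None
        for T0 in candidates:
            run = _icp_iterations(
                src,
                tgt,
                tree,
                T0,
                min(self._CANDIDATE_ITERATIONS, self.max_iterations),
                self.rms_tolerance,
                self.trim_fraction,
            )
            # a later candidate must be meaningfully better to displace an
            # earlier one, so symmetry-equivalent poses resolve
            # deterministically to the first (identity-first) candidate
            if best is None or run[1][-1] < best[1][-1] * (1 - 1e-9) - 1e-12:
                best = run
        T, history, converged = best
        if not converged and self.max_iterations > self._CANDIDATE_ITERATIONS:
            T, tail, converged = _icp_iterations(
                src,
                tgt,
                tree,
                T,
                self.max_iterations - len(history),
                self.rms_tolerance,
                self.trim_fraction,
            )
            history = history + tail
        self.transform_ = T
        self.rotation_ = T.rotation
        self.translation_ = T.translation
        self.rms_history_ = np.asarray(history)
        self.converged_ = converged
        self.n_iter_ = len(history)
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        return self.transform_.apply(check_array(X, dtype=np.float64))


def _initial_candidates(
    src: np.ndarray, tgt: np.ndarray, center_init: bool
) -> list[RigidTransform]:
    """Deterministic starting transforms for the ICP search.

    Point-to-point ICP is a local method; from a plain centroid shift it
    can stall well away from the optimum under rotations of tens of
    degrees. Alongside identity and the centroid shift, the principal
    axes of the two clouds give rotation candidates (four sign
    combinations with determinant +1); every candidate gets a short
    rollout and the best is refined, which keeps the search deterministic
    and recovers large known rotations exactly on identical geometry.
    """
    candidates = [RigidTransform.identity()]
    cs, cg = src.mean(axis=0), tgt.mean(axis=0)
    if center_init:
        candidates.append(RigidTransform(np.eye(3), cg - cs))
        cov_s = np.cov((src - cs).T)
        cov_g = np.cov((tgt - cg).T)
        _, vec_s = np.linalg.eigh(cov_s)
        _, vec_g = np.linalg.eigh(cov_g)
        for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            signs = np.array([s1, s2, 1.0])
            Vg = vec_g * signs
            R = Vg @ vec_s.T
            if np.linalg.det(R) < 0:
                R = (Vg * np.array([1.0, 1.0, -1.0])) @ vec_s.T
            candidates.append(RigidTransform(R, cg - R @ cs))
    return candidates


def _icp_iterations(
    src: np.ndarray,
    tgt: np.ndarray,
    tree: cKDTree,
    T: RigidTransform,
    max_iterations: int,
    rms_tolerance: float,
    trim_fraction: float,
) -> tuple[RigidTransform, list[float], bool]:
    """Run plain ICP rounds from ``T``; returns (T, rms history, converged)."""
    cur = T.apply(src)
    history: list[float] = []
    converged = False
    for _ in range(max_iterations):
        dists, idx = tree.query(cur)
        if trim_fraction > 0.0:
            n_keep = max(3, int(np.ceil(len(cur) * (1.0 - trim_fraction))))
            keep = np.argsort(dists, kind="stable")[:n_keep]
        else:
            keep = slice(None)
        try:
            delta = kabsch_fit(cur[keep], tgt[idx[keep]])
        except SingularConfigurationError:
            # correspondences collapsed (e.g. single-point target); freeze
            break
        T = delta.compose(T)
        cur = T.apply(src)
        # the reported RMS is the optimized (trimmed) objective, so that
        # convergence checks and start-candidate comparison are robust
        res2 = np.sum((cur[keep] - tgt[idx[keep]]) ** 2, axis=1)
        rms = float(np.sqrt(np.mean(res2)))
        history.append(rms)
        if rms < rms_tolerance or (
            len(history) >= 2 and abs(history[-2] - rms) < rms_tolerance
        ):
            converged = True
            break
    if not history:
        dists, _ = tree.query(cur)
        history = [float(np.sqrt(np.mean(dists**2)))]
    return T, history, converged


def icp_align(
    source: SurfaceMesh,
    target: SurfaceMesh,
    settings: ICPSettings | None = None,
) -> ICPResult:
    """Rigidly align ``source`` onto ``target`` (vertex-to-vertex ICP)."""
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("cannot align empty meshes")
    settings = settings or ICPSettings()
    est = RigidICP(
        max_iterations=settings.max_iterations,
        rms_tolerance=settings.rms_tolerance,
        trim_fraction=settings.correspondence_trim_fraction,
        center_init=settings.initial_transform.is_identity(),
        initial_transform=(
            None
            if settings.initial_transform.is_identity()
            else settings.initial_transform
        ),
    )
    est.fit(source.vertices, target.vertices)
    return ICPResult(
        transform=est.transform_,
        rms_history=est.rms_history_,
        converged=est.converged_,
    )


@dataclass
class CascadeResult:
    """Output of the three-step alignment cascade."""

    unloaded_face: SurfaceMesh
    loaded_face: SurfaceMesh
    respirator_whole: SurfaceMesh
    respirator_internal: SurfaceMesh
    unloaded_transform: RigidTransform
    loaded_transform: RigidTransform
    respirator_transform: RigidTransform
    unloaded_result: ICPResult
    loaded_result: ICPResult
    respirator_result: ICPResult


def align_cascade(
    unloaded_face: SurfaceMesh,
    loaded_face: SurfaceMesh,
    respirator_whole: SurfaceMesh,
    respirator_internal: SurfaceMesh,
    reference_head: SurfaceMesh,
    reference_head_with_respirator: SurfaceMesh,
    settings: ICPSettings | None = None,
) -> CascadeResult:
    """Run the three-step alignment into the reference-head frame.

    1. The unloaded and loaded facial scans are each ICP-aligned to the
       reference head.
    2. The respirator's whole geometry is ICP-aligned to the reference
       head with the respirator in situ (a rough placement of the
       respirator on the face).
    3. The respirator's internal surface is carried along by the step-2
       transform (it was scanned in the same frame as the whole geometry
       but has no stable overlap of its own to register).
    """
    r_unloaded = icp_align(unloaded_face, reference_head, settings)
    r_loaded = icp_align(loaded_face, reference_head, settings)
    r_resp = icp_align(
        respirator_whole, reference_head_with_respirator, settings
    )
    return CascadeResult(
        unloaded_face=apply_transform(unloaded_face, r_unloaded.transform),
        loaded_face=apply_transform(loaded_face, r_loaded.transform),
        respirator_whole=apply_transform(respirator_whole, r_resp.transform),
        respirator_internal=apply_transform(
            respirator_internal, r_resp.transform
        ),
        unloaded_transform=r_unloaded.transform,
        loaded_transform=r_loaded.transform,
        respirator_transform=r_resp.transform,
        unloaded_result=r_unloaded,
        loaded_result=r_loaded,
        respirator_result=r_resp,
    )
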