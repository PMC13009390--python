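"""Rigid registration: closed-form superposition and ICP refinement.

``rigid_from_correspondences`` is the Kabsch/Umeyama closed-form
least-squares fit (cross-covariance SVD with a reflection guard).  ``icp``
alternates exact closest-point-on-surface matching (point-to-triangle) with
that closed-form update, which makes the matched-pair RMS residual
monotonically non-increasing and every run fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._surface import SurfaceQuery
from .transforms import RigidTransform, apply_transform, compose

log = logging.getLogger(__name__)


class RegistrationError(ValueError):
    pass


@dataclass
class CorrespondenceSet:
    """Paired source/target points (mm) for closed-form superposition."""

    source_points: np.ndarray
    target_points: np.ndarray
    min_points: int = 3

    def __post_init__(self) -> None:
        self.source_points = np.atleast_2d(np.asarray(self.source_points, float))
        self.target_points = np.atleast_2d(np.asarray(self.target_points, float))
        if self.source_points.shape != self.target_points.shape:
            raise RegistrationError("source and target point lists differ in shape")
        if len(self.source_points) < self.min_points:
            raise RegistrationError(
                f"need at least {self.min_points} correspondences, got {len(self.source_points)}"
            )
        if not (
            np.isfinite(self.source_points).all() and np.isfinite(self.target_points).all()
        ):
            raise RegistrationError("correspondence points must be finite")

    def _source_eigvals(self) -> np.ndarray:
        x = self.source_points - self.source_points.mean(axis=0)
        return np.sort(np.linalg.eigvalsh(x.T @ x / len(x)))

    @property
    def is_collinear(self) -> bool:
        """True when the source points span at most a line (Kabsch ill-posed)."""
        return bool(self._source_eigvals()[1] <= 1e-12)

    @property
    def is_planar(self) -> bool:
        """Flagged degenerate-to-a-plane; still well-posed for Kabsch."""
        return bool(self._source_eigvals()[0] <= 1e-12)


@dataclass
class ICPParams:
    """Convergence and sampling controls for ICP."""

    tol: float = 1e-6  # mm change in RMS residual
    max_iter: int = 100
    distance_cap_mm: float | None = None  # drop matches beyond this distance
    max_sample_points: int = 20000  # uniform index-stride subsample beyond this


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_residual: float
    n_iterations: int
    converged: bool
    residual_history: list = field(default_factory=list)


def rigid_from_correspondences(c: CorrespondenceSet) -> RigidTransform:
    """Least-squares rigid transform mapping source onto target (Kabsch).

    Minimises sum ||R s_i + t - t_i||^2 in closed form via SVD of the
    cross-covariance; if the unconstrained optimum is a reflection the
    proper-rotation branch is taken (smallest singular direction flipped).
    """
    if c.is_collinear:
        raise RegistrationError(
            "degenerate correspondences: source points are collinear "
            "(rotation about the line is unconstrained)"
        )
    src = c.source_points
    tgt = c.target_points
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    h = (src - mu_s).T @ (tgt - mu_t)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d < 0:
        log.debug("reflection-optimal case: proper-rotation branch taken")
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_t - r @ mu_s
    return RigidTransform.from_rotation_translation(r, t)


def _sample_vertices(vertices: np.ndarray, cap: int) -> np.ndarray:
    if len(vertices) <= cap:
        return vertices
    stride = int(np.ceil(len(vertices) / cap))
    return vertices[::stride]


def icp(
    floating,
    fixed,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
) -> ICPResult:
    """Register the floating mesh onto the fixed mesh surface.

    The returned transform maps floating-model coordinates into the fixed
    model's frame.  Raises :class:`RegistrationError` when, under the
    distance cap, fewer than three floating samples find a match (no
    overlap).
    """
    params = params or ICPParams()
    init = init or RigidTransform.identity()
    if len(floating.vertices) == 0 or len(fixed.vertices) == 0:
        raise RegistrationError("icp requires non-empty meshes")

    query = SurfaceQuery(fixed)
    pts0 = _sample_vertices(floating.vertices, params.max_sample_points)
    transform = init
    history: list[float] = []
    converged = False
    n_iter = 0

    warm_tri = None
    for n_iter in range(1, params.max_iter + 1):
        p = apply_transform(transform, pts0)
        # warm-started candidate matching: the previous matched triangle is
        # always a candidate, so per-point match distance never exceeds the
        # previous post-update distance (monotone residual history)
        cp, d, warm_tri = query.query_fast(p, warm_tri)
        if params.distance_cap_mm is not None:
            mask = d <= params.distance_cap_mm
            if mask.sum() < 3:
                raise RegistrationError(
                    f"no overlap: fewer than 3 matches within "
                    f"{params.distance_cap_mm} mm distance cap"
                )
            p_m, cp_m = p[mask], cp[mask]
        else:
            p_m, cp_m = p, cp

        update = rigid_from_correspondences(
            CorrespondenceSet(p_m, cp_m, min_points=3)
        )
        transform = compose(update, transform)
        resid = apply_transform(update, p_m) - cp_m
        rms = float(np.sqrt(np.mean(np.einsum("ij,ij->i", resid, resid))))
        history.append(rms)
        if len(history) >= 2 and abs(history[-2] - history[-1]) < params.tol:
            converged = True
            break

    if not converged:
        log.info("icp: max_iter=%d reached without tol=%g", params.max_iter, params.tol)
    return ICPResult(
        transform=transform,
        rms_residual=history[-1],
        n_iterations=n_iter,
        converged=converged,
        residual_history=history,
    )
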