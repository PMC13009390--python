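"""The Global Positioning Layout (GPL) pipeline.

Accuracy of a CAD-CAM mandibular reconstruction is quantified as a chain of
three roto-translational matrices:

1. RTM1 anchors a unique reference system (GPL-RS) in the reference
   mandible's own geometry and brings the planned mandible and the designed
   prosthesis into it.
2. RTM2 registers the postoperative prosthesis (floating) onto the designed
   prosthesis (fixed) by ICP; applied to the postoperative mandible it
   places the whole postoperative scan in the GPL-RS, anchored on the
   prosthesis.
3. RTM3 aligns the postoperative mandible onto the planned mandible; its
   decomposition into Rot-X/Y/Z (degrees) and Trans-X/Y/Z (mm) is the
   six-component accuracy result.

The pipeline consumes no operator input and is fully deterministic:
repeated runs of the same case are bit-identical.

GPL-RS construction here is the principal-axes frame of the
reference-mandible vertex cloud: centroid at the origin, largest-variance
axis on X, second on Y, third on Z, each axis signed so that the vertex
with the largest absolute coordinate along it lies on the positive side
(ties broken by lowest vertex index), with the third axis flipped if needed
to keep the frame right-handed.  This is landmark-free and deterministic;
component values are expressed in this frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .mesh_io import TriMesh
from .registration import ICPParams, ICPResult, RegistrationError, icp
from .transforms import (
    RigidTransform,
    RTMComponents,
    apply_transform,
    compose,
    decompose,
    invert,
)

log = logging.getLogger(__name__)

#: Default distance cap (mm) for the mandible-to-mandible ICP of step 3,
#: softening resection-site mismatch between postoperative and planned bone.
DEFAULT_MANDIBLE_CAP_MM = 10.0


@dataclass
class GPLCase:
    """The five-model bundle of one patient."""

    patient_id: str
    reference_mandible: TriMesh
    planned_mandible: TriMesh
    designed_prosthesis: TriMesh
    postop_mandible: TriMesh
    postop_prosthesis: TriMesh

    def __post_init__(self) -> None:
        for name in (
            "reference_mandible",
            "planned_mandible",
            "designed_prosthesis",
            "postop_mandible",
            "postop_prosthesis",
        ):
            mesh = getattr(self, name)
            if not isinstance(mesh, TriMesh):
                raise TypeError(f"{name} must be a TriMesh")
            mesh.validate()


@dataclass
class GPLResult:
    patient_id: str
    rtm1_gpl_rs: RigidTransform
    rtm2_prosthesis: RigidTransform
    rtm3_accuracy: RigidTransform
    components: RTMComponents
    icp2: ICPResult
    icp3: ICPResult

    def to_json(self) -> str:
        """Row-schema JSON: the six components plus diagnostics."""
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "components": self.components.as_dict(),
                "rtm1_gpl_rs": [float(x) for x in self.rtm1_gpl_rs.matrix.ravel()],
                "rtm2_prosthesis": [float(x) for x in self.rtm2_prosthesis.matrix.ravel()],
                "rtm3_accuracy": [float(x) for x in self.rtm3_accuracy.matrix.ravel()],
                "icp2": {
                    "rms_residual": self.icp2.rms_residual,
                    "n_iterations": self.icp2.n_iterations,
                    "converged": self.icp2.converged,
                },
                "icp3": {
                    "rms_residual": self.icp3.rms_residual,
                    "n_iterations": self.icp3.n_iterations,
                    "converged": self.icp3.converged,
                },
            },
            sort_keys=True,
        )


def establish_gpl_rs(reference_mandible: TriMesh) -> RigidTransform:
    """RTM1: transform mapping the reference mandible into canonical pose.

    Principal-component frame of the vertex cloud with the deterministic
    sign rule documented in the module docstring.
    """
    v = reference_mandible.vertices
    if len(v) < 4:
        raise ValueError("GPL-RS needs at least 4 vertices")
    centroid = v.mean(axis=0)
    x = v - centroid
    cov = x.T @ x / len(x)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    order = [2, 1, 0]  # largest variance -> X, second -> Y, third -> Z
    axes = eigvecs[:, order].T.copy()
    gaps = np.abs(np.diff(np.sort(eigvals)))
    if np.any(gaps < 1e-9 * max(eigvals.max(), 1.0)):
        log.warning("GPL-RS: near-degenerate principal variances; sign rule still deterministic")
    for i in range(3):
        proj = x @ axes[i]
        j = int(np.argmax(np.abs(proj)))  # ties -> lowest vertex index
        if proj[j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return RigidTransform.from_rotation_translation(axes, -axes @ centroid)


def _principal_frame_init(floating: TriMesh, fixed: TriMesh) -> RigidTransform:
    """Deterministic global initialization by principal-frame superposition.

    The per-axis sign rule can disagree between two copies of a
    near-symmetric shape (a body-spanning prosthesis is almost an arc tube),
    so all four proper axis-flip combinations are evaluated and the one
    with the smallest summed squared surface distance wins (ties broken by
    candidate order).
    """
    from ._surface import SurfaceQuery

    f_float = establish_gpl_rs(floating)
    f_fixed = establish_gpl_rs(fixed)
    query = SurfaceQuery(fixed)
    sample = floating.vertices[:: max(1, len(floating.vertices) // 300)]
    best = None
    best_cost = np.inf
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        flip = RigidTransform.from_rotation_translation(np.diag(signs).astype(float), np.zeros(3))
        candidate = compose(invert(f_fixed), compose(flip, f_float))
        _, d, _ = query.query_fast(apply_transform(candidate, sample))
        cost = float(np.sum(d * d))
        if cost < best_cost:
            best, best_cost = candidate, cost
    return best


def run_gpl(case: GPLCase, params: ICPParams | None = None) -> GPLResult:
    """Run the three-RTM chain on one case.

    ``params`` controls the step-2 prosthesis ICP; step 3 reuses it but
    activates a distance cap (default 10 mm) unless one is already set,
    because the postoperative and planned mandibles only partially overlap
    at the resection site.
    """
    params = params or ICPParams()

    rtm1 = establish_gpl_rs(case.reference_mandible)
    planned = apply_transform(rtm1, case.planned_mandible)
    designed = apply_transform(rtm1, case.designed_prosthesis)

    # automated step-2 initialization: superpose the principal-axes frames
    # of the two prosthesis models (the postoperative scan pose is
    # arbitrary); the ICP then refines from near-superposition
    init2 = _principal_frame_init(case.postop_prosthesis, designed)
    try:
        icp2 = icp(case.postop_prosthesis, designed, init=init2, params=params)
    except RegistrationError as exc:
        raise RegistrationError(f"GPL step 2 (prosthesis registration): {exc}") from exc
    rtm2 = icp2.transform
    postop_mand = apply_transform(rtm2, case.postop_mandible)

    step3_params = params
    if params.distance_cap_mm is None:
        step3_params = ICPParams(
            tol=params.tol,
            max_iter=params.max_iter,
            distance_cap_mm=DEFAULT_MANDIBLE_CAP_MM,
            max_sample_points=params.max_sample_points,
        )
    try:
        icp3 = icp(postop_mand, planned, init=None, params=step3_params)
    except RegistrationError as exc:
        raise RegistrationError(f"GPL step 3 (mandible alignment): {exc}") from exc
    rtm3 = icp3.transform

    return GPLResult(
        patient_id=case.patient_id,
        rtm1_gpl_rs=rtm1,
        rtm2_prosthesis=rtm2,
        rtm3_accuracy=rtm3,
        components=decompose(rtm3),
        icp2=icp2,
        icp3=icp3,
    )
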