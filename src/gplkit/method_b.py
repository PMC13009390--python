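"""Method B: surface-based accuracy via sampled Hausdorff statistics.

The Tarsitano-style protocol: the operator seeds the alignment with at
least four corresponding points on the planned (VSP) and postoperative
models, the registration is refined automatically (ICP), and the aligned
pair is summarised by minimum / maximum / mean (+/- RMS) of the sampled
closest-surface distances.

Sampling follows the MeshLab convention: the default is the directed
(one-way) measure sampling the postoperative model's vertices against the
VSP surface; a symmetric variant pools both directed sample sets.  RMS is
sqrt(mean of squared sample distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._surface import SurfaceQuery
from .mesh_io import TriMesh
from .registration import (
    CorrespondenceSet,
    ICPParams,
    ICPResult,
    RegistrationError,
    icp,
    rigid_from_correspondences,
)
from .transforms import apply_transform


class MethodBError(ValueError):
    pass


@dataclass
class HausdorffResult:
    d_min: float
    d_max: float
    d_mean: float
    rms: float
    direction: str
    n_samples: int

    def __post_init__(self) -> None:
        # tolerance absorbs last-ulp summation error when all samples tie
        tol = 1e-9 * max(1.0, abs(self.d_max))
        if not (0.0 <= self.d_min <= self.d_mean + tol and self.d_mean <= self.d_max + tol):
            raise MethodBError("Hausdorff ordering violated: need 0 <= min <= mean <= max")
        if self.rms > self.d_max + tol or self.rms ** 2 < self.d_mean ** 2 - tol:
            raise MethodBError("RMS must satisfy mean^2 <= rms^2 <= max^2")

    def as_dict(self) -> dict:
        return {
            "Hmin": self.d_min,
            "Hmax": self.d_max,
            "Hmean": self.d_mean,
            "Hrms": self.rms,
            "direction": self.direction,
            "n_samples": self.n_samples,
        }


def _directed_distances(src: TriMesh, dst: TriMesh) -> np.ndarray:
    """Closest-surface distance of each vertex of ``src`` to ``dst``."""
    _, d, _ = SurfaceQuery(dst).query(src.vertices)
    return d


def hausdorff(a: TriMesh, b: TriMesh, direction: str = "one_way") -> HausdorffResult:
    """Sampled Hausdorff statistics between two aligned meshes.

    ``one_way`` samples the vertices of ``a`` against the surface of ``b``;
    ``symmetric`` pools both directed sample sets before summarising.
    """
    if direction not in ("one_way", "symmetric"):
        raise MethodBError(f"unknown direction {direction!r}")
    a.validate()
    b.validate()
    d = _directed_distances(a, b)
    if direction == "symmetric":
        # sorting the pooled multiset makes the summary statistics exactly
        # invariant under argument swap (same summation order)
        d = np.sort(np.concatenate([d, _directed_distances(b, a)]))
    return HausdorffResult(
        d_min=float(d.min()),
        d_max=float(d.max()),
        d_mean=float(d.mean()),
        rms=float(np.sqrt(np.mean(d ** 2))),
        direction=direction,
        n_samples=int(len(d)),
    )


def seeded_align(
    vsp: TriMesh,
    postop: TriMesh,
    seeds: CorrespondenceSet,
    params: ICPParams | None = None,
) -> ICPResult:
    """Operator-seeded initial registration, refined by ICP.

    Seeds are postoperative-model points paired with their VSP
    counterparts (n >= 4); the closed-form fit of the seeds initialises an
    ICP of the postoperative model onto the VSP surface.
    """
    if len(seeds.source_points) < 4:
        raise MethodBError("at least four seed correspondences are required")
    init = rigid_from_correspondences(seeds)
    return icp(postop, vsp, init=init, params=params)


def run_method_b(
    vsp: TriMesh,
    postop: TriMesh,
    seeds: CorrespondenceSet,
    params: ICPParams | None = None,
    direction: str = "one_way",
) -> HausdorffResult:
    """Full Method B: seeded alignment, then Hausdorff statistics.

    The directed default samples the aligned postoperative model against
    the VSP surface.
    """
    result = seeded_align(vsp, postop, seeds, params=params)
    aligned = apply_transform(result.transform, postop)
    if direction == "one_way":
        return hausdorff(aligned, vsp, direction="one_way")
    return hausdorff(aligned, vsp, direction=direction)
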