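"""Method A: landmark-based transverse-distance accuracy (Wilde protocol).

Six bilateral landmark pairs (A-A' ... F-F') are identified on the planned
(VSP) and postoperative models.  Each pair's inter-landmark distance is
measured three times on both models — here, three independent
landmark-picking sessions — and accuracy per pair is

    accuracy = mean(postoperative distance) - mean(VSP distance)

in mm, sign preserved.  Landmarks that cannot be identified (in the
clinical series D-D' never, C-C' and E-E' rarely) propagate as MISSING.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh_io import MISSING, LandmarkSet

log = logging.getLogger(__name__)

#: The six bilateral pairs, in protocol order.
PAIR_LABELS = ("A-A'", "B-B'", "C-C'", "D-D'", "E-E'", "F-F'")


class MethodAError(ValueError):
    pass


@dataclass
class MethodAResult:
    patient_id: str
    #: pair label -> dict(mean_vsp_mm, mean_postop_mm, accuracy_mm) or MISSING
    pairs: dict = field(default_factory=dict)

    def accuracy(self, pair_label: str):
        entry = self.pairs.get(pair_label, MISSING)
        return MISSING if entry is MISSING else entry["accuracy_mm"]


def pair_distance(landmarks: LandmarkSet, pair_label: str):
    """Euclidean distance of one bilateral pair; MISSING if either end is."""
    if pair_label not in PAIR_LABELS:
        raise MethodAError(f"unknown pair label {pair_label!r}")
    left, right = pair_label.split("-")
    a = landmarks.get(left)
    b = landmarks.get(right)
    if a is MISSING or b is MISSING:
        return MISSING
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def accuracy_eq1(vsp_replicates, postop_replicates) -> float:
    """mean(postop) - mean(VSP) over exactly three replicate distances each."""
    vsp = np.asarray(vsp_replicates, dtype=float)
    postop = np.asarray(postop_replicates, dtype=float)
    for name, arr in (("vsp", vsp), ("postop", postop)):
        if arr.shape != (3,):
            raise MethodAError(f"{name} replicates: expected exactly 3 values, got shape {arr.shape}")
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise MethodAError(f"{name} replicates must be finite and non-negative")
    return float(postop.mean() - vsp.mean())


def run_method_a(
    vsp_landmark_sessions,
    postop_landmark_sessions,
    patient_id: str = "",
) -> MethodAResult:
    """Triplicate protocol: three picking sessions per model, accuracy per pair.

    A pair MISSING in any of the six sessions yields a MISSING result for
    that pair (logged).
    """
    vsp_sessions = list(vsp_landmark_sessions)
    postop_sessions = list(postop_landmark_sessions)
    if len(vsp_sessions) < 3 or len(postop_sessions) < 3:
        raise MethodAError("three landmark sessions per model are required")
    vsp_sessions = vsp_sessions[:3]
    postop_sessions = postop_sessions[:3]

    result = MethodAResult(patient_id=patient_id)
    for pair in PAIR_LABELS:
        vsp_d = [pair_distance(s, pair) for s in vsp_sessions]
        postop_d = [pair_distance(s, pair) for s in postop_sessions]
        if any(d is MISSING for d in vsp_d + postop_d):
            log.info("patient %s: pair %s MISSING in at least one session", patient_id, pair)
            result.pairs[pair] = MISSING
            continue
        result.pairs[pair] = {
            "mean_vsp_mm": float(np.mean(vsp_d)),
            "mean_postop_mm": float(np.mean(postop_d)),
            "accuracy_mm": accuracy_eq1(vsp_d, postop_d),
        }
    return result
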