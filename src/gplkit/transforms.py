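"""Rigid roto-translational matrix (RTM) algebra.

An RTM is a 4x4 homogeneous matrix combining a proper rotation R and a
translation t (mm).  The chain of three RTMs is the core accuracy object of
the Global Positioning Layout: the final RTM is decomposed into six error
components, three rotations (degrees) and three translations (mm).

Euler convention
----------------
The six components use the fixed-axes (extrinsic) X-then-Y-then-Z
convention, i.e. ``R = Rz(rot_z) @ Ry(rot_y) @ Rx(rot_x)``, angles in
degrees.  This is algebraically identical to the intrinsic Z-Y'-X''
sequence.  ``decompose`` returns ``rot_y`` in [-90, 90] degrees; at gimbal
lock (|rot_y| = 90) the convention ``rot_x := 0`` is applied and the
remaining freedom is folded into ``rot_z``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "RTMComponents",
    "identity",
    "compose",
    "invert",
    "apply_transform",
    "decompose",
    "compose_from_components",
    "rotation_xyz",
]

_ORTHO_TOL = 1e-9
_DRIFT_TOL = 1e-12


class TransformError(ValueError):
    """Raised when a matrix violates the rigid-transform invariants."""


def _check_rigid(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise TransformError(f"expected 4x4 matrix, got shape {m.shape}")
    if not np.isfinite(m).all():
        raise TransformError("matrix contains non-finite entries")
    if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
        raise TransformError("bottom row must be exactly (0, 0, 0, 1)")
    r = m[:3, :3]
    drift = np.abs(r.T @ r - np.eye(3)).max()
    if drift > _ORTHO_TOL:
        raise TransformError(f"rotation block not orthonormal (drift {drift:.3e})")
    if abs(np.linalg.det(r) - 1.0) > _ORTHO_TOL:
        raise TransformError("rotation block must have det +1 (no reflection)")
    return m


def _nearest_rotation(r: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via SVD."""
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class RigidTransform:
    """A validated 4x4 homogeneous rigid transform (rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", _check_rigid(self.matrix))
        self.matrix.setflags(write=False)

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: np.ndarray
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def to_json(self) -> str:
        return json.dumps({"matrix": [float(x) for x in self.matrix.ravel()]})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        data = json.loads(text)
        return cls(np.asarray(data["matrix"], dtype=float).reshape(4, 4))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RigidTransform):
            return NotImplemented
        return np.array_equal(self.matrix, other.matrix)


@dataclass(frozen=True)
class RTMComponents:
    """The six GPL error components: rotations in degrees, translations in mm."""

    rot_x: float
    rot_y: float
    rot_z: float
    trans_x: float
    trans_y: float
    trans_z: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.isfinite(vals).all():
            raise TransformError("components must be finite")
        for name in ("rot_x", "rot_y", "rot_z"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise TransformError(f"{name}={a} outside (-180, 180] degrees")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rot_x, self.rot_y, self.rot_z, self.trans_x, self.trans_y, self.trans_z]
        )

    def as_dict(self) -> dict:
        """Keyed with the conventional Rot-X ... Trans-Z labels."""
        return {
            "Rot-X": self.rot_x,
            "Rot-Y": self.rot_y,
            "Rot-Z": self.rot_z,
            "Trans-X": self.trans_x,
            "Trans-Y": self.trans_y,
            "Trans-Z": self.trans_z,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RTMComponents":
        return cls(
            d["Rot-X"], d["Rot-Y"], d["Rot-Z"], d["Trans-X"], d["Trans-Y"], d["Trans-Z"]
        )

    def to_json(self) -> str:
        return json.dumps(self.as_dict())


def identity() -> RigidTransform:
    return RigidTransform.identity()


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``b`` first, then ``a``."""
    m = a.matrix @ b.matrix
    r = m[:3, :3]
    if np.abs(r.T @ r - np.eye(3)).max() > _DRIFT_TOL:
        m = m.copy()
        m[:3, :3] = _nearest_rotation(r)
    m[3] = (0.0, 0.0, 0.0, 1.0)
    return RigidTransform(m)


def invert(t: RigidTransform) -> RigidTransform:
    r = t.rotation.T
    return RigidTransform.from_rotation_translation(r, -r @ t.translation)


def apply_transform(t: RigidTransform, points):
    """Map points (or a mesh; anything with ``.transformed``) by ``R p + t``.

    Point arrays of shape (n, 3) or (3,) return the same shape; objects
    exposing ``transformed(transform)`` (e.g. TriMesh) are delegated to.
    """
    if hasattr(points, "transformed"):
        return points.transformed(t)
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    out = np.atleast_2d(p) @ t.rotation.T + t.translation
    return out[0] if single else out


def rotation_xyz(rot_x_deg: float, rot_y_deg: float, rot_z_deg: float) -> np.ndarray:
    """Rotation matrix for extrinsic X-Y-Z angles: Rz @ Ry @ Rx."""
    a, b, c = np.radians([rot_x_deg, rot_y_deg, rot_z_deg])
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


def compose_from_components(c: RTMComponents) -> RigidTransform:
    r = rotation_xyz(c.rot_x, c.rot_y, c.rot_z)
    return RigidTransform.from_rotation_translation(r, [c.trans_x, c.trans_y, c.trans_z])


def decompose(t: RigidTransform) -> RTMComponents:
    """Six error components under the extrinsic X-Y-Z convention.

    Inverse of :func:`compose_from_components` away from gimbal lock
    (|rot_y| = 90 deg), where ``rot_x`` is set to 0 by convention and a
    warning is emitted.
    """
    r = t.rotation
    sy = -r[2, 0]
    sy = min(1.0, max(-1.0, sy))
    rot_y = math.degrees(math.asin(sy))
    if abs(abs(sy) - 1.0) < 1e-9:
        warnings.warn(
            "gimbal lock (|rot_y| = 90 deg): rot_x set to 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        rot_x = 0.0
        rot_z = math.degrees(math.atan2(-r[0, 1], r[1, 1]))
    else:
        rot_x = math.degrees(math.atan2(r[2, 1], r[2, 2]))
        rot_z = math.degrees(math.atan2(r[1, 0], r[0, 0]))
    tx, ty, tz = t.translation
    # atan2 returns -180 at the branch cut; map into (-180, 180]
    rot_x = 180.0 if rot_x == -180.0 else rot_x
    rot_z = 180.0 if rot_z == -180.0 else rot_z
    return RTMComponents(rot_x, rot_y, rot_z, float(tx), float(ty), float(tz))
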