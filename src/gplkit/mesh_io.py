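"""Mesh and table I/O: triangle surface meshes, landmark sets, measurements.

All coordinates are interpreted as millimetres; no unit metadata is read
from files.  STL carries no shared-vertex topology, so meshes are
re-indexed on read by merging coincident vertices (within ~1e-6 mm), which
registration and distance kernels rely on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger(__name__)

#: The twelve Wilde-protocol landmark labels: six bilateral pairs, the
#: primed member on the left side (A: innermost condyle point, B: outermost
#: condyle point, C: lowest notch point, D: lingula tip, E: coronoid tip,
#: F: most caudal angle point).
LANDMARK_LABELS = tuple(
    f"{letter}{prime}" for letter in "ABCDEF" for prime in ("", "'")
)

OPERATORS = ("O1", "O2", "O3")


class MeshValidationError(ValueError):
    """A mesh violates a structural invariant (named in the message)."""


class TableValidationError(ValueError):
    """A landmark or measurement table violates its schema."""


@dataclass
class TriMesh:
    """Triangle surface mesh in mm: (n, 3) float vertices, (m, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshValidationError("mesh has no vertices or no faces")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("vertex coordinates must be finite")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError("face index out of vertex range")
        a, b, c = self.faces.T
        if np.any((a == b) | (b == c) | (a == c)):
            raise MeshValidationError("degenerate face (repeated vertex index)")

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) triangle corner coordinates."""
        return self.vertices[self.faces]

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def transformed(self, transform) -> "TriMesh":
        verts = self.vertices @ transform.rotation.T + transform.translation
        return TriMesh(verts, self.faces.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, name: str = "") -> "TriMesh":
        return cls(np.asarray(mesh.vertices, float), np.asarray(mesh.faces), name)


def read_mesh(path, format: str = "auto") -> TriMesh:
    """Read an STL (binary or ASCII) or PLY mesh; merge coincident vertices."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    file_type = None if format == "auto" else format
    try:
        raw = trimesh.load_mesh(str(path), file_type=file_type, process=False)
    except Exception as exc:  # unreadable / unparseable
        raise IOError(f"could not read mesh {path}: {exc}") from exc
    if isinstance(raw, trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshValidationError(f"{path}: file contains no mesh geometry")
        raw = geoms[0]
    raw.merge_vertices()
    faces = np.asarray(raw.faces)
    if len(faces):
        a, b, c = faces.T
        faces = faces[(a != b) & (b != c) & (a != c)]
    if len(np.asarray(raw.vertices)) == 0 or len(faces) == 0:
        raise MeshValidationError(f"{path}: mesh has no vertices or no faces")
    mesh = TriMesh(np.asarray(raw.vertices, float), faces, name=path.stem)
    log.info("read %s: %d vertices, %d faces", path.name, len(mesh.vertices), len(mesh.faces))
    return mesh


def write_mesh(mesh: TriMesh, path, format: str | None = None) -> Path:
    """Write STL (binary, or ASCII via format='stl_ascii') or PLY (ASCII).

    Round-trips through :func:`read_mesh` with vertex error < 1e-5 mm for
    coordinates of anatomical magnitude (binary STL stores float32).
    """
    mesh.validate()
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"stl": "stl", "ply": "ply"}.get(suffix)
        if format is None:
            raise IOError(f"cannot infer mesh format from {path}")
    tm = mesh.to_trimesh()
    try:
        if format == "ply":
            data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        elif format == "stl_ascii":
            data = trimesh.exchange.stl.export_stl_ascii(tm).encode()
        elif format == "stl":
            data = trimesh.exchange.stl.export_stl(tm)
        else:
            raise IOError(f"unsupported mesh format: {format}")
        path.write_bytes(data)
    except OSError as exc:
        raise IOError(f"could not write mesh to {path}: {exc}") from exc
    return path


MISSING = None  # sentinel for an unpickable landmark / absent measurement


@dataclass
class LandmarkSet:
    """Named anatomical points on one model; absent landmarks are MISSING."""

    model_id: str
    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for label, xyz in self.points.items():
            label = _normalize_label(label)
            if label not in LANDMARK_LABELS:
                raise TableValidationError(f"unknown landmark label {label!r}")
            if xyz is MISSING:
                continue
            p = np.asarray(xyz, dtype=float)
            if p.shape != (3,) or not np.isfinite(p).all():
                raise TableValidationError(f"landmark {label}: invalid coordinates {xyz!r}")
            clean[label] = p
        self.points = clean

    def get(self, label: str):
        return self.points.get(_normalize_label(label), MISSING)

    def present(self) -> tuple:
        return tuple(l for l in LANDMARK_LABELS if l in self.points)

    def missing(self) -> tuple:
        return tuple(l for l in LANDMARK_LABELS if l not in self.points)

    def transformed(self, transform) -> "LandmarkSet":
        from .transforms import apply_transform

        return LandmarkSet(
            self.model_id,
            {l: apply_transform(transform, p) for l, p in self.points.items()},
        )


def _normalize_label(label: str) -> str:
    # accept the typographic prime as well as the ASCII apostrophe
    return str(label).strip().replace("′", "'")


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark CSV (header label,x,y,z) or JSON ({label: [x,y,z]})."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return LandmarkSet(model_id=data.get("model_id", path.stem), points=data.get("points", data if "model_id" not in data else {}))
    try:
        df = pd.read_csv(path, dtype={"label": str})
    except pd.errors.EmptyDataError:
        return LandmarkSet(model_id=path.stem, points={})
    if df.empty:
        return LandmarkSet(model_id=path.stem, points={})
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TableValidationError(f"{path}: expected columns label,x,y,z")
    points = {}
    for i, row in df.iterrows():
        try:
            points[row["label"]] = (float(row["x"]), float(row["y"]), float(row["z"]))
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"{path}: malformed row {i + 2}: {exc}") from exc
    return LandmarkSet(model_id=path.stem, points=points)


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    rows = [
        {"label": l, "x": p[0], "y": p[1], "z": p[2]}
        for l, p in landmarks.points.items()
    ]
    pd.DataFrame(rows, columns=["label", "x", "y", "z"]).to_csv(path, index=False)
    return path


@dataclass
class MeasurementRecord:
    """One accuracy value tagged patient / operator / occasion / metric."""

    patient_id: str
    operator_id: str
    occasion: int
    metric: str
    value: float | None

    def __post_init__(self) -> None:
        self.occasion = int(self.occasion)
        if self.occasion not in (1, 2):
            raise TableValidationError(f"occasion must be 1 or 2, got {self.occasion}")
        if self.value is not MISSING:
            self.value = float(self.value)
            if not np.isfinite(self.value):
                raise TableValidationError("measurement value must be finite")


def read_measurements(path) -> list:
    """Read a long-format measurement CSV; empty value cells become MISSING."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"measurement file not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str, "operator_id": str, "metric": str})
    required = {"patient_id", "operator_id", "occasion", "metric", "value"}
    if not required.issubset(df.columns):
        raise TableValidationError(f"{path}: expected columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        value = MISSING if pd.isna(row["value"]) else float(row["value"])
        records.append(
            MeasurementRecord(
                patient_id=str(row["patient_id"]),
                operator_id=str(row["operator_id"]),
                occasion=int(row["occasion"]),
                metric=str(row["metric"]),
                value=value,
            )
        )
    n_missing = sum(r.value is MISSING for r in records)
    if n_missing:
        log.info("read %s: %d records, %d MISSING", path.name, len(records), n_missing)
    return records


def write_measurements(records, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "operator_id": r.operator_id,
                "occasion": r.occasion,
                "metric": r.metric,
                "value": "" if r.value is MISSING else r.value,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
    return path
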