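"""Meniscus mesh data model: I/O, validation, anatomical frame, mirroring.

A meniscus is represented as a triangulated surface in mm, in a
right-handed canonical frame: x = anterior-posterior (length),
y = medio-lateral (width), z = inferior-superior (height). Each mesh
carries the anterior and posterior root landmarks (the tibial attachment
points) that anchor the oriented-bounding-box measurement.
"""
from __future__ import annotations

import dataclasses
import enum
import os
import zlib

import numpy as np
import pandas as pd
import trimesh

from ._geometry import SurfaceQuery

__all__ = [
    "Side",
    "Laterality",
    "MeniscusMesh",
    "MeshError",
    "MeshFormatError",
    "DegenerateFaceError",
    "DisconnectedMeshError",
    "LandmarkError",
    "load_mesh",
    "save_mesh",
    "mirror_to_right",
    "load_bank_metadata",
]

#: maximum allowed distance (mm) from a root landmark to the surface
LANDMARK_TOL_MM = 2.0
#: face area below this (mm^2) counts as degenerate
DEGENERATE_AREA_MM2 = 1e-10

_SUPPORTED_EXTENSIONS = {".ply", ".stl", ".obj"}


class Side(str, enum.Enum):
    MEDIAL = "medial"
    LATERAL = "lateral"


class Laterality(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class MeshError(ValueError):
    """Base class for mesh validation / I/O errors."""


class MeshFormatError(MeshError):
    """Unsupported or unparseable mesh file."""


class DegenerateFaceError(MeshError):
    """Mesh contains zero-area triangles or out-of-range indices."""


class DisconnectedMeshError(MeshError):
    """Mesh is not a single connected component."""


class LandmarkError(MeshError):
    """Root landmark farther than LANDMARK_TOL_MM from the surface."""


@dataclasses.dataclass
class MeniscusMesh:
    """Triangulated meniscus surface with anatomical metadata (mm)."""

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int
    patient_id: str
    side: Side
    laterality: Laterality
    root_anterior: np.ndarray  # (3,) mm
    root_posterior: np.ndarray  # (3,) mm

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.side = Side(self.side)
        self.laterality = Laterality(self.laterality)
        self.root_anterior = np.asarray(self.root_anterior, dtype=float)
        self.root_posterior = np.asarray(self.root_posterior, dtype=float)

    @property
    def key(self) -> str:
        """Stable identifier used for caching and deterministic seeding."""
        return f"{self.patient_id}|{self.side.value}|{self.laterality.value}"

    def seed(self, salt: int = 0) -> int:
        """Deterministic 31-bit seed derived from the mesh key."""
        return (zlib.crc32(self.key.encode()) ^ (salt & 0x7FFFFFFF)) & 0x7FFFFFFF

    def content_hash(self) -> int:
        """Hash of the geometry (vertices, faces, roots); caches assume
        meshes are not mutated in place after first use."""
        cached = getattr(self, "_content_hash", None)
        if cached is None:
            h = zlib.crc32(np.ascontiguousarray(self.vertices).tobytes())
            h = zlib.crc32(np.ascontiguousarray(self.faces).tobytes(), h)
            h = zlib.crc32(np.ascontiguousarray(self.root_anterior).tobytes(), h)
            h = zlib.crc32(np.ascontiguousarray(self.root_posterior).tobytes(), h)
            cached = h
            self._content_hash = h
        return cached

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def copy(self, **updates) -> "MeniscusMesh":
        fields = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        fields.update(updates)
        return MeniscusMesh(**fields)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MeniscusMesh":
        """Apply a rigid motion jointly to vertices and landmarks."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return self.copy(
            vertices=self.vertices @ R.T + t,
            root_anterior=R @ self.root_anterior + t,
            root_posterior=R @ self.root_posterior + t,
        )

    def validate(self) -> "MeniscusMesh":
        """Check all structural invariants; raise a specific MeshError."""
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise MeshFormatError("vertices must be (n,3), faces (m,3)")
        if len(f) == 0 or len(v) < 3:
            raise MeshFormatError("empty mesh")
        if f.min() < 0 or f.max() >= len(v):
            raise DegenerateFaceError("face index out of range")
        tri = v[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if np.any(areas < DEGENERATE_AREA_MM2):
            raise DegenerateFaceError(
                f"{int(np.sum(areas < DEGENERATE_AREA_MM2))} zero-area triangles"
            )
        _check_connected(len(v), f)
        sq = SurfaceQuery(v, f)
        d = sq.distance(np.vstack([self.root_anterior, self.root_posterior]))
        if np.any(d > LANDMARK_TOL_MM):
            raise LandmarkError(
                f"root landmark {d.max():.2f} mm from surface "
                f"(limit {LANDMARK_TOL_MM} mm)"
            )
        return self


def _check_connected(n_vertices: int, faces: np.ndarray) -> None:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    referenced = np.zeros(n_vertices, dtype=bool)
    referenced[faces.ravel()] = True
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(n_vertices, n_vertices),
    )
    n_comp, labels = connected_components(adj, directed=False)
    used_labels = np.unique(labels[referenced])
    if len(used_labels) > 1:
        raise DisconnectedMeshError(f"mesh has {len(used_labels)} connected components")


def load_mesh(
    path: str | os.PathLike,
    patient_id: str,
    side: Side | str,
    laterality: Laterality | str,
    root_anterior,
    root_posterior,
) -> MeniscusMesh:
    """Read a PLY/STL/OBJ surface (dialect by extension) and validate it.

    Coordinates are taken as millimetres verbatim. Duplicate vertices
    (unavoidable in STL, which stores one vertex triple per facet) are
    merged on load.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXTENSIONS:
        raise MeshFormatError(f"unsupported mesh format {ext!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(path, force="mesh", process=False)
        tm.merge_vertices()
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    mesh = MeniscusMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        patient_id=patient_id,
        side=side,
        laterality=laterality,
        root_anterior=root_anterior,
        root_posterior=root_posterior,
    )
    return mesh.validate()


def save_mesh(mesh: MeniscusMesh, path: str | os.PathLike) -> None:
    """Write the mesh to PLY/STL/OBJ chosen by extension (lossless to float)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXTENSIONS:
        raise MeshFormatError(f"unsupported mesh format {ext!r}")
    mesh.as_trimesh().export(path)


def mirror_to_right(mesh: MeniscusMesh) -> MeniscusMesh:
    """Reflect a left meniscus across the sagittal (x-z) plane.

    Width is the y-axis, so the reflection is y -> -y; triangle winding
    is flipped to keep outward normals outward, and the root landmarks
    are reflected with the surface. A right meniscus is returned as-is.
    """
    if mesh.laterality is Laterality.RIGHT:
        return mesh
    flip = np.array([1.0, -1.0, 1.0])
    return mesh.copy(
        vertices=mesh.vertices * flip,
        faces=mesh.faces[:, ::-1].copy(),
        laterality=Laterality.RIGHT,
        root_anterior=mesh.root_anterior * flip,
        root_posterior=mesh.root_posterior * flip,
    )


def _parse_xyz(text: str) -> np.ndarray:
    try:
        vals = np.array([float(x) for x in str(text).replace(";", " ").split()])
    except ValueError as exc:
        raise MeshFormatError(f"cannot parse xyz triple from {text!r}") from exc
    if vals.shape != (3,):
        raise MeshFormatError(f"cannot parse xyz triple from {text!r}")
    return vals


def load_bank_metadata(csv_path: str | os.PathLike) -> list[MeniscusMesh]:
    """Load every mesh listed in a bank metadata CSV.

    Expected columns: patient_id, side, laterality, mesh_path,
    root_anterior_xyz, root_posterior_xyz (xyz as space- or
    semicolon-separated mm triples; mesh_path relative to the CSV).
    """
    csv_path = os.fspath(csv_path)
    base = os.path.dirname(os.path.abspath(csv_path))
    df = pd.read_csv(csv_path)
    meshes = []
    for _, row in df.iterrows():
        mesh_path = row["mesh_path"]
        if not os.path.isabs(mesh_path):
            mesh_path = os.path.join(base, mesh_path)
        meshes.append(
            load_mesh(
                mesh_path,
                patient_id=str(row["patient_id"]),
                side=row["side"],
                laterality=row["laterality"],
                root_anterior=_parse_xyz(row["root_anterior_xyz"]),
                root_posterior=_parse_xyz(row["root_posterior_xyz"]),
            )
        )
    return meshes
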