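"""Mesh and landmark I/O plus mesh-integrity reporting.

All geometry in this package is in millimetres, in a right-handed frame
with +Z proximal (up the shank), +X anterior (toward the toes) and
+Y = Z x X.  Meshes are plain triangle soups welded by *exact* coordinate
equality on read: scan exports (STL in particular) duplicate the vertices
of every triangle, and exact welding recovers connectivity without the
non-determinism of epsilon merging.

The two container types here, :class:`SurfaceMesh` and :class:`LandmarkSet`,
are consumed by every downstream module.  File parsing and STL export are
delegated to :mod:`trimesh`; the integrity report (:func:`validate_mesh`)
is computed directly from edge incidence counts so that "watertight" has
one unambiguous, printable definition: no boundary edges and no
non-manifold edges.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    EmptyMeshError,
    InputValidationError,
    LandmarkError,
    MeshFormatError,
    MeshIOError,
)

log = logging.getLogger(__name__)

LANDMARK_NAMES = ("heel", "mh1", "mh2", "mh5", "lm", "mm", "lt", "mt")

_SUPPORTED_EXTENSIONS = {".stl", ".ply", ".obj"}


@dataclass
class SurfaceMesh:
    """A triangulated surface in millimetres.

    ``faces`` index into ``vertices`` with counter-clockwise outward
    orientation.  Construction validates the structural invariants:
    finite coordinates, indices in range, no face repeating a vertex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InputValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InputValidationError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise InputValidationError("mesh has non-finite vertex coordinates")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise InputValidationError("face index out of range")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise InputValidationError("a face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        """Unnormalized face normals (cross products; length = 2 x area)."""
        tri = self.vertices[self.faces]
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals."""
        fn = self.face_normals()  # area-weighted already (length 2A)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1)
        norms[norms < 1e-30] = 1.0
        return vn / norms[:, None]


@dataclass(frozen=True)
class MeshReport:
    """Integrity summary of a surface mesh.

    watertight is equivalent to boundary_edge_count == 0 and
    nonmanifold_edge_count == 0.
    """

    watertight: bool
    boundary_edge_count: int
    nonmanifold_edge_count: int
    degenerate_face_count: int
    euler_characteristic: int


@dataclass
class LandmarkSet:
    """The eight manually marked anatomical points, in millimetres.

    heel; first/second/fifth metatarsal heads (mh1, mh2, mh5); lateral and
    medial malleoli (lm, mm); lateral and medial tibial condyles (lt, mt).
    """

    heel: np.ndarray
    mh1: np.ndarray
    mh2: np.ndarray
    mh5: np.ndarray
    lm: np.ndarray
    mm: np.ndarray
    lt: np.ndarray
    mt: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=np.float64).reshape(-1)
            if p.shape != (3,):
                raise LandmarkError(f"landmark '{name}' must be a 3D point")
            if not np.isfinite(p).all():
                raise LandmarkError(f"landmark '{name}' has non-finite coordinates")
            object.__setattr__(self, name, p)
        for a, b in (("lm", "mm"), ("lt", "mt"), ("mh1", "mh5")):
            if np.array_equal(getattr(self, a), getattr(self, b)):
                raise LandmarkError(f"landmarks '{a}' and '{b}' coincide")

    def as_dict(self) -> dict:
        return {name: getattr(self, name).tolist() for name in LANDMARK_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in d]
        if missing:
            raise LandmarkError(f"missing landmark(s): {', '.join(missing)}")
        extra = sorted(set(d) - set(LANDMARK_NAMES))
        if extra:
            log.warning("ignoring unknown landmark keys: %s", ", ".join(extra))
        coords = {}
        for name in LANDMARK_NAMES:
            value = d[name]
            try:
                p = np.asarray(value, dtype=np.float64).reshape(3)
            except (TypeError, ValueError) as exc:
                raise LandmarkError(
                    f"landmark '{name}' is not a 3-number array: {value!r}"
                ) from exc
            coords[name] = p
        return cls(**coords)

    def points(self) -> np.ndarray:
        """All eight landmarks as an (8, 3) array, in canonical name order."""
        return np.stack([getattr(self, n) for n in LANDMARK_NAMES])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply a rigid transform p -> R p + t to every landmark."""
        R = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        return LandmarkSet(
            **{n: R @ getattr(self, n) + t for n in LANDMARK_NAMES}
        )

    def replace(self, **kwargs) -> "LandmarkSet":
        return replace(self, **kwargs)


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices with bit-identical coordinates; drop degenerate faces."""
    unique, inverse = np.unique(vertices, axis=0, return_inverse=True)
    faces = inverse[faces]
    f = faces
    degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    if degenerate.any():
        log.warning("dropping %d degenerate face(s) after welding", int(degenerate.sum()))
        faces = faces[~degenerate]
    return unique, faces


def read_mesh(path) -> SurfaceMesh:
    """Read an STL (ASCII or binary), PLY or OBJ surface mesh.

    Vertices are welded by exact coordinate match; stored orientation is
    preserved.  Raises :class:`MeshFormatError` for unreadable files and
    :class:`EmptyMeshError` when the file holds no triangles.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"mesh file not found: {path}")
    ext = path.suffix.lower()
    if ext not in _SUPPORTED_EXTENSIONS:
        raise MeshFormatError(f"unsupported mesh extension '{ext}' for {path}")
    if path.stat().st_size == 0:
        raise EmptyMeshError(f"{path} is empty (zero bytes)")
    try:
        loaded = trimesh.load(str(path), file_type=ext.lstrip("."), process=False)
    except EmptyMeshError:
        raise
    except Exception as exc:  # noqa: BLE001 - any parser failure is a format error
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path} contains no geometry")
        loaded = trimesh.util.concatenate(geoms)
    faces = np.asarray(loaded.faces)
    if faces.size == 0:
        raise EmptyMeshError(f"{path} contains zero faces")
    vertices, faces = _weld_exact(np.asarray(loaded.vertices, dtype=np.float64), faces)
    return SurfaceMesh(vertices, faces, name=path.stem)


def write_stl(mesh: SurfaceMesh, path, binary: bool = True) -> Path:
    """Write a mesh as STL.  Binary files are exactly 84 + 50*n_faces bytes."""
    # SurfaceMesh construction already guarantees finite coordinates; revalidate
    # in case arrays were mutated in place after construction.
    if not np.isfinite(mesh.vertices).all():
        raise InputValidationError("mesh has non-finite vertex coordinates")
    path = Path(path)
    tm = mesh.to_trimesh()
    data = tm.export(file_type="stl" if binary else "stl_ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def read_landmarks(path) -> LandmarkSet:
    """Read the eight named landmarks from a JSON file (mm)."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except FileNotFoundError:
        raise MeshIOError(f"landmark file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise LandmarkError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise LandmarkError(f"{path} must hold a JSON object keyed by landmark name")
    return LandmarkSet.from_dict(data)


def write_landmarks(lm_set: LandmarkSet, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(lm_set.as_dict(), fh, indent=2)
        fh.write("\n")
    return path


def validate_mesh(mesh: SurfaceMesh) -> MeshReport:
    """Classify edges by incident-face count and report integrity.

    1 incident face = boundary edge, 2 = manifold, >=3 = non-manifold.
    The Euler characteristic is V - E + F over all stored vertices.
    """
    f = mesh.faces
    if len(f) == 0:
        return MeshReport(False, 0, 0, 0, mesh.n_vertices)
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = int((counts == 1).sum())
    nonmanifold = int((counts >= 3).sum())
    n_edges = len(counts)
    areas = 0.5 * np.linalg.norm(mesh.face_normals(), axis=1)
    degenerate = int((areas < 1e-12).sum())
    euler = mesh.n_vertices - n_edges + mesh.n_faces
    return MeshReport(
        watertight=(boundary == 0 and nonmanifold == 0),
        boundary_edge_count=boundary,
        nonmanifold_edge_count=nonmanifold,
        degenerate_face_count=degenerate,
        euler_characteristic=euler,
    )
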