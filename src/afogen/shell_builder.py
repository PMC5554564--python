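"""From neutralized scan + template region to a printable orthosis solid.

Stages (composed by :func:`design_afo`):

1. ``offset_surface`` — displace the whole leg surface outward by the
   clearance along area-weighted vertex normals (clamped where a
   displacement would invert a neighboring triangle), so the shell
   conforms to the leg without touching it;
2. ``apply_template_trim`` — drop every face whose centroid falls outside
   the template keep-region, keep the largest connected component;
3. ``thicken_and_seal`` — offset the trimmed open shell outward by the wall
   thickness, stitch the boundary loops with a triangulated rim, and emit
   a closed solid.

Face-level trimming by centroid test is an approximation of the template
curves whose resolution is controlled by the scan density; it is robust
and order-independent.  Offsetting before trimming avoids boundary-normal
artifacts along the trim edges.

Quality gates are computed on the result: watertightness, ray-sampled
wall thickness, minimum distance to the malleoli (relief check), and the
footplate-to-shank angle.  Ray casting is a vectorized Moller-Trumbore
implementation (also used, edge-versus-triangle, for the self-intersection
report), seeded for bit-reproducible QA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .afo_template import TemplateRegion, TemplateSpec, build_template
from .anatomy_axes import compute_axes, plantar_normal
from .errors import (
    EmptyShellError,
    GeometryError,
    InputValidationError,
    NothingToSealError,
    ParameterError,
    StageError,
)
from .geometry_io import LandmarkSet, MeshReport, SurfaceMesh, validate_mesh
from .neutral_alignment import AlignmentResult, neutralize

log = logging.getLogger(__name__)


@dataclass
class ShellParams:
    """Shell construction and QA parameters."""

    clearance_mm: float = 2.0
    thickness_mm: float = 3.0
    thickness_tolerance_mm: float = 0.5
    sample_count: int = 500
    rng_seed: int = 0
    check_self_intersection: bool = True

    def validate(self) -> None:
        if self.clearance_mm < 0:
            raise ParameterError("clearance_mm must be >= 0")
        if self.thickness_mm <= 0:
            raise ParameterError("thickness_mm must be > 0")
        if self.thickness_tolerance_mm <= 0:
            raise ParameterError("thickness_tolerance_mm must be > 0")
        if self.sample_count < 1:
            raise ParameterError("sample_count must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ShellParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown shell parameter(s): {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


@dataclass
class QAReport:
    """Printability and fit gates for one designed orthosis."""

    watertight: bool
    mesh_report: MeshReport
    thickness_samples: int
    thickness_within_tolerance_fraction: float
    thickness_percentiles_mm: dict
    min_distance_to_lateral_malleolus_mm: float
    min_distance_to_medial_malleolus_mm: float
    relief_clearance_ok: bool
    footplate_shank_angle_deg: float
    oblique_plane_angle_deg: float
    self_intersecting_face_count: int
    applied_sagittal_correction_deg: float
    applied_coronal_correction_deg: float

    def gates_pass(self) -> bool:
        return (
            self.watertight
            and self.thickness_within_tolerance_fraction >= 0.95
            and self.relief_clearance_ok
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["mesh_report"] = vars(self.mesh_report).copy() if not isinstance(
            self.mesh_report, dict) else self.mesh_report
        d["gates_pass"] = self.gates_pass()
        return d


@dataclass
class DesignResult:
    """Output of design_afo: the solid plus its QA report and alignment."""

    mesh: SurfaceMesh
    qa: QAReport
    alignment: AlignmentResult
    template_region: TemplateRegion


# ----------------------------------------------------------------------
# stage 1: conforming offset


def offset_surface(mesh: SurfaceMesh, c: float, max_clamp_iterations: int = 10) -> SurfaceMesh:
    """Displace every vertex by ``c`` along its area-weighted normal.

    Displacements are iteratively halved on vertices whose movement would
    invert a neighboring triangle.  Connectivity is unchanged.
    """
    if c < 0:
        raise ParameterError("offset distance must be >= 0")
    report = validate_mesh(mesh)
    if report.nonmanifold_edge_count > 0:
        raise GeometryError(
            f"cannot offset: {report.nonmanifold_edge_count} non-manifold edge(s) "
            "make vertex normals ill-defined"
        )
    if c == 0:
        return mesh.copy()
    normals = mesh.vertex_normals()
    displacement = c * normals
    reference = mesh.face_normals()
    scale = np.ones(len(mesh.vertices))
    for _ in range(max_clamp_iterations):
        candidate = mesh.vertices + scale[:, None] * displacement
        moved = SurfaceMesh(candidate, mesh.faces, mesh.name)
        flipped = np.einsum("ij,ij->i", moved.face_normals(), reference) <= 0
        if not flipped.any():
            break
        bad_vertices = np.unique(mesh.faces[flipped])
        scale[bad_vertices] *= 0.5
    else:
        candidate = mesh.vertices + scale[:, None] * displacement
    return SurfaceMesh(candidate, mesh.faces.copy(), mesh.name + "_offset")


# ----------------------------------------------------------------------
# stage 2: template trim


def _largest_face_component(faces: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest edge-connected face component."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    face_ids = np.tile(np.arange(len(faces)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_sorted = edges[order]
    faces_sorted = face_ids[order]
    same = (np.diff(edges_sorted, axis=0) == 0).all(axis=1)
    a = faces_sorted[:-1][same]
    b = faces_sorted[1:][same]
    n = len(faces)
    graph = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp <= 1:
        return np.ones(n, dtype=bool)
    largest = np.bincount(labels).argmax()
    return labels == largest


def apply_template_trim(mesh: SurfaceMesh, region: TemplateRegion) -> SurfaceMesh:
    """Keep faces whose centroids satisfy the template keep-predicate."""
    keep = region.keep(mesh.face_centroids())
    if not keep.any():
        raise EmptyShellError("template region excludes every face")
    faces = mesh.faces[keep]
    faces = faces[_largest_face_component(faces)]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], mesh.name + "_trimmed")


# ----------------------------------------------------------------------
# stage 3: thicken and seal


def _enforce_vertex_clearance(
    mesh: SurfaceMesh, centers, min_dist: float
) -> SurfaceMesh:
    """Drop faces referencing any vertex closer than ``min_dist`` to a center.

    Centroid trimming leaves boundary-face vertices up to one edge length
    inside an excluded sphere; this pass restores a hard vertex-level
    clearance around the malleoli.
    """
    bad = np.zeros(mesh.n_vertices, dtype=bool)
    for c in centers:
        bad |= np.linalg.norm(mesh.vertices - np.asarray(c), axis=1) < min_dist
    if not bad.any():
        return mesh
    keep = ~bad[mesh.faces].any(axis=1)
    if not keep.any():
        raise EmptyShellError("relief clearance excludes every face")
    faces = mesh.faces[keep]
    faces = faces[_largest_face_component(faces)]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], mesh.name)


def _boundary_edges_directed(faces: np.ndarray) -> np.ndarray:
    """Boundary edges in face winding order (each appears in one face)."""
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(
        undirected, axis=0, return_inverse=True, return_counts=True
    )
    return directed[counts[inverse] == 1]


def thicken_and_seal(shell: SurfaceMesh, t: float,
                     check_self_intersection: bool = True) -> SurfaceMesh:
    """Extrude an open shell by wall thickness ``t`` into a closed solid.

    The outer skin is the shell offset by ``t`` along vertex normals; the
    boundary loops are stitched with a triangulated rim.  Self-intersections
    (if any) are counted and logged as a warning, never fatal.
    """
    if t <= 0:
        raise ParameterError("thickness must be > 0")
    report = validate_mesh(shell)
    if report.boundary_edge_count == 0:
        raise NothingToSealError("input shell is closed; nothing to seal")
    normals = shell.vertex_normals()
    n = shell.n_vertices
    outer_vertices = shell.vertices + t * normals
    vertices = np.concatenate([shell.vertices, outer_vertices])
    inner_faces = shell.faces[:, ::-1]  # reversed: normals face the leg
    outer_faces = shell.faces + n
    boundary = _boundary_edges_directed(shell.faces)
    a, b = boundary[:, 0], boundary[:, 1]
    rim = np.concatenate(
        [
            np.stack([a, b, b + n], axis=1),
            np.stack([a, b + n, a + n], axis=1),
        ]
    )
    solid = SurfaceMesh(
        vertices,
        np.concatenate([inner_faces, outer_faces, rim]),
        shell.name + "_solid",
    )
    if check_self_intersection:
        count = count_self_intersecting_faces(solid)
        if count:
            log.warning("thickened shell has %d self-intersecting face(s)", count)
    return solid


# ----------------------------------------------------------------------
# ray casting and intersection utilities (Moller-Trumbore)


def _moller_trumbore(origins, directions, tri0, tri1, tri2, t_min, t_max):
    """Ray/segment-triangle intersection for aligned arrays of queries.

    All inputs are (n, 3); returns (hit_mask, t) where t is the ray
    parameter of the intersection.
    """
    eps = 1e-12
    e1 = tri1 - tri0
    e2 = tri2 - tri0
    pvec = np.cross(directions, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origins - tri0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", directions, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    hit &= (t >= t_min) & (t <= t_max)
    return hit, t


def ray_first_hit_distance(
    origins: np.ndarray,
    directions: np.ndarray,
    mesh: SurfaceMesh,
    t_min: float = 1e-6,
    t_max: float = np.inf,
    chunk: int = 16,
) -> np.ndarray:
    """Distance along each ray to the nearest triangle hit (nan if none)."""
    tri = mesh.vertices[mesh.faces]
    m = len(tri)
    out = np.full(len(origins), np.nan)
    for start in range(0, len(origins), chunk):
        o = origins[start : start + chunk]
        d = directions[start : start + chunk]
        k = len(o)
        O = np.repeat(o, m, axis=0)
        D = np.repeat(d, m, axis=0)
        T0 = np.tile(tri[:, 0], (k, 1))
        T1 = np.tile(tri[:, 1], (k, 1))
        T2 = np.tile(tri[:, 2], (k, 1))
        hit, t = _moller_trumbore(O, D, T0, T1, T2, t_min, t_max)
        t = np.where(hit, t, np.inf).reshape(k, m)
        best = t.min(axis=1)
        out[start : start + chunk] = np.where(np.isfinite(best), best, np.nan)
    return out


def count_self_intersecting_faces(mesh: SurfaceMesh, pair_chunk: int = 200_000) -> int:
    """Number of faces intersected by an edge of a non-adjacent face.

    Candidate pairs come from a KD-tree on face centroids; each pair is
    tested edge-against-triangle both ways.  Coplanar overlaps without an
    edge crossing are not detected (adequate as a printability warning).
    """
    from scipy.spatial import cKDTree

    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    # circumscribing radius bound per face
    r = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(2.0 * float(r.max()), output_type="ndarray")
    if len(pairs) == 0:
        return 0
    # prune: centroid distance must be under the sum of the two radii
    d = np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]], axis=1)
    pairs = pairs[d < r[pairs[:, 0]] + r[pairs[:, 1]]]
    # exclude pairs sharing a vertex (adjacent faces touch legitimately)
    f = mesh.faces
    share = np.zeros(len(pairs), dtype=bool)
    for i in range(3):
        for j in range(3):
            share |= f[pairs[:, 0], i] == f[pairs[:, 1], j]
    pairs = pairs[~share]
    bad_faces = set()
    for start in range(0, len(pairs), pair_chunk):
        p = pairs[start : start + pair_chunk]
        ta = tri[p[:, 0]]
        tb = tri[p[:, 1]]
        hit_pair = np.zeros(len(p), dtype=bool)
        for (src, dst) in ((ta, tb), (tb, ta)):
            for e in range(3):
                o = src[:, e]
                d_vec = src[:, (e + 1) % 3] - o
                hit, _ = _moller_trumbore(
                    o, d_vec, dst[:, 0], dst[:, 1], dst[:, 2], 0.0, 1.0
                )
                hit_pair |= hit
        for idx in np.nonzero(hit_pair)[0]:
            bad_faces.add(int(p[idx, 0]))
            bad_faces.add(int(p[idx, 1]))
    return len(bad_faces)


# ----------------------------------------------------------------------
# QA measurements


def sample_wall_thickness(
    solid: SurfaceMesh,
    inner_face_count: int,
    params: ShellParams,
) -> np.ndarray:
    """Ray-sampled wall thickness from the inner skin toward the outer.

    The first ``inner_face_count`` faces of the solid are the (reversed)
    inner skin.  Seeded area-weighted face sampling; rays travel along the
    outward normal (i.e. against the inner skin's stored orientation).
    """
    rng = np.random.default_rng(params.rng_seed)
    inner = solid.faces[:inner_face_count]
    tri = solid.vertices[inner]
    n_vec = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(n_vec, axis=1)
    prob = areas / areas.sum()
    chosen = rng.choice(len(inner), size=params.sample_count, p=prob)
    bary = rng.dirichlet(np.ones(3), size=params.sample_count)
    points = np.einsum("ik,ikj->ij", bary, tri[chosen])
    # inner skin is stored reversed, so its stored normal points at the leg;
    # the outward wall direction is the negated stored normal
    directions = -n_vec[chosen] / np.linalg.norm(n_vec[chosen], axis=1)[:, None]
    outer = SurfaceMesh(
        solid.vertices, solid.faces[inner_face_count:], "outer_skin"
    )
    return ray_first_hit_distance(points, directions, outer, t_min=1e-6)


def design_afo(
    mesh: SurfaceMesh,
    lm_set: LandmarkSet,
    template: TemplateSpec = None,
    shell: ShellParams = None,
) -> DesignResult:
    """Full design pipeline: neutralize, template, offset, trim, seal, QA."""
    template = template if template is not None else TemplateSpec()
    shell = shell if shell is not None else ShellParams()
    template.validate()
    shell.validate()

    def stage(name, fn, *args, **kwargs):
        # input-validation problems keep their type (they are caller errors);
        # geometric failures are wrapped with the stage name
        try:
            return fn(*args, **kwargs)
        except InputValidationError:
            raise
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    alignment = stage("neutralize", neutralize, mesh, lm_set)
    region = stage("build_template", build_template, alignment.landmarks, template)
    offset = stage("offset_surface", offset_surface, alignment.mesh, shell.clearance_mm)
    trimmed = stage("apply_template_trim", apply_template_trim, offset, region)

    # The wall is extruded outward, so outer-skin vertices can approach the
    # malleoli even when the inner shell clears them; iterate the clearance
    # pass against the thickened solid until the hard bound holds.
    clearance = template.malleolar_relief_radius_mm - 1.0
    solid = None
    for _ in range(6):
        solid = stage(
            "thicken_and_seal",
            thicken_and_seal,
            trimmed,
            shell.thickness_mm,
            check_self_intersection=False,
        )
        if clearance <= 0:
            break
        n_inner = trimmed.n_vertices
        bad = np.zeros(n_inner, dtype=bool)
        for c in region.relief_centers:
            d = np.linalg.norm(solid.vertices - np.asarray(c), axis=1)
            viol = d < clearance
            bad |= viol[:n_inner] | viol[n_inner:]
        if not bad.any():
            break
        keep = ~bad[trimmed.faces].any(axis=1)
        if not keep.any():
            raise StageError("relief_clearance", EmptyShellError(
                "relief clearance excludes every face"))
        faces = trimmed.faces[keep]
        faces = faces[_largest_face_component(faces)]
        used = np.unique(faces)
        remap = np.full(trimmed.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        trimmed = SurfaceMesh(trimmed.vertices[used], remap[faces], trimmed.name)

    report = validate_mesh(solid)
    thickness = sample_wall_thickness(solid, trimmed.n_faces, shell)
    valid = thickness[np.isfinite(thickness)]
    if len(valid):
        within = np.abs(valid - shell.thickness_mm) <= shell.thickness_tolerance_mm
        frac = float(within.mean() * len(valid) / len(thickness))
        pct = {
            "p05": float(np.percentile(valid, 5)),
            "p50": float(np.percentile(valid, 50)),
            "p95": float(np.percentile(valid, 95)),
        }
    else:
        frac = 0.0
        pct = {"p05": float("nan"), "p50": float("nan"), "p95": float("nan")}

    lm_pt, mm_pt = region.relief_centers
    d_lm = float(np.linalg.norm(solid.vertices - lm_pt, axis=1).min())
    d_mm = float(np.linalg.norm(solid.vertices - mm_pt, axis=1).min())
    relief_ok = min(d_lm, d_mm) >= region.relief_radius_mm - 1.0

    axes = compute_axes(alignment.landmarks)
    n_p = plantar_normal(alignment.landmarks, toward=axes.c_k)
    footplate_angle = float(
        np.degrees(np.arccos(np.clip(abs(n_p @ axes.leg_axis), -1.0, 1.0)))
    )
    ob_point, ob_normal = region.oblique_plane
    oblique_angle = float(np.degrees(np.arccos(np.clip(abs(ob_normal @ n_p), -1, 1))))

    self_count = (
        count_self_intersecting_faces(solid) if shell.check_self_intersection else 0
    )
    if self_count:
        log.warning("designed shell has %d self-intersecting face(s)", self_count)

    qa = QAReport(
        watertight=report.watertight,
        mesh_report=report,
        thickness_samples=int(len(thickness)),
        thickness_within_tolerance_fraction=frac,
        thickness_percentiles_mm=pct,
        min_distance_to_lateral_malleolus_mm=d_lm,
        min_distance_to_medial_malleolus_mm=d_mm,
        relief_clearance_ok=bool(relief_ok),
        footplate_shank_angle_deg=90.0 - footplate_angle,
        oblique_plane_angle_deg=oblique_angle,
        self_intersecting_face_count=int(self_count),
        applied_sagittal_correction_deg=alignment.applied_sagittal_correction_deg,
        applied_coronal_correction_deg=alignment.applied_coronal_correction_deg,
    )
    return DesignResult(mesh=solid, qa=qa, alignment=alignment, template_region=region)
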