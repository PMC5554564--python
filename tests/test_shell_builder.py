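import numpy as np
import pytest
import trimesh

from afogen.afo_template import TemplateSpec, build_template
from afogen.errors import (
    EmptyShellError,
    GeometryError,
    NothingToSealError,
    StageError,
)
from afogen.geometry_io import SurfaceMesh, validate_mesh
from afogen.shell_builder import (
    ShellParams,
    apply_template_trim,
    design_afo,
    offset_surface,
    thicken_and_seal,
)
from afogen.synthetic_leg import SyntheticLegSpec, generate_leg


def square_patch(size=100.0, n=11) -> SurfaceMesh:
    """Flat square in the z=0 plane with +z normals."""
    xs = np.linspace(0, size, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return SurfaceMesh(verts, np.array(faces), name="patch")


def spherical_cap(radius=50.0, cap_angle_deg=40.0) -> SurfaceMesh:
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    mesh = SurfaceMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))
    z_min = radius * np.cos(np.radians(cap_angle_deg))
    centroids = mesh.face_centroids()
    keep = centroids[:, 2] >= z_min
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], name="cap")


class TestOffsetSurface:
    def test_sphere_offsets_to_larger_sphere(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=50.0)
        mesh = SurfaceMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))
        out = offset_surface(mesh, 2.0)
        r = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(r - 52.0).max() <= 0.2

    def test_zero_offset_is_identity(self, neutral_leg):
        mesh, _ = neutral_leg
        out = offset_surface(mesh, 0.0)
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_flat_patch_translates_exactly(self):
        patch = square_patch()
        out = offset_surface(patch, 3.0)
        assert np.allclose(out.vertices - patch.vertices, [0.0, 0.0, 3.0], atol=1e-12)

    def test_connectivity_unchanged(self, neutral_leg):
        mesh, _ = neutral_leg
        out = offset_surface(mesh, 2.0)
        assert np.array_equal(out.faces, mesh.faces)

    def test_nonmanifold_mesh_refused(self):
        # two triangles sharing an edge plus a third fin on the same edge
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1.0]])
        faces = np.array([[0, 1, 2], [0, 3, 1], [0, 1, 4]])
        with pytest.raises(GeometryError):
            offset_surface(SurfaceMesh(verts, faces), 1.0)


@pytest.fixture(scope="module")
def trimmed(neutral_leg):
    mesh, lm_set = neutral_leg
    region = build_template(lm_set, TemplateSpec())
    return apply_template_trim(mesh, region), region


@pytest.fixture(scope="module")
def neutral_design(neutral_leg):
    mesh, lm_set = neutral_leg
    return design_afo(mesh, lm_set)


class TestTemplateTrim:
    def test_all_kept_centroids_satisfy_predicate(self, trimmed):
        shell, region = trimmed
        assert region.keep(shell.face_centroids()).all()

    def test_open_shell_with_boundary(self, trimmed):
        shell, _ = trimmed
        rep = validate_mesh(shell)
        assert rep.boundary_edge_count >= 1
        assert rep.nonmanifold_edge_count == 0

    def test_trim_is_idempotent(self, trimmed, neutral_leg):
        shell, region = trimmed
        again = apply_template_trim(shell, region)
        assert again.n_faces == shell.n_faces

    def test_empty_region_raises(self, neutral_leg):
        mesh, lm_set = neutral_leg
        region = build_template(lm_set, TemplateSpec())
        region.keep_predicate = lambda pts: np.zeros(len(np.atleast_2d(pts)), bool)
        with pytest.raises(EmptyShellError):
            apply_template_trim(mesh, region)


class TestThickenAndSeal:
    def test_flat_slab_volume(self):
        patch = square_patch(size=100.0, n=11)
        solid = thicken_and_seal(patch, 3.0)
        rep = validate_mesh(solid)
        assert rep.watertight
        volume = abs(solid.to_trimesh().volume)
        assert volume == pytest.approx(30_000.0, rel=0.01)

    def test_spherical_cap_volume_close_to_area_times_t(self):
        cap = spherical_cap()
        area = 0.5 * np.linalg.norm(cap.face_normals(), axis=1).sum()
        solid = thicken_and_seal(cap, 3.0)
        assert validate_mesh(solid).watertight
        volume = abs(solid.to_trimesh().volume)
        assert volume == pytest.approx(area * 3.0, rel=0.15)

    def test_closed_input_rejected(self, unit_cube):
        with pytest.raises(NothingToSealError):
            thicken_and_seal(unit_cube, 1.0)

    def test_winding_consistent_positive_volume(self):
        solid = thicken_and_seal(square_patch(), 3.0)
        tm = solid.to_trimesh()
        assert tm.is_winding_consistent
        assert tm.volume > 0


class TestDesignAfo:
    def test_output_watertight(self, neutral_design):
        assert neutral_design.qa.watertight
        assert validate_mesh(neutral_design.mesh).watertight

    def test_wall_thickness_gate(self, neutral_design):
        assert neutral_design.qa.thickness_within_tolerance_fraction >= 0.95

    def test_malleolar_clearance(self, neutral_design, neutral_leg):
        _, lm_set = neutral_leg
        solid = neutral_design.mesh
        for center in (lm_set.lm, lm_set.mm):
            d = np.linalg.norm(solid.vertices - center, axis=1).min()
            assert d >= 30.0 - 1.0

    def test_footplate_perpendicular_to_shank(self, neutral_design):
        assert abs(neutral_design.qa.footplate_shank_angle_deg - 90.0) <= 1.0

    def test_deformed_leg_gives_same_footplate_angle(self, neutral_design, deformed_leg):
        mesh, lm_set = deformed_leg
        result = design_afo(mesh, lm_set)
        assert result.qa.watertight
        assert abs(
            result.qa.footplate_shank_angle_deg
            - neutral_design.qa.footplate_shank_angle_deg
        ) <= 1.0

    def test_deterministic_given_seed(self, neutral_leg):
        mesh, lm_set = neutral_leg
        params = ShellParams(rng_seed=11)
        a = design_afo(mesh, lm_set, shell=params)
        b = design_afo(mesh, lm_set, shell=params)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.faces, b.mesh.faces)
        assert a.qa.to_dict() == b.qa.to_dict()

    def test_larger_relief_never_increases_area(self, neutral_leg):
        mesh, lm_set = neutral_leg
        areas = []
        for radius in (20.0, 30.0, 40.0):
            res = design_afo(
                mesh, lm_set, template=TemplateSpec(malleolar_relief_radius_mm=radius)
            )
            areas.append(res.mesh.to_trimesh().area)
        assert areas[0] >= areas[1] >= areas[2]

    def test_clearance_from_leg_surface(self, neutral_design, neutral_leg):
        from scipy.spatial import cKDTree

        leg = neutral_design.alignment.mesh
        n_inner = neutral_design.mesh.n_vertices // 2
        inner_vertices = neutral_design.mesh.vertices[:n_inner]
        d = cKDTree(leg.vertices).query(inner_vertices)[0]
        assert d.min() >= 2.0 - 0.3

    def test_degenerate_landmarks_fail_with_input_error(self, neutral_leg):
        from afogen.errors import InputValidationError
        from afogen.geometry_io import LandmarkSet

        mesh, _ = neutral_leg
        with pytest.raises(InputValidationError):
            bad = LandmarkSet(*(np.zeros(3) for _ in range(8)))
            design_afo(mesh, bad)

    def test_stage_error_names_stage(self, neutral_leg):
        mesh, lm_set = neutral_leg
        # reliefs large enough to swallow the whole leg keep no face at all
        huge_relief = TemplateSpec(malleolar_relief_radius_mm=10_000.0)
        with pytest.raises(StageError) as err:
            design_afo(mesh, lm_set, template=huge_relief)
        assert err.value.stage == "apply_template_trim"
        assert isinstance(err.value.__cause__, EmptyShellError)
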