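"""Parametric lower-leg meshes with ground-truth landmarks.

There is no public scan data to develop against, so this module generates
a stylized right lower leg as a watertight, genus-0 swept surface: a
tapered circular shank down the leg axis, a quarter-torus bend at the
ankle whose outer side forms the heel, and a lofted foot of egg-shaped
cross-section (taller dorsally than plantarly) ending in a rounded toe.
Two malleolar bumps are raised on the distal shank.

The construction is arranged so that the *neutral* leg realizes the
package's neutral references exactly:

* heel, mh1 and mh5 lie in one horizontal plane (plantar plane
  perpendicular to the shank axis -> eversion 0),
* mh2 sits on the dorsal surface at the height of the malleolar midpoint
  (foot axis perpendicular to the leg axis -> sagittal angle 90).

A plantarflexion angle delta and an eversion angle epsilon then rotate the
foot sub-body about the malleolar and anterior axes through the ankle
(with the same blend band the neutralization module uses, so there is no
crease), which is exactly the deformity the alignment stage must undo.
Ground-truth landmarks are returned after the deformity and before any
jitter, so recovery error isolates algorithmic error; optional landmark
jitter emulates manual marking error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .geometry_io import LandmarkSet, SurfaceMesh
from .neutral_alignment import blended_rotation

#: How far the malleolar bump apex protrudes from the distal shank (mm).
MALLEOLUS_PROTRUSION_MM = 10.0

#: Vertical drop from the foot tube centerline to the sole (mm).
SOLE_DROP_MM = 30.0

#: Length of the rounded toe beyond the metatarsal station (mm).
TOE_EXTENT_MM = 25.0


@dataclass
class SyntheticLegSpec:
    """Dimensions, deformity angles and noise for one synthetic leg."""

    shank_length_mm: float = 380.0
    shank_radius_proximal_mm: float = 45.0
    shank_radius_distal_mm: float = 35.0
    foot_length_mm: float = 240.0  # 3D distance heel -> mh2
    foot_width_mm: float = 80.0  # distance mh1 -> mh5
    malleolus_bump_radius_mm: float = 12.0
    plantarflexion_deg: float = 0.0
    eversion_deg: float = 0.0
    circumferential_resolution: int = 64
    axial_resolution: int = 80
    jitter_sigma_mm: float = 0.0
    landmark_jitter_sigma_mm: float = 0.0
    mirror: bool = False  # produce a left leg
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "shank_length_mm",
            "shank_radius_proximal_mm",
            "shank_radius_distal_mm",
            "foot_length_mm",
            "foot_width_mm",
            "malleolus_bump_radius_mm",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if abs(self.plantarflexion_deg) > 45:
            raise ParameterError("|plantarflexion_deg| must be <= 45")
        if abs(self.eversion_deg) > 30:
            raise ParameterError("|eversion_deg| must be <= 30")
        if self.circumferential_resolution < 8 or self.axial_resolution < 8:
            raise ParameterError("resolutions must be >= 8")
        if self.jitter_sigma_mm < 0 or self.landmark_jitter_sigma_mm < 0:
            raise ParameterError("jitter sigma must be >= 0")


def _bend_radius(spec: SyntheticLegSpec) -> float:
    return spec.shank_radius_distal_mm + 5.0


def _cross_section_offsets(psi, a, b_up, b_dn):
    """Egg cross-section: (up_offset, side_offset) for ring angles psi."""
    c = np.cos(psi)
    s = np.sin(psi)
    b = np.where(c >= 0, b_up, b_dn)
    return b * c, a * s


def _heel_point(spec: SyntheticLegSpec) -> np.ndarray:
    """Analytic heel landmark: outer bend surface at 45 degrees."""
    r_b = _bend_radius(spec)
    r_d = spec.shank_radius_distal_mm
    alpha = np.radians(45.0)
    center = np.array([r_b, 0.0, 0.0])
    path = center + r_b * np.array([-np.cos(alpha), 0.0, -np.sin(alpha)])
    e_up = np.array([np.cos(alpha), 0.0, np.sin(alpha)])
    # down-side radius blends shank circle -> sole drop across the bend
    b_dn = r_d + (SOLE_DROP_MM - r_d) * (alpha / (np.pi / 2))
    return path - b_dn * e_up


def landmark_geometry(spec: SyntheticLegSpec) -> dict:
    """Analytic positions of all eight landmarks on the neutral leg.

    Also returns derived construction values (foot half-width, metatarsal
    station) used by the mesh builder.
    """
    r_b = _bend_radius(spec)
    r_d = spec.shank_radius_distal_mm
    heel = _heel_point(spec)
    z_f = -r_b  # foot tube centerline height
    # mh2 on the dorsal surface at malleolar-midpoint height (z = 0)
    dz = heel[2]
    if spec.foot_length_mm <= abs(dz):
        raise ParameterError("foot_length_mm too short for this leg geometry")
    x_mh = heel[0] + np.sqrt(spec.foot_length_mm**2 - dz**2)
    mh2 = np.array([x_mh, 0.0, 0.0])
    # mh1/mh5 on the plantar-side surface at the heel's height
    cos_psi = (heel[2] - z_f) / SOLE_DROP_MM
    if not -1.0 < cos_psi < 0.0:
        raise ParameterError("sole drop incompatible with heel height")
    sin_psi = np.sqrt(1.0 - cos_psi**2)
    half_width = spec.foot_width_mm / 2.0
    a_f = half_width / sin_psi  # foot cross-section half-width
    mh5 = np.array([x_mh, +half_width, heel[2]])  # lateral at +Y
    mh1 = np.array([x_mh, -half_width, heel[2]])  # medial at -Y
    lm = np.array([0.0, +(r_d + MALLEOLUS_PROTRUSION_MM), 0.0])
    mm = np.array([0.0, -(r_d + MALLEOLUS_PROTRUSION_MM), 0.0])
    lt = np.array([0.0, +spec.shank_radius_proximal_mm, spec.shank_length_mm])
    mt = np.array([0.0, -spec.shank_radius_proximal_mm, spec.shank_length_mm])
    return {
        "heel": heel,
        "mh1": mh1,
        "mh2": mh2,
        "mh5": mh5,
        "lm": lm,
        "mm": mm,
        "lt": lt,
        "mt": mt,
        "a_f": a_f,
        "x_mh": x_mh,
        "z_f": z_f,
    }


def _stations(spec: SyntheticLegSpec, geo: dict):
    """Sweep stations knee -> toe: (center, e_up, a, b_up, b_dn) tuples."""
    r_b = _bend_radius(spec)
    r_d = spec.shank_radius_distal_mm
    r_p = spec.shank_radius_proximal_mm
    L = spec.shank_length_mm
    a_f, x_mh, z_f = geo["a_f"], geo["x_mh"], geo["z_f"]
    x_toe = x_mh + TOE_EXTENT_MM

    len_shank = L
    len_bend = (np.pi / 2) * r_b
    len_foot = x_mh - r_b
    len_toe = TOE_EXTENT_MM
    total = len_shank + len_bend + len_foot + len_toe
    n = spec.axial_resolution

    def alloc(length, minimum):
        return max(minimum, int(round(n * length / total)))

    n_bend = alloc(len_bend, 6)
    n_toe = alloc(len_toe, 4)
    n_foot = alloc(len_foot, 6)
    n_shank = max(6, n - n_bend - n_toe - n_foot)

    stations = []
    # shank: knee (z = L) down to ankle (z = 0), circular sections
    for z in np.linspace(L, 0.0, n_shank + 1):
        r = r_d + (r_p - r_d) * z / L
        stations.append((np.array([0.0, 0.0, z]), np.array([1.0, 0.0, 0.0]), r, r, r))
    # bend: quarter arc, blending circle -> egg
    center = np.array([r_b, 0.0, 0.0])
    for alpha in np.linspace(0.0, np.pi / 2, n_bend + 1)[1:]:
        t = alpha / (np.pi / 2)
        p = center + r_b * np.array([-np.cos(alpha), 0.0, -np.sin(alpha)])
        e_up = np.array([np.cos(alpha), 0.0, np.sin(alpha)])
        a = r_d + (a_f - r_d) * t
        b_up = r_d + (r_b - r_d) * t
        b_dn = r_d + (SOLE_DROP_MM - r_d) * t
        stations.append((p, e_up, a, b_up, b_dn))
    # foot: constant egg section to the metatarsal station
    e_up = np.array([0.0, 0.0, 1.0])
    for x in np.linspace(r_b, x_mh, n_foot + 1)[1:]:
        stations.append((np.array([x, 0.0, z_f]), e_up, a_f, r_b, SOLE_DROP_MM))
    # toe: elliptical taper to the tip
    for f in np.linspace(0.0, 1.0, n_toe + 1)[1:-1]:
        scale = np.sqrt(max(1.0 - f * f, 0.0))
        x = x_mh + TOE_EXTENT_MM * f
        stations.append(
            (np.array([x, 0.0, z_f]), e_up, a_f * scale, r_b * scale, SOLE_DROP_MM * scale)
        )
    toe_apex = np.array([x_toe, 0.0, z_f])
    return stations, toe_apex


def _sweep_mesh(spec: SyntheticLegSpec, geo: dict) -> SurfaceMesh:
    stations, toe_apex = _stations(spec, geo)
    c = spec.circumferential_resolution
    psi = 2 * np.pi * np.arange(c) / c
    y_hat = np.array([0.0, 1.0, 0.0])

    rings = []
    for p, e_up, a, b_up, b_dn in stations:
        up, side = _cross_section_offsets(psi, a, b_up, b_dn)
        rings.append(p + up[:, None] * e_up + side[:, None] * y_hat)
    verts = [np.concatenate(rings)]
    n_rings = len(rings)

    faces = []
    for i in range(n_rings - 1):
        base0, base1 = i * c, (i + 1) * c
        j = np.arange(c)
        jn = (j + 1) % c
        # winding chosen for outward orientation (verified by signed volume)
        faces.append(np.stack([base0 + j, base1 + j, base1 + jn], axis=1))
        faces.append(np.stack([base0 + j, base1 + jn, base0 + jn], axis=1))

    # knee cap (first ring) and toe cap (last ring) fans
    knee_apex_idx = n_rings * c
    toe_apex_idx = knee_apex_idx + 1
    verts.append(np.array([0.0, 0.0, spec.shank_length_mm])[None, :])
    verts.append(toe_apex[None, :])
    j = np.arange(c)
    jn = (j + 1) % c
    faces.append(np.stack([np.full(c, knee_apex_idx), j, jn], axis=1))
    last = (n_rings - 1) * c
    faces.append(np.stack([np.full(c, toe_apex_idx), last + jn, last + j], axis=1))

    vertices = np.concatenate(verts)
    face_arr = np.concatenate(faces)
    mesh = SurfaceMesh(vertices, face_arr, name="synthetic_leg")
    # enforce outward orientation via signed volume
    if mesh.to_trimesh().volume < 0:
        mesh = SurfaceMesh(vertices, face_arr[:, ::-1], name=mesh.name)
    return mesh


def _raise_malleolar_bumps(mesh: SurfaceMesh, spec: SyntheticLegSpec) -> None:
    r_d = spec.shank_radius_distal_mm
    support = 2.0 * spec.malleolus_bump_radius_mm
    for sign in (+1.0, -1.0):
        center = np.array([0.0, sign * r_d, 0.0])
        d = np.linalg.norm(mesh.vertices - center, axis=1)
        u = np.clip(d / support, 0.0, 1.0)
        w = (1.0 - u * u) ** 2
        same_side = sign * mesh.vertices[:, 1] > 0.5 * r_d
        w = np.where(same_side, w, 0.0)
        mesh.vertices[:, 1] += sign * MALLEOLUS_PROTRUSION_MM * w


def generate_leg(spec: SyntheticLegSpec | None = None):
    """Build the synthetic leg: returns ``(SurfaceMesh, LandmarkSet)``.

    Landmarks are ground truth: exact analytic positions after the
    deformity rotations, before vertex jitter.
    """
    if spec is None:
        spec = SyntheticLegSpec()
    spec.validate()
    geo = landmark_geometry(spec)
    mesh = _sweep_mesh(spec, geo)
    _raise_malleolar_bumps(mesh, spec)

    lm_set = LandmarkSet(**{k: geo[k] for k in
                            ("heel", "mh1", "mh2", "mh5", "lm", "mm", "lt", "mt")})

    # deformity: plantarflexion about the malleolar axis, then eversion
    # about the anterior axis, both through the malleolar midpoint
    delta = np.radians(spec.plantarflexion_deg)
    eps = np.radians(spec.eversion_deg)
    if delta != 0.0 or eps != 0.0:
        rot = Rotation.from_rotvec(delta * np.array([0.0, 1.0, 0.0])) * \
            Rotation.from_rotvec(eps * np.array([1.0, 0.0, 0.0]))
        c_t = np.zeros(3)
        z_hat = np.array([0.0, 0.0, 1.0])
        new_v = blended_rotation(mesh.vertices, rot, c_t, z_hat)
        mesh = SurfaceMesh(new_v, mesh.faces, name=mesh.name)
        moved = {name: rot.apply(getattr(lm_set, name))
                 for name in ("heel", "mh1", "mh2", "mh5")}
        lm_set = lm_set.replace(**moved)

    rng = np.random.default_rng(spec.seed)
    if spec.jitter_sigma_mm > 0:
        mesh = SurfaceMesh(
            mesh.vertices + rng.normal(0.0, spec.jitter_sigma_mm, mesh.vertices.shape),
            mesh.faces,
            name=mesh.name,
        )
    if spec.landmark_jitter_sigma_mm > 0:
        jittered = {
            name: getattr(lm_set, name)
            + rng.normal(0.0, spec.landmark_jitter_sigma_mm, 3)
            for name in ("heel", "mh1", "mh2", "mh5", "lm", "mm", "lt", "mt")
        }
        lm_set = LandmarkSet(**jittered)

    if spec.mirror:
        v = mesh.vertices.copy()
        v[:, 1] *= -1.0
        mesh = SurfaceMesh(v, mesh.faces[:, ::-1].copy(), name=mesh.name + "_left")
        flipped = {}
        for name in ("heel", "mh1", "mh2", "mh5", "lm", "mm", "lt", "mt"):
            p = getattr(lm_set, name).copy()
            p[1] *= -1.0
            flipped[name] = p
        lm_set = LandmarkSet(**flipped)

    return mesh, lm_set
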