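"""Rigid neutralization of the foot about the ankle.

Before the orthosis template is applied, the scanned foot is rotated back
to neutral: first the sagittal deviation (dorsiflexion/plantarflexion) is
removed by a rotation about the malleolar axis through the malleolar
midpoint, then the coronal deviation (eversion/inversion) by a rotation
about the anterior axis through the same point.

The rotation is applied to the foot as a rigid body (all vertices distal
to the ankle), fades to zero across a +/-20 mm blend band around the
malleolar midpoint along the leg axis (a smoothstep-weighted fraction of
the rotation angle), and leaves everything proximal untouched.  The blend
avoids a crease at the ankle; connectivity never changes.

Foot landmarks (heel, mh1, mh2, mh5) receive the full rotation; the
malleoli and condyles are shank landmarks and stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .anatomy_axes import compute_axes
from .errors import ImplausibleDeformityError
from .geometry_io import LandmarkSet, SurfaceMesh

#: Z-offsets (mm) around the malleolar midpoint bounding the blend band.
BLEND_BAND_MM = (-20.0, 20.0)

#: Largest sagittal deviation from 90 deg accepted as a plausible deformity.
MAX_SAGITTAL_DEVIATION_DEG = 60.0

_FOOT_LANDMARKS = ("heel", "mh1", "mh2", "mh5")


@dataclass
class AlignmentResult:
    """A neutralized mesh + landmarks and the corrections that produced it."""

    mesh: SurfaceMesh
    landmarks: LandmarkSet
    applied_sagittal_correction_deg: float
    applied_coronal_correction_deg: float
    blend_band_mm: tuple


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def blended_rotation(
    vertices: np.ndarray,
    rotation: Rotation,
    center: np.ndarray,
    z_axis: np.ndarray,
    band: tuple = BLEND_BAND_MM,
) -> np.ndarray:
    """Rotate points about ``center``, weighted by height along ``z_axis``.

    Points with height <= band[0] get the full rotation, points with
    height >= band[1] none; in between the rotation angle is scaled by a
    smoothstep of the height.  Returns new coordinates.
    """
    lo, hi = band
    h = (vertices - center) @ z_axis
    w = 1.0 - _smoothstep((h - lo) / (hi - lo))
    rotvec = rotation.as_rotvec()
    if np.linalg.norm(rotvec) < 1e-15:
        return vertices.copy()
    scaled = Rotation.from_rotvec(w[:, None] * rotvec[None, :])
    return center + scaled.apply(vertices - center)


def _apply_correction(
    mesh: SurfaceMesh,
    lm_set: LandmarkSet,
    rotation: Rotation,
    center: np.ndarray,
    z_axis: np.ndarray,
) -> tuple:
    new_vertices = blended_rotation(mesh.vertices, rotation, center, z_axis)
    new_mesh = SurfaceMesh(new_vertices, mesh.faces.copy(), mesh.name)
    moved = {
        name: center + rotation.apply(getattr(lm_set, name) - center)
        for name in _FOOT_LANDMARKS
    }
    new_lm = lm_set.replace(**moved)
    return new_mesh, new_lm


def correct_dorsiflexion(mesh: SurfaceMesh, lm_set: LandmarkSet) -> AlignmentResult:
    """Rotate the foot about the malleolar axis to 90 deg sagittal."""
    axes = compute_axes(lm_set)
    deviation = axes.sagittal_angle_deg - 90.0
    if abs(deviation) > MAX_SAGITTAL_DEVIATION_DEG:
        raise ImplausibleDeformityError(
            f"sagittal deviation {deviation:+.1f} deg exceeds "
            f"{MAX_SAGITTAL_DEVIATION_DEG} deg; check the landmarks"
        )
    correction = -deviation
    rot = Rotation.from_rotvec(np.radians(correction) * axes.frame.y_hat)
    new_mesh, new_lm = _apply_correction(
        mesh, lm_set, rot, axes.c_t, axes.frame.z_hat
    )
    return AlignmentResult(
        mesh=new_mesh,
        landmarks=new_lm,
        applied_sagittal_correction_deg=float(correction),
        applied_coronal_correction_deg=0.0,
        blend_band_mm=BLEND_BAND_MM,
    )


def correct_eversion(mesh: SurfaceMesh, lm_set: LandmarkSet) -> AlignmentResult:
    """Rotate the foot about the anterior axis to 0 deg eversion."""
    axes = compute_axes(lm_set)
    correction = -axes.eversion_angle_deg
    rot = Rotation.from_rotvec(np.radians(correction) * axes.frame.x_hat)
    new_mesh, new_lm = _apply_correction(
        mesh, lm_set, rot, axes.c_t, axes.frame.z_hat
    )
    return AlignmentResult(
        mesh=new_mesh,
        landmarks=new_lm,
        applied_sagittal_correction_deg=0.0,
        applied_coronal_correction_deg=float(correction),
        blend_band_mm=BLEND_BAND_MM,
    )


def neutralize(mesh: SurfaceMesh, lm_set: LandmarkSet) -> AlignmentResult:
    """Sagittal correction followed by coronal correction.

    The order is part of the contract (it matters for large combined
    deformities).  Because the eversion measurement de-rotates the sagittal
    deviation first, the two corrections form an exact decomposition and
    the composition is idempotent: running neutralize on its own output is
    the identity to numerical precision.
    """
    step1 = correct_dorsiflexion(mesh, lm_set)
    step2 = correct_eversion(step1.mesh, step1.landmarks)
    return AlignmentResult(
        mesh=step2.mesh,
        landmarks=step2.landmarks,
        applied_sagittal_correction_deg=step1.applied_sagittal_correction_deg,
        applied_coronal_correction_deg=step2.applied_coronal_correction_deg,
        blend_band_mm=BLEND_BAND_MM,
    )


def residual_angles(lm_set: LandmarkSet) -> tuple:
    """(sagittal - 90, eversion) of a landmark set, in degrees."""
    axes = compute_axes(lm_set)
    return axes.sagittal_angle_deg - 90.0, axes.eversion_angle_deg


__all__ = [
    "AlignmentResult",
    "BLEND_BAND_MM",
    "blended_rotation",
    "correct_dorsiflexion",
    "correct_eversion",
    "neutralize",
    "residual_angles",
]
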