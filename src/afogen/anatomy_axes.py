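"""Anatomical axes and deformity angles from the eight landmarks.

The foot axis runs from the malleolar midpoint C_T toward the second
metatarsal head (anterior), the leg axis from C_T toward the condylar
midpoint C_K (proximal).  A shank-fixed frame is attached to the landmarks:

* z_hat  — the leg axis,
* y_hat  — the malleolar line lm-mm orthogonalized against z_hat
           (flipped, together with x_hat, so that x_hat points anteriorly,
           i.e. has positive dot product with heel->mh2),
* x_hat  — y_hat x z_hat (anterior).

Because the malleoli and condyles belong to the shank, this frame does not
move when the foot is rotated at the ankle, so the two deformity angles
read out an exact two-rotation (malleolar-axis then anterior-axis)
decomposition of the foot pose:

* sagittal angle — angle between the x/z-plane projections of the foot and
  leg axes, in [0, 180] degrees.  90 is neutral, > 90 plantarflexed
  (drop foot), < 90 dorsiflexed.
* eversion angle — the sagittal deviation is first removed by rotating the
  plantar-plane normal back about the malleolar axis; the signed tilt of
  the result away from the leg axis in the coronal plane is the eversion.
  Positive values mean the sole faces laterally (eversion), negative
  medially (inversion); 0 is neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateLandmarkError,
    DegeneratePlaneError,
    ProjectionDegenerateError,
)
from .geometry_io import LandmarkSet

_EPS_AXIS = 1e-9
_EPS_PROJ = 1e-6


def _unit(v: np.ndarray, what: str, pair: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS_AXIS:
        raise DegenerateLandmarkError(f"{what} is zero-length ({pair} coincide)")
    return v / n


@dataclass(frozen=True)
class ShankFrame:
    """Right-handed orthonormal frame rigidly attached to the shank."""

    origin: np.ndarray  # c_t
    x_hat: np.ndarray  # anterior
    y_hat: np.ndarray  # malleolar (mediolateral) direction
    z_hat: np.ndarray  # proximal (leg axis)


@dataclass(frozen=True)
class AnatomicalAxes:
    """Foot/leg axes, ankle midpoints and the two deformity angles."""

    c_t: np.ndarray
    c_k: np.ndarray
    foot_axis: np.ndarray
    leg_axis: np.ndarray
    sagittal_angle_deg: float
    eversion_angle_deg: float
    frame: ShankFrame


def shank_frame(lm_set: LandmarkSet) -> ShankFrame:
    """Construct the shank-fixed frame from malleoli, condyles, heel, mh2."""
    c_t = 0.5 * (lm_set.lm + lm_set.mm)
    c_k = 0.5 * (lm_set.lt + lm_set.mt)
    z_hat = _unit(c_k - c_t, "leg axis", "c_t and c_k")
    y_raw = lm_set.lm - lm_set.mm
    y_perp = y_raw - (y_raw @ z_hat) * z_hat
    y_hat = _unit(y_perp, "malleolar axis", "lm and mm (or parallel to leg axis)")
    x_hat = np.cross(y_hat, z_hat)
    anterior_hint = lm_set.mh2 - lm_set.heel
    if x_hat @ anterior_hint < 0:
        x_hat = -x_hat
        y_hat = -y_hat
    return ShankFrame(origin=c_t, x_hat=x_hat, y_hat=y_hat, z_hat=z_hat)


def plantar_normal(lm_set: LandmarkSet, toward: np.ndarray) -> np.ndarray:
    """Unit normal of the plane through heel, mh1, mh5, oriented toward a point."""
    n = np.cross(lm_set.mh1 - lm_set.heel, lm_set.mh5 - lm_set.heel)
    norm = np.linalg.norm(n)
    # scale-free collinearity test
    span = max(
        np.linalg.norm(lm_set.mh1 - lm_set.heel),
        np.linalg.norm(lm_set.mh5 - lm_set.heel),
    )
    if norm < 1e-9 * max(span**2, 1.0):
        raise DegeneratePlaneError("heel, mh1 and mh5 are collinear")
    n = n / norm
    centroid = (lm_set.heel + lm_set.mh1 + lm_set.mh5) / 3.0
    if n @ (toward - centroid) < 0:
        n = -n
    return n


def _sagittal_angle(foot_axis, leg_axis, frame: ShankFrame) -> float:
    f2 = np.array([foot_axis @ frame.x_hat, foot_axis @ frame.z_hat])
    l2 = np.array([leg_axis @ frame.x_hat, leg_axis @ frame.z_hat])
    if np.linalg.norm(f2) < _EPS_PROJ or np.linalg.norm(l2) < _EPS_PROJ:
        raise ProjectionDegenerateError(
            "axis projects to zero length in the sagittal plane"
        )
    cross = f2[0] * l2[1] - f2[1] * l2[0]
    dot = f2 @ l2
    return float(np.degrees(np.arctan2(abs(cross), dot)))


def sagittal_ankle_angle(axes: AnatomicalAxes) -> float:
    """Angle (degrees, [0,180]) between sagittal projections of the axes."""
    return _sagittal_angle(axes.foot_axis, axes.leg_axis, axes.frame)


def _eversion_angle(lm_set: LandmarkSet, frame: ShankFrame, sagittal_deg: float,
                    c_k: np.ndarray) -> float:
    n_p = plantar_normal(lm_set, toward=c_k)
    # remove the sagittal deviation about the malleolar axis so the coronal
    # tilt is read in the foot's own de-rotated frame (exact decomposition)
    derot = Rotation.from_rotvec(np.radians(-(sagittal_deg - 90.0)) * frame.y_hat)
    n_d = derot.apply(n_p)
    y = n_d @ frame.y_hat
    z = n_d @ frame.z_hat
    if abs(y) < _EPS_PROJ and abs(z) < _EPS_PROJ:
        raise ProjectionDegenerateError(
            "plantar normal projects to zero length in the coronal plane"
        )
    return float(np.degrees(np.arctan2(-y, z)))


def coronal_eversion_angle(lm_set: LandmarkSet, axes: AnatomicalAxes) -> float:
    """Signed eversion angle (degrees); positive = sole faces laterally."""
    return _eversion_angle(lm_set, axes.frame, axes.sagittal_angle_deg, axes.c_k)


def compute_axes(lm_set: LandmarkSet) -> AnatomicalAxes:
    """Build the foot and leg axes and measure both deformity angles.

    Rigid-transform equivariant: transforming the landmarks transforms the
    axes and leaves both angles unchanged.
    """
    frame = shank_frame(lm_set)
    c_t = frame.origin
    c_k = 0.5 * (lm_set.lt + lm_set.mt)
    foot_axis = _unit(lm_set.mh2 - c_t, "foot axis", "mh2 and c_t")
    leg_axis = frame.z_hat
    sagittal = _sagittal_angle(foot_axis, leg_axis, frame)
    eversion = _eversion_angle(lm_set, frame, sagittal, c_k)
    return AnatomicalAxes(
        c_t=c_t,
        c_k=c_k,
        foot_axis=foot_axis,
        leg_axis=leg_axis,
        sagittal_angle_deg=round(sagittal, 6),
        eversion_angle_deg=round(eversion, 6),
        frame=frame,
    )
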