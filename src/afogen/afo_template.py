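"""Landmark-scaled trimming geometry for the orthosis shell.

The orthosis is a one-piece (jointless) posterior-shell design: a footplate
under the foot, a posterior calf shell up the shank, and a flexible neck
joining them behind the ankle.  Its outline is expressed as a *keep
predicate* over 3D points, built from the neutralized landmarks:

* footplate — everything below the malleolar midpoint inside a box sized
  by the landmarks: length = |heel - mh2| + toe margin along the anterior
  axis from the heel, width = |mh1 - mh5| + 2 x side margin centered
  between the metatarsal heads;
* calf shell — the posterior fraction of the shank circumference, from the
  malleoli up to a fraction of the malleolus-to-condyle distance;
* malleolar reliefs — open discs (strict inequality) of fixed radius
  around each malleolus are excluded;
* heel oblique — a plane through the point ``heel + d_h x anterior``,
  inclined 45 degrees to the plantar plane and extruded mediolaterally;
  sub-malleolar material strictly on its anterior-superior side is
  excluded, which frees the dorsum of the foot and shapes the neck.

Linear dimensions scale with the landmarks; the relief radius, margins and
heel offset are absolute millimetres.  The radius and heel offset are
design constants of this package (no published values exist for them);
defaults reflect adult malleolar prominence and posterior-leaf-spring
practice and are overridable in the design config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .anatomy_axes import compute_axes, plantar_normal
from .errors import ParameterError, PoseError
from .geometry_io import LandmarkSet

#: Pose tolerance (degrees) for accepting landmarks as neutralized.
NEUTRAL_POSE_TOL_DEG = 1.0


@dataclass
class TemplateSpec:
    """All trimming parameters of the orthosis template."""

    malleolar_relief_radius_mm: float = 30.0
    heel_oblique_distance_mm: float = 60.0
    oblique_angle_deg: float = 45.0
    clearance_mm: float = 2.0
    thickness_mm: float = 3.0
    shank_trim_fraction: float = 0.8
    footplate_toe_margin_mm: float = 10.0
    footplate_side_margin_mm: float = 5.0
    posterior_wrap_fraction: float = 0.5

    def validate(self) -> None:
        if self.malleolar_relief_radius_mm < 0:
            raise ParameterError("malleolar_relief_radius_mm must be >= 0")
        if self.heel_oblique_distance_mm <= 0:
            raise ParameterError("heel_oblique_distance_mm must be > 0")
        if self.oblique_angle_deg != 45.0:
            raise ParameterError("oblique_angle_deg is fixed at 45")
        if self.clearance_mm < 0:
            raise ParameterError("clearance_mm must be >= 0")
        if self.thickness_mm <= 0:
            raise ParameterError("thickness_mm must be > 0")
        if not 0 < self.shank_trim_fraction <= 1:
            raise ParameterError("shank_trim_fraction must be in (0, 1]")
        if self.footplate_toe_margin_mm < 0 or self.footplate_side_margin_mm < 0:
            raise ParameterError("footplate margins must be >= 0")
        if not 0 < self.posterior_wrap_fraction <= 1:
            raise ParameterError("posterior_wrap_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateSpec":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown template parameter(s): {sorted(unknown)}")
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class TemplateRegion:
    """Trimming region: keep predicate plus its defining geometry."""

    keep_predicate: Callable[[np.ndarray], np.ndarray]
    relief_centers: tuple
    relief_radius_mm: float
    oblique_plane: tuple  # (point, unit normal)
    footplate_length_mm: float
    footplate_width_mm: float
    shank_trim_height_mm: float

    def keep(self, points: np.ndarray) -> np.ndarray:
        """Vectorized keep test for an (n, 3) array (or single point)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = self.keep_predicate(pts)
        return out if np.asarray(points).ndim == 2 else bool(out[0])


def malleolar_reliefs(lm_set: LandmarkSet, radius: float):
    """Exclusion predicate: True where within ``radius`` of either malleolus.

    Strict inequality: a point at exactly the radius is *not* excluded.
    """
    if radius < 0:
        raise ParameterError("relief radius must be >= 0")
    lm, mm = lm_set.lm.copy(), lm_set.mm.copy()

    def excluded(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d_lm = np.linalg.norm(pts - lm, axis=1)
        d_mm = np.linalg.norm(pts - mm, axis=1)
        return (d_lm < radius) | (d_mm < radius)

    return excluded


def _require_neutral(lm_set: LandmarkSet):
    axes = compute_axes(lm_set)
    if (
        abs(axes.sagittal_angle_deg - 90.0) > NEUTRAL_POSE_TOL_DEG
        or abs(axes.eversion_angle_deg) > NEUTRAL_POSE_TOL_DEG
    ):
        raise PoseError(
            f"landmarks are not neutralized (sagittal "
            f"{axes.sagittal_angle_deg:.2f} deg, eversion "
            f"{axes.eversion_angle_deg:.2f} deg); run neutralize first"
        )
    return axes


def heel_oblique(lm_set: LandmarkSet, spec: TemplateSpec):
    """The 45-degree heel oblique trimming plane: ``(point, unit normal)``.

    The plane passes through the point ``heel_oblique_distance_mm`` anterior
    of the heel, contains the mediolateral direction, and is inclined 45
    degrees to the plantar plane; its unit normal points to the excluded
    anterior-superior side.
    """
    if spec.heel_oblique_distance_mm <= 0:
        raise ParameterError("heel_oblique_distance_mm must be > 0")
    axes = _require_neutral(lm_set)
    frame = axes.frame
    point = lm_set.heel + spec.heel_oblique_distance_mm * frame.x_hat
    # reference the plantar plane itself so the 45-degree inclination is
    # exact even when the pose is only neutral to within tolerance
    n_p = plantar_normal(lm_set, toward=axes.c_k)
    x_p = frame.x_hat - (frame.x_hat @ n_p) * n_p
    x_p = x_p / np.linalg.norm(x_p)
    angle = np.radians(spec.oblique_angle_deg)
    normal = np.sin(angle) * x_p + np.cos(angle) * n_p
    return point, normal / np.linalg.norm(normal)


def build_template(lm_set: LandmarkSet, spec: TemplateSpec) -> TemplateRegion:
    """Assemble the full keep-region from neutralized landmarks."""
    spec.validate()
    axes = _require_neutral(lm_set)
    frame = axes.frame
    c_t, c_k = axes.c_t, axes.c_k
    x_hat, y_hat, z_hat = frame.x_hat, frame.y_hat, frame.z_hat

    footplate_length = (
        float(np.linalg.norm(lm_set.heel - lm_set.mh2)) + spec.footplate_toe_margin_mm
    )
    footplate_width = (
        float(np.linalg.norm(lm_set.mh1 - lm_set.mh5))
        + 2.0 * spec.footplate_side_margin_mm
    )
    shank_height = spec.shank_trim_fraction * float(np.linalg.norm(c_k - c_t))
    wrap_half_angle = spec.posterior_wrap_fraction * np.pi
    heel = lm_set.heel.copy()
    mid_met = 0.5 * (lm_set.mh1 + lm_set.mh5)

    oblique_point, oblique_normal = heel_oblique(lm_set, spec)
    relief = malleolar_reliefs(lm_set, spec.malleolar_relief_radius_mm)

    def keep(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        rel = pts - c_t
        h = rel @ z_hat

        # shank part: posterior wrap, malleoli up to the trim height
        d_x = rel @ x_hat
        d_y = rel @ y_hat
        azimuth = np.arctan2(d_y, -d_x)  # 0 at posterior
        shank_keep = (h >= 0) & (h <= shank_height) & (np.abs(azimuth) <= wrap_half_angle)

        # foot part: footplate box below the malleoli, minus the oblique cut
        u = (pts - heel) @ x_hat
        v = (pts - mid_met) @ y_hat
        in_box = (u <= footplate_length) & (np.abs(v) <= footplate_width / 2.0)
        above_oblique = (pts - oblique_point) @ oblique_normal > 0.0
        foot_keep = (h < 0) & in_box & ~above_oblique

        return (shank_keep | foot_keep) & ~relief(pts)

    return TemplateRegion(
        keep_predicate=keep,
        relief_centers=(lm_set.lm.copy(), lm_set.mm.copy()),
        relief_radius_mm=spec.malleolar_relief_radius_mm,
        oblique_plane=(oblique_point, oblique_normal),
        footplate_length_mm=footplate_length,
        footplate_width_mm=footplate_width,
        shank_trim_height_mm=shank_height,
    )
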