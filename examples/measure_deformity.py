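"""Measure ankle deformity angles and neutralize them.

Generates a leg with a known 15-degree plantarflexion and -10-degree
eversion (inversion), measures both angles from the eight landmarks, and
shows that neutralization drives them back to the neutral references
(90 degrees between the foot and leg axes; plantar plane perpendicular to
the shank).
"""

from afogen import SyntheticLegSpec, compute_axes, generate_leg, neutralize

mesh, landmarks = generate_leg(
    SyntheticLegSpec(plantarflexion_deg=15.0, eversion_deg=-10.0)
)

before = compute_axes(landmarks)
print(f"before: sagittal {before.sagittal_angle_deg:.3f} deg "
      f"(90 = neutral, >90 = drop foot), "
      f"eversion {before.eversion_angle_deg:+.3f} deg (0 = neutral)")

result = neutralize(mesh, landmarks)
after = compute_axes(result.landmarks)
print(f"after : sagittal {after.sagittal_angle_deg:.3f} deg, "
      f"eversion {after.eversion_angle_deg:+.3f} deg")
print(f"applied corrections: {result.applied_sagittal_correction_deg:+.1f} deg "
      f"about the malleolar axis, {result.applied_coronal_correction_deg:+.1f} deg "
      f"about the anterior axis")
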