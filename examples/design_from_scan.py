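"""Design an orthosis end-to-end from a scan + landmarks.

A synthetic right leg with a 20-degree drop-foot (plantarflexion) and
10 degrees of eversion stands in for the patient scan.  The pipeline
neutralizes the ankle, overlays the landmark-scaled template and emits a
watertight printable solid, then prints the quality gates: watertightness,
the fraction of sampled wall thicknesses within tolerance, the clearance
kept around each malleolus and the footplate-to-shank angle (90 = the
footplate is exactly perpendicular to the shank shell).
"""

from afogen import ShellParams, SyntheticLegSpec, design_afo, generate_leg, write_stl

scan, landmarks = generate_leg(
    SyntheticLegSpec(plantarflexion_deg=20.0, eversion_deg=10.0)
)
result = design_afo(scan, landmarks, shell=ShellParams(rng_seed=1))

write_stl(result.mesh, "afo_example.stl")
qa = result.qa
print(f"corrections applied : sagittal {qa.applied_sagittal_correction_deg:+.1f} deg, "
      f"coronal {qa.applied_coronal_correction_deg:+.1f} deg")
print(f"watertight          : {qa.watertight}")
print(f"wall thickness      : {100 * qa.thickness_within_tolerance_fraction:.1f}% of "
      f"samples within 3.0 +/- 0.5 mm "
      f"(median {qa.thickness_percentiles_mm['p50']:.2f} mm)")
print(f"malleolar clearance : lateral {qa.min_distance_to_lateral_malleolus_mm:.1f} mm, "
      f"medial {qa.min_distance_to_medial_malleolus_mm:.1f} mm (ok={qa.relief_clearance_ok})")
print(f"footplate-shank     : {qa.footplate_shank_angle_deg:.2f} deg")
print(f"heel oblique plane  : {qa.oblique_plane_angle_deg:.2f} deg to the sole")
print("wrote afo_example.stl")
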