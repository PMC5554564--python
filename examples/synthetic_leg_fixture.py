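"""Generate a synthetic leg fixture and check its integrity.

The generator emulates a lower-leg surface scan with analytically known
landmarks, controllable deformity angles and optional Gaussian noise.  It
is the test bed for every pipeline stage: here we generate a noisy left
leg, confirm it is a closed printable surface, and write it to disk with
its ground-truth landmark file.
"""

from afogen import SyntheticLegSpec, generate_leg, validate_mesh, write_landmarks, write_stl

spec = SyntheticLegSpec(
    plantarflexion_deg=10.0,
    jitter_sigma_mm=0.5,   # scanner noise on the surface
    mirror=True,           # left leg
    seed=42,
)
mesh, landmarks = generate_leg(spec)
report = validate_mesh(mesh)

print(f"vertices/faces      : {mesh.n_vertices} / {mesh.n_faces}")
print(f"watertight          : {report.watertight}")
print(f"euler characteristic: {report.euler_characteristic} (2 = genus-0 closed surface)")
write_stl(mesh, "synthetic_leg.stl")
write_landmarks(landmarks, "synthetic_leg_landmarks.json")
print("wrote synthetic_leg.stl + synthetic_leg_landmarks.json")
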