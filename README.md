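# afogen — automated ankle-foot-orthosis design from a lower-leg scan

People with foot drop (for example from common peroneal neuropathy) are
usually fitted with an ankle-foot orthosis (AFO): a one-piece shell that
holds the ankle near neutral.  Conventional manufacture is manual —
plaster casting, thermoplastic molding, hand trimming — and has to be
repeated whenever the device breaks or the patient changes.  `afogen`
implements the automated alternative: an algorithmic scan-to-STL pipeline
that turns a surface scan of the lower leg plus eight manually marked
anatomical landmarks into a printable, individualized AFO shell.

It is written for rehabilitation engineers and orthotics researchers who
want a scriptable, testable design pipeline rather than interactive CAD.

## The algorithm

Landmarks (all coordinates in millimetres): heel, first/second/fifth
metatarsal heads (MH1/MH2/MH5), lateral/medial malleoli (LM/MM),
lateral/medial tibial condyles (LT/MT).

1. **Axes.**  C_T = (LM+MM)/2, C_K = (LT+MT)/2.  The *foot axis* runs from
   C_T toward MH2; the *leg axis* from C_T toward C_K.  A shank-fixed frame
   (z up the leg axis, y along the malleolar line, x anterior) defines the
   sagittal and coronal planes.
2. **Deformity angles.**  The sagittal ankle angle is the angle between the
   sagittal projections of the two axes (90° = neutral, >90° =
   plantarflexed drop foot).  Eversion is the signed coronal tilt of the
   plantar-plane normal (through heel, MH1, MH5) after the sagittal
   deviation is removed; positive = sole faces laterally.
3. **Neutralization.**  The foot is rotated rigidly about the malleolar
   axis through C_T by (90° − sagittal angle), then about the anterior axis
   by −eversion.  The rotation fades to zero across a ±20 mm blend band
   around C_T so the mesh never creases; the shank is untouched.
4. **Template.**  A keep-region scaled by the landmarks: a footplate box
   (length |heel−MH2| + toe margin, width |MH1−MH5| + side margins), the
   posterior half of the shank circumference up to 0.8·|C_T−C_K|, minus
   30 mm relief discs around each malleolus, minus everything
   anterior-superior of a plane through the point 60 mm anterior of the
   heel inclined 45° to the sole.
5. **Shell.**  The leg surface is offset by the clearance (2 mm), trimmed
   by the template (face-centroid test), thickened by the wall thickness
   (3 mm) and sealed into a watertight solid, with QA gates: ray-sampled
   wall thickness within ±0.5 mm for ≥95 % of samples, a hard vertex
   clearance of relief radius − 1 mm around both malleoli, and a footplate
   perpendicular to the shank within 1°.

A parametric synthetic-leg generator (watertight, genus 0, exact
analytic landmarks, controllable plantarflexion δ and eversion ε plus
Gaussian noise) makes the whole pipeline testable without patient data.
Evaluation utilities cover the durability-test load definition (sinusoidal
force, stress ratio R = F_min/F_max = 0.1, peak 50 N, 1 Hz, 300,000 cycles
≙ 4 months at 2,500 steps/day) and QUEST satisfaction scoring (eight 1–5
items, mean rounded half-up to one decimal).

## Worked example

```sh
python examples/design_from_scan.py
```

designs an AFO for a synthetic leg with a 20° drop foot and 10° eversion
and prints:

```
corrections applied : sagittal -20.0 deg, coronal -10.0 deg
watertight          : True
wall thickness      : 100.0% of samples within 3.0 +/- 0.5 mm (median 3.00 mm)
malleolar clearance : lateral 29.8 mm, medial 29.1 mm (ok=True)
footplate-shank     : 90.00 deg
heel oblique plane  : 45.00 deg to the sole
wrote afo_example.stl
```

The corrections are exactly the injected deformity with the sign flipped;
the shell is a closed printable solid whose wall is the requested 3 mm
everywhere sampled; no part of it comes within 29 mm of either malleolus
(the 30 mm relief minus a 1 mm tolerance); and the footplate ends up
perpendicular to the shank, i.e. the device holds the ankle at neutral.
The other scripts in `examples/` demonstrate deformity measurement,
the fatigue load profile, QUEST scoring and the synthetic-leg fixture.

The same pipeline is available as a CLI:

```sh
afogen synth-leg --output-stl leg.stl --output-landmarks lm.json --plantarflexion 20
afogen measure lm.json
afogen design --config design.yaml --seed 1
afogen quest --scores 4,5,4,5,5,5,4,4
afogen fatigue-profile --output profile.csv --cycles 100
```

`design` exits 0 only if all QA gates pass (1 = validation error,
2 = geometry failure, 3 = I/O) and writes a JSON QA sidecar next to the
STL with the package version and a config hash for provenance.

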