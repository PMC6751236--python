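"""Recover the rigid motion between time points and apply the QC gate.

Registration runs on Euclidean distance maps of the bone segmentations
(CT >= 200 HU), matching 7-voxel blocks by normalized cross-correlation and
fitting a rigid transform by trimmed least squares; a second pass refines the
fit inside a region of interest around the tumor.  The QC gate (bone Dice and
mean residual block displacement) replaces expert visual review.
"""

import numpy as np

from recurmap import PhantomSpec, generate_patient, register_pair
from recurmap.registration import RigidTransform

true_t = RigidTransform.from_euler((2.0, -3.0, 1.0), (6.0, -4.0, 2.0), center=(64.0, 64.0, 48.0))

for deformity in (False, True):
    patient = generate_patient(PhantomSpec(seed=3, rigid_offset=true_t, deformity=deformity))
    result = register_pair(patient.pre_ct, patient.post_ct, patient.registration_roi())
    err = np.abs(result.transform.translation - true_t.translation)
    kind = "deformed " if deformity else "rigid    "
    print(f"{kind} patient: recovered translation {np.round(result.transform.translation, 2)} mm "
          f"(true {true_t.translation})")
    print(f"          bone dice {result.bone_dice:.3f}, "
          f"mean residual {result.mean_residual_mm:.2f} mm, "
          f"QC {'PASS' if result.qc_pass else 'FAIL'}")

print()
print("The rigid case is recovered to sub-voxel accuracy and passes QC; the")
print("deformity case (tumor and hyoid-like bone shifted between time points)")
print("leaves residual block displacements a rigid model cannot absorb, so the")
print("gate excludes the patient, mirroring expert exclusion of unreliable")
print("registrations.")
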