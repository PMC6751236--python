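"""Metabolic volumes, coverage curves and the regional failure/responder comparison.

For each patient the pre-treatment GTV is partitioned into GTVfailure (overlap
with the registered recurrent tumor) and GTVresponder.  MTV coverage curves
sweep the SUVmax threshold 0..100%; the six histogram features of each region
are compared across the cohort with exact Wilcoxon signed-rank tests.
"""

import numpy as np

from recurmap import (
    PhantomSpec,
    apply_transform,
    compare_regions,
    compute_tumor_volumes,
    coverage_curve,
    generate_cohort,
    histogram_features,
    partition_recurrence,
)

cohort = generate_cohort(8, PhantomSpec(seed=21, signal_strength=1.5))
pairs = []
for p in cohort:
    warped = apply_transform(p.true_transform, p.gtv_recur_postspace, p.gtv_pre.grid)
    part = partition_recurrence(p.gtv_pre, warped)
    pairs.append(
        (histogram_features(p.pre_pet, part.gtv_failure),
         histogram_features(p.pre_pet, part.gtv_responder))
    )

p = cohort[0]
vols = compute_tumor_volumes(p.pre_pet, p.gtv_pre)
part = partition_recurrence(p.gtv_pre, apply_transform(p.true_transform, p.gtv_recur_postspace, p.gtv_pre.grid))
curve_f = coverage_curve(p.pre_pet, p.gtv_pre, part.gtv_failure)
curve_r = coverage_curve(p.pre_pet, p.gtv_pre, part.gtv_responder)

print(f"patient {p.patient_id}: SUVmax {vols.suv_max:.2f}, MTV50 {vols.mtv50_volume_ml:.1f} mL, "
      f"TLG50 {vols.tlg50:.1f} SUV*mL")
for t in (20, 50, 80):
    print(f"  MTV@{t:3d}%: covers {curve_f[t, 1]:.0%} of failure, {curve_r[t, 1]:.0%} of responder")

print()
print(compare_regions(pairs).round(3).to_string(index=False))
print()
print("Mid-range thresholds cover the (hotter) failure region preferentially;")
print("significant rows (p <= 0.05) show which histogram features separate the")
print("regions across the cohort.")
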