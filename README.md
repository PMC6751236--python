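# recurmap

Voxel-wise mapping and prediction of tumor-recurrence sub-regions from
pre-treatment PET/CT, for head-and-neck cancers treated with (chemo)radiotherapy.

Roughly a third of locally advanced head-and-neck tumors recur locally after
treatment. If the sub-region of the tumor that will eventually recur could be
identified on the *pre-treatment* FDG-PET, radiotherapy dose could be escalated
there selectively ("dose painting"). `recurmap` implements the full analysis
pipeline for that question:

1. **Registration** — the post-treatment (recurrence) CT is rigidly aligned to
   pre-treatment space. Because soft tissue changes drastically over a course
   of chemoradiotherapy, registration runs on Euclidean distance maps of the
   bone segmentations (CT ≥ 200 HU): a block-matching algorithm maximizes
   normalized cross-correlation of 7-voxel blocks over integer displacements,
   fits a rigid transform by trimmed least squares, iterates to convergence on
   a two-level pyramid, then refines inside a region of interest around the
   tumor. An automated QC gate (bone Dice + mean residual block displacement
   in the ROI) excludes patients whose anatomy changed too much for a rigid
   model.
2. **Labeling** — the warped recurrent tumor partitions the pre-treatment GTV
   into GTV<sub>failure</sub> (overlap) and GTV<sub>responder</sub> (rest).
   Metabolic tumor volumes MTV(t) = {v ∈ GTV : SUV(v) ≥ t·SUV<sub>max</sub>}
   are swept over t = 0…100%, with the classical dose-escalation candidate
   MTV<sub>50</sub> + 10 mm margin, and TLG₅₀ = mean SUV × volume.
3. **Regional statistics** — six histogram features (min, max, mean,
   population variance, Fisher skewness, excess kurtosis) per region, compared
   across the cohort with exact Wilcoxon signed-rank tests (full 2ⁿ sign
   enumeration up to n = 15), plus Fleiss's κ for multi-rater registration
   review.
4. **Voxel-wise model** — each GTV voxel gets 22 features: relative SUV,
   distances to v<sub>max</sub>/v<sub>min</sub>/surface, 7 Haralick statistics
   of a local 64-bin grey-level co-occurrence matrix (5×5×5 patch, 13
   symmetrized distance-1 offsets, on an isotropically resampled grid),
   Laplacian-of-Gaussian, normalized tumor-frame position, MTV₅₀₊₁₀
   membership, shape descriptors, MTV₅₀, TLG₅₀ and tumor site. A probability
   random forest (per-voxel probability = fraction of trees voting
   "failure") is evaluated leave-one-patient-out by ROC AUC, with
   out-of-bag error defined as 1 − OOB-AUC, mean-decrease-Gini importance,
   and recursive backward feature elimination.

Because the patient images such a study uses are not publicly distributable,
the package ships a first-class **synthetic cohort generator**: paired
pre/post PET/CT phantoms with bony structures, a heterogeneous tumor (smooth
baseline + correlated Gaussian texture + noise), a planted recurrence
sub-region whose placement couples to local uptake and texture
(`signal_strength`; 0 gives a null cohort), tumor regression in responders, a
known rigid offset, and optional soft-tissue deformity cases that registration
QC should reject. Every stage is tested against this known ground truth; real
data enters through the same NIfTI reading path.

## Worked example

`examples/` contains one short script per capability. Registration and QC
(`examples/02_registration_qc.py`):

```text
rigid     patient: recovered translation [ 4.69 -4.86  1.89] mm (true [ 6. -4.  2.])
          bone dice 0.915, mean residual 1.76 mm, QC PASS
deformed  patient: recovered translation [ 4.75 -5.15  1.29] mm (true [ 6. -4.  2.])
          bone dice 0.585, mean residual 4.07 mm, QC FAIL
```

The rigid case is recovered to within a fraction of a voxel (the residual
translation difference is absorbed by the recovered rotation about a different
center — the mapped-point error at the tumor is ≈ 0.2 mm); the deformity case
leaves residuals a rigid model cannot absorb and is excluded, the automated
counterpart of an expert rejecting an unreliable registration.

Leave-one-patient-out prediction on an 8-phantom cohort
(`examples/04_voxel_model.py`):

```text
held-out patient   AUC   max prob   OOB error (train)
  P00           0.990   0.997      0.012
  ...
median AUC 0.978  (mean 0.972)
reliability r (max prob vs AUC): 0.87
```

AUC > 0.5 means the forest ranks true recurrence voxels above responder voxels
on a patient it never saw; the correlation between a fold's maximum
probability and its AUC is the per-patient reliability signal of the map.

## Command line

A thin CLI wraps the pipeline stages:

```bash
recurmap synth-cohort --n 15 --seed 7 --out cohort/
recurmap register --pre-ct pre_ct.nii.gz --post-ct post_ct.nii.gz --roi roi.nii.gz --out reg.json
recurmap label-volumes --pet pre_pet.nii.gz --gtv gtv.nii.gz --out vols/
recurmap extract-features --pet pre_pet.nii.gz --gtv gtv.nii.gz --out features.csv
recurmap train-eval --features cohort_features.csv --trees 500 --seed 7 --out model/
recurmap run-all --seed 7 --out run/
```

`run-all` executes the whole study on a synthetic cohort and writes the
registration/QC table, tumor volumes, coverage curves, regional statistics,
the voxel feature table, per-fold AUCs, the elimination trace, probability
maps (NIfTI) and a manifest; two runs with the same seed are byte-identical.

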