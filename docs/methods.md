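# Methods

This note documents the models, conventions and defaults behind `recurmap`,
the choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish.

## Coordinate and image conventions

Volumes live on axis-aligned grids with 0-based indices; world coordinate =
origin + index × spacing (mm). Oblique NIfTI affines are reoriented to the
nearest canonical axes on read; residual shear is rejected. All distances are
physical (mm between voxel centers), with anisotropy handled by per-axis
spacing weights — a "10 mm margin" therefore means 10 mm regardless of voxel
size. Masks defined on a CT grid are moved to the PET grid by nearest-neighbor
resampling before any PET-voxel-level analysis. Isotropic resampling targets
the minimum spacing component of the input grid unless overridden; intensities
are interpolated trilinearly, labels by nearest neighbor, with nearest-edge
extrapolation so constant images stay constant.

## Registration

**Model.** Rigid (rotation + translation); deformable registration is
deliberately out of scope — per-voxel correspondence claims under a deformable
model are exactly what cannot be trusted in this anatomy.

**Signal.** Bone is segmented at ≥ 200 HU and both CTs are reduced to
Euclidean distance maps of their bone masks. Distance maps are insensitive to
contrast agents and soft-tissue change, and turn sparse bone into a smooth
field with long-range support, which is what makes block matching work at
coarse alignment.

**Block matching.** Blocks of 7³ voxels on a stride of 3 are matched by
normalized cross-correlation over all integer displacements within a search
radius (8 voxels at the coarsest pyramid level, 3 once roughly aligned). NCC
ties resolve to the smallest displacement magnitude, then lexicographic axis
order. The integer peak is refined to sub-voxel precision by a least-squares
quadratic fit on the surrounding 3×3×3 NCC values (accepted only when the
fitted Hessian is negative definite and the stationary point lies within one
voxel). A rigid transform is fitted to the block correspondences by Kabsch
with least-trimmed squares (worst 30% of residuals discarded, one re-fit),
and the procedure iterates — warp, re-match, re-fit — until the incremental
transform moves the rotation center less than 0.1 mm (max 10 iterations), over
a 2-level pyramid. A second stage repeats the matching restricted to blocks
inside a region of interest around the tumor (the synthetic cohort uses the
tumor bounding box padded by 20 mm). The rotation center is the centroid of
the pre-treatment bone mask.

**Block selection.** Distance maps are smooth and locally planar almost
everywhere, so a block sitting on a planar stretch constrains displacement
only along the distance gradient (the aperture problem); such blocks
contribute noise votes and, worse, inflate the residual-displacement
statistic the QC gate relies on. Besides a variance floor (10⁻³ mm²), blocks
are therefore required to have the smallest eigenvalue of their averaged
structure tensor ∑∇d∇dᵀ above 0.02 — only blocks that pin the displacement
down in all three directions vote. Up to 500 blocks are used per stage
(deterministically subsampled when more qualify).

**Quality gate.** Human visual review of each registration is replaced by an
automated proxy: accept iff bone Dice inside the ROI ≥ 0.5 AND the mean
residual block displacement after the final fit ≤ 2.5 mm. The Dice bound is
permissive by design (real cohorts show modest bone Dice even for acceptable
registrations because the statistic is sensitive to ROI size). The residual
bound was calibrated once on a mixed synthetic cohort — non-deformed patients
show 1.7–1.9 mm (residual NCC localization noise), deformed ones 3.3–4.1 mm —
and then frozen. On phantoms the gate separates the two classes exactly.

**Expected accuracy.** For rigid offsets up to 10 mm / 5° per axis on
non-deformed phantoms, the mapped-point error at the tumor is ≈ 0.2 mm and
the rotation error < 1°. Note that comparing raw translation vectors between
transforms with different rotation centers overstates the error; accuracy is
therefore measured as point error at the tumor center.

## Volumes and labeling

SUVmax is the single hottest voxel inside the delineated GTV (ties all count
at threshold 100%). MTV at t% is restricted to the GTV; hot voxels outside the
delineation are ignored. MTV₅₀₊₁₀ is the metric 10 mm dilation of MTV₅₀,
implemented through the exact Euclidean distance transform. Volumes are voxel
count × voxel volume / 1000 (mL); TLG₅₀ = mean SUV inside MTV₅₀ × its volume.
GTVfailure = GTV ∩ warped recurrent GTV (no clipping of the recurrent
delineation before intersection); GTVresponder is the set difference, so the
partition is exact by construction. An empty intersection raises a warning
flag rather than an error.

## Regional statistics

Histogram features use population variance (ddof 0), Fisher moment skewness
and excess kurtosis; a single-voxel or constant region has variance 0 and
undefined higher moments (flagged). The Wilcoxon signed-rank statistic is
W⁺ = sum of ranks of positive differences, zeros dropped before ranking
(Wilcoxon's original treatment), mid-ranks for ties. For n ≤ 15 informative
pairs the two-sided p value is exact, from full enumeration of the 2ⁿ sign
assignments conditional on the observed |differences| (so it remains exact
under ties); beyond that, a normal approximation with continuity correction
and tie-corrected variance ∑rᵢ²/4. No multiple-testing correction is applied
across the six features; the table reports the tests as-is. Fleiss's κ is
computed by statsmodels from an items × categories count table; κ is undefined
(raises) when every rating falls in one category.

A caution the test suite makes explicit: comparing failure vs responder is
*not* a calibrated null comparison even when recurrence placement is
uptake-independent, because the two regions differ in size (≈23% vs 77% of
the GTV) and extreme-value features depend on sample size — the minimum over
the larger region is stochastically smaller no matter where the recurrence
sits. Type-I calibration of the test itself is therefore checked under a
per-patient random role swap (a permutation null, exchangeable by
construction); a significant "minimum" row in the raw comparison should be
read with the size asymmetry in mind.

## Voxel features

22 features per GTV voxel, computed after isotropic resampling:

| group | features | notes |
|---|---|---|
| uptake | rel_suv | SUV / SUVmax of the GTV, in (0, 1] |
| geometry | dist_vmax, dist_vmin, dist_surface | mm; v_max/v_min are argextrema of the 26-neighborhood-averaged SUV (average restricted to the GTV, lexicographic tie-break); surface voxels are GTV voxels with a 6-neighbor outside |
| texture | energy, entropy, correlation, contrast, homogeneity, cluster shade, cluster prominence | from a 64-bin GLCM of the 5×5×5 patch around the voxel, clipped to the GTV, accumulated symmetrically over the 13 unique distance-1 offsets |
| filter | log_value | Laplacian of Gaussian, σ = 2 mm, per-mm² units, with the truncated-kernel constant-response bias subtracted so constants map to exactly 0 |
| position | pos_x, pos_y, pos_z | (voxel − GTV centroid) / bounding-box half-extent per axis |
| volumes | in_mtv50_plus10, mtv50_ml, tlg50 | membership flag; tumor-level scalars replicated per row |
| shape | sphericity, compactness, surface_to_volume | π^⅓(6V)^⅔/A, V/A^3/2, A/V with A from exposed voxel faces |
| clinical | site_code | integer coding: oropharynx 0, hypopharynx 1, oral cavity 2, larynx 3 |

Discretization for the GLCM is fixed-bin-number (64) over the [min, max] SUV
of the patient's GTV. "Local texture" is read as a per-voxel patch GLCM
(radius 2, offset distance 1); the offset distance is configurable for the
alternative reading. Patches with fewer than two in-GTV voxels yield no
co-occurrence pair; their texture features are imputed with the patient-wise
median and the imputation count is recorded on the table. A degenerate GLCM
marginal (σ = 0) makes correlation undefined; it is imputed as 0.

Haralick features of corresponding voxels are invariant to 90° grid rotations
(isotropic grid + symmetric accumulation over all 13 directions), which the
suite verifies to 10⁻⁹.

## Probability forest

scikit-learn's `RandomForestClassifier` (Gini criterion, bootstrap with
replacement, mtry = ⌊√p⌋, minimum node size 10 mapped to `min_samples_split`)
stands behind the module surface. The per-voxel probability is the fraction
of trees whose hard vote is "failure" (an averaged-leaf-probability mode is
available in config). Out-of-bag probabilities are computed per sample from
the trees that did not see it; the reported OOB error is defined as
1 − AUC(OOB probabilities, training labels) — an identity enforced by
construction — with the OOB Brier score logged alongside for transparency.
Importance is scikit-learn's mean decrease in impurity (normalized to sum 1;
rankings, which are what the elimination uses, are unaffected by the
normalization). Backward elimination retrains on the pooled cohort, drops the
single lowest-importance feature per step (importance recomputed each step),
and selects the remaining set at the first global OOB minimum. Pooled
selection leaks labels across leave-one-out folds; it is used because the
elimination is reported as a cohort-level description, and per-fold selection
can be run by calling `backward_eliminate` inside a fold loop. Class
imbalance (≈23% positives) is handled natively by the forest; no rebalancing.
Categorical tumor site enters as an integer code.

The production default is 10,000 trees; experiments and tests in this
repository run 500 trees with fixed seeds, which is past the point where AUC
and importance rankings stabilize at these sample sizes. A per-patient voxel
cap (seeded subsample of training voxels; evaluation always uses all held-out
voxels) keeps leave-one-out runs at desk scale; the pipeline default caps at
800 training voxels per patient (none in the library default).

## Synthetic cohort

The phantom emulates the *structure* the analysis depends on, not anatomy:

- 64×64×48 grid at 2 mm isotropic; bones (skull shell, spine discs, mandible
  arc, a small hyoid-like disc near the tumor) at 1000 HU on 40 HU soft
  tissue, so a 200 HU threshold recovers bone exactly on noiseless CT.
- Tumor: ellipsoid (~2000 voxels) with a center-peaked baseline profile
  (edge at 50% of the 8 SUV center) plus a stationary Gaussian random field
  (white noise smoothed at 6 mm correlation length, 1.5 SUV amplitude), plus
  0.2 SUV Gaussian acquisition noise truncated at zero, applied independently
  per time point.
- Recurrence: grown greedily (26-connected) from the best-scoring voxel until
  it covers 23% of the GTV, the score being signal_strength × (standardized
  smoothed SUV + standardized local texture energy) plus an infinitesimal
  random tie-break. signal_strength = 0 makes placement uptake-independent
  (up to a small inward-growth bias of ≈ +0.02 SUV in the mean, measured over
  100 seeds — compact blobs slightly favor the tumor interior); the default
  1.5 plants a learnable association.
- Post-treatment scene: responder uptake × 0.3, recurrence uptake × 1.2, then
  a rigid move (per-patient random, ≤ 5°, ≤ 8 mm by default). Deformity cases
  additionally shift the tumor and the hyoid-like bone by (8, 4, 0) mm between
  time points: a soft-tissue change carrying a nearby bone with it (as the
  tongue carries the hyoid), which is what makes the case detectable by a
  bone-based QC gate while still breaking the rigid correspondence at the
  tumor.
- Sites are drawn with probabilities 6:4:3:2 (oropharynx, hypopharynx, oral
  cavity, larynx); per-patient seeds, tumor positions and sizes fan out
  deterministically from the cohort seed.

**What passing tests on phantoms do and do not show.** They show the
machinery is correct: transforms are recovered when the rigid model holds,
planted signal is found (LOOCV median AUC ≥ 0.8 at signal_strength 1.5) and
absent signal is not (null cohorts give ≈ 0.5), the gate rejects exactly the
cases whose geometry breaks the rigid assumption, and every statistic matches
its independent oracle. They do not show that real recurrences are
predictable: the phantom's uptake–recurrence coupling is planted, its texture
is stationary Gaussian, there is no scanner point-spread function, no
partial-volume effect, no delineation variability, and its deformities are a
single stylized mode. Real-data performance is an empirical question the
synthetic cohort cannot answer.

## Numerical and degenerate-input policy

Empty GTV, empty distance-map source, two empty masks in Dice, all-zero
Wilcoxon differences, single-class training labels and single-category rating
tables raise immediately with descriptive messages. Ties are broken
deterministically everywhere (lexicographic voxel order; smallest
displacement; first minimum in the elimination trace). All randomness flows
from explicit seeds through SHA-256-derived sub-streams, so every pipeline
run, test and script is reproducible bit-for-bit; tabular outputs are written
with a fixed float format ("%.10g") to make byte-level comparison meaningful.

## Problem sizes used in this repository

Tests and the acceptance script run the default 64×64×48 phantom; cohorts of
15 (signal recovery, full pipeline), 26 (QC gate), 10 (null model), and 50
replicates of 10 (statistical calibration); forests of 40–500 trees with
per-patient voxel caps of 100–800. These sizes are where the measured
quantities plateau at this phantom scale; the production-scale defaults
(10,000 trees, no cap) are exposed in the same configs.
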