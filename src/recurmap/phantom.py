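"""Synthetic paired pre/post PET/CT head-and-neck phantoms with known ground truth.

Each phantom patient mimics the ingredients the analysis depends on, without
claiming anatomical realism:

* a CT with bright bony structures (skull shell, spine discs, a mandible arc
  and a small hyoid-like bone near the tumor) at >= 700 HU on soft tissue of
  ~40 HU, so a 200 HU threshold recovers bone exactly;
* a PET in SUV units with a heterogeneous tumor: an ellipsoidal baseline
  uptake profile plus a correlated Gaussian random field (smoothed white
  noise), plus independent acquisition noise truncated at zero;
* a planted recurrence sub-region covering a known fraction of the tumor
  (default 23% of the GTV), grown greedily from the hottest voxel on a score
  coupling local uptake and local texture energy — the structure the
  downstream classifier is supposed to learn.  With ``signal_strength = 0``
  the score is pure noise and placement is uptake-independent (a null cohort);
* a post-treatment scene in which responder tissue has regressed
  (multiplicative SUV decay), the recurrence kept its uptake, and the whole
  scene is moved by a known rigid transform;
* optional soft-tissue "deformity" cases: the tumor region and the hyoid-like
  bone shift relative to the rest of the skeleton between time points, the
  kind of anatomical change a rigid model cannot absorb and registration QC
  should reject.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._util import derive_seed
from .core import GridSpec, ImageVolume, Mask
from .registration import RigidTransform, apply_transform

__all__ = ["BoneGeometry", "TumorSpec", "PhantomSpec", "PhantomPatient", "generate_patient", "generate_cohort"]

SITES = ("oropharynx", "hypopharynx", "oral_cavity", "larynx")
# cohort mix of primary-tumor sites (oropharynx most common)
SITE_MIX = (6 / 15, 4 / 15, 3 / 15, 2 / 15)

SOFT_TISSUE_HU = 40.0
AIR_HU = -1000.0
BONE_HU_VALUE = 1000.0


@dataclass(frozen=True)
class BoneGeometry:
    """Centers/radii in mm, world coordinates."""

    skull_center: tuple[float, float, float] = (64.0, 64.0, 82.0)
    skull_radius: float = 38.0
    skull_thickness: float = 6.0
    spine_center_xy: tuple[float, float] = (64.0, 94.0)
    spine_radius: float = 7.0
    spine_top_z: float = 60.0
    mandible_center: tuple[float, float, float] = (64.0, 46.0, 52.0)
    mandible_radius: float = 26.0
    mandible_thickness: float = 5.0
    hyoid_center: tuple[float, float, float] = (64.0, 52.0, 34.0)
    hyoid_radius: float = 6.0
    hu_value: float = BONE_HU_VALUE


@dataclass(frozen=True)
class TumorSpec:
    center: tuple[float, float, float] = (52.0, 66.0, 36.0)
    semi_axes: tuple[float, float, float] = (18.0, 16.0, 13.0)  # mm
    baseline_suv: float = 8.0
    edge_fraction: float = 0.5  # SUV at the tumor edge relative to center
    texture_corr_mm: float = 6.0
    texture_amplitude: float = 1.5  # SUV (std of the correlated field)


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec((64, 64, 48), (2.0, 2.0, 2.0)))
    bones: BoneGeometry = field(default_factory=BoneGeometry)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    recurrence_fraction: float = 0.23
    signal_strength: float = 1.5
    rigid_offset: RigidTransform | None = None  # drawn from the seed when None
    responder_decay: float = 0.3
    recurrence_boost: float = 1.2
    deformity: bool = False
    deformity_shift_mm: tuple[float, float, float] = (8.0, 4.0, 0.0)
    noise_sd: float = 0.2
    background_suv: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.recurrence_fraction < 1.0:
            raise ValueError("recurrence_fraction must lie in (0, 1)")
        if any(a <= 0 for a in self.tumor.semi_axes):
            raise ValueError("tumor semi-axes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")


@dataclass
class PhantomPatient:
    patient_id: str
    spec: PhantomSpec
    pre_ct: ImageVolume
    pre_pet: ImageVolume
    post_ct: ImageVolume
    post_pet: ImageVolume
    gtv_pre: Mask
    gtv_recur_postspace: Mask
    true_transform: RigidTransform  # post-treatment space -> pre-treatment space
    true_failure: Mask  # in pre-treatment space
    site_label: str
    deformity: bool

    def registration_roi(self, pad_mm: float = 20.0) -> Mask:
        """Tumor bounding box plus a pad, the ROI of the fine registration pass."""
        idx = self.gtv_pre.indices()
        sp = np.asarray(self.gtv_pre.grid.spacing)
        pad = np.ceil(pad_mm / sp).astype(int)
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + pad + 1, self.gtv_pre.grid.shape)
        member = np.zeros(self.gtv_pre.grid.shape, bool)
        member[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] = True
        return Mask(grid=self.gtv_pre.grid, membership=member, label="registration_roi")


# ---------------------------------------------------------------------------
# scene rendering


def _grid_points(grid: GridSpec) -> np.ndarray:
    """(nx, ny, nz, 3) world coordinates of voxel centers."""
    axes = [
        grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _render_ct(points: np.ndarray, geom: BoneGeometry, grid: GridSpec,
               hyoid_shift: np.ndarray | None = None) -> np.ndarray:
    """Analytic CT scene at arbitrary world points (crisp bone edges)."""
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    cx, cy = extent[0] / 2, extent[1] / 2
    # body: elliptic cylinder of soft tissue
    body = ((x - cx) / (extent[0] * 0.45)) ** 2 + ((y - cy) / (extent[1] * 0.42)) ** 2 <= 1.0
    hu = np.where(body, SOFT_TISSUE_HU, AIR_HU)

    sk = np.asarray(geom.skull_center)
    r = np.sqrt((x - sk[0]) ** 2 + (y - sk[1]) ** 2 + (z - sk[2]) ** 2)
    skull = (np.abs(r - geom.skull_radius) <= geom.skull_thickness / 2) & (z >= sk[2] - 10)

    sx, sy = geom.spine_center_xy
    spine = ((x - sx) ** 2 + (y - sy) ** 2 <= geom.spine_radius**2) & (z <= geom.spine_top_z)

    mc = np.asarray(geom.mandible_center)
    rho = np.sqrt((x - mc[0]) ** 2 + (y - mc[1]) ** 2)
    mandible = (
        (np.abs(rho - geom.mandible_radius) <= geom.mandible_thickness / 2)
        & (np.abs(z - mc[2]) <= geom.mandible_thickness)
        & (y <= mc[1] + geom.mandible_radius * 0.6)
    )

    hc = np.asarray(geom.hyoid_center, dtype=float)
    if hyoid_shift is not None:
        hc = hc + hyoid_shift
    hyoid = (x - hc[0]) ** 2 + (y - hc[1]) ** 2 + (z - hc[2]) ** 2 <= geom.hyoid_radius**2

    hu[skull | spine | mandible | hyoid] = geom.hu_value
    return hu


def _tumor_profile(points: np.ndarray, tumor: TumorSpec) -> tuple[np.ndarray, np.ndarray]:
    """(gtv bool field, baseline uptake field) at the given points."""
    c = np.asarray(tumor.center)
    a = np.asarray(tumor.semi_axes)
    rho2 = (((points - c) / a) ** 2).sum(axis=-1)
    gtv = rho2 <= 1.0
    profile = tumor.baseline_suv * (1.0 - (1.0 - tumor.edge_fraction) * np.clip(rho2, 0, 1))
    return gtv, np.where(gtv, profile, 0.0)


def _correlated_field(grid: GridSpec, corr_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary Gaussian random field (smoothed white noise)."""
    white = rng.standard_normal(grid.shape)
    sigma_vox = np.asarray([corr_mm / s for s in grid.spacing])
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    return (f - f.mean()) / f.std()


def _grow_failure(
    score: np.ndarray, gtv: np.ndarray, target_count: int
) -> np.ndarray:
    """Greedy 26-connected region growth from the best-scoring voxel."""
    shape = score.shape
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    inside = np.zeros(shape, bool)
    seen = np.zeros(shape, bool)
    seed_idx = np.unravel_index(np.argmax(np.where(gtv, score, -np.inf)), shape)
    heap: list[tuple[float, tuple[int, int, int]]] = [(-score[seed_idx], seed_idx)]
    seen[seed_idx] = True
    count = 0
    while heap and count < target_count:
        _, idx = heapq.heappop(heap)
        inside[idx] = True
        count += 1
        for di, dj, dk in offsets:
            n = (idx[0] + di, idx[1] + dj, idx[2] + dk)
            if (
                0 <= n[0] < shape[0]
                and 0 <= n[1] < shape[1]
                and 0 <= n[2] < shape[2]
                and gtv[n]
                and not seen[n]
            ):
                seen[n] = True
                heapq.heappush(heap, (-score[n], n))
    return inside


def _standardize(values: np.ndarray, where: np.ndarray) -> np.ndarray:
    v = values[where]
    sd = v.std()
    return (values - v.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------


def generate_patient(spec: PhantomSpec, patient_id: str = "P00") -> PhantomPatient:
    """Render one paired pre/post phantom with known ground truth."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    pts = _grid_points(grid)

    # --- pre-treatment scene
    pre_ct_vals = _render_ct(pts, spec.bones, grid)
    gtv_arr, profile = _tumor_profile(pts, spec.tumor)
    n_gtv = int(gtv_arr.sum())
    if n_gtv == 0:
        raise ValueError("tumor ellipsoid contains no voxels on this grid")
    texture = _correlated_field(grid, spec.tumor.texture_corr_mm, rng)
    tumor_clean = np.where(gtv_arr, np.clip(profile + spec.tumor.texture_amplitude * texture, 0.2, None), 0.0)

    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    cx, cy = extent[0] / 2, extent[1] / 2
    body = (
        ((pts[..., 0] - cx) / (extent[0] * 0.45)) ** 2
        + ((pts[..., 1] - cy) / (extent[1] * 0.42)) ** 2
        <= 1.0
    )
    background = np.where(body, spec.background_suv, 0.05)
    pre_pet_clean = np.where(gtv_arr, tumor_clean, background)

    # --- plant the recurrence sub-region
    target = int(round(spec.recurrence_fraction * n_gtv))
    if target < 1:
        raise ValueError("recurrence_fraction yields fewer than one voxel for this tumor")
    smooth_suv = ndimage.gaussian_filter(pre_pet_clean, sigma=1.0)
    resid = pre_pet_clean - ndimage.gaussian_filter(pre_pet_clean, sigma=2.0)
    tex_energy = ndimage.gaussian_filter(resid**2, sigma=2.0)
    score = spec.signal_strength * (
        _standardize(smooth_suv, gtv_arr) + _standardize(tex_energy, gtv_arr)
    )
    score = score + 1e-6 * rng.random(grid.shape)  # uptake-independent tie-break
    failure_arr = _grow_failure(score, gtv_arr, target)

    # --- post-treatment scene in pre-treatment coordinates
    responder_arr = gtv_arr & ~failure_arr
    tumor_post = np.where(
        failure_arr,
        tumor_clean * spec.recurrence_boost,
        np.where(responder_arr, tumor_clean * spec.responder_decay, 0.0),
    )
    recur_arr = failure_arr.copy()
    hyoid_shift = None
    if spec.deformity:
        shift_vox = np.round(
            np.asarray(spec.deformity_shift_mm) / np.asarray(grid.spacing)
        ).astype(int)
        tumor_post = np.roll(tumor_post, shift_vox, axis=(0, 1, 2))
        recur_arr = np.roll(recur_arr, shift_vox, axis=(0, 1, 2))
        hyoid_shift = np.asarray(spec.deformity_shift_mm)
    post_pet_prespace = np.where(tumor_post > 0, tumor_post, background)

    # --- rigid motion between time points
    t = spec.rigid_offset
    if t is None:
        angles = rng.uniform(-5.0, 5.0, size=3)
        trans = rng.uniform(-8.0, 8.0, size=3)
        t = RigidTransform.from_euler(tuple(angles), tuple(trans), center=tuple(extent / 2))
    post_pts = t.apply_points(pts.reshape(-1, 3)).reshape(pts.shape)
    post_ct_vals = _render_ct(post_pts, spec.bones, grid, hyoid_shift=hyoid_shift)

    pet_vol_prespace = ImageVolume(grid=grid, values=post_pet_prespace, modality="PET_SUV")
    post_pet_vol = apply_transform(t.inverse(), pet_vol_prespace, grid, cval=0.05)
    recur_mask_pre = Mask(grid=grid, membership=recur_arr, label="gtv_recur")
    gtv_recur_post = apply_transform(t.inverse(), recur_mask_pre, grid)

    # --- acquisition noise (PET only), independent draws per time point
    pre_pet_vals = np.clip(pre_pet_clean + spec.noise_sd * rng.standard_normal(grid.shape), 0, None)
    post_pet_vals = np.clip(
        post_pet_vol.values + spec.noise_sd * rng.standard_normal(grid.shape), 0, None
    )

    site = rng.choice(len(SITES), p=SITE_MIX)

    return PhantomPatient(
        patient_id=patient_id,
        spec=spec,
        pre_ct=ImageVolume(grid=grid, values=pre_ct_vals, modality="CT_HU"),
        pre_pet=ImageVolume(grid=grid, values=pre_pet_vals, modality="PET_SUV"),
        post_ct=ImageVolume(grid=grid, values=post_ct_vals, modality="CT_HU"),
        post_pet=ImageVolume(grid=grid, values=post_pet_vals, modality="PET_SUV"),
        gtv_pre=Mask(grid=grid, membership=gtv_arr, label="gtv_pre"),
        gtv_recur_postspace=Mask(grid=grid, membership=gtv_recur_post.membership, label="gtv_recur"),
        true_transform=t,
        true_failure=Mask(grid=grid, membership=failure_arr, label="true_failure"),
        site_label=SITES[site],
        deformity=spec.deformity,
    )


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    deformity_rate: float = 0.0,
) -> list[PhantomPatient]:
    """Generate ``n`` phantom patients with per-patient seeds fanned out from the base seed.

    ``round(n * deformity_rate)`` patients (chosen deterministically from the
    base seed) are rendered with a soft-tissue deformity and flagged as such.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients (leave-one-out)")
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(derive_seed(base_spec.seed, "cohort"))
    n_deformed = int(round(n * deformity_rate))
    deformed = np.zeros(n, bool)
    if n_deformed:
        deformed[rng.choice(n, size=n_deformed, replace=False)] = True
    patients = []
    for i in range(n):
        jitter = np.random.default_rng(derive_seed(base_spec.seed, "tumor", i))
        center = np.asarray(base_spec.tumor.center) + jitter.uniform(-4, 4, 3)
        axes = np.asarray(base_spec.tumor.semi_axes) * jitter.uniform(0.85, 1.15, 3)
        tumor = replace(base_spec.tumor, center=tuple(center), semi_axes=tuple(axes))
        spec = replace(
            base_spec,
            seed=derive_seed(base_spec.seed, "patient", i),
            tumor=tumor,
            deformity=bool(deformed[i]),
        )
        patients.append(generate_patient(spec, patient_id=f"P{i:02d}"))
    return patients
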