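"""Per-voxel radiomics features of the pre-treatment PET inside the GTV.

Each GTV voxel is described by 22 features mixing local, positional and
tumor-level information:

* relative SUV (SUV / SUVmax of the GTV);
* Euclidean distances (mm) to the hottest and coldest voxels (26-neighborhood
  averaged SUV) and to the tumor surface;
* seven Haralick statistics (energy, entropy, correlation, contrast,
  homogeneity, cluster shade, cluster prominence) of a grey-level
  co-occurrence matrix with 64 fixed bins over the GTV SUV range, accumulated
  symmetrically over the 13 unique distance-1 3D offsets inside a radius-2
  (5x5x5) patch clipped to the GTV;
* the Laplacian-of-Gaussian response;
* the voxel position in a normalized tumor frame;
* membership of the 10 mm-expanded half-maximum metabolic volume;
* tumor-level descriptors replicated on every row: sphericity, compactness,
  surface-to-volume ratio, MTV_50 volume (mL), TLG_50, and a tumor-site code.

PET is resampled to an isotropic grid before any texture computation so that
co-occurrence offsets are rotation-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    ImageVolume,
    Mask,
    euclidean_distance_map,
    resample_isotropic,
    resample_mask_to,
)
from .labeling import RecurrencePartition, TumorVolumes, compute_tumor_volumes

__all__ = [
    "FeatureConfig",
    "GLCMMatrix",
    "FEATURE_NAMES",
    "SITE_CODES",
    "find_landmarks",
    "discretize",
    "local_glcm",
    "haralick_features",
    "log_filter",
    "shape_descriptors",
    "extract_table",
]

FEATURE_NAMES = (
    "rel_suv",
    "dist_vmax",
    "dist_vmin",
    "dist_surface",
    "haralick_energy",
    "haralick_entropy",
    "haralick_correlation",
    "haralick_contrast",
    "haralick_homogeneity",
    "cluster_shade",
    "cluster_prominence",
    "log_value",
    "pos_x",
    "pos_y",
    "pos_z",
    "in_mtv50_plus10",
    "sphericity",
    "compactness",
    "surface_to_volume",
    "mtv50_ml",
    "tlg50",
    "site_code",
)

HARALICK_NAMES = FEATURE_NAMES[4:11]

SITE_CODES = {"oropharynx": 0, "hypopharynx": 1, "oral_cavity": 2, "larynx": 3}

# the 13 unique 3D neighbor directions at Chebyshev distance 1
OFFSETS_13 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) > (0, 0, 0)
]


@dataclass
class FeatureConfig:
    """Knobs of the extraction; defaults match the production pipeline."""

    n_bins: int = 64
    glcm_radius: int = 2  # patch half-width in voxels
    glcm_offset_distance: int = 1  # co-occurrence offset length (voxels)
    log_sigma_mm: float = 2.0
    target_spacing_mm: float | None = None  # None: minimum input spacing


@dataclass
class GLCMMatrix:
    """Normalized grey-level co-occurrence matrix and its marginal moments."""

    p: np.ndarray  # (n_bins, n_bins), sums to 1
    bin_edges: np.ndarray  # (n_bins + 1,) SUV

    @property
    def mu_x(self) -> float:
        i = np.arange(self.p.shape[0])
        return float((self.p.sum(axis=1) * i).sum())

    @property
    def mu_y(self) -> float:
        j = np.arange(self.p.shape[1])
        return float((self.p.sum(axis=0) * j).sum())


def find_landmarks(pet: ImageVolume, gtv: Mask) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Indices of the hottest (vMax) and coldest (vMin) GTV voxels.

    Hot/cold is judged on the SUV averaged over the voxel and its 26 neighbors,
    the average being restricted to GTV voxels; ties resolve to the
    lexicographically smallest index.
    """
    if gtv.count == 0:
        raise ValueError("empty GTV")
    m = gtv.membership.astype(float)
    num = ndimage.uniform_filter(pet.values * m, size=3, mode="constant") * 27.0
    den = ndimage.uniform_filter(m, size=3, mode="constant") * 27.0
    smoothed = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    hot = np.where(gtv.membership, smoothed, -np.inf)
    cold = np.where(gtv.membership, smoothed, np.inf)
    vmax = np.unravel_index(int(np.argmax(hot)), hot.shape)
    vmin = np.unravel_index(int(np.argmin(cold)), cold.shape)
    return tuple(int(i) for i in vmax), tuple(int(i) for i in vmin)


def discretize(pet: ImageVolume, gtv: Mask, n_bins: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bin-number discretization over the [min, max] SUV of the GTV.

    Returns (integer level volume with levels 0..n_bins-1 inside the value
    range, bin edges).  Values outside the GTV are binned with the same edges.
    """
    vals = pet.values[gtv.membership]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    levels = np.clip(((pet.values - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    return levels, edges


def _patch_pairs(
    levels: np.ndarray,
    valid: np.ndarray,
    center: tuple[int, int, int],
    radius: int,
    offset_distance: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Co-occurring level pairs (both endpoints inside patch ∩ GTV), unsymmetrized."""
    lo = [max(0, c - radius) for c in center]
    hi = [min(s, c + radius + 1) for c, s in zip(center, levels.shape)]
    patch = levels[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
    pmask = valid[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
    a_list, b_list = [], []
    d = offset_distance
    for off in OFFSETS_13:
        oi, oj, ok = (o * d for o in off)
        sl_a = tuple(
            slice(max(0, -o), patch.shape[ax] - max(0, o))
            for ax, o in enumerate((oi, oj, ok))
        )
        sl_b = tuple(
            slice(max(0, o), patch.shape[ax] - max(0, -o))
            for ax, o in enumerate((oi, oj, ok))
        )
        ok_pair = pmask[sl_a] & pmask[sl_b]
        if ok_pair.any():
            a_list.append(patch[sl_a][ok_pair])
            b_list.append(patch[sl_b][ok_pair])
    if not a_list:
        return np.empty(0, int), np.empty(0, int)
    return np.concatenate(a_list), np.concatenate(b_list)


def local_glcm(
    levels: np.ndarray,
    valid: np.ndarray,
    center: tuple[int, int, int],
    bin_edges: np.ndarray,
    radius: int = 2,
    offset_distance: int = 1,
) -> GLCMMatrix:
    """Symmetrized, normalized GLCM of the radius-``radius`` patch at ``center``.

    ``valid`` restricts both endpoints of every co-occurrence pair to the GTV.
    Raises when the patch holds fewer than two valid voxels (no pairs).
    """
    n_bins = len(bin_edges) - 1
    a, b = _patch_pairs(levels, valid, center, radius, offset_distance)
    if a.size == 0:
        raise ValueError("patch has no valid co-occurrence pairs")
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)
    return GLCMMatrix(p=counts / counts.sum(), bin_edges=np.asarray(bin_edges, float))


def _haralick_from_pairs(i: np.ndarray, j: np.ndarray, p: np.ndarray) -> np.ndarray:
    """The 7 Haralick statistics from the sparse entries of a normalized GLCM."""
    mu_x = float((i * p).sum())
    mu_y = float((j * p).sum())
    sig_x = np.sqrt(float(((i - mu_x) ** 2 * p).sum()))
    sig_y = np.sqrt(float(((j - mu_y) ** 2 * p).sum()))
    energy = float((p**2).sum())
    entropy = float(-(p * np.log2(p, where=p > 0, out=np.zeros_like(p))).sum())
    if sig_x > 0 and sig_y > 0:
        correlation = float(((i - mu_x) * (j - mu_y) * p).sum() / (sig_x * sig_y))
    else:
        correlation = 0.0  # degenerate marginals: flagged undefined, imputed 0
    d2 = (i - j) ** 2
    contrast = float((d2 * p).sum())
    homogeneity = float((p / (1.0 + d2)).sum())
    s = i + j - mu_x - mu_y
    shade = float((s**3 * p).sum())
    prominence = float((s**4 * p).sum())
    return np.array([energy, entropy, correlation, contrast, homogeneity, shade, prominence])


def haralick_features(glcm: GLCMMatrix) -> np.ndarray:
    """Energy, entropy, correlation, contrast, homogeneity, cluster shade,
    cluster prominence of a normalized GLCM (in that order)."""
    nz = np.nonzero(glcm.p)
    return _haralick_from_pairs(nz[0].astype(float), nz[1].astype(float), glcm.p[nz])


def log_filter(pet: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Laplacian of Gaussian at a physical scale.

    Sign convention: an isolated hot spot gives a negative response at its
    center (plain Laplacian of the smoothed image, no sign flip).
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = [sigma_mm / s for s in pet.grid.spacing]
    out = ndimage.gaussian_laplace(pet.values, sigma=sigma_vox, mode="nearest")
    # discrete-kernel bias correction: the truncated LoG kernel does not sum
    # exactly to zero, so subtract the response it gives to a constant field
    bias = ndimage.gaussian_laplace(np.ones_like(pet.values), sigma=sigma_vox, mode="nearest")
    out = out - pet.values * bias
    # gaussian_laplace works in voxel units; rescale to per-mm^2 for an
    # isotropic grid (uniform spacing assumed after resampling)
    out = out / (pet.grid.spacing[0] ** 2)
    return ImageVolume(grid=pet.grid, values=out, modality="CT_HU")


def shape_descriptors(gtv: Mask) -> tuple[float, float, float, np.ndarray]:
    """(sphericity, compactness, surface_to_volume, surface-voxel bool array).

    Surface area is estimated from exposed voxel faces; sphericity is
    pi^(1/3) (6V)^(2/3) / A, compactness V / A^(3/2), both dimensionless only
    up to the voxel metric — conventions fixed here once for the pipeline.
    """
    m = gtv.membership
    sp = gtv.grid.spacing
    nvox = int(m.sum())
    volume = nvox * gtv.grid.voxel_volume_mm3
    area = 0.0
    face_areas = (sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1])
    for ax, fa in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += float(np.abs(diff).sum()) * fa
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1))
    surface_voxels = m & ~eroded
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    compactness = float(volume / area ** 1.5)
    return sphericity, compactness, float(area / volume), surface_voxels


def extract_table(
    pet: ImageVolume,
    gtv: Mask,
    partition: RecurrencePartition | None = None,
    site: str = "oropharynx",
    patient_id: str = "P00",
    config: FeatureConfig | None = None,
    volumes: TumorVolumes | None = None,
) -> pd.DataFrame:
    """One row per GTV voxel with the 22 features (plus bookkeeping columns).

    Resamples PET and masks to an isotropic grid first.  Rows carry the voxel
    index on that grid (``i, j, k``), the patient id, and — when a
    failure/responder partition is given — the binary ``label`` column.
    Texture features of voxels whose patch has no valid co-occurrence pair are
    imputed with the patient-wise median; ``n_imputed`` is recorded in
    ``df.attrs``.
    """
    cfg = config or FeatureConfig()
    if not pet.grid.is_compatible(gtv.grid):
        raise ValueError("PET and GTV grids differ")
    target = cfg.target_spacing_mm or min(pet.grid.spacing)
    iso_needed = not np.allclose(pet.grid.spacing, target)
    if iso_needed:
        pet = resample_isotropic(pet, target)
        gtv = resample_mask_to(gtv, pet.grid)
    if gtv.count == 0:
        raise ValueError("empty GTV after resampling")
    if volumes is None or iso_needed:
        volumes = compute_tumor_volumes(pet, gtv)
    if partition is not None and not partition.gtv_failure.grid.is_compatible(pet.grid):
        partition = RecurrencePartition(
            gtv_failure=resample_mask_to(partition.gtv_failure, pet.grid),
            gtv_responder=resample_mask_to(partition.gtv_responder, pet.grid),
        )

    idx = gtv.indices()
    n = len(idx)
    suv = pet.values[tuple(idx.T)]
    suv_max = float(suv.max())
    rel_suv = suv / suv_max

    vmax, vmin = find_landmarks(pet, gtv)
    world = pet.grid.world_coordinates(idx)
    dist_vmax = np.linalg.norm(world - pet.grid.world_coordinates(np.array([vmax])), axis=1)
    dist_vmin = np.linalg.norm(world - pet.grid.world_coordinates(np.array([vmin])), axis=1)

    sphericity, compactness, s2v, surface_voxels = shape_descriptors(gtv)
    surf_dist = euclidean_distance_map(
        Mask(grid=pet.grid, membership=surface_voxels, label="surface")
    ).distance
    dist_surface = surf_dist[tuple(idx.T)]

    levels, edges = discretize(pet, gtv, cfg.n_bins)
    texture = np.empty((n, 7))
    imputed = np.zeros(n, bool)
    valid = gtv.membership
    for r, c in enumerate(idx):
        a, b = _patch_pairs(levels, valid, tuple(c), cfg.glcm_radius, cfg.glcm_offset_distance)
        if a.size == 0:
            imputed[r] = True
            continue
        ab = np.concatenate([a, b]).astype(float)
        ba = np.concatenate([b, a]).astype(float)
        key = ab * cfg.n_bins + ba
        uniq, counts = np.unique(key, return_counts=True)
        p = counts / counts.sum()
        texture[r] = _haralick_from_pairs(uniq // cfg.n_bins, uniq % cfg.n_bins, p)
    if imputed.any():
        med = np.median(texture[~imputed], axis=0)
        texture[imputed] = med

    log_vals = log_filter(pet, cfg.log_sigma_mm).values[tuple(idx.T)]

    centroid = world.mean(axis=0)
    half_extent = np.maximum((world.max(axis=0) - world.min(axis=0)) / 2.0, 1e-6)
    pos = (world - centroid) / half_extent

    in_m50p10 = volumes.mtv50_plus10.membership[tuple(idx.T)].astype(float)

    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "i": idx[:, 0],
            "j": idx[:, 1],
            "k": idx[:, 2],
            "rel_suv": rel_suv,
            "dist_vmax": dist_vmax,
            "dist_vmin": dist_vmin,
            "dist_surface": dist_surface,
            "haralick_energy": texture[:, 0],
            "haralick_entropy": texture[:, 1],
            "haralick_correlation": texture[:, 2],
            "haralick_contrast": texture[:, 3],
            "haralick_homogeneity": texture[:, 4],
            "cluster_shade": texture[:, 5],
            "cluster_prominence": texture[:, 6],
            "log_value": log_vals,
            "pos_x": pos[:, 0],
            "pos_y": pos[:, 1],
            "pos_z": pos[:, 2],
            "in_mtv50_plus10": in_m50p10,
            "sphericity": sphericity,
            "compactness": compactness,
            "surface_to_volume": s2v,
            "mtv50_ml": volumes.mtv50_volume_ml,
            "tlg50": volumes.tlg50,
            "site_code": float(SITE_CODES[site]),
        }
    )
    if partition is not None:
        df["label"] = partition.gtv_failure.membership[tuple(idx.T)].astype(int)
    df.attrs["n_imputed"] = int(imputed.sum())
    df.attrs["iso_spacing_mm"] = float(target)
    return df
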