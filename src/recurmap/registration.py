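"""Rigid alignment of post-treatment to pre-treatment CT by block matching.

Head-and-neck anatomy changes substantially over a course of chemoradiotherapy
(weight loss, tumor regression, contrast agents), so intensity-based rigid
registration of the raw CT is unreliable.  Instead, bone is segmented by
thresholding CT at 200 HU, Euclidean distance maps are computed from the bone
masks, and block matching is run on the distance maps: smooth, monotone fields
whose local structure encodes the position of the nearest bone and is invariant
to soft-tissue and contrast changes.

A global pass aligns the whole head; a second pass restricted to a region of
interest around the tumor refines the transform where it matters.  An automated
quality gate (bone Dice inside the ROI plus the residual block displacement
after the rigid fit) stands in for expert visual review and excludes patients
whose anatomy changed too much for a rigid model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .core import (
    GridSpec,
    ImageVolume,
    Mask,
    dice_score,
    euclidean_distance_map,
    resample_grid,
    threshold_mask,
)

__all__ = [
    "RigidTransform",
    "BlockMatchConfig",
    "QCThresholds",
    "RegistrationResult",
    "register_pair",
    "apply_transform",
    "qc_gate",
]

BONE_HU = 200.0


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about a center plus translation: x -> R (x - c) + c + t (mm).

    Used throughout with the convention that the transform maps post-treatment
    world coordinates into pre-treatment world coordinates.
    """

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (determinant +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))

    @classmethod
    def identity(cls, center: np.ndarray | tuple = (0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, float))

    @classmethod
    def from_euler(
        cls,
        angles_deg: tuple[float, float, float],
        translation_mm: tuple[float, float, float],
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Build from intrinsic x-y-z Euler angles in degrees."""
        ax, ay, az = np.deg2rad(angles_deg)
        rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
        ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
        rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
        return cls(rz @ ry @ rx, np.asarray(translation_mm, float), np.asarray(center, float))

    def euler_angles_deg(self) -> np.ndarray:
        """Recover intrinsic x-y-z Euler angles (degrees) from the matrix."""
        r = self.rotation
        ay = np.arcsin(np.clip(-r[2, 0], -1.0, 1.0))
        ax = np.arctan2(r[2, 1], r[2, 2])
        az = np.arctan2(r[1, 0], r[0, 0])
        return np.rad2deg(np.array([ax, ay, az]))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return (pts - self.center) @ self.rotation.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        # x' = R(x-c)+c+t  =>  x = R^T(x'-c)+c - R^T t
        return RigidTransform(rinv, -rinv @ self.translation, self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        # self(other(x)) = R1 R2 (x - c2) + R1 (c2 + t2 - c1) + c1 + t1
        r = self.rotation @ other.rotation
        new_center = other.center
        offset = (
            self.rotation @ (other.center + other.translation - self.center)
            + self.center
            + self.translation
        )
        # want R (x - c2) + c2 + t_new == R (x - c2) + offset
        t = offset - other.center
        return RigidTransform(r, t, new_center)

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix acting on world coordinates."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation + self.center - self.rotation @ self.center
        return m

    def parameter_distance(self, other: "RigidTransform", lever_mm: float = 100.0) -> float:
        """Scalar magnitude of the difference, in mm (rotation via a lever arm)."""
        dm = self.as_matrix() @ np.linalg.inv(other.as_matrix())
        dt = np.linalg.norm(dm[:3, 3] + (dm[:3, :3] - np.eye(3)) @ self.center)
        ang = np.arccos(np.clip((np.trace(dm[:3, :3]) - 1) / 2, -1.0, 1.0))
        return float(dt + lever_mm * ang)


@dataclass
class BlockMatchConfig:
    """Tunables of the block-matching registration (voxel units unless noted)."""

    block_size: int = 7
    search_radius: int = 8  # used at the coarsest pyramid level
    fine_search_radius: int = 3  # once roughly aligned, search stays local
    block_stride: int = 3
    trim_fraction: float = 0.3
    pyramid_levels: int = 2
    max_iterations: int = 10
    convergence_tol: float = 0.1  # mm
    variance_floor: float = 1e-3  # mm^2; skip blocks with near-constant distance
    structure_floor: float = 0.02  # min eigenvalue of the block structure tensor;
    # rejects blocks whose distance field is locally planar (aperture ambiguity)
    max_blocks: int = 500

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if not 0 <= self.trim_fraction <= 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5]")


@dataclass
class QCThresholds:
    """Automated registration quality gate, calibrated once on phantoms and frozen."""

    dice_min: float = 0.5
    resid_max: float = 2.5  # mm, mean residual block displacement in the ROI


@dataclass
class RegistrationResult:
    transform: RigidTransform
    bone_dice: float
    qc_pass: bool
    mean_residual_mm: float
    max_residual_mm: float
    n_blocks: int


# ---------------------------------------------------------------------------


def apply_transform(
    t: RigidTransform,
    moving: ImageVolume | Mask,
    reference: GridSpec,
    interpolation: str | None = None,
    cval: float | None = None,
) -> ImageVolume | Mask:
    """Resample moving data onto ``reference`` through ``t`` (moving -> reference space).

    Each reference voxel center x is filled with the moving data sampled at
    t^-1(x).  Masks always use nearest-neighbor.
    """
    tinv = t.inverse()
    # reference index -> world -> moving world -> moving index
    sp_ref = np.asarray(reference.spacing)
    sp_mov = np.asarray(moving.grid.spacing)
    a = tinv.rotation @ np.diag(sp_ref)
    b = tinv.apply_points(np.asarray(reference.origin))
    # moving index = (A @ ref_index + b - mov_origin) / mov_spacing
    matrix = a / sp_mov[:, None]
    offset = (b - np.asarray(moving.grid.origin)) / sp_mov

    if isinstance(moving, Mask):
        out = ndimage.affine_transform(
            moving.membership.astype(np.float64), matrix, offset=offset,
            output_shape=reference.shape, order=0, mode="constant", cval=0.0,
        )
        return Mask(grid=reference, membership=out > 0.5, label=moving.label)
    order = 0 if interpolation == "nearest" else 1
    fill = float(np.min(moving.values)) if cval is None else float(cval)
    out = ndimage.affine_transform(
        moving.values, matrix, offset=offset,
        output_shape=reference.shape, order=order, mode="constant",
        cval=fill,
    )
    return ImageVolume(grid=reference, values=out, modality=moving.modality)


def _fit_rigid(src: np.ndarray, dst: np.ndarray, center: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src points onto dst (Kabsch)."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # dst ≈ R (src - sc) + dc  =>  rewrite about the requested center
    t = dc - (r @ (sc - center)) - center
    return RigidTransform(r, t, center)


def _fit_rigid_trimmed(
    src: np.ndarray, dst: np.ndarray, center: np.ndarray, trim_fraction: float
) -> RigidTransform:
    """Rigid fit with least-trimmed-squares: fit, drop worst residuals, re-fit."""
    t = _fit_rigid(src, dst, center)
    if trim_fraction > 0 and len(src) >= 8:
        resid = np.linalg.norm(t.apply_points(src) - dst, axis=1)
        keep = int(np.ceil(len(src) * (1.0 - trim_fraction)))
        order = np.argsort(resid, kind="stable")[:keep]
        t = _fit_rigid(src[order], dst[order], center)
    return t


def _block_centers(
    shape: tuple[int, int, int],
    half: int,
    search: int,
    stride: int,
    roi: np.ndarray | None,
) -> np.ndarray:
    lo = half + search
    axes = [np.arange(lo, s - lo, stride) for s in shape]
    if any(len(a) == 0 for a in axes):
        return np.empty((0, 3), dtype=int)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if roi is not None:
        keep = roi[grid[:, 0], grid[:, 1], grid[:, 2]]
        grid = grid[keep]
    return grid


def _quad_design(offsets: np.ndarray) -> np.ndarray:
    x, y, z = offsets.T
    return np.column_stack(
        [np.ones(len(offsets)), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z]
    )


# pseudo-inverse of the quadratic design over the 3x3x3 offset stencil
_QUAD_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
)
_QUAD_PINV = np.linalg.pinv(_quad_design(_QUAD_OFFSETS))


def _quadratic_peak(neigh: np.ndarray) -> np.ndarray:
    """Subvoxel offsets of the NCC maximum from its 3x3x3 neighborhoods.

    ``neigh`` is (n, 27) in the offset order of ``_QUAD_OFFSETS``.  Falls back
    to the integer peak (zero offset) when the fitted quadratic has no interior
    maximum within one voxel.
    """
    coef = neigh @ _QUAD_PINV.T  # (n, 10)
    b = coef[:, 1:4]
    h = np.empty((len(coef), 3, 3))
    h[:, 0, 0] = 2 * coef[:, 4]
    h[:, 1, 1] = 2 * coef[:, 5]
    h[:, 2, 2] = 2 * coef[:, 6]
    h[:, 0, 1] = h[:, 1, 0] = coef[:, 7]
    h[:, 0, 2] = h[:, 2, 0] = coef[:, 8]
    h[:, 1, 2] = h[:, 2, 1] = coef[:, 9]
    out = np.zeros_like(b)
    det = np.linalg.det(h)
    solvable = np.abs(det) > 1e-12
    if solvable.any():
        sol = np.linalg.solve(h[solvable], -b[solvable][..., None])[..., 0]
        ok = np.all(np.abs(sol) <= 1.0, axis=1)
        # require a maximum: negative-definite Hessian (all eigenvalues < 0)
        eig = np.linalg.eigvalsh(h[solvable])
        ok &= np.all(eig < 0, axis=1)
        idx = np.flatnonzero(solvable)[ok]
        out[idx] = sol[ok]
    return out


def _gather_blocks(windows: np.ndarray, corners: np.ndarray) -> np.ndarray:
    return windows[corners[:, 0], corners[:, 1], corners[:, 2]].reshape(len(corners), -1)


def _match_blocks(
    fixed: np.ndarray,
    moving: np.ndarray,
    centers: np.ndarray,
    r: int,
    cfg: BlockMatchConfig,
    spacing: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block displacement (mm, world) maximizing NCC, subvoxel refined.

    NCC is evaluated for every integer displacement within radius ``r`` (all
    blocks batched per displacement); ties resolve to the smallest displacement
    magnitude, then lexicographic axis order; the integer peak is refined with
    a 3D quadratic fit on the surrounding 3x3x3 NCC values.

    Returns (kept centers (n,3) voxel indices, displacements (n,3) mm).
    """
    half = cfg.block_size // 2
    bs = cfg.block_size
    windows = sliding_window_view(moving, (bs, bs, bs))
    f = _gather_blocks(sliding_window_view(fixed, (bs, bs, bs)), centers - half)
    keep = f.var(axis=1) >= cfg.variance_floor
    centers = centers[keep]
    f = f[keep]
    if len(centers) == 0:
        return np.empty((0, 3), int), np.empty((0, 3))
    fc = f - f.mean(axis=1, keepdims=True)
    fn = np.linalg.norm(fc, axis=1)

    side = 2 * r + 1
    disp_axis = np.arange(-r, r + 1)
    ncc = np.empty((len(centers), side, side, side))
    for a, di in enumerate(disp_axis):
        for b, dj in enumerate(disp_axis):
            for c, dk in enumerate(disp_axis):
                m = _gather_blocks(windows, centers - half + np.array([di, dj, dk]))
                mc = m - m.mean(axis=1, keepdims=True)
                denom = fn * np.linalg.norm(mc, axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    val = np.einsum("ij,ij->i", fc, mc) / denom
                ncc[:, a, b, c] = np.where(denom > 1e-12, val, -1.0)

    # argmax with the tie-break: visit displacements by (|d|^2, lexicographic)
    dgrid = np.stack(np.meshgrid(disp_axis, disp_axis, disp_axis, indexing="ij"), -1).reshape(-1, 3)
    prio = np.lexsort((dgrid[:, 2], dgrid[:, 1], dgrid[:, 0], (dgrid**2).sum(axis=1)))
    flat = ncc.reshape(len(centers), -1)[:, prio]
    best = np.argmax(flat, axis=1)  # first max in priority order
    d_int = dgrid[prio[best]]

    frac = np.zeros((len(centers), 3))
    interior = np.all(np.abs(d_int) < r, axis=1)
    if interior.any():
        peaks = d_int[interior] + r
        neigh = np.empty((int(interior.sum()), 27))
        for q, off in enumerate(_QUAD_OFFSETS.astype(int)):
            neigh[:, q] = ncc[
                np.flatnonzero(interior),
                peaks[:, 0] + off[0],
                peaks[:, 1] + off[1],
                peaks[:, 2] + off[2],
            ]
        frac[interior] = _quadratic_peak(neigh)
    disp = (d_int + frac) * spacing
    return centers, disp


def _subsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    sm = ndimage.uniform_filter(arr, size=factor, mode="nearest")
    return sm[::factor, ::factor, ::factor]


def _filter_structured(
    dm: np.ndarray, spacing: np.ndarray, centers: np.ndarray, cfg: BlockMatchConfig
) -> np.ndarray:
    """Keep blocks whose distance field constrains displacement in all 3 axes.

    A block on a locally planar stretch of the distance map can slide along
    the iso-distance surface (the aperture problem); the smallest eigenvalue
    of the block-averaged structure tensor measures how well all directions
    are pinned down.
    """
    if len(centers) == 0:
        return centers
    g = np.gradient(dm, *spacing)
    prods = np.empty(dm.shape + (6,))
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    for q, (a, b) in enumerate(pairs):
        prods[..., q] = ndimage.uniform_filter(g[a] * g[b], size=cfg.block_size, mode="nearest")
    st = prods[centers[:, 0], centers[:, 1], centers[:, 2]]
    tensors = np.empty((len(centers), 3, 3))
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = st[:, 0], st[:, 1], st[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = st[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = st[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = st[:, 5]
    lam_min = np.linalg.eigvalsh(tensors)[:, 0]
    keep = lam_min >= cfg.structure_floor
    if keep.sum() >= 6:
        return centers[keep]
    return centers  # degenerate geometry: fall back to the unfiltered set


def _block_match_stage(
    fixed_dm: np.ndarray,
    moving_dm: np.ndarray,
    grid: GridSpec,
    roi: np.ndarray | None,
    cfg: BlockMatchConfig,
    init: RigidTransform,
    rng: np.random.Generator,
) -> tuple[RigidTransform, np.ndarray]:
    """Iterative block matching of a moving distance map onto a fixed one.

    Returns the refined transform and the residual block-displacement magnitudes
    (mm) observed after the final iteration.
    """
    t = init
    residual = np.empty(0)
    spacing = np.asarray(grid.spacing)
    mov_vol = ImageVolume(grid=grid, values=moving_dm, modality="CT_HU")
    far = float(moving_dm.max())
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        factor = 2**level
        coarsest = level == cfg.pyramid_levels - 1
        r = cfg.search_radius if coarsest else cfg.fine_search_radius
        f = _subsample(fixed_dm, factor)
        m_roi = None
        if roi is not None:
            m_roi = _subsample(roi.astype(float), factor) > 0.25
        lvl_grid = GridSpec(shape=f.shape, spacing=tuple(spacing * factor), origin=grid.origin)
        lvl_spacing = spacing * factor
        centers = _block_centers(f.shape, cfg.block_size // 2, r, cfg.block_stride, m_roi)
        centers = _filter_structured(f, lvl_spacing, centers, cfg)
        if len(centers) > cfg.max_blocks:
            centers = centers[np.sort(rng.choice(len(centers), cfg.max_blocks, replace=False))]
        for _ in range(cfg.max_iterations):
            warped = apply_transform(t, mov_vol, lvl_grid, cval=far)
            kept, disp = _match_blocks(f, warped.values, centers, r, cfg, lvl_spacing)
            if len(kept) < 6:
                raise ValueError("insufficient structure: fewer than 6 valid blocks")
            residual = np.linalg.norm(disp, axis=1)
            pts = lvl_grid.world_coordinates(kept)
            s = _fit_rigid_trimmed(pts, pts + disp, np.asarray(t.center), cfg.trim_fraction)
            t_new = s.inverse().compose(t)
            if s.parameter_distance(RigidTransform.identity(s.center)) < cfg.convergence_tol:
                t = t_new
                break
            t = t_new
    return t, residual


def register_pair(
    pre_ct: ImageVolume,
    post_ct: ImageVolume,
    roi: Mask,
    cfg: BlockMatchConfig | None = None,
    qc: QCThresholds | None = None,
    seed: int = 0,
) -> RegistrationResult:
    """Recover the rigid transform mapping post-treatment space to pre-treatment space.

    Stage 1 matches blocks of the bone distance maps over the whole volume;
    stage 2 repeats the matching restricted to blocks inside ``roi`` (a region
    around the pre-treatment tumor), refining the transform locally.  The bone
    Dice inside the ROI and the residual block displacement feed the QC gate.
    """
    cfg = cfg or BlockMatchConfig()
    qc = qc or QCThresholds()
    rng = np.random.default_rng(seed)

    pre_bone = threshold_mask(pre_ct, BONE_HU)
    post_bone = threshold_mask(post_ct, BONE_HU)
    if pre_bone.count == 0 or post_bone.count == 0:
        raise ValueError("no bone voxels at 200 HU; cannot register")
    fixed_dm = euclidean_distance_map(pre_bone).distance
    moving_dm = euclidean_distance_map(post_bone).distance

    center = pre_bone.grid.world_coordinates(pre_bone.indices()).mean(axis=0)
    init = RigidTransform.identity(center)

    t, _ = _block_match_stage(fixed_dm, moving_dm, pre_ct.grid, None, cfg, init, rng)
    roi_arr = roi.membership if roi is not None else None
    fine_cfg = replace(cfg, pyramid_levels=1, search_radius=cfg.fine_search_radius)
    t, residual = _block_match_stage(fixed_dm, moving_dm, pre_ct.grid, roi_arr, fine_cfg, t, rng)

    warped_bone = apply_transform(t, post_bone, pre_ct.grid)
    bone_dice = _roi_dice(pre_bone, warped_bone, roi)
    mean_res = float(residual.mean()) if residual.size else float("nan")
    max_res = float(residual.max()) if residual.size else float("nan")
    result = RegistrationResult(
        transform=t,
        bone_dice=bone_dice,
        qc_pass=False,
        mean_residual_mm=mean_res,
        max_residual_mm=max_res,
        n_blocks=int(residual.size),
    )
    result.qc_pass = qc_gate(result, qc)
    return result


def _roi_dice(pre_bone: Mask, warped_bone: Mask, roi: Mask | None) -> float:
    a, b = pre_bone.membership, warped_bone.membership
    if roi is not None:
        a = a & roi.membership
        b = b & roi.membership
    if a.sum() + b.sum() == 0:
        return 0.0
    return 2.0 * float((a & b).sum()) / float(a.sum() + b.sum())


def qc_gate(result: RegistrationResult, thresholds: QCThresholds | None = None) -> bool:
    """Automated acceptance proxy: bone Dice and residual displacement bounds.

    Patients failing the gate are excluded from all downstream analysis, the
    automated counterpart of excluding registrations a clinician judged
    anatomically inaccurate.
    """
    thresholds = thresholds or QCThresholds()
    ok_dice = result.bone_dice >= thresholds.dice_min
    ok_resid = result.mean_residual_mm <= thresholds.resid_max
    return bool(ok_dice and ok_resid)
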