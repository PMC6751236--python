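"""Voxel-wise feature extraction: GLCM/Haralick oracles, landmarks, LoG, table schema."""

import math

import numpy as np
import pytest

from recurmap.core import GridSpec, ImageVolume, Mask
from recurmap.features import (
    FEATURE_NAMES,
    FeatureConfig,
    GLCMMatrix,
    OFFSETS_13,
    discretize,
    extract_table,
    find_landmarks,
    haralick_features,
    local_glcm,
    log_filter,
    shape_descriptors,
)
from recurmap.labeling import partition_recurrence

from conftest import make_mask, make_volume


def glcm_pair_oracle(levels, valid, center, radius, n_bins):
    """Exhaustive pair enumeration over the clipped patch, symmetrized."""
    shape = levels.shape
    lo = [max(0, c - radius) for c in center]
    hi = [min(s, c + radius + 1) for c, s in zip(center, shape)]
    counts = np.zeros((n_bins, n_bins))
    for i in range(lo[0], hi[0]):
        for j in range(lo[1], hi[1]):
            for k in range(lo[2], hi[2]):
                if not valid[i, j, k]:
                    continue
                for oi, oj, ok in OFFSETS_13:
                    ni, nj, nk = i + oi, j + oj, k + ok
                    if lo[0] <= ni < hi[0] and lo[1] <= nj < hi[1] and lo[2] <= nk < hi[2]:
                        if valid[ni, nj, nk]:
                            a, b = levels[i, j, k], levels[ni, nj, nk]
                            counts[a, b] += 1
                            counts[b, a] += 1
    total = counts.sum()
    return counts / total if total else counts


def haralick_loop_oracle(p):
    """Longhand double-loop evaluation of the 7 Haralick statistics."""
    n = p.shape[0]
    mu_x = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_y = sum(j * p[i, j] for i in range(n) for j in range(n))
    sx = math.sqrt(sum((i - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n)))
    sy = math.sqrt(sum((j - mu_y) ** 2 * p[i, j] for i in range(n) for j in range(n)))
    energy = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    entropy = -sum(
        p[i, j] * math.log2(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
    )
    corr = (
        sum((i - mu_x) * (j - mu_y) * p[i, j] for i in range(n) for j in range(n)) / (sx * sy)
        if sx > 0 and sy > 0
        else 0.0
    )
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    homog = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    shade = sum((i + j - mu_x - mu_y) ** 3 * p[i, j] for i in range(n) for j in range(n))
    prom = sum((i + j - mu_x - mu_y) ** 4 * p[i, j] for i in range(n) for j in range(n))
    return np.array([energy, entropy, corr, contrast, homog, shade, prom])


class TestLandmarks:
    def test_single_voxel_gtv(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 3.0
        gtv = np.zeros((5, 5, 5), bool)
        gtv[2, 2, 2] = True
        vmax, vmin = find_landmarks(make_volume(vals, modality="PET_SUV"), make_mask(gtv))
        assert vmax == vmin == (2, 2, 2)

    def test_hot_block_found(self, rng):
        vals = rng.random((9, 9, 9))
        vals[5:8, 5:8, 5:8] += 10.0
        gtv = np.ones((9, 9, 9), bool)
        vmax, _ = find_landmarks(make_volume(vals, modality="CT_HU"), make_mask(gtv))
        assert all(5 <= c <= 7 for c in vmax)

    def test_tie_breaks_lexicographic(self):
        vals = np.zeros((9, 5, 5))
        vals[2, 2, 2] = 5.0
        vals[6, 2, 2] = 5.0  # symmetric equal interior maxima
        gtv = np.ones((9, 5, 5), bool)
        vmax, _ = find_landmarks(make_volume(vals, modality="CT_HU"), make_mask(gtv))
        # the neighborhood-averaged field ties over each hot voxel's whole
        # 27-neighborhood; the lexicographically smallest tied index wins
        assert vmax == (1, 1, 1)

    def test_empty_gtv_rejected(self):
        with pytest.raises(ValueError):
            find_landmarks(make_volume(np.zeros((3, 3, 3))), make_mask(np.zeros((3, 3, 3), bool)))


class TestGLCM:
    def test_constant_patch_degenerate(self):
        levels = np.full((5, 5, 5), 7, dtype=int)
        valid = np.ones((5, 5, 5), bool)
        g = local_glcm(levels, valid, (2, 2, 2), np.linspace(0, 1, 65))
        assert g.p[7, 7] == pytest.approx(1.0)
        feats = haralick_features(g)
        assert feats[0] == pytest.approx(1.0)  # energy
        assert feats[1] == pytest.approx(0.0)  # entropy
        assert feats[3] == pytest.approx(0.0)  # contrast
        assert feats[5] == pytest.approx(0.0)  # cluster shade

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(3, 6, size=3))
            levels = rng.integers(0, 8, size=shape)
            valid = rng.random(shape) < 0.8
            center = tuple(int(rng.integers(0, s)) for s in shape)
            oracle = glcm_pair_oracle(levels, valid, center, 2, 8)
            if oracle.sum() == 0:
                with pytest.raises(ValueError):
                    local_glcm(levels, valid, center, np.linspace(0, 1, 9), radius=2)
                continue
            g = local_glcm(levels, valid, center, np.linspace(0, 1, 9), radius=2)
            np.testing.assert_allclose(g.p, oracle, atol=1e-12)

    def test_mirror_symmetry(self, rng):
        levels = rng.integers(0, 6, size=(5, 5, 5))
        valid = np.ones((5, 5, 5), bool)
        g1 = local_glcm(levels, valid, (2, 2, 2), np.linspace(0, 1, 7))
        g2 = local_glcm(levels[::-1].copy(), valid, (2, 2, 2), np.linspace(0, 1, 7))
        np.testing.assert_allclose(g1.p, g2.p, atol=1e-12)


class TestHaralick:
    def test_identity_diagonal_uniform(self):
        p = np.eye(64) / 64
        feats = haralick_features(GLCMMatrix(p=p, bin_edges=np.linspace(0, 1, 65)))
        assert feats[3] == pytest.approx(0.0)  # contrast
        assert feats[4] == pytest.approx(1.0)  # homogeneity
        assert feats[0] == pytest.approx(1 / 64)  # energy

    def test_matches_longhand_loop(self, rng):
        for _ in range(20):
            m = rng.random((4, 4))
            m = m + m.T  # symmetric, like an accumulated GLCM
            p = m / m.sum()
            feats = haralick_features(GLCMMatrix(p=p, bin_edges=np.linspace(0, 1, 5)))
            np.testing.assert_allclose(feats, haralick_loop_oracle(p), atol=1e-12)

    def test_degenerate_marginal_correlation_zero(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        feats = haralick_features(GLCMMatrix(p=p, bin_edges=np.linspace(0, 1, 5)))
        assert feats[2] == 0.0


class TestLoG:
    def test_constant_is_zero(self):
        vol = make_volume(np.full((8, 8, 8), 5.0), spacing=(2.0, 2.0, 2.0))
        out = log_filter(vol, 2.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_quadratic_profile(self):
        # f = a x^2 -> laplacian 2a, approached for sigma small vs curvature scale
        shape = (41, 9, 9)
        x = (np.arange(shape[0]) - 20)[:, None, None] * 1.0
        a = 0.05
        vol = make_volume(np.broadcast_to(a * x**2, shape).copy(), spacing=(1.0, 1.0, 1.0))
        out = log_filter(vol, 1.5)
        interior = out.values[15:26, 4, 4]
        np.testing.assert_allclose(interior, 2 * a, rtol=0.05)

    def test_hot_voxel_negative_center(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 10.0
        out = log_filter(make_volume(vals), 1.0)
        assert out.values[4, 4, 4] < 0

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            log_filter(make_volume(np.zeros((3, 3, 3))), 0.0)


@pytest.fixture(scope="module")
def table(phantom):
    part = partition_recurrence(phantom.gtv_pre, phantom.true_failure)
    return extract_table(
        phantom.pre_pet, phantom.gtv_pre, partition=part, site=phantom.site_label
    ), phantom


class TestExtractTable:

    def test_schema_22_features(self, table):
        df, phantom = table
        assert len(FEATURE_NAMES) == 22
        assert [c for c in df.columns if c in FEATURE_NAMES] == list(FEATURE_NAMES)
        assert len(df) == phantom.gtv_pre.count  # grid already isotropic

    def test_rel_suv_bounds_and_argmax(self, table):
        df, _ = table
        assert df.rel_suv.max() == pytest.approx(1.0)
        assert (df.rel_suv > 0).all()
        assert df.dist_vmax.min() == 0.0  # the vMax voxel itself
        hottest = df.loc[df.rel_suv.idxmax()]
        # PET noise can separate the raw SUVmax voxel from the
        # neighborhood-averaged vMax by a couple of voxels
        assert hottest.dist_vmax <= 3 * np.sqrt(3) * 2.0 + 1e-9

    def test_surface_voxels_zero_distance(self, table):
        df, _ = table
        assert (df.dist_surface == 0).sum() > 0
        assert df.dist_surface.min() == 0.0

    def test_tumor_level_columns_constant(self, table):
        df, _ = table
        for col in ("sphericity", "compactness", "surface_to_volume", "mtv50_ml", "tlg50", "site_code"):
            assert df[col].nunique() == 1

    def test_mtv50_membership_flag(self, table):
        df, phantom = table
        from recurmap.labeling import mtv

        m50 = mtv(phantom.pre_pet, phantom.gtv_pre, 50.0)
        idx = df[["i", "j", "k"]].to_numpy()
        inside = m50.membership[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.all(df.in_mtv50_plus10.to_numpy()[inside] == 1.0)

    def test_positions_normalized(self, table):
        df, _ = table
        for c in ("pos_x", "pos_y", "pos_z"):
            assert df[c].abs().max() <= 1.0 + 1e-9

    def test_label_prevalence_matches_partition(self, table):
        df, phantom = table
        assert df.label.mean() == pytest.approx(
            phantom.true_failure.count / phantom.gtv_pre.count, abs=1e-9
        )

    def test_rotation_robustness_90deg(self):
        """Haralick features are unchanged under a 90-degree grid rotation."""
        rng = np.random.default_rng(7)
        vals = rng.gamma(4.0, 1.0, size=(14, 14, 14))
        gtv = np.zeros((14, 14, 14), bool)
        gtv[3:11, 3:11, 3:11] = True
        pet = make_volume(vals, modality="PET_SUV")
        df1 = extract_table(pet, make_mask(gtv), site="larynx")
        rot_vals = np.rot90(vals, k=1, axes=(0, 1)).copy()
        rot_gtv = np.rot90(gtv, k=1, axes=(0, 1)).copy()
        df2 = extract_table(make_volume(rot_vals, modality="PET_SUV"), make_mask(rot_gtv), site="larynx")
        # map voxel (i, j, k) -> rotated (N-1-j, i, k)
        n = 14
        key1 = {(r.i, r.j, r.k): r for r in df1.itertuples()}
        checked = 0
        for r2 in df2.itertuples():
            orig = (r2.j, n - 1 - r2.i, r2.k)
            r1 = key1.get(orig)
            if r1 is None:
                continue
            for col in ("haralick_energy", "haralick_entropy", "haralick_correlation",
                        "haralick_contrast", "haralick_homogeneity", "cluster_shade",
                        "cluster_prominence"):
                assert getattr(r1, col) == pytest.approx(getattr(r2, col), abs=1e-9)
            checked += 1
        assert checked == len(df1)


def test_shape_descriptors_cube_closed_form():
    m = np.zeros((8, 8, 8), bool)
    m[2:6, 2:6, 2:6] = True  # 4x4x4 cube, spacing 1: V=64, A=96
    sph, comp, s2v, surf = shape_descriptors(make_mask(m))
    assert s2v == pytest.approx(96 / 64)
    assert sph == pytest.approx(np.pi ** (1 / 3) * (6 * 64) ** (2 / 3) / 96)
    assert comp == pytest.approx(64 / 96**1.5)
    assert surf.sum() == 4**3 - 2**3


def test_discretize_levels_span_range(rng):
    vals = rng.random((6, 6, 6)) * 10
    gtv = np.ones((6, 6, 6), bool)
    levels, edges = discretize(make_volume(vals, modality="PET_SUV"), make_mask(gtv), 64)
    assert levels.min() == 0 and levels.max() == 63
    assert len(edges) == 65
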