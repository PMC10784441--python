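"""Handcrafted features: catalog, per-family examples, brute-force oracles."""

import math

import numpy as np
import pytest

from ptrarad import handcrafted as hc
from ptrarad.preprocess import CTSlice, make_variants

# ---------------------------------------------------------------------------
# independent oracles: explicit pair/run enumeration with loop-level formulas
# ---------------------------------------------------------------------------


def naive_glcm(labels, n_bins, directions=hc.GLCM_DIRECTIONS):
    """Count co-occurring in-ROI label pairs one by one, per direction."""
    h, w = labels.shape
    mats = []
    for dr, dc in directions:
        m = np.zeros((n_bins, n_bins))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and labels[r, c] > 0 and labels[r2, c2] > 0:
                    m[labels[r, c] - 1, labels[r2, c2] - 1] += 1
                    m[labels[r2, c2] - 1, labels[r, c] - 1] += 1
        if m.sum() > 0:
            mats.append(m / m.sum())
    return np.mean(mats, axis=0) if mats else np.zeros((n_bins, n_bins))


def naive_glcm_features(p):
    """Loop-wise Haralick statistics (independent of the vectorized path)."""
    n = p.shape[0]
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mx = sum((i + 1) * px[i] for i in range(n))
    my = sum((j + 1) * py[j] for j in range(n))
    sx = math.sqrt(sum((i + 1 - mx) ** 2 * px[i] for i in range(n)))
    sy = math.sqrt(sum((j + 1 - my) ** 2 * py[j] for j in range(n)))
    feats = dict.fromkeys(hc.GLCM_STATS, 0.0)
    pxy = {}
    for i in range(n):
        for j in range(n):
            v = p[i][j]
            d = (i + 1) - (j + 1)
            s = (i + 1) + (j + 1) - mx - my
            feats["contrast"] += d * d * v
            feats["dissimilarity"] += abs(d) * v
            feats["energy"] += v * v
            feats["entropy"] -= v * math.log2(v) if v > 0 else 0.0
            feats["homogeneity"] += v / (1 + abs(d))
            feats["homogeneity2"] += v / (1 + d * d)
            feats["cluster_shade"] += s**3 * v
            feats["cluster_prominence"] += s**4 * v
            feats["autocorrelation"] += (i + 1) * (j + 1) * v
            pxy[(i + 1) + (j + 1)] = pxy.get((i + 1) + (j + 1), 0.0) + v
    if sx > 0 and sy > 0:
        feats["correlation"] = sum(
            ((i + 1) - mx) * ((j + 1) - my) * p[i][j] for i in range(n) for j in range(n)
        ) / (sx * sy)
    else:
        feats["correlation"] = 1.0
    feats["sum_average"] = sum(k * v for k, v in pxy.items())
    feats["sum_entropy"] = -sum(v * math.log2(v) for v in pxy.values() if v > 0)
    feats["maximum_probability"] = max(max(row) for row in p)
    return feats


def naive_glrlm_features(labels, n_bins, n_pixels, directions=hc.GLCM_DIRECTIONS):
    """Walk runs pixel by pixel along each direction's lines; average features."""
    h, w = labels.shape
    per_dir = []
    for dr, dc in directions:
        runs = []  # (level, length)
        if (dr, dc) == (0, 1):
            starts = [(r, 0) for r in range(h)]
        elif (dr, dc) == (1, 0):
            starts = [(0, c) for c in range(w)]
        elif (dr, dc) == (1, 1):
            starts = [(0, c) for c in range(w)] + [(r, 0) for r in range(1, h)]
        else:  # (-1, 1)
            starts = [(r, 0) for r in range(h)] + [(h - 1, c) for c in range(1, w)]
        for r0, c0 in starts:
            r, c = r0, c0
            prev, length = 0, 0
            while 0 <= r < h and 0 <= c < w:
                v = labels[r, c]
                if v == prev and v != 0:
                    length += 1
                else:
                    if prev != 0:
                        runs.append((prev, length))
                    prev, length = v, 1
                r, c = r + dr, c + dc
            if prev != 0:
                runs.append((prev, length))
        nr = len(runs)
        feats = {
            "SRE": sum(1 / l**2 for _, l in runs) / nr,
            "LRE": sum(l**2 for _, l in runs) / nr,
            "GLN": sum(
                sum(1 for g, _ in runs if g == lev) ** 2 for lev in range(1, n_bins + 1)
            )
            / nr,
            "RLN": sum(
                sum(1 for _, l in runs if l == L) ** 2
                for L in range(1, max(h, w) + 1)
            )
            / nr,
            "RP": nr / n_pixels,
            "LGRE": sum(1 / g**2 for g, _ in runs) / nr,
            "HGRE": sum(g**2 for g, _ in runs) / nr,
            "LRHGLE": sum(g**2 * l**2 for g, l in runs) / nr,
        }
        per_dir.append(feats)
    return {k: np.mean([f[k] for f in per_dir]) for k in hc.GLRLM_STATS}


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


class TestDiscretize:
    def test_full_range(self):
        img = np.arange(32, dtype=float).reshape(4, 8)
        labels = hc.discretize(img, np.ones_like(img, bool), 32)
        assert sorted(np.unique(labels)) == list(range(1, 33))

    def test_constant_roi(self):
        labels = hc.discretize(np.full((4, 4), 9.0), np.ones((4, 4), bool), 8)
        assert np.all(labels == 1)

    def test_two_bins_split_at_midpoint(self):
        img = np.array([[0.0, 10.0, 20.0, 30.0]])
        labels = hc.discretize(img, np.ones_like(img, bool), 2)
        np.testing.assert_array_equal(labels, [[1, 1, 2, 2]])

    def test_outside_mask_is_zero(self):
        img = np.arange(16.0).reshape(4, 4)
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        labels = hc.discretize(img, mask, 4)
        assert np.all(labels[~mask] == 0)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


class TestShape:
    def test_disk_circularity(self):
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        feats = hc.shape_features(disk, spacing=0.5)
        assert abs(feats["circularity"] - 1.0) < 0.1
        assert abs(feats["area"] - np.pi * 10**2) < 5  # radius 20 px * 0.5 mm

    def test_elongation_orders_square_below_rectangle(self):
        sq = np.zeros((40, 40), bool)
        sq[10:30, 10:30] = True
        rect = np.zeros((40, 60), bool)
        rect[15:25, 5:45] = True  # same area 400, elongated
        assert hc.shape_features(sq)["elongation"] < hc.shape_features(rect)["elongation"]
        assert abs(hc.shape_features(sq)["elongation"] - 1.0) < 0.05

    def test_convex_mask_solidity(self):
        m = np.zeros((20, 20), bool)
        m[4:16, 6:14] = True
        assert hc.shape_features(m)["solidity"] == pytest.approx(1.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            hc.shape_features(np.zeros((8, 8), bool))


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


class TestHistogram:
    def test_constant_roi_degenerate(self):
        f = hc.histogram_features(np.full((5, 5), 4.0), np.ones((5, 5), bool))
        assert f["variance"] == 0
        assert f["entropy"] == 0
        assert f["uniformity"] == 1

    def test_hand_arithmetic(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        f = hc.histogram_features(img, np.ones((2, 2), bool))
        assert f["mean"] == pytest.approx(2.5)
        assert f["mean_absolute_deviation"] == pytest.approx(1.0)
        assert f["range"] == pytest.approx(3.0)

    def test_two_equal_bins(self):
        img = np.array([[0.0, 0.0, 10.0, 10.0]])
        f = hc.histogram_features(img, np.ones_like(img, bool), n_bins=2)
        assert f["uniformity"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0, 10, (6, 6))
        mask = np.ones((6, 6), bool)
        f1 = hc.histogram_features(img, mask)
        perm = img.copy()
        perm[mask] = rng.permutation(img[mask])
        f2 = hc.histogram_features(perm, mask)
        for k in hc.HIST_STATS:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


class TestGLCM:
    def test_constant_roi(self):
        f = hc.glcm_features(np.full((6, 6), 2.0), np.ones((6, 6), bool))
        assert f["contrast"] == 0
        assert f["energy"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["correlation"] == 1.0  # zero-variance convention

    def test_checkerboard_horizontal(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 * 10.0
        labels = hc.discretize(board, np.ones((6, 6), bool), 2)
        p = hc.glcm_matrix(labels, 2, directions=((0, 1),))
        f = hc.glcm_features_from_matrix(p)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)

    def test_symmetric_levels_zero_shade(self):
        # levels symmetric about the mean make the odd central moment vanish
        p = np.array([[0.25, 0.25], [0.25, 0.25]])
        assert hc.glcm_features_from_matrix(p)["cluster_shade"] == pytest.approx(0.0)

    def test_matrix_normalized_and_symmetric(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 5, (8, 8))
        labels = hc.discretize(img, np.ones((8, 8), bool), 8)
        p = hc.glcm_matrix(labels, 8)
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T, atol=1e-12)

    def test_oracle_equivalence_random_rois(self):
        # vectorized path vs naive pair enumeration on 50 seeded 8x8 ROIs
        rng = np.random.default_rng(42)
        for trial in range(50):
            img = rng.normal(0, 10, (8, 8))
            mask = rng.uniform(size=(8, 8)) < 0.8
            if mask.sum() < 4:
                mask[:2, :2] = True
            labels = hc.discretize(img, mask, 6)
            p_fast = hc.glcm_matrix(labels, 6)
            p_naive = naive_glcm(labels, 6)
            np.testing.assert_allclose(p_fast, p_naive, atol=1e-10)
            mine = hc.glcm_features_from_matrix(p_fast)
            ref = naive_glcm_features(p_naive)
            for k in hc.GLCM_STATS:
                assert mine[k] == pytest.approx(ref[k], abs=1e-10), k


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


class TestGLRLM:
    def test_constant_4x4_horizontal(self):
        labels = np.ones((4, 4), dtype=np.int64)
        m = hc.glrlm_matrix(labels, 1, (0, 1))
        f = hc.glrlm_features_from_matrix(m, 16)
        assert f["LRE"] == pytest.approx(16.0)
        assert f["SRE"] == pytest.approx(1 / 16)
        assert f["RP"] == pytest.approx(0.25)

    def test_alternating_row_all_unit_runs(self):
        img = np.tile([0.0, 10.0], 4)[None, :]
        f = hc.glrlm_features(img, np.ones_like(img, bool), n_bins=2, directions=((0, 1),))
        assert f["SRE"] == pytest.approx(1.0)
        assert f["LRE"] == pytest.approx(1.0)

    def test_oracle_equivalence_random_rois(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            img = rng.normal(0, 10, (8, 8))
            mask = rng.uniform(size=(8, 8)) < 0.75
            if mask.sum() < 4:
                mask[:2, :2] = True
            f = hc.glrlm_features(img, mask, n_bins=4)
            labels = hc.discretize(img, mask, 4)
            ref = naive_glrlm_features(labels, 4, int(mask.sum()))
            for k in hc.GLRLM_STATS:
                assert f[k] == pytest.approx(ref[k], abs=1e-10), k

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            hc.glrlm_features_from_matrix(np.zeros((2, 4)), 8)


# ---------------------------------------------------------------------------
# fractal
# ---------------------------------------------------------------------------


class TestFractal:
    def test_flat_surface_dimension_two(self):
        img = np.full((32, 32), 5.0)
        d = hc.fractal_feature(img, np.ones((32, 32), bool))
        assert abs(d - 2.0) < 0.05

    def test_noise_raises_dimension(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        noisy = rng.normal(0, 30, (32, 32))
        smooth = gaussian_filter(noisy, 2.0)
        mask = np.ones((32, 32), bool)
        assert hc.fractal_feature(noisy, mask) > hc.fractal_feature(smooth, mask)

    def test_intensity_shift_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 20, (24, 24))
        mask = np.ones((24, 24), bool)
        assert hc.fractal_feature(img, mask) == pytest.approx(
            hc.fractal_feature(img + 100.0, mask), abs=1e-12
        )

    def test_small_roi_rejected(self):
        with pytest.raises(ValueError):
            hc.fractal_feature(np.zeros((10, 10)), np.pad(np.ones((4, 4), bool), 3))


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def study_and_mask():
    rng = np.random.default_rng(3)
    img = rng.normal(0, 30, (48, 48))
    study = make_variants(CTSlice(img))
    mask = np.zeros((48, 48), bool)
    mask[8:40, 10:38] = True
    return study, mask


class TestExtractHandcrafted:
    def test_catalog_size_and_order(self, study_and_mask):
        study, mask = study_and_mask
        vec, report = hc.extract_handcrafted(study, mask)
        assert len(vec) == 116
        assert list(vec.index) == hc.catalog()
        assert not vec.isna().any()
        assert report == {}

    def test_deterministic(self, study_and_mask):
        study, mask = study_and_mask
        a, _ = hc.extract_handcrafted(study, mask)
        b, _ = hc.extract_handcrafted(study, mask)
        assert (a == b).all()

    def test_shape_block_mask_only(self, study_and_mask):
        # the shape block depends only on the mask, not on the image variant
        study, mask = study_and_mask
        vec, _ = hc.extract_handcrafted(study, mask)
        direct = hc.shape_features(mask, study.X.spacing)
        for k, v in direct.items():
            assert vec[f"Shape_{k}"] == pytest.approx(v)

    def test_table2_names_present(self):
        names = set(hc.catalog())
        for expected in (
            "XH_H_uniformity",
            "XL_H_mean_absolute_deviation",
            "XH_GLCM_correlation",
            "XL_GLRLM_LRHGLE",
            "XH_GLCM_cluster_shade",
            "XL_H_standard_deviation",
            "X_GLCM_contrast",
            "XH_H_mean",
        ):
            assert expected in names
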