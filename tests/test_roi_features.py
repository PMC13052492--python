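"""ROI extraction, masking, abundance, and Haralick texture features,
cross-checked against brute-force pair-enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_predict

from optophen import roi_features as rf

# ---------------------------------------------------------------------------
# brute-force oracle (independent of the implementation path)
# ---------------------------------------------------------------------------

OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees


def oracle_quantize(img, levels=64, lo=2000, hi=65535):
    q = np.empty(img.shape, int)
    valid = np.empty(img.shape, bool)
    for idx in np.ndindex(img.shape):
        v = img[idx]
        valid[idx] = lo <= v < hi
        q[idx] = min(int((v - lo) / (hi - lo) * levels), levels - 1) if valid[idx] else -1
    return q, valid


def oracle_glcm(q, valid, levels, offset):
    """Count co-occurring valid pairs in both directions of one offset."""
    h, w = q.shape
    p = np.zeros((levels, levels))
    dy, dx = offset
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and valid[y, x] and valid[y2, x2]:
                p[q[y, x], q[y2, x2]] += 1
                p[q[y2, x2], q[y, x]] += 1
    total = p.sum()
    return p / total if total else p


def oracle_haralick_13(p):
    """The 13 statistics computed with explicit loops."""
    g = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(g))
    mu_y = sum(j * py[j] for j in range(g))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(g)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(g)))
    p_sum = np.zeros(2 * g - 1)
    p_diff = np.zeros(g)
    for i in range(g):
        for j in range(g):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def ent(q):
        return -sum(v * math.log(v) for v in q.ravel() if v > 0)

    asm = float((p**2).sum())
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    if sd_x > 0 and sd_y > 0:
        corr = (sum(i * j * p[i, j] for i in range(g) for j in range(g))
                - mu_x * mu_y) / (sd_x * sd_y)
    else:
        corr = 0.0
    var = sum((i - mu_x) ** 2 * p[i, j] for i in range(g) for j in range(g))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    savg = sum(k * p_sum[k] for k in range(2 * g - 1))
    svar = sum((k - savg) ** 2 * p_sum[k] for k in range(2 * g - 1))
    sent = ent(p_sum)
    entr = ent(p)
    dmean = sum(k * p_diff[k] for k in range(g))
    dvar = sum((k - dmean) ** 2 * p_diff[k] for k in range(g))
    dent = ent(p_diff)
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i, j] * math.log(px[i] * py[j])
        for i in range(g) for j in range(g)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log(px[i] * py[j])
        for i in range(g) for j in range(g) if px[i] * py[j] > 0
    )
    imc1 = (entr - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - entr))))
    return np.array([asm, contrast, corr, var, idm, savg, svar, sent, entr,
                     dvar, dent, imc1, imc2])


def oracle_haralick(img, levels=64):
    q, valid = oracle_quantize(img, levels)
    feats = [
        oracle_haralick_13(oracle_glcm(q, valid, levels, off)) for off in OFFSETS
    ]
    return np.mean(feats, axis=0)


# ---------------------------------------------------------------------------
# extraction and masking
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_constant_image_gives_constant_roi(self):
        stack = np.full((2, 100, 100), 4321, dtype=np.uint16)
        rois = rf.extract_rois(stack, [(50, 50)], size=70)
        assert rois.shape == (1, 2, 70, 70)
        assert (rois == 4321).all()

    def test_delta_at_center_lands_at_window_index_35(self):
        stack = np.full((1, 100, 100), 2500, dtype=np.uint16)
        stack[0, 60, 40] = 60000
        roi = rf.extract_rois(stack, [(40, 60)], size=70)[0, 0]
        assert np.unravel_index(roi.argmax(), roi.shape) == (35, 35)

    def test_roi_count_matches_in_bounds_spot_count(
        self, small_dataset, small_centers, small_rois
    ):
        # brute-force bounds check over all grid spots
        h, w = small_dataset.stack.shape
        n_in = sum(
            1
            for cx, cy in small_dataset.centers
            if cx - 35 >= 0 and cx + 35 <= w and cy - 35 >= 0 and cy + 35 <= h
        )
        assert len(small_rois) == n_in == len(small_centers)

    def test_out_of_bounds_extraction_raises(self):
        stack = np.zeros((1, 50, 50), dtype=np.uint16)
        with pytest.raises(ValueError):
            rf.extract_rois(stack, [(5, 5)], size=70)


class TestMasking:
    @pytest.mark.parametrize(
        "value,expect_valid",
        [(1999, False), (2000, True), (65534, True), (65535, False)],
    )
    def test_threshold_boundaries(self, value, expect_valid):
        roi = np.full((1, 4, 4), value, dtype=np.int64)
        assert rf.mask_valid(roi).all() == expect_valid

    def test_mixed_roi_mask_cardinality(self):
        rng = np.random.default_rng(0)
        roi = rng.integers(0, 66000, size=(1, 20, 20))
        k = sum(1 for v in roi.ravel() if 2000 <= v < 65535)
        assert rf.mask_valid(roi).sum() == k

    def test_fully_masked_spot_excluded_from_table(self, caplog):
        rois = np.full((1, 5, 70, 70), 1999, dtype=np.uint16)
        with caplog.at_level("WARNING"):
            table = rf.build_feature_table(rois, ["s0"], [1], with_texture=False)
        assert len(table) == 0
        assert "excluded" in caplog.text


class TestAbundance:
    def test_constant_roi(self):
        roi = np.full((5, 70, 70), 3000.0)
        np.testing.assert_allclose(rf.abundance(roi), 3000.0)

    def test_half_and_half(self):
        roi = np.full((1, 2, 2), 2000.0)
        roi[0, :, 1] = 4000.0
        np.testing.assert_allclose(rf.abundance(roi), [3000.0])

    @settings(max_examples=25, deadline=None)
    @given(hst.integers(0, 2**31 - 1))
    def test_masked_mean_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        roi = rng.integers(0, 66000, size=(2, 12, 12)).astype(float)
        got = rf.abundance(roi)
        for c in range(2):
            vals = [v for v in roi[c].ravel() if 2000 <= v < 65535]
            if vals:
                assert abs(got[c] - np.mean(vals)) < 1e-9
            else:
                assert np.isnan(got[c])

    def test_ratio_normalization(self):
        a = np.array([1.0, 2.0, 3.0, 2.0, 4.0])
        out = rf.normalize_abundance(a)
        np.testing.assert_allclose(out, [0.5, 1.0, 1.5, 2.0, 2.0])

    def test_equal_channels_ratio_one(self):
        out = rf.normalize_abundance(np.full(5, 7.0))
        np.testing.assert_allclose(out[:4], 1.0)
        assert out[4] == 7.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            rf.normalize_abundance(np.array([1.0, 1, 1, 0, 1]))


# ---------------------------------------------------------------------------
# Haralick
# ---------------------------------------------------------------------------

class TestHaralick:
    def test_constant_roi_degenerate_glcm(self):
        roi = np.full((16, 16), 30000.0)
        f = rf.haralick(roi)
        named = dict(zip(rf.HARALICK_NAMES, f))
        assert named["asm"] == 1.0
        assert named["contrast"] == 0.0
        assert named["entropy"] == 0.0

    def test_checkerboard_contrast_equals_squared_level_difference(self):
        """On a two-level checkerboard every axial d=1 pair crosses the
        levels, so contrast at 0/90 degrees equals (q1-q0)^2."""
        width = (65535 - 2000) / 64
        lo_val = 2000 + 0.5 * width      # level 0
        hi_val = 2000 + 5.5 * width      # level 5
        board = np.indices((8, 8)).sum(axis=0) % 2
        img = np.where(board, hi_val, lo_val)
        q = rf.quantize(img)
        mats = rf.glcm(q)
        contrast_0 = ((np.arange(64)[:, None] - np.arange(64)) ** 2
                      * mats[:, :, 0]).sum()
        assert contrast_0 == pytest.approx(25.0)

    def test_glcm_slices_are_normalized(self):
        rng = np.random.default_rng(1)
        q = rf.quantize(rng.integers(2000, 65535, size=(20, 20)))
        mats = rf.glcm(q)
        np.testing.assert_allclose(mats.sum(axis=(0, 1)), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_all_13_features_match_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(1000, 66000, size=(8, 8)).astype(float)
        got = rf.haralick(img)
        want = oracle_haralick(img)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_small_level_count_oracle(self):
        rng = np.random.default_rng(7)
        img = rng.integers(2000, 65535, size=(6, 6)).astype(float)
        got = rf.haralick(img, levels=4)
        want = oracle_haralick(img, levels=4)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_rotation_invariance_under_angle_averaging(self):
        rng = np.random.default_rng(2)
        img = rng.integers(2000, 65535, size=(16, 16)).astype(float)
        f0 = rf.haralick(img)
        f90 = rf.haralick(np.rot90(img))
        np.testing.assert_allclose(f0, f90, atol=1e-12)

    def test_shape_statistics_invariant_to_gray_level_shift(self):
        """GLCM-shape statistics (ASM, contrast, IDM, entropies, the
        difference statistics and information measures) depend only on
        the co-occurrence pattern, not the absolute gray level."""
        rng = np.random.default_rng(3)
        q = rng.integers(0, 10, size=(12, 12))
        width = (65535 - 2000) / 64
        img0 = 2000 + (q + 0.5) * width
        img1 = 2000 + (q + 20 + 0.5) * width
        f0 = dict(zip(rf.HARALICK_NAMES, rf.haralick(img0)))
        f1 = dict(zip(rf.HARALICK_NAMES, rf.haralick(img1)))
        for name in ("asm", "contrast", "correlation", "idm", "sum_entropy",
                     "entropy", "difference_variance", "difference_entropy",
                     "imc1", "imc2"):
            assert f0[name] == pytest.approx(f1[name], abs=1e-9), name


class TestFeatureTable:
    def test_abundance_only_width_five(self, small_rois, small_dataset,
                                       small_centers):
        table = rf.build_feature_table(
            small_rois[:10], small_centers["barcode"][:10],
            small_dataset.assignments[:10], with_texture=False,
        )
        assert table.shape[1] - 2 == 5

    def test_full_width_seventy(self, small_rois, small_dataset, small_centers):
        table = rf.build_feature_table(
            small_rois[:10], small_centers["barcode"][:10],
            small_dataset.assignments[:10], with_texture=True,
        )
        assert table.shape[1] - 2 == 70

    def test_zero_spots_empty_table_valid_schema(self):
        table = rf.build_feature_table(
            np.empty((0, 5, 70, 70)), [], [], with_texture=True
        )
        assert len(table) == 0
        assert list(table.columns[:2]) == ["spot", "label"]
        assert table.shape[1] == 72

    def test_texture_separates_texture_coded_clusters_abundance_does_not(
        self, small_dataset, small_centers, small_rois
    ):
        """Clusters that differ only in texture correlation length:
        a linear classifier on abundance is near chance, on Haralick
        features it separates well."""
        labels = small_dataset.assignments
        table = rf.build_feature_table(
            small_rois, small_centers["barcode"], labels, with_texture=True
        )
        sub = table[table["label"].isin([0, 2])]
        y = (sub["label"] == 2).to_numpy(int)
        ab_cols = [f"abundance_{i+1}" for i in range(5)]
        tex_cols = [c for c in sub.columns if c.startswith("haralick")]

        def cv_auc(cols):
            x = sub[cols].to_numpy()
            x = (x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0))
            scores = cross_val_predict(
                LogisticRegression(max_iter=2000), x, y, cv=5,
                method="decision_function",
            )
            return roc_auc_score(y, scores)

        assert cv_auc(ab_cols) < 0.75
        assert cv_auc(tex_cols) > 0.9
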