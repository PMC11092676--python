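"""Feature families: registry structure, toy-oracle values, invariances."""

import numpy as np
import pytest

from phantombench.phantom import FAT, GLANDULAR, LIGAMENT, SKIN
from phantombench import features as F


# ---------------------------------------------------------------------------
# registry

def test_registry_structure(registry):
    names = registry.names
    assert len(names) == len(set(names))
    assert len(registry) >= 1000
    fams = set(registry.families())
    assert fams == {"texture", "morphology", "skeleton", "fractal",
                    "moments", "fg_ratio"}
    glcm = [n for n in names if n.startswith("tex_glcm_")]
    assert len(glcm) == 14 * (4 * 4 + 4)
    assert len(F.PUBLIC_METRIC_FEATURES) == 9
    assert set(F.PUBLIC_METRIC_FEATURES) <= set(names)
    assert len(registry.version) == 12


def test_registry_subset_and_manifest(registry):
    sub = registry.subset(names=list(F.PUBLIC_METRIC_FEATURES))
    assert len(sub) == 9
    with pytest.raises(KeyError):
        registry.subset(names=["not_a_feature"])
    man = registry.manifest()
    assert man["n_features"] == len(registry)
    assert man["version"] == registry.version


# ---------------------------------------------------------------------------
# summarization

def test_summary_scheme():
    s = F.summarize([1.0, 2.0, 3.0, 4.0])
    assert s["count"] == 4 and s["mean"] == 2.5
    assert s["q1"] == 1.75 and s["q2"] == 2.5 and s["q3"] == 3.25  # linear interp
    empty = F.summarize([])
    assert empty["count"] == 0 and np.isnan(empty["mean"])


# ---------------------------------------------------------------------------
# texture

def _uniform_disk_image(value=100, size=64, r=24):
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r ** 2
    img = np.where(mask, value, 0).astype(np.uint8)
    lm = np.where(mask, FAT, 0).astype(np.uint8)
    return img, lm


def test_glcm_constant_foreground():
    img, lm = _uniform_disk_image()
    out = F.texture_features(img, lm)
    assert out["tex_glcm_asm_d1_a0"] == pytest.approx(1.0)
    assert out["tex_glcm_contrast_d1_a0"] == pytest.approx(0.0)


def test_glcm_contrast_matches_bruteforce_pairs():
    """2x2 checkerboard tile: contrast at d=1, 0 deg by pair enumeration."""
    tile = np.array([[40, 200], [200, 40]], dtype=np.uint8)
    img = np.tile(tile, (4, 4))
    lm = np.full(img.shape, FAT, dtype=np.uint8)

    levels = (img.astype(int) * 64) // 256
    pairs = []
    h, w = img.shape
    for y in range(h):          # horizontal symmetric pairs
        for x in range(w - 1):
            pairs.append((levels[y, x], levels[y, x + 1]))
            pairs.append((levels[y, x + 1], levels[y, x]))
    brute = np.mean([(i - j) ** 2 for i, j in pairs])

    out = F.texture_features(img, lm)
    assert out["tex_glcm_contrast_d1_a0"] == pytest.approx(brute)


def test_first_order_scope_statistics():
    img, lm = _uniform_disk_image(value=100)
    out = F.texture_features(img, lm)
    n_fat = int((lm == FAT).sum())
    assert out["tex_fo_F_count"] == n_fat
    assert out["tex_fo_F_mean"] == pytest.approx(100.0)
    assert out["tex_fo_F_sd"] == pytest.approx(0.0)
    assert np.isnan(out["tex_fo_G_mean"])  # no glandular tissue
    # 64-bin histogram concentrates in the bin of value 100
    assert out["tex_hist_F_b25"] == pytest.approx(1.0)  # 100*64//256 == 25


# ---------------------------------------------------------------------------
# morphology

def test_morphology_single_disk():
    _, lm = _uniform_disk_image()
    lm = np.where(lm == FAT, FAT, 0).astype(np.uint8)
    out = F.morphology_features(lm)
    assert out["morph_F_area_count"] == 1
    assert out["morph_F_solidity_mean"] == pytest.approx(1.0, abs=0.05)
    assert out["morph_F_circularity_mean"] == pytest.approx(1.0, abs=0.1)
    assert out["morph_G_area_count"] == 0


def test_morphology_notched_disk_convexity():
    yy, xx = np.mgrid[0:80, 0:80]
    disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 30 ** 2
    notched = disk & ~((np.abs(xx - 40) < 5) & (yy < 40))
    lm = np.where(notched, FAT, 0).astype(np.uint8)
    out = F.morphology_features(lm)
    assert out["morph_F_convexity_perimeter_mean"] < 0.9
    assert out["morph_B_convexity_perimeter"] < 0.9


def test_morphology_two_squares():
    lm = np.zeros((40, 40), dtype=np.uint8)
    lm[2:10, 2:10] = FAT      # 64 px
    lm[20:26, 20:26] = FAT    # 36 px
    out = F.morphology_features(lm)
    assert out["morph_F_area_count"] == 2
    assert out["morph_F_area_min"] == 36
    assert out["morph_F_area_max"] == 64


# ---------------------------------------------------------------------------
# skeleton

def test_skeleton_straight_line():
    lm = np.zeros((60, 60), dtype=np.uint8)
    lm[30, 5:55] = LIGAMENT
    out = F.skeleton_features(lm)
    assert out["skel_n_skeletons"] == 1
    assert out["skel_endpoints_mean"] == 2
    assert out["skel_branchpoints_mean"] == 0
    assert out["skel_length_mean"] == 50


def test_skeleton_cross_endpoints_and_branch():
    lm = np.zeros((41, 41), dtype=np.uint8)
    lm[20, 5:36] = LIGAMENT
    lm[5:36, 20] = LIGAMENT
    out = F.skeleton_features(lm)
    assert out["skel_n_skeletons"] == 1
    assert out["skel_endpoints_mean"] == 4
    assert out["skel_branchpoints_mean"] == 1


def test_skeleton_ring_bounds_one_region():
    yy, xx = np.mgrid[0:60, 0:60]
    r2 = (yy - 30) ** 2 + (xx - 30) ** 2
    disk = r2 <= 20 ** 2
    ring = disk & (r2 >= 19 ** 2)   # outermost ring of the same disk
    lm = np.where(disk, FAT, 0).astype(np.uint8)
    lm[ring] = LIGAMENT
    out = F.skeleton_features(lm)
    assert out["skel_region_area_count"] == 1


def test_skeleton_empty_ligament():
    lm = np.full((20, 20), FAT, dtype=np.uint8)
    out = F.skeleton_features(lm)
    assert out["skel_n_skeletons"] == 0
    assert out["skel_endpoints_count"] == 0


# ---------------------------------------------------------------------------
# fractal

def test_box_dimension_plane_and_line():
    filled = np.ones((128, 128), dtype=bool)
    assert F.box_dimension(filled) == pytest.approx(2.0, abs=0.01)
    line = np.zeros((128, 128), dtype=bool)
    line[64, :] = True
    assert F.box_dimension(line) == pytest.approx(1.0, abs=0.05)


def test_lacunarity_uniform_and_sparse():
    filled = np.ones((64, 64), dtype=bool)
    for r in (2, 8, 32):
        assert F.lacunarity(filled, r) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    sparse = rng.random((64, 64)) < 0.01
    dense = rng.random((64, 64)) < 0.5
    assert F.lacunarity(sparse, 2) > F.lacunarity(dense, 2)


def test_fractal_empty_mask_is_missing():
    lm = np.zeros((32, 32), dtype=np.uint8)
    out = F.fractal_features(lm)
    assert np.isnan(out["frac_L_boxdim"])


# ---------------------------------------------------------------------------
# moments

def _L_mask(size=64):
    m = np.zeros((size, size), dtype=bool)
    m[10:40, 10:18] = True
    m[32:40, 10:34] = True
    return m


def test_moments_translation_invariance():
    m = _L_mask()
    lm1 = np.where(m, FAT, 0).astype(np.uint8)
    lm2 = np.roll(lm1, (7, 11), axis=(0, 1))
    img = (lm1 > 0).astype(np.uint8) * 90
    img2 = np.roll(img, (7, 11), axis=(0, 1))
    a = F.moment_features(img, lm1)
    b = F.moment_features(img2, lm2)
    for key in a:
        if any(t in key for t in ("_mu", "_nu", "_hu")):
            assert np.isclose(a[key], b[key], rtol=1e-9, atol=1e-12,
                              equal_nan=True), key
    assert a["mom_F_bin_m00"] == b["mom_F_bin_m00"]
    assert a["mom_F_bin_m10"] != b["mom_F_bin_m10"]  # raw moments do move


def test_moments_unit_square():
    lm = np.zeros((10, 10), dtype=np.uint8)
    lm[4:6, 4:6] = FAT
    img = (lm > 0).astype(np.uint8)
    out = F.moment_features(img, lm)
    assert out["mom_F_bin_m00"] == 4.0
    assert out["mom_F_bin_m10"] / out["mom_F_bin_m00"] == pytest.approx(4.5)
    assert out["mom_F_bin_m01"] / out["mom_F_bin_m00"] == pytest.approx(4.5)


def test_hu_rotation_invariance():
    m = _L_mask()
    lm1 = np.where(m, FAT, 0).astype(np.uint8)
    lm2 = np.where(np.rot90(m), FAT, 0).astype(np.uint8)
    img1 = m.astype(np.uint8) * 120
    img2 = np.rot90(img1)
    a = F.moment_features(img1, lm1)
    b = F.moment_features(img2, lm2)
    for i in range(1, 8):
        for w in ("bin", "wt"):
            key = f"mom_F_{w}_hu{i}"
            assert a[key] == pytest.approx(b[key], rel=1e-6), key


# ---------------------------------------------------------------------------
# fg ratio and full vector

def test_fg_ratio_toys():
    lm = np.zeros((20, 20), dtype=np.uint8)
    lm[:10] = FAT
    lm[10:] = GLANDULAR
    assert F.fg_ratio(lm) == pytest.approx(1.0)
    lm2 = np.zeros((20, 20), dtype=np.uint8)
    lm2.ravel()[:300] = FAT
    lm2.ravel()[300:400] = GLANDULAR
    assert F.fg_ratio(lm2) == pytest.approx(3.0)
    with pytest.warns(UserWarning):
        assert np.isnan(F.fg_ratio(np.zeros((5, 5), dtype=np.uint8)))


def test_fg_ratio_consistent_with_manifest(small_records, small_table):
    """Segmented F/G ratio tracks the generator's glandular fraction."""
    for rec in small_records:
        g = rec["glandular_fraction"]
        expected = (1 - g) / g
        got = small_table.loc[rec["filename"], "fg_ratio"]
        assert got == pytest.approx(expected, rel=0.05)


def test_extract_deterministic_and_aligned(small_records, registry):
    img = small_records[0]["image"]
    v1 = F.extract_features(img, registry)
    v2 = F.extract_features(img, registry)
    assert v1.shape == (len(registry),)
    assert np.array_equal(v1, v2, equal_nan=True)


def test_batch_table_stable_under_permutation(small_records, registry, small_table):
    """Per-image vectors do not depend on batch order."""
    subset = list(reversed(small_records[:4]))
    table = F.extract_table(((r["filename"], r["image"]) for r in subset),
                            registry)
    for rec in subset:
        a = table.loc[rec["filename"]].to_numpy()
        b = small_table.loc[rec["filename"]].to_numpy()
        assert np.array_equal(a, b, equal_nan=True)


def test_generated_features_mostly_finite(small_table):
    nan_frac = small_table.isna().to_numpy().mean()
    assert nan_frac < 0.02
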