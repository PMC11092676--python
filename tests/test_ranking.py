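"""Screening and ranking: memorization, Fréchet distance, PCA, KS metric."""

import numpy as np
import pandas as pd
import pytest

from phantombench import ranking as R
from phantombench.ranking import RankingConfig


# ---------------------------------------------------------------------------
# KS statistic and cosine distances

def test_ks_statistic_edge_cases():
    a = np.array([1.0, 2.0, 3.0])
    assert R.ks_statistic(a, a.copy()) == 0.0
    assert R.ks_statistic(a, a + 100.0) == 1.0
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=300), rng.normal(size=300)
    d = R.ks_statistic(x, y)
    assert 0.0 <= d <= 1.0
    assert d == R.ks_statistic(y, x)
    from scipy import stats
    assert d == pytest.approx(stats.ks_2samp(x, y).statistic)


def test_cosine_distance_identities():
    rng = np.random.default_rng(1)
    same = np.tile([[1.0, 2.0, 3.0]], (5, 1))
    d = R.cosine_distance_distribution(same, None, 100, rng)
    assert np.allclose(d, 0.0, atol=1e-12)
    ortho = np.array([[1.0, 0.0], [0.0, 1.0]])
    d = R.cosine_distance_distribution(ortho[:1].repeat(2, 0),
                                       ortho[1:].repeat(2, 0), 50, rng)
    assert np.allclose(d, 1.0)
    opp = np.array([[1.0, 0.0], [-1.0, 0.0]])
    d = R.cosine_distance_distribution(opp[:1].repeat(2, 0), opp[1:].repeat(2, 0),
                                       50, rng)
    assert np.allclose(d, 2.0)
    with pytest.raises(ValueError):
        R.cosine_distance_distribution(ortho[:1], None, 10, rng)


def test_baseline_pairs_exclude_identical_indices():
    rng = np.random.default_rng(2)
    pts = np.diag([1.0, 1.0, 1.0])  # orthogonal: identical pair iff distance 0
    d = R.cosine_distance_distribution(pts, None, 500, rng)
    assert (d > 0.5).all()


# ---------------------------------------------------------------------------
# Fréchet distance

def test_frechet_identical_sets_is_zero():
    rng = np.random.default_rng(3)
    e = rng.normal(size=(500, 8))
    assert R.frechet_distance(e, e.copy()) == pytest.approx(0.0, abs=1e-8)


def test_frechet_univariate_gaussian_shift():
    rng = np.random.default_rng(4)
    a = rng.normal(0.0, 1.0, size=(100_000, 1))
    b = rng.normal(1.0, 1.0, size=(100_000, 1))
    assert R.frechet_distance(a, b) == pytest.approx(1.0, abs=0.05)


def test_frechet_diagonal_gaussian_closed_form():
    rng = np.random.default_rng(5)
    mu1, mu2 = np.array([0.0, 2.0, -1.0]), np.array([1.0, 0.0, -1.0])
    v1, v2 = np.array([1.0, 4.0, 0.5]), np.array([2.0, 1.0, 0.5])
    a = rng.normal(mu1, np.sqrt(v1), size=(200_000, 3))
    b = rng.normal(mu2, np.sqrt(v2), size=(200_000, 3))
    closed = ((mu1 - mu2) ** 2).sum() + ((np.sqrt(v1) - np.sqrt(v2)) ** 2).sum()
    assert R.frechet_distance(a, b) == pytest.approx(closed, rel=0.02)


def test_frechet_symmetry_and_nonfinite_error():
    rng = np.random.default_rng(6)
    a, b = rng.normal(size=(200, 5)), rng.normal(1.0, 2.0, size=(300, 5))
    assert R.frechet_distance(a, b) == pytest.approx(R.frechet_distance(b, a))
    bad = a.copy()
    bad[3, 2] = np.nan
    with pytest.raises(ValueError, match="rows"):
        R.frechet_distance(bad, b)


def test_random_projection_embedder_deterministic():
    embed = R.random_projection_embedder(seed=9)
    imgs = np.random.default_rng(0).integers(0, 255, (4, 64, 64)).astype(np.uint8)
    e1 = embed(imgs)
    e2 = R.random_projection_embedder(seed=9)(imgs)
    assert np.array_equal(e1, e2)
    assert e1.shape == (4, 64)


# ---------------------------------------------------------------------------
# PCA space

def test_pc_space_projection_variance_identity():
    rng = np.random.default_rng(7)
    table = pd.DataFrame(rng.normal(size=(200, 6)) @ rng.normal(size=(6, 6)),
                         columns=list("abcdef"))
    model = R.fit_pc_space(table, n_components=4)
    proj = model.project(table)
    assert np.allclose(proj.var(axis=0, ddof=1), model.explained_variance,
                       rtol=1e-8)
    assert np.allclose(model.components @ model.components.T, np.eye(4),
                       atol=1e-10)


def test_pc_space_known_covariance_eigenvectors():
    """3-feature toy with analytic principal axes."""
    rng = np.random.default_rng(8)
    # independent latent scales along known orthonormal axes
    u = np.array([[1, 1, 0], [1, -1, 0], [0, 0, 1]]) / np.sqrt([2, 2, 1])[:, None]
    z = rng.normal(size=(50_000, 3)) * np.array([5.0, 2.0, 1.0])
    x = z @ u
    x = (x - x.mean(0)) / x.std(0)  # model standardizes; compare in z-space
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)          # independent oracle
    order = np.argsort(evals)[::-1]
    table = pd.DataFrame(x, columns=list("abc"))
    model = R.fit_pc_space(table, n_components=3)
    for i in range(3):
        cos = abs(model.components[i] @ evecs[:, order[i]])
        assert cos == pytest.approx(1.0, abs=1e-3)


def test_pc_space_handles_duplicate_and_constant_columns():
    rng = np.random.default_rng(9)
    base = rng.normal(size=(50, 3))
    table = pd.DataFrame(np.column_stack([base, base[:, 0], np.ones(50)]),
                         columns=list("abcde"))
    model = R.fit_pc_space(table, n_components=2)
    assert model.kept.sum() == 4  # constant column dropped, duplicate kept
    proj = model.project(table)
    assert np.isfinite(proj).all()


def test_pc_space_imputes_with_training_means():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                          "b": [2.0, np.nan, 4.0, 6.0, 1.0, 5.0]})
    model = R.fit_pc_space(table, n_components=1)
    assert model.impute[1] == pytest.approx(np.nanmean(table["b"]))
    new = pd.DataFrame({"a": [np.nan], "b": [np.nan]})
    assert np.isfinite(model.project(new)).all()


def test_pc_space_requires_enough_images():
    table = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 8)))
    table.columns = [str(c) for c in table.columns]
    with pytest.raises(ValueError):
        R.fit_pc_space(table, n_components=10)


# ---------------------------------------------------------------------------
# memorization

@pytest.fixture(scope="module")
def mask_bank(small_records_module):
    recs = small_records_module
    imgs = [r["image"] for r in recs]
    masks = R.boundary_masks(imgs)
    return masks, (recs[0]["image"].shape[0], recs[0]["image"].shape[1])


@pytest.fixture(scope="module")
def small_records_module():
    from phantombench.phantom import GeneratorConfig, iter_ensemble
    cfg = GeneratorConfig(image_size=128, n_images=40, seed=77)
    return list(iter_ensemble(cfg))


def test_planted_copies_all_flagged(mask_bank):
    masks, shape = mask_bank
    rep = R.memorization_measure(masks[:8], masks, shape, prefilter_top=10)
    assert rep.n_flagged == 8
    assert np.allclose(rep.measures, 1.0, atol=1e-5)
    assert np.array_equal(rep.best_match, np.arange(8))


def test_disjoint_masks_correlate_nonpositively():
    a = np.zeros(100, dtype=np.float32)
    b = np.zeros(100, dtype=np.float32)
    a[:20] = 1
    b[50:70] = 1
    r, _ = R._pearson_max(a, b[None, :])
    assert r <= 0


def test_prefilter_equals_exhaustive(mask_bank):
    masks, shape = mask_bank
    pre = R.memorization_measure(masks[:12], masks[12:], shape, prefilter_top=10)
    full = R.memorization_measure(masks[:12], masks[12:], shape, prefilter_top=None)
    assert np.allclose(pre.measures, full.measures, atol=1e-6)
    assert np.array_equal(pre.best_match, full.best_match)


def test_calibration_rule_and_bounds(mask_bank):
    masks, shape = mask_bank
    rng = np.random.default_rng(0)
    thr, record = R.calibrate_memorization_threshold(
        masks, shape, n_holdout=10, rng=rng, prefilter_top=None)
    assert thr == pytest.approx(record["max"] + record["sd"])
    assert thr >= record["max"]
    assert thr < 1.0  # random layouts contain no duplicates


def test_calibration_degenerate_identical_ensemble():
    mask = np.zeros((1, 400), dtype=np.float32)
    mask[0, 100:140] = 1
    bank = np.repeat(mask, 12, axis=0)
    with pytest.warns(UserWarning):
        thr, record = R.calibrate_memorization_threshold(
            bank, (20, 20), n_holdout=4, rng=np.random.default_rng(1),
            prefilter_top=None)
    assert record["max"] == pytest.approx(1.0, abs=1e-6)
    assert thr == pytest.approx(1.0, abs=1e-5)


# ---------------------------------------------------------------------------
# ranking metric

def _toy_tables(n=80, p=12, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"f{i}" for i in range(p)]
    tr = pd.DataFrame(rng.normal(size=(n, p)) @ rng.normal(size=(p, p)),
                      columns=cols)
    ge = pd.DataFrame(rng.normal(size=(n, p)) @ rng.normal(size=(p, p)),
                      columns=cols)
    return tr, ge


def test_ranking_metric_null_vs_gross_shift():
    tr, _ = _toy_tables(n=120, seed=3)
    half_a, half_b = tr.iloc[::2], tr.iloc[1::2]
    cfg = RankingConfig(n_pcs=5, n_pairs=500, n_boot=40, seed=0)
    null = R.ranking_metric(half_a, half_b, cfg)
    assert null.mean_ks < 0.2
    assert 0.0 <= null.ks_values.min() and null.ks_values.max() <= 1.0
    shifted = half_b + 200.0 * half_a.std()
    alt = R.ranking_metric(half_a, shifted, cfg)
    assert alt.mean_ks > null.mean_ks + 3.0 * null.sd_ks




def test_ranking_metric_monotone_under_graded_shift():
    tr, _ = _toy_tables(n=120, seed=4)
    half_a, half_b = tr.iloc[::2], tr.iloc[1::2]
    cfg = RankingConfig(n_pcs=5, n_pairs=500, n_boot=40, seed=1)
    scale = half_a.std()
    ks = [R.ranking_metric(half_a, half_b + lam * scale, cfg).mean_ks
          for lam in (0.0, 1.0, 4.0, 16.0)]
    assert ks == sorted(ks)


def test_bootstrap_sd_shrinks_with_pair_count():
    tr, _ = _toy_tables(n=200, seed=5)
    half_a, half_b = tr.iloc[::2], tr.iloc[1::2]
    sd = []
    for n_pairs in (200, 3200):
        cfg = RankingConfig(n_pcs=5, n_pairs=n_pairs, n_boot=60, seed=2)
        sd.append(R.ranking_metric(half_a, half_b, cfg).sd_ks)
    assert sd[1] < sd[0]


def test_ranking_metric_rejects_mismatched_registries():
    tr, ge = _toy_tables()
    with pytest.raises(ValueError):
        R.ranking_metric(tr, ge.rename(columns={"f0": "x"}))


def test_public_metric_on_real_features(medium_table):
    """Public (nine-feature) metric: near zero on a split-half null."""
    tr, ge = medium_table.iloc[::2], medium_table.iloc[1::2]
    cfg = RankingConfig(n_pcs=10, n_pairs=1000, n_boot=30, seed=0)
    res = R.public_metric(tr, ge, cfg)
    assert res.mean_ks < 0.2
    assert res.config.n_pcs == 9  # truncated to the nine-feature subspace
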