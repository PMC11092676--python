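"""Two-stage evaluation: screening and the bootstrapped-KS ranking metric.

Stage 1 screens a generated ensemble for (a) memorization — the maximum
zero-lag correlation of each generated image's fat-glandular boundary mask
against every training boundary mask, flagged above a calibrated threshold
(default 0.9) — and (b) perceptual distance via the Fréchet distance between
Gaussian fits of ensemble embeddings (the embedder is pluggable).

Stage 2 ranks ensembles by distributional similarity in feature space:
PCA is fitted on training features, both ensembles are projected to the
top PCs (default 10), and the distribution of random train-generated cosine
distances is compared against the train-train baseline with the two-sample
Kolmogorov-Smirnov statistic, averaged over bootstrap replicates.  Lower
mean KS means a better rank.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA

from . import segmentation
from .features import FeatureRegistry, PUBLIC_METRIC_FEATURES, default_registry

# ---------------------------------------------------------------------------
# memorization

MEMORIZATION_THRESHOLD = 0.9


@dataclasses.dataclass
class MemorizationReport:
    measures: np.ndarray          # per generated image, in [0, 1]
    best_match: np.ndarray        # index of the best-matching training image
    flags: np.ndarray             # measure > threshold
    threshold: float
    calibration: dict | None = None

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def boundary_masks(images: Sequence[np.ndarray], dilation_radius: int = 2,
                   thresholds: segmentation.SegmentationThresholds | None = None,
                   ) -> np.ndarray:
    """Stacked, flattened fat-glandular boundary masks (n, H*W) as float32."""
    masks = []
    for img in images:
        lm = segmentation.segment(img, thresholds)
        masks.append(segmentation.fg_boundary_mask(lm, dilation_radius).ravel())
    return np.asarray(masks, dtype=np.float32)


def _pearson_max(query: np.ndarray, bank: np.ndarray,
                 bank_stats: tuple[np.ndarray, np.ndarray] | None = None,
                 candidates: np.ndarray | None = None,
                 ) -> tuple[float, int]:
    """Max zero-lag Pearson correlation of one flattened mask vs a mask bank."""
    n = query.size
    if bank_stats is None:
        means = bank.mean(axis=1)
        sds = bank.std(axis=1)
    else:
        means, sds = bank_stats
    qm = query.mean()
    qs = query.std()
    if qs == 0:
        return 0.0, -1
    idx = np.arange(bank.shape[0]) if candidates is None else candidates
    sub = bank[idx]
    cov = sub @ query / n - means[idx] * qm
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sds[idx] > 0, cov / (sds[idx] * qs), 0.0)
    best = int(np.argmax(corr))
    return float(corr[best]), int(idx[best])


def _pool4(flat_masks: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """4x max-pooled versions of flattened masks (prefilter resolution)."""
    h, w = shape
    h4, w4 = h // 4 * 4, w // 4 * 4
    m = flat_masks.reshape(-1, h, w)[:, :h4, :w4]
    pooled = m.reshape(-1, h4 // 4, 4, w4 // 4, 4).max(axis=(2, 4))
    return pooled.reshape(flat_masks.shape[0], -1)


def memorization_measure(gen_masks: np.ndarray, train_masks: np.ndarray,
                         image_shape: tuple[int, int],
                         threshold: float = MEMORIZATION_THRESHOLD,
                         prefilter_top: int = 50) -> MemorizationReport:
    """Per-generated-image maximum boundary-mask correlation and flags.

    For speed the training bank is prefiltered at 4x max-pooled resolution,
    keeping the ``prefilter_top`` candidates per query, which are then
    re-scored at full resolution.  Set ``prefilter_top=None`` (or larger
    than the bank) for exhaustive search.
    """
    n_train = train_masks.shape[0]
    use_prefilter = prefilter_top is not None and prefilter_top < n_train
    bank_stats = (train_masks.mean(axis=1), train_masks.std(axis=1))
    if use_prefilter:
        train_small = _pool4(train_masks, image_shape)
        small_stats = (train_small.mean(axis=1), train_small.std(axis=1))
        gen_small = _pool4(gen_masks, image_shape)

    measures = np.zeros(gen_masks.shape[0])
    best = np.full(gen_masks.shape[0], -1, dtype=int)
    for i, q in enumerate(gen_masks):
        if q.std() == 0:
            warnings.warn(f"generated image {i} has an empty tissue boundary")
            continue
        cand = None
        if use_prefilter:
            qs = gen_small[i]
            n = qs.size
            cov = train_small @ qs / n - small_stats[0] * qs.mean()
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(small_stats[1] > 0,
                                cov / (small_stats[1] * qs.std()), -np.inf)
            cand = np.argsort(corr)[-prefilter_top:]
        measures[i], best[i] = _pearson_max(q, train_masks, bank_stats, cand)
    measures = np.clip(measures, 0.0, 1.0)
    return MemorizationReport(measures=measures, best_match=best,
                              flags=measures > threshold, threshold=threshold)


def calibrate_memorization_threshold(train_masks: np.ndarray,
                                     image_shape: tuple[int, int],
                                     n_holdout: int = 3000,
                                     rng: np.random.Generator | None = None,
                                     prefilter_top: int = 50,
                                     ) -> tuple[float, dict]:
    """Threshold = max + 1 sd of held-out-vs-remainder measures.

    A random subset of the training bank is scored against the remainder as
    if it were generated; the returned threshold is the maximum observed
    measure plus one standard deviation of the held-out measures.
    """
    rng = rng or np.random.default_rng()
    n = train_masks.shape[0]
    if n <= n_holdout:
        raise ValueError("ensemble must be larger than the holdout")
    held = rng.choice(n, size=n_holdout, replace=False)
    rest = np.setdiff1d(np.arange(n), held)
    rep = memorization_measure(train_masks[held], train_masks[rest],
                               image_shape, prefilter_top=prefilter_top)
    mx = float(rep.measures.max())
    sd = float(rep.measures.std())
    if sd == 0:
        warnings.warn("degenerate calibration: zero spread, threshold = max")
    threshold = mx + sd
    record = {"max": mx, "sd": sd, "n_holdout": n_holdout,
              "threshold": threshold}
    return threshold, record


# ---------------------------------------------------------------------------
# Fréchet distance

FID_SCREEN_THRESHOLD = 30.0


def frechet_distance(emb_a: np.ndarray, emb_b: np.ndarray,
                     eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two embedding sets.

    ||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2}), with covariances
    regularized by ``eps`` on the diagonal.
    """
    for name, e in (("a", emb_a), ("b", emb_b)):
        bad = ~np.isfinite(np.asarray(e, dtype=float)).all(axis=1)
        if bad.any():
            raise ValueError(
                f"non-finite embeddings in set {name}, rows {np.flatnonzero(bad)[:10]}")
    mu1, mu2 = emb_a.mean(axis=0), emb_b.mean(axis=0)
    s1 = np.cov(emb_a, rowvar=False) + eps * np.eye(emb_a.shape[1])
    s2 = np.cov(emb_b, rowvar=False) + eps * np.eye(emb_b.shape[1])
    covmean = linalg.sqrtm(s1 @ s2)
    if np.iscomplexobj(covmean):
        imag = np.abs(covmean.imag).max()
        if imag > 1e-3:
            raise FloatingPointError(f"matrix sqrt has imaginary residue {imag:g}")
        covmean = covmean.real
    diff = mu1 - mu2
    return float(diff @ diff + np.trace(s1 + s2 - 2.0 * covmean))


def random_projection_embedder(dim: int = 64, pool: int = 8,
                               seed: int = 0) -> Callable[[np.ndarray], np.ndarray]:
    """Weight-free default embedder: mean-pooled pixels through a fixed
    seeded Gaussian projection.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    proj: dict[int, np.ndarray] = {}

    def embed(images: np.ndarray) -> np.ndarray:
        imgs = np.asarray(images, dtype=np.float64) / 255.0
        n, h, w = imgs.shape
        hp, wp = h // pool * pool, w // pool * pool
        pooled = imgs[:, :hp, :wp].reshape(n, hp // pool, pool, wp // pool, pool)
        pooled = pooled.mean(axis=(2, 4)).reshape(n, -1)
        d_in = pooled.shape[1]
        if d_in not in proj:
            proj[d_in] = rng.standard_normal((d_in, dim)) / np.sqrt(d_in)
        return pooled @ proj[d_in]

    return embed


# ---------------------------------------------------------------------------
# PCA space

@dataclasses.dataclass
class PCModel:
    """Training-fitted standardization + principal components."""

    feature_names: list[str]
    kept: np.ndarray              # bool mask of non-degenerate columns
    mean: np.ndarray              # per-kept-feature training mean
    scale: np.ndarray             # per-kept-feature training sd
    impute: np.ndarray            # training means for NaN imputation (all cols)
    components: np.ndarray        # (n_components, n_kept)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, table: pd.DataFrame, n_components: int | None = None
                ) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=float)
        x = np.where(np.isfinite(x), x, self.impute)
        z = (x[:, self.kept] - self.mean) / self.scale
        k = n_components or self.n_components
        return z @ self.components[:k].T


def fit_pc_space(train_table: pd.DataFrame,
                 n_components: int = 10) -> PCModel:
    """Standardize (training statistics only) and fit PCA.

    NaNs are imputed with training column means; zero-variance columns are
    dropped and recorded via the ``kept`` mask.
    """
    x = train_table.to_numpy(dtype=float)
    if x.shape[0] <= n_components:
        raise ValueError("fewer training images than requested components")
    impute = np.zeros(x.shape[1])
    finite = np.isfinite(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(np.where(finite, x, np.nan), axis=0)
    impute = np.where(np.isfinite(col_mean), col_mean, 0.0)
    x = np.where(finite, x, impute)
    sd = x.std(axis=0)
    kept = sd > 1e-12
    z = (x[:, kept] - x[:, kept].mean(axis=0)) / sd[kept]
    n_components = min(n_components, z.shape[1], z.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(z)
    return PCModel(
        feature_names=list(train_table.columns),
        kept=kept,
        mean=x[:, kept].mean(axis=0),
        scale=sd[kept],
        impute=impute,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# cosine distances and the KS ranking metric

def cosine_distance_distribution(points_a: np.ndarray,
                                 points_b: np.ndarray | None,
                                 n_pairs: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Random-pair cosine distances 1 - u.v/(|u||v|).

    With ``points_b=None`` the baseline is drawn from ``points_a`` using two
    distinct indices per pair.  Zero-norm draws are resampled with a warning.
    """
    a = np.asarray(points_a, dtype=float)
    b = a if points_b is None else np.asarray(points_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two points on each side")
    ia = rng.integers(0, a.shape[0], size=n_pairs)
    if points_b is None:
        ib = rng.integers(0, a.shape[0] - 1, size=n_pairs)
        ib[ib >= ia] += 1  # distinct index, uniform over the rest
    else:
        ib = rng.integers(0, b.shape[0], size=n_pairs)
    u, v = a[ia], b[ib]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu == 0) | (nv == 0)
    tries = 0
    while bad.any() and tries < 100:
        warnings.warn(f"resampling {int(bad.sum())} zero-norm pairs")
        ia2 = rng.integers(0, a.shape[0], size=int(bad.sum()))
        ib2 = rng.integers(0, b.shape[0], size=int(bad.sum()))
        u[bad], v[bad] = a[ia2], b[ib2]
        nu[bad] = np.linalg.norm(u[bad], axis=1)
        nv[bad] = np.linalg.norm(v[bad], axis=1)
        bad = (nu == 0) | (nv == 0)
        tries += 1
    return 1.0 - np.einsum("ij,ij->i", u, v) / (nu * nv)


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup CDF distance)."""
    a = np.sort(np.asarray(sample_a))
    b = np.sort(np.asarray(sample_b))
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / a.size
    cdf_b = np.searchsorted(b, allv, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


@dataclasses.dataclass
class RankingConfig:
    n_pcs: int = 10
    n_pairs: int = 10000
    n_boot: int = 1000
    seed: int = 0


@dataclasses.dataclass
class RankingResult:
    mean_ks: float
    sd_ks: float
    ks_values: np.ndarray
    baseline_sample: np.ndarray   # from the first replicate, for inspection
    cross_sample: np.ndarray
    config: RankingConfig
    family_metrics: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict)


def _ks_bootstrap(train_pts: np.ndarray, gen_pts: np.ndarray,
                  cfg: RankingConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ks_vals = np.empty(cfg.n_boot)
    first = (None, None)
    for b in range(cfg.n_boot):
        tr = train_pts[rng.integers(0, train_pts.shape[0], train_pts.shape[0])]
        ge = gen_pts[rng.integers(0, gen_pts.shape[0], gen_pts.shape[0])]
        base = cosine_distance_distribution(tr, None, cfg.n_pairs, rng)
        cross = cosine_distance_distribution(tr, ge, cfg.n_pairs, rng)
        ks_vals[b] = ks_statistic(base, cross)
        if b == 0:
            first = (base, cross)
    return ks_vals, first[0], first[1]


def ranking_metric(train_table: pd.DataFrame, gen_table: pd.DataFrame,
                   config: RankingConfig | None = None,
                   registry: FeatureRegistry | None = None,
                   per_family: bool = False) -> RankingResult:
    """Mean two-sample KS statistic between cosine-distance distributions.

    PCA is fitted on the training table only; both tables are projected to
    the top ``n_pcs`` components.  Each bootstrap replicate resamples images
    with replacement on both sides, then draws fresh baseline (train-train)
    and cross (train-generated) cosine-distance samples of ``n_pairs`` each.
    """
    cfg = config or RankingConfig()
    if list(train_table.columns) != list(gen_table.columns):
        raise ValueError("train and generated tables must share one registry")
    rng = np.random.default_rng(cfg.seed)
    model = fit_pc_space(train_table, n_components=cfg.n_pcs)
    tr = model.project(train_table)
    ge = model.project(gen_table)
    ks_vals, base, cross = _ks_bootstrap(tr, ge, cfg, rng)
    result = RankingResult(
        mean_ks=float(ks_vals.mean()), sd_ks=float(ks_vals.std()),
        ks_values=ks_vals, baseline_sample=base, cross_sample=cross,
        config=cfg)
    if per_family:
        registry = registry or default_registry()
        for fam in registry.families():
            names = [e.name for e in registry.entries if e.family == fam
                     and e.name in train_table.columns]
            if len(names) < 2:
                continue
            sub_cfg = dataclasses.replace(cfg, n_pcs=min(cfg.n_pcs, len(names)))
            sub = ranking_metric(train_table[names], gen_table[names], sub_cfg)
            result.family_metrics[fam] = (sub.mean_ks, sub.sd_ks)
    return result


def public_metric(train_table: pd.DataFrame, gen_table: pd.DataFrame,
                  config: RankingConfig | None = None) -> RankingResult:
    """The nine-feature public variant of the ranking metric.

    Uses only intensity-histogram and tissue-area derived features:
    per-tissue areas and mean intensities (F, G, S, L) plus the F/G ratio.
    """
    names = list(PUBLIC_METRIC_FEATURES)
    cfg = config or RankingConfig()
    cfg = dataclasses.replace(cfg, n_pcs=min(cfg.n_pcs, len(names)))
    return ranking_metric(train_table[names], gen_table[names], cfg)
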