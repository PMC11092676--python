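"""Class-based and artifact diagnostics for generated ensembles.

These analyses sit outside the ranking metric proper: breast-class
prevalence (via a glandularity rule), k-NN density and coverage in the
top-2 PC space (fidelity and diversity), the semivariogram of the
ensemble-mean image (ergodicity/diversity), and per-image artifact
detectors (boundary breaks via the convexity-perimeter ratio, disconnected
skeletons, background residue, ligament sticking, and the lacunarity
distribution of heterogeneous-class images).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist
from skimage import measure

from . import segmentation
from .features import lacunarity
from .phantom import (DEFAULT_CLASS_BANDS, FAT, GLANDULAR, LIGAMENT, CLASSES)

# ---------------------------------------------------------------------------
# class rule

def classify_by_glandularity(label_map: np.ndarray,
                             class_bands: dict | None = None) -> str:
    """Breast class from the glandular fraction g = G/(G+F).

    Rule-based stand-in for a learned breast-type classifier: class bands
    are left-closed and default to the generator's own bands.  An image with
    no glandular tissue is "fatty" (with a warning).
    """
    bands = class_bands or DEFAULT_CLASS_BANDS
    g = int(np.count_nonzero(label_map == GLANDULAR))
    f = int(np.count_nonzero(label_map == FAT))
    if g == 0:
        warnings.warn("no glandular tissue found; classifying as fatty")
        return "fatty"
    frac = g / (g + f)
    for cls in CLASSES:
        lo, hi = bands[cls]
        if lo <= frac < hi or (cls == "dense" and frac >= lo):
            return cls
    return "dense"  # pragma: no cover


def class_prevalence(classes: list[str]) -> dict[str, float]:
    n = len(classes)
    return {cls: classes.count(cls) / n for cls in CLASSES}


# ---------------------------------------------------------------------------
# density / coverage

@dataclasses.dataclass
class DensityCoverageResult:
    density: float
    coverage: float
    per_class: dict[str, tuple[float, float]]
    k: int


def _density_coverage_pair(real: np.ndarray, fake: np.ndarray, k: int
                           ) -> tuple[float, float]:
    d_rr = cdist(real, real)
    np.fill_diagonal(d_rr, np.inf)
    radii = np.sort(d_rr, axis=1)[:, k - 1]  # k-th nearest real neighbor
    d_fr = cdist(fake, real)  # (M, N)
    inside = d_fr <= radii[None, :]
    density = float(inside.sum() / (k * fake.shape[0]))
    coverage = float(inside.any(axis=0).mean())
    return density, coverage


def density_coverage(train_pts: np.ndarray, gen_pts: np.ndarray, k: int = 5,
                     train_classes: list[str] | None = None,
                     gen_classes: list[str] | None = None,
                     ) -> DensityCoverageResult:
    """k-NN manifold density (fidelity) and coverage (diversity).

    With NND_k(x) the distance from training point x to its k-th nearest
    training neighbor: density counts how often generated points fall inside
    the training balls, normalized by k per generated point; coverage is the
    fraction of training points whose ball captures at least one generated
    point.  Identical point sets give coverage 1 and density (k+1)/k.
    """
    train_pts = np.asarray(train_pts, dtype=float)
    gen_pts = np.asarray(gen_pts, dtype=float)
    if train_pts.shape[0] <= k:
        raise ValueError("need more than k training points")
    density, coverage = _density_coverage_pair(train_pts, gen_pts, k)
    per_class: dict[str, tuple[float, float]] = {}
    if train_classes is not None and gen_classes is not None:
        tc = np.asarray(train_classes)
        gc = np.asarray(gen_classes)
        for cls in CLASSES:
            tmask, gmask = tc == cls, gc == cls
            if tmask.sum() < k + 1 or gmask.sum() < 1:
                per_class[cls] = (np.nan, np.nan)
                continue
            per_class[cls] = _density_coverage_pair(
                train_pts[tmask], gen_pts[gmask], k)
    return DensityCoverageResult(density=density, coverage=coverage,
                                 per_class=per_class, k=k)


# ---------------------------------------------------------------------------
# semivariogram of the mean image

@dataclasses.dataclass
class SemivarianceResult:
    lags: np.ndarray
    gamma: np.ndarray
    sill: float
    tail_rel_slope: float
    support_fraction: float


def mean_image(images) -> np.ndarray:
    """Pixelwise mean over an iterable of equally sized images."""
    acc = None
    n = 0
    for img in images:
        a = np.asarray(img, dtype=np.float64)
        acc = a if acc is None else acc + a
        n += 1
    if n < 2:
        raise ValueError("need at least two images")
    return acc / n


def mean_image_semivariance(mean_img: np.ndarray, lag_max: int = 100,
                            n_pair_samples: int = 3000,
                            rng: np.random.Generator | None = None,
                            support_threshold: float = 1.0,
                            ) -> SemivarianceResult:
    """Isotropic empirical semivariogram of the ensemble-mean image.

    gamma(h) = 0.5 E[(z_p - z_q)^2] over sampled pixel pairs with both ends
    in the support (mean > ``support_threshold``) and |p - q| in
    [h - 0.5, h + 0.5).  The sill is the mean of gamma over the last
    quartile of lags; ``tail_rel_slope`` is the fitted slope of that tail
    relative to the sill (near 0 for an ergodic, position-free ensemble).
    """
    rng = rng or np.random.default_rng()
    z = np.asarray(mean_img, dtype=np.float64)
    support = z > support_threshold
    if not support.any():
        raise ValueError("empty support: mean image below threshold everywhere")
    coords = np.argwhere(support)
    lags = np.arange(1, lag_max + 1)
    gamma = np.full(lag_max, np.nan)
    h_idx, w_idx = z.shape
    for li, h in enumerate(lags):
        p = coords[rng.integers(0, len(coords), n_pair_samples)]
        ang = rng.uniform(0, 2 * np.pi, n_pair_samples)
        q = np.rint(p + np.stack([h * np.sin(ang), h * np.cos(ang)], axis=1)
                    ).astype(int)
        ok = (q[:, 0] >= 0) & (q[:, 0] < h_idx) & (q[:, 1] >= 0) & (q[:, 1] < w_idx)
        q = q[ok]
        p = p[ok]
        ok2 = support[q[:, 0], q[:, 1]]
        if ok2.sum() < 10:
            continue
        dz = z[p[ok2, 0], p[ok2, 1]] - z[q[ok2, 0], q[ok2, 1]]
        gamma[li] = 0.5 * np.mean(dz ** 2)

    tail = slice(3 * lag_max // 4, lag_max)
    tail_gamma = gamma[tail]
    tail_lags = lags[tail]
    good = np.isfinite(tail_gamma)
    sill = float(np.nanmean(tail_gamma)) if good.any() else np.nan
    if good.sum() >= 2 and sill > 0:
        slope = np.polyfit(tail_lags[good], tail_gamma[good], 1)[0]
        rel_slope = float(slope * lag_max / sill)
    else:
        rel_slope = np.nan
    return SemivarianceResult(lags=lags, gamma=gamma, sill=sill,
                              tail_rel_slope=rel_slope,
                              support_fraction=float(support.mean()))


# ---------------------------------------------------------------------------
# artifact detectors

CONVEXITY_FLAG_THRESHOLD = 0.9


def convexity_perimeter_ratio(mask: np.ndarray) -> float:
    """Convex-hull perimeter over marching-squares contour perimeter.

    Near 1 for convex breast outlines; below ~0.9 signals a broken or
    deeply indented boundary.  Discretization keeps the ratio within about
    2% of 1 even for a perfect disk.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.nan
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.nan
    contour = max(contours, key=lambda c: c.shape[0])
    # light circular smoothing removes the marching-squares staircase, which
    # would otherwise inflate the contour length of a smooth convex shape
    if contour.shape[0] > 15:
        win = 7
        kernel = np.ones(win) / win
        closed = np.vstack([contour[:-1], contour[:-1][:win]])
        sm = np.column_stack([
            np.convolve(closed[:, 0], kernel, mode="valid"),
            np.convolve(closed[:, 1], kernel, mode="valid")])
        contour = np.vstack([sm, sm[:1]])
    d = np.diff(contour, axis=0)
    contour_perim = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if contour_perim == 0:
        return np.nan
    try:
        hull = ConvexHull(contour)
    except QhullError:
        return np.nan
    return float(hull.area) / contour_perim  # 2-D ConvexHull.area = perimeter


@dataclasses.dataclass
class ArtifactReport:
    convexity_ratio: np.ndarray
    boundary_flags: np.ndarray
    n_skeletons: np.ndarray
    median_region_area: np.ndarray
    background_fraction: np.ndarray
    background_mean: np.ndarray
    background_sd: np.ndarray
    sticking_score: float
    train_sticking_score: float | None
    het_lacunarity: np.ndarray
    train_het_lacunarity: np.ndarray | None
    failures: list[int]


def _ligament_sticking(lig_masks: list[np.ndarray], n_pairs: int,
                       rng: np.random.Generator) -> float:
    """Mean pairwise zero-lag correlation of ligament masks."""
    flat = np.asarray([m.ravel() for m in lig_masks], dtype=np.float32)
    n = flat.shape[0]
    if n < 2:
        return np.nan
    means = flat.mean(axis=1)
    sds = flat.std(axis=1)
    all_pairs = n * (n - 1) // 2
    if all_pairs <= n_pairs:
        idx = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    else:
        idx = rng.integers(0, n, size=(n_pairs, 2))
        idx = idx[idx[:, 0] != idx[:, 1]]
    corrs = []
    d = flat.shape[1]
    for i, j in idx:
        if sds[i] == 0 or sds[j] == 0:
            continue
        cov = float(flat[i] @ flat[j]) / d - means[i] * means[j]
        corrs.append(cov / (sds[i] * sds[j]))
    return float(np.mean(corrs)) if corrs else np.nan


def artifact_scan(images, train_images=None, n_sticking_pairs: int = 1000,
                  rng: np.random.Generator | None = None,
                  thresholds: segmentation.SegmentationThresholds | None = None,
                  class_bands: dict | None = None) -> ArtifactReport:
    """Per-image and ensemble-level artifact indicators.

    Per image: convexity-perimeter ratio of the breast mask (flag < 0.9),
    disconnected-skeleton count and median ligament-bounded region area,
    and nonzero-background statistics.  Per ensemble: ligament-sticking
    score (mean pairwise ligament-mask correlation; near 1 means a shared,
    "stuck" ligament layout) and the lacunarity distribution of the
    glandular mask over images classified heterogeneous.  When a training
    ensemble is supplied its sticking score and lacunarity distribution are
    attached for reference.
    """
    rng = rng or np.random.default_rng()
    t = thresholds or segmentation.SegmentationThresholds()

    def scan_one_side(imgs):
        conv, nskel, medarea, bfrac, bmean, bsd = [], [], [], [], [], []
        lig_masks, het_lac, fails = [], [], []
        for i, img in enumerate(imgs):
            try:
                lm = segmentation.segment(img, t, require_foreground=True)
            except segmentation.NoBreastRegionError:
                fails.append(i)
                for acc in (conv, nskel, medarea, bfrac, bmean, bsd):
                    acc.append(np.nan)
                continue
            bmask = segmentation.breast_mask(lm)
            conv.append(convexity_perimeter_ratio(bmask))
            lig = lm == LIGAMENT
            lig_masks.append(lig)
            nlab = measure.label(lig, connectivity=2).max() if lig.any() else 0
            nskel.append(float(nlab))
            regions = measure.label(bmask & ~lig, connectivity=1)
            areas = np.bincount(regions[regions > 0])
            areas = areas[areas > 0]
            medarea.append(float(np.median(areas)) if len(areas) else np.nan)
            bg = np.asarray(img)[~bmask]
            nz = bg[bg > 0]
            bfrac.append(float(nz.size / bg.size) if bg.size else np.nan)
            bmean.append(float(nz.mean()) if nz.size else 0.0)
            bsd.append(float(nz.std()) if nz.size else 0.0)
            if classify_by_glandularity(lm, class_bands) == "heterogeneous":
                het_lac.append(lacunarity(lm == GLANDULAR, 8))
        return (np.asarray(conv), np.asarray(nskel), np.asarray(medarea),
                np.asarray(bfrac), np.asarray(bmean), np.asarray(bsd),
                lig_masks, np.asarray(het_lac), fails)

    (conv, nskel, medarea, bfrac, bmean, bsd,
     lig_masks, het_lac, fails) = scan_one_side(images)
    sticking = _ligament_sticking(lig_masks, n_sticking_pairs, rng)

    train_sticking = None
    train_het = None
    if train_images is not None:
        (_, _, _, _, _, _, tr_lig, tr_het, _) = scan_one_side(train_images)
        train_sticking = _ligament_sticking(tr_lig, n_sticking_pairs, rng)
        train_het = tr_het

    with np.errstate(invalid="ignore"):
        flags = conv < CONVEXITY_FLAG_THRESHOLD
    return ArtifactReport(
        convexity_ratio=conv, boundary_flags=flags, n_skeletons=nskel,
        median_region_area=medarea, background_fraction=bfrac,
        background_mean=bmean, background_sd=bsd,
        sticking_score=sticking, train_sticking_score=train_sticking,
        het_lacunarity=het_lac, train_het_lacunarity=train_het,
        failures=fails)
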