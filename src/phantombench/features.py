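"""Hand-crafted image features for ensemble comparison.

Six feature families are extracted per image, from individual tissues
(F fat, G glandular, S skin, L ligament) or the whole breast region (B):

* texture — gray-level co-occurrence (Haralick) statistics at 64 gray
  levels, plus first-order intensity statistics and 64-bin intensity
  histograms per tissue;
* morphology — shape descriptors per connected component of F and G and
  for the single B region;
* skeleton — connectivity statistics of the ligament network;
* fractal — box-counting dimension and gliding-box lacunarity (F, G, L);
* moments — raw/central/normalized/Hu image moments, binary and
  intensity-weighted (F, G, B);
* fg_ratio — the fat-to-glandular pixel ratio that drives breast class.

Features that yield several values per image (for example per-component
areas) are summarized by a fixed 8-statistic scheme: count, mean, standard
deviation, minimum, maximum, and the three quartiles (linear-interpolation
convention).  Missing values are encoded as NaN and never fabricated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.feature import graycomatrix
from skimage.morphology import skeletonize

from .phantom import FAT, GLANDULAR, SKIN, LIGAMENT
from .segmentation import SegmentationThresholds, segment, breast_mask

# ---------------------------------------------------------------------------
# registry scaffolding

SUMMARY_STATS = ("count", "mean", "sd", "min", "max", "q1", "q2", "q3")

GLCM_DISTANCES = (1, 2, 4, 8)
GLCM_ANGLES_DEG = (0, 45, 90, 135)
GLCM_LEVELS = 64
HARALICK_STATS = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_avg",
    "sum_var", "sum_entropy", "entropy", "diff_var", "diff_entropy",
    "imc1", "imc2", "mcc",
)

FIRST_ORDER_STATS = SUMMARY_STATS + ("skewness", "kurtosis", "energy", "hist_entropy")
TISSUE_SCOPES = ("F", "G", "S", "L", "B")
SCOPE_LABELS = {"F": FAT, "G": GLANDULAR, "S": SKIN, "L": LIGAMENT}

MORPH_METRICS = (
    "area", "perimeter", "hull_area", "hull_perimeter", "solidity",
    "convexity_perimeter", "eccentricity", "major_axis", "minor_axis",
    "orientation", "extent", "equiv_diameter", "circularity", "euler",
)

SKELETON_MULTI = ("endpoints", "branchpoints", "length",
                  "segment_length", "region_area")

FRACTAL_SIZES = (2, 4, 8, 16, 32, 64)
FRACTAL_SCOPES = ("F", "G", "L")

RAW_MOMENTS = ("m00", "m01", "m02", "m03", "m10",
               "m11", "m12", "m20", "m21", "m30")
CENTRAL_MOMENTS = ("mu02", "mu03", "mu11", "mu12", "mu20", "mu21", "mu30")
NORM_MOMENTS = tuple(m.replace("mu", "nu") for m in CENTRAL_MOMENTS)
HU_MOMENTS = tuple(f"hu{i}" for i in range(1, 8))
MOMENT_SCOPES = ("F", "G", "B")
MOMENT_WEIGHTINGS = ("bin", "wt")

#: The nine intensity-histogram / tissue-area features of the public metric:
#: per-tissue pixel counts (areas), per-tissue mean intensities, and the
#: fat-to-glandular ratio.
PUBLIC_METRIC_FEATURES = tuple(
    [f"tex_fo_{s}_count" for s in ("F", "G", "S", "L")]
    + [f"tex_fo_{s}_mean" for s in ("F", "G", "S", "L")]
    + ["fg_ratio"]
)


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str   # texture | morphology | skeleton | fractal | moments | fg_ratio
    scope: str    # F | G | S | L | B


@dataclasses.dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, versioned enumeration of all extracted features."""

    entries: tuple[FeatureSpec, ...]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def version(self) -> str:
        h = hashlib.sha1("\n".join(self.names).encode()).hexdigest()
        return h[:12]

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, names: Sequence[str] | None = None,
               family: str | None = None) -> "FeatureRegistry":
        if names is not None:
            wanted = set(names)
            entries = tuple(e for e in self.entries if e.name in wanted)
            missing = wanted - {e.name for e in entries}
            if missing:
                raise KeyError(f"unknown feature names: {sorted(missing)}")
        else:
            entries = tuple(e for e in self.entries if e.family == family)
            if not entries:
                raise KeyError(f"no features in family {family!r}")
        return FeatureRegistry(entries)

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.family, None)
        return list(seen)

    def manifest(self) -> dict:
        return {
            "version": self.version,
            "n_features": len(self),
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }


def _texture_names() -> Iterable[FeatureSpec]:
    for d in GLCM_DISTANCES:
        for a in GLCM_ANGLES_DEG:
            for s in HARALICK_STATS:
                yield FeatureSpec(f"tex_glcm_{s}_d{d}_a{a}", "texture", "B")
        for s in HARALICK_STATS:
            yield FeatureSpec(f"tex_glcm_{s}_d{d}_amean", "texture", "B")
    for scope in TISSUE_SCOPES:
        for s in FIRST_ORDER_STATS:
            yield FeatureSpec(f"tex_fo_{scope}_{s}", "texture", scope)
    for scope in TISSUE_SCOPES:
        for b in range(GLCM_LEVELS):
            yield FeatureSpec(f"tex_hist_{scope}_b{b:02d}", "texture", scope)


def _morphology_names() -> Iterable[FeatureSpec]:
    for scope in ("F", "G"):
        for m in MORPH_METRICS:
            for s in SUMMARY_STATS:
                yield FeatureSpec(f"morph_{scope}_{m}_{s}", "morphology", scope)
    for m in MORPH_METRICS:
        yield FeatureSpec(f"morph_B_{m}", "morphology", "B")


def _skeleton_names() -> Iterable[FeatureSpec]:
    yield FeatureSpec("skel_n_skeletons", "skeleton", "L")
    for m in SKELETON_MULTI:
        for s in SUMMARY_STATS:
            yield FeatureSpec(f"skel_{m}_{s}", "skeleton", "L")


def _fractal_names() -> Iterable[FeatureSpec]:
    for scope in FRACTAL_SCOPES:
        yield FeatureSpec(f"frac_{scope}_boxdim", "fractal", scope)
        for r in FRACTAL_SIZES:
            yield FeatureSpec(f"frac_{scope}_lac_r{r}", "fractal", scope)
        yield FeatureSpec(f"frac_{scope}_lac_mean", "fractal", scope)


def _moment_names() -> Iterable[FeatureSpec]:
    for scope in MOMENT_SCOPES:
        for w in MOMENT_WEIGHTINGS:
            for m in RAW_MOMENTS + CENTRAL_MOMENTS + NORM_MOMENTS + HU_MOMENTS:
                yield FeatureSpec(f"mom_{scope}_{w}_{m}", "moments", scope)


def default_registry() -> FeatureRegistry:
    entries = (
        list(_texture_names()) + list(_morphology_names())
        + list(_skeleton_names()) + list(_fractal_names())
        + list(_moment_names())
        + [FeatureSpec("fg_ratio", "fg_ratio", "B")]
    )
    return FeatureRegistry(tuple(entries))


# ---------------------------------------------------------------------------
# summarization

def summarize(values: np.ndarray) -> dict[str, float]:
    """Apply the fixed 8-statistic summary; empty input keeps only the count."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    out: dict[str, float] = {"count": float(v.size)}
    if v.size == 0:
        for s in SUMMARY_STATS[1:]:
            out[s] = np.nan
        return out
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    out.update(mean=float(v.mean()), sd=float(v.std()),
               min=float(v.min()), max=float(v.max()),
               q1=float(q1), q2=float(q2), q3=float(q3))
    return out


# ---------------------------------------------------------------------------
# texture

def _haralick_from_glcm(p: np.ndarray) -> dict[str, float]:
    """The 14 classical co-occurrence statistics from one normalized GLCM."""
    eps = 1e-12
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sx = math.sqrt(max(((i - mux) ** 2 * px).sum(), 0.0))
    sy = math.sqrt(max(((i - muy) ** 2 * py).sum(), 0.0))

    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(),
                       minlength=2 * n - 1)
    pdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(),
                        minlength=n)
    ks = np.arange(psum.size, dtype=float)
    kd = np.arange(pdiff.size, dtype=float)

    asm = float((p ** 2).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    corr = float(((ii * jj * p).sum() - mux * muy) / (sx * sy)) \
        if sx > 0 and sy > 0 else np.nan
    variance = float(((ii - mux) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((ks * psum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * psum).sum())
    sum_entropy = float(-(psum * np.log(psum + eps)).sum())
    entropy = float(-(p * np.log(p + eps)).sum())
    mud = float((kd * pdiff).sum())
    diff_var = float(((kd - mud) ** 2 * pdiff).sum())
    diff_entropy = float(-(pdiff * np.log(pdiff + eps)).sum())

    hx = float(-(px * np.log(px + eps)).sum())
    hy = float(-(py * np.log(py + eps)).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(p * np.log(pxy + eps)).sum())
    hxy2 = float(-(pxy * np.log(pxy + eps)).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else np.nan
    imc2 = float(math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of the 2nd eigenvalue of Q
    keep = px > eps
    if keep.sum() >= 2:
        pk = p[np.ix_(keep, keep)]
        pxk = px[keep]
        pyk = py[keep]
        q = (pk / pxk[:, None]) @ (pk / pyk[:, None]).T
        try:
            ev = np.sort(np.abs(np.linalg.eigvals(q)))
            mcc = float(math.sqrt(max(0.0, min(1.0, ev[-2]))))
        except np.linalg.LinAlgError:  # pragma: no cover
            mcc = np.nan
    else:
        mcc = np.nan

    return dict(asm=asm, contrast=contrast, correlation=corr, variance=variance,
                idm=idm, sum_avg=sum_avg, sum_var=sum_var,
                sum_entropy=sum_entropy, entropy=entropy, diff_var=diff_var,
                diff_entropy=diff_entropy, imc1=imc1, imc2=imc2, mcc=mcc)


def texture_features(image: np.ndarray, label_map: np.ndarray) -> dict[str, float]:
    """Co-occurrence, first-order, and histogram texture features.

    Co-occurrence matrices are computed on the whole breast region only
    (pixel pairs with both ends in the foreground), with intensities binned
    to 64 gray levels, at distances {1, 2, 4, 8} and the four principal
    angles, symmetric and normalized.  The per-distance angular mean of each
    statistic is also reported.
    """
    out: dict[str, float] = {}
    fg = breast_mask(label_map)
    binned = (image.astype(np.int32) * GLCM_LEVELS) // 256
    coded = np.where(fg, binned + 1, 0).astype(np.uint8)

    angles = [math.radians(a) for a in GLCM_ANGLES_DEG]
    glcm = graycomatrix(coded, distances=list(GLCM_DISTANCES), angles=angles,
                        levels=GLCM_LEVELS + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(float)  # drop background level
    for di, d in enumerate(GLCM_DISTANCES):
        per_angle: dict[str, list[float]] = {s: [] for s in HARALICK_STATS}
        for ai, a in enumerate(GLCM_ANGLES_DEG):
            mat = glcm[:, :, di, ai]
            tot = mat.sum()
            if tot <= 0:
                stats = {s: np.nan for s in HARALICK_STATS}
            else:
                stats = _haralick_from_glcm(mat / tot)
            for s in HARALICK_STATS:
                out[f"tex_glcm_{s}_d{d}_a{a}"] = stats[s]
                per_angle[s].append(stats[s])
        for s in HARALICK_STATS:
            vals = np.asarray(per_angle[s], dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[f"tex_glcm_{s}_d{d}_amean"] = float(np.nanmean(vals)) \
                    if np.isfinite(vals).any() else np.nan

    for scope in TISSUE_SCOPES:
        mask = fg if scope == "B" else (label_map == SCOPE_LABELS[scope])
        vals = image[mask].astype(float)
        summ = summarize(vals)
        if vals.size:
            hist = np.bincount((vals.astype(np.int64) * GLCM_LEVELS) // 256,
                               minlength=GLCM_LEVELS).astype(float)
            prob = hist / hist.sum()
            centered = vals - vals.mean()
            sd = vals.std()
            summ["skewness"] = float((centered ** 3).mean() / sd ** 3) if sd > 0 else 0.0
            summ["kurtosis"] = float((centered ** 4).mean() / sd ** 4) if sd > 0 else 0.0
            summ["energy"] = float((prob ** 2).sum())
            summ["hist_entropy"] = float(-(prob * np.log(prob + 1e-12)).sum())
        else:
            prob = np.full(GLCM_LEVELS, np.nan)
            summ.update(skewness=np.nan, kurtosis=np.nan,
                        energy=np.nan, hist_entropy=np.nan)
        for s in FIRST_ORDER_STATS:
            out[f"tex_fo_{scope}_{s}"] = summ[s]
        for b in range(GLCM_LEVELS):
            out[f"tex_hist_{scope}_b{b:02d}"] = float(prob[b])
    return out


# ---------------------------------------------------------------------------
# morphology

def _hull_metrics(coords: np.ndarray) -> tuple[float, float]:
    """Convex-hull area and perimeter of a pixel set via its corner points."""
    corners = np.concatenate([
        coords + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))
    ])
    try:
        hull = ConvexHull(corners)
    except QhullError:  # pragma: no cover - corners are never collinear
        return np.nan, np.nan
    return float(hull.volume), float(hull.area)  # 2-D: volume=area, area=perimeter


def _boundary_coords(mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(mask)
    border = mask & ~inner
    if not border.any():
        border = mask
    return np.argwhere(border)


def _region_metrics(region: "measure._regionprops.RegionProperties",
                    offset: tuple[int, int] = (0, 0)) -> dict[str, float]:
    area = float(region.area)
    perim = float(region.perimeter)
    coords = region.coords.astype(float)
    if area > 400:
        sub = np.zeros(region.image.shape, dtype=bool)
        sub[region.image] = True
        coords = (_boundary_coords(sub)
                  + np.asarray(region.bbox[:2], dtype=float)).astype(float)
    hull_area, hull_perim = _hull_metrics(coords)
    return {
        "area": area,
        "perimeter": perim,
        "hull_area": hull_area,
        "hull_perimeter": hull_perim,
        "solidity": area / hull_area if hull_area > 0 else np.nan,
        "convexity_perimeter": hull_perim / perim if perim > 0 else np.nan,
        "eccentricity": float(region.eccentricity),
        "major_axis": float(region.axis_major_length),
        "minor_axis": float(region.axis_minor_length),
        "orientation": float(region.orientation),
        "extent": float(region.extent),
        "equiv_diameter": float(region.equivalent_diameter_area),
        "circularity": 4 * math.pi * area / perim ** 2 if perim > 0 else np.nan,
        "euler": float(region.euler_number),
    }


def _mask_metric_table(mask: np.ndarray) -> dict[str, np.ndarray]:
    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels)
    table: dict[str, list[float]] = {m: [] for m in MORPH_METRICS}
    for r in regions:
        metrics = _region_metrics(r)
        for m in MORPH_METRICS:
            table[m].append(metrics[m])
    return {m: np.asarray(v, dtype=float) for m, v in table.items()}


def morphology_features(label_map: np.ndarray) -> dict[str, float]:
    """Per-component shape statistics for F and G, direct values for B."""
    out: dict[str, float] = {}
    for scope, lbl in (("F", FAT), ("G", GLANDULAR)):
        table = _mask_metric_table(label_map == lbl)
        for m in MORPH_METRICS:
            summ = summarize(table[m])
            for s in SUMMARY_STATS:
                out[f"morph_{scope}_{m}_{s}"] = summ[s]
    bmask = breast_mask(label_map)
    if bmask.any():
        labels = measure.label(bmask, connectivity=2)
        regions = measure.regionprops(labels)
        big = max(regions, key=lambda r: r.area)
        metrics = _region_metrics(big)
    else:
        metrics = {m: np.nan for m in MORPH_METRICS}
    for m in MORPH_METRICS:
        out[f"morph_B_{m}"] = metrics[m]
    return out


# ---------------------------------------------------------------------------
# skeleton

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def skeleton_features(label_map: np.ndarray) -> dict[str, float]:
    """Connectivity statistics of the ligament network.

    The ligament mask is defensively re-skeletonized to 1-px width.
    Endpoints have exactly one 8-neighbor; branch points are 8-connected
    clusters of pixels with three or more neighbors (a junction wider than
    one pixel counts once).  Bounded regions are the connected components of
    the breast region with ligament pixels removed.
    """
    lig = np.asarray(label_map) == LIGAMENT
    skel = skeletonize(lig) if lig.any() else lig
    out: dict[str, float] = {}

    if skel.any():
        labels = measure.label(skel, connectivity=2)
        n = int(labels.max())
        nbrs = ndimage.convolve(skel.astype(np.int8), _NEIGHBOR_KERNEL,
                                mode="constant")
        endpoints = skel & (nbrs == 1)
        branchpts = skel & (nbrs >= 3)
        ep = np.bincount(labels[endpoints], minlength=n + 1)[1:].astype(float)
        bp_clusters = measure.label(branchpts, connectivity=2)
        bp = np.zeros(n, dtype=float)
        for region in measure.regionprops(bp_clusters):
            y, x = region.coords[0]
            bp[labels[y, x] - 1] += 1
        lengths = np.bincount(labels[skel], minlength=n + 1)[1:].astype(float)
        seg_labels = measure.label(skel & ~branchpts, connectivity=2)
        seg_lengths = np.bincount(seg_labels[seg_labels > 0]).astype(float)
        seg_lengths = seg_lengths[seg_lengths > 0]
    else:
        n = 0
        ep = bp = lengths = seg_lengths = np.empty(0)

    fg = breast_mask(label_map)
    regions = measure.label(fg & ~lig, connectivity=1)
    areas = np.bincount(regions[regions > 0]).astype(float)
    areas = areas[areas > 0]

    out["skel_n_skeletons"] = float(n)
    for name, vals in zip(SKELETON_MULTI, (ep, bp, lengths, seg_lengths, areas)):
        summ = summarize(vals)
        for s in SUMMARY_STATS:
            out[f"skel_{name}_{s}"] = summ[s]
    return out


# ---------------------------------------------------------------------------
# fractal

def box_dimension(mask: np.ndarray,
                  sizes: Sequence[int] = FRACTAL_SIZES) -> float:
    """Box-counting dimension: LS slope of log N(r) against log(1/r).

    The box grid is anchored at the array origin (no offset averaging).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.nan
    counts = []
    for r in sizes:
        h = int(np.ceil(mask.shape[0] / r)) * r
        w = int(np.ceil(mask.shape[1] / r)) * r
        padded = np.zeros((h, w), dtype=bool)
        padded[:mask.shape[0], :mask.shape[1]] = mask
        blocks = padded.reshape(h // r, r, w // r, r).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    counts = np.asarray(counts, dtype=float)
    if (counts >= 2).sum() == 0 and counts.max() < 2:
        return np.nan
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(counts), 1)[0]
    return float(slope)


def lacunarity(mask: np.ndarray, size: int) -> float:
    """Gliding-box lacunarity 1 + var(mass)/mean(mass)^2 at one box size.

    Boxes glide with unit stride inside the bounding box of the mask, so a
    filled rectangular mask has lacunarity exactly 1 at every size.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.nan
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sub = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].astype(np.float64)
    if size > min(sub.shape):
        return np.nan
    ii = np.pad(sub, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    masses = (ii[size:, size:] - ii[:-size, size:]
              - ii[size:, :-size] + ii[:-size, :-size])
    mean = masses.mean()
    if mean <= 0:
        return np.nan
    return float(1.0 + masses.var() / mean ** 2)


def fractal_features(label_map: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    for scope in FRACTAL_SCOPES:
        mask = np.asarray(label_map) == SCOPE_LABELS[scope]
        out[f"frac_{scope}_boxdim"] = box_dimension(mask)
        lacs = []
        for r in FRACTAL_SIZES:
            val = lacunarity(mask, r)
            out[f"frac_{scope}_lac_r{r}"] = val
            lacs.append(val)
        lacs = np.asarray(lacs, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[f"frac_{scope}_lac_mean"] = float(np.nanmean(lacs)) \
                if np.isfinite(lacs).any() else np.nan
    return out


# ---------------------------------------------------------------------------
# moments

def _moment_set(arr: np.ndarray) -> dict[str, float]:
    m = measure.moments(arr, order=3)
    mu = measure.moments_central(arr, order=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = measure.moments_normalized(mu, order=3)
    hu = measure.moments_hu(nu)
    out = {}
    for name in RAW_MOMENTS:
        out[name] = float(m[int(name[1]), int(name[2])])
    for name in CENTRAL_MOMENTS:
        out[name] = float(mu[int(name[2]), int(name[3])])
    for name in NORM_MOMENTS:
        out[name] = float(nu[int(name[2]), int(name[3])])
    for i, name in enumerate(HU_MOMENTS):
        out[name] = float(hu[i])
    return out


def moment_features(image: np.ndarray, label_map: np.ndarray) -> dict[str, float]:
    """Raw, central, normalized and Hu moments (order <= 3) per scope.

    Each scope (F, G, B) is measured twice: on the binary mask and
    intensity-weighted (raw 8-bit values inside the mask, zero outside).
    """
    out: dict[str, float] = {}
    fg = breast_mask(label_map)
    for scope in MOMENT_SCOPES:
        mask = fg if scope == "B" else (label_map == SCOPE_LABELS[scope])
        for w in MOMENT_WEIGHTINGS:
            if not mask.any():
                vals = {m: np.nan
                        for m in RAW_MOMENTS + CENTRAL_MOMENTS + NORM_MOMENTS + HU_MOMENTS}
            else:
                arr = mask.astype(np.float64) if w == "bin" \
                    else np.where(mask, image, 0).astype(np.float64)
                vals = _moment_set(arr)
            for m, v in vals.items():
                out[f"mom_{scope}_{w}_{m}"] = v
    return out


# ---------------------------------------------------------------------------
# fat/glandular ratio and the full vector

def fg_ratio(label_map: np.ndarray) -> float:
    """Fat pixel count over glandular pixel count; NaN when G is empty."""
    g = int(np.count_nonzero(label_map == GLANDULAR))
    f = int(np.count_nonzero(label_map == FAT))
    if g == 0:
        warnings.warn("no glandular tissue: fat/glandular ratio is undefined")
        return np.nan
    return f / g


def extract_features(image: np.ndarray,
                     registry: FeatureRegistry | None = None,
                     thresholds: SegmentationThresholds | None = None,
                     label_map: np.ndarray | None = None) -> np.ndarray:
    """Segment an image (unless a label map is given) and extract all families.

    Returns values aligned to the registry order; per-family failures yield
    NaN blocks rather than aborting the vector.
    """
    registry = registry or default_registry()
    if label_map is None:
        label_map = segment(image, thresholds)
    values: dict[str, float] = {}
    values.update(texture_features(image, label_map))
    values.update(morphology_features(label_map))
    values.update(skeleton_features(label_map))
    values.update(fractal_features(label_map))
    values.update(moment_features(image, label_map))
    values["fg_ratio"] = fg_ratio(label_map)
    return np.asarray([values.get(n, np.nan) for n in registry.names])


def extract_table(images: Iterable[tuple[str, np.ndarray]],
                  registry: FeatureRegistry | None = None,
                  thresholds: SegmentationThresholds | None = None,
                  progress: Callable[[str], None] | None = None) -> pd.DataFrame:
    """Feature table (images x registry) from (name, image) pairs."""
    registry = registry or default_registry()
    rows, index = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, img in images:
            rows.append(extract_features(img, registry, thresholds))
            index.append(name)
            if progress is not None:
                progress(name)
    return pd.DataFrame(rows, index=index, columns=registry.names)
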