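"""Ensemble I/O, run configuration, feature caching, and the full pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import diagnostics, ranking, segmentation
from .features import default_registry, extract_table
from .ranking import RankingConfig

log = logging.getLogger("phantombench")

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class Ensemble:
    """A directory of equally sized 8-bit grayscale images, lexicographic order."""

    directory: str
    filenames: list[str]
    image_size: tuple[int, int]
    manifest: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.filenames)

    def load(self, name: str) -> np.ndarray:
        return np.asarray(Image.open(os.path.join(self.directory, name)))

    def images(self) -> Iterator[np.ndarray]:
        for name in self.filenames:
            yield self.load(name)

    def named_images(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in self.filenames:
            yield name, self.load(name)


def read_ensemble(directory: str) -> Ensemble:
    """Open an image directory; validates bit depth, mode, and size agreement.

    An optional ``manifest.csv`` is joined by filename.
    """
    exts = (".png", ".tif", ".tiff")
    names = sorted(f for f in os.listdir(directory)
                   if f.lower().endswith(exts))
    if not names:
        raise FileNotFoundError(f"no PNG/TIFF images in {directory}")
    size = None
    offenders = []
    for name in names:
        with Image.open(os.path.join(directory, name)) as im:
            if im.mode != "L":
                raise ValueError(f"{name}: expected 8-bit grayscale, got mode {im.mode}")
            if size is None:
                size = im.size
            elif im.size != size:
                offenders.append(name)
    if offenders:
        raise ValueError(f"mixed image sizes; offending files: {offenders[:10]}")
    manifest = None
    mpath = os.path.join(directory, "manifest.csv")
    if os.path.exists(mpath):
        manifest = pd.read_csv(mpath)
        manifest = manifest.set_index("filename").reindex(names).reset_index()
    return Ensemble(directory=directory, filenames=names,
                    image_size=(size[1], size[0]), manifest=manifest)


@dataclasses.dataclass
class RunConfig:
    """Full-pipeline configuration; serialized alongside every report."""

    train_dir: str = ""
    gen_dir: str = ""
    cache_dir: str | None = None
    out_path: str | None = None
    n_pcs: int = 10
    n_pairs: int = 10000
    n_boot: int = 1000
    k_neighbors: int = 5
    memorization_threshold: float = ranking.MEMORIZATION_THRESHOLD
    fid_threshold: float = ranking.FID_SCREEN_THRESHOLD
    boundary_dilation: int = 2
    semivariance_lag_max: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _dir_fingerprint(ens: Ensemble) -> str:
    h = hashlib.sha1()
    for name in ens.filenames:
        path = os.path.join(ens.directory, name)
        st = os.stat(path)
        h.update(f"{name}:{st.st_size}".encode())
    return h.hexdigest()[:16]


def cached_feature_table(ens: Ensemble, cache_dir: str | None = None,
                         registry=None) -> pd.DataFrame:
    """Feature table for an ensemble with an on-disk CSV cache.

    The cache key combines the registry version and a fingerprint of the
    directory contents, so edits or regeneration invalidate it.
    """
    registry = registry or default_registry()
    if cache_dir is None:
        return extract_table(ens.named_images(), registry)
    os.makedirs(cache_dir, exist_ok=True)
    key = f"features_{registry.version}_{_dir_fingerprint(ens)}.csv"
    path = os.path.join(cache_dir, key)
    if os.path.exists(path):
        log.info("feature cache hit: %s", path)
        return pd.read_csv(path, index_col=0)
    table = extract_table(ens.named_images(), registry)
    table.to_csv(path)
    return table


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_full_evaluation(config: RunConfig) -> dict:
    """Stage 1 (FID + memorization), stage 2 (KS metric), then diagnostics.

    Stage failures are recorded in the report; later independent stages are
    still attempted.  With a cache directory and fixed seed, reruns produce
    byte-identical reports.
    """
    logging.basicConfig(level=config.log_level)
    registry = default_registry()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "registry_version": registry.version,
        "errors": {},
    }
    train = read_ensemble(config.train_dir)
    gen = read_ensemble(config.gen_dir)

    # ---- stage 1
    try:
        embed = ranking.random_projection_embedder(seed=config.seed)
        tr_imgs = np.stack(list(train.images()))
        ge_imgs = np.stack(list(gen.images()))
        fid = ranking.frechet_distance(embed(tr_imgs), embed(ge_imgs))
        tr_masks = ranking.boundary_masks(tr_imgs,
                                          dilation_radius=config.boundary_dilation)
        ge_masks = ranking.boundary_masks(ge_imgs,
                                          dilation_radius=config.boundary_dilation)
        mem = ranking.memorization_measure(
            ge_masks, tr_masks, train.image_size,
            threshold=config.memorization_threshold)
        report["stage1"] = {
            "fid": fid,
            "fid_threshold": config.fid_threshold,
            "fid_pass": bool(fid <= config.fid_threshold),
            "memorization_threshold": config.memorization_threshold,
            "n_memorized": mem.n_flagged,
            "memorization_pass": bool(mem.n_flagged == 0),
            "memorization_max": float(mem.measures.max()) if len(mem.measures) else None,
        }
        del tr_imgs, ge_imgs, tr_masks, ge_masks
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        log.exception("stage 1 failed")
        report["errors"]["stage1"] = repr(exc)

    # ---- stage 2
    try:
        train_feats = cached_feature_table(train, config.cache_dir, registry)
        gen_feats = cached_feature_table(gen, config.cache_dir, registry)
        cfg = RankingConfig(n_pcs=config.n_pcs, n_pairs=config.n_pairs,
                            n_boot=config.n_boot, seed=config.seed)
        res = ranking.ranking_metric(train_feats, gen_feats, cfg,
                                     registry=registry, per_family=True)
        pub = ranking.public_metric(train_feats, gen_feats, cfg)
        report["stage2"] = {
            "mean_ks": res.mean_ks, "sd_ks": res.sd_ks,
            "per_family": {k: {"mean_ks": v[0], "sd_ks": v[1]}
                           for k, v in res.family_metrics.items()},
            "public_metric": {"mean_ks": pub.mean_ks, "sd_ks": pub.sd_ks},
        }
    except Exception as exc:  # noqa: BLE001
        log.exception("stage 2 failed")
        report["errors"]["stage2"] = repr(exc)
        train_feats = gen_feats = None

    # ---- diagnostics
    try:
        diag: dict = {}
        if train_feats is not None:
            model = ranking.fit_pc_space(train_feats, n_components=2)
            tr2 = model.project(train_feats)
            ge2 = model.project(gen_feats)
            tr_cls = [diagnostics.classify_by_glandularity(segmentation.segment(im))
                      for im in train.images()]
            ge_cls = [diagnostics.classify_by_glandularity(segmentation.segment(im))
                      for im in gen.images()]
            dc = diagnostics.density_coverage(tr2, ge2, k=config.k_neighbors,
                                              train_classes=tr_cls,
                                              gen_classes=ge_cls)
            diag["prevalence"] = diagnostics.class_prevalence(ge_cls)
            diag["density"] = dc.density
            diag["coverage"] = dc.coverage
            diag["per_class"] = {c: {"density": v[0], "coverage": v[1]}
                                 for c, v in dc.per_class.items()}
        rng = np.random.default_rng(config.seed)
        sv = diagnostics.mean_image_semivariance(
            diagnostics.mean_image(gen.images()),
            lag_max=config.semivariance_lag_max, rng=rng)
        diag["semivariance"] = {"sill": sv.sill,
                                "tail_rel_slope": sv.tail_rel_slope}
        art = diagnostics.artifact_scan(gen.images(), train.images(), rng=rng)
        diag["artifacts"] = {
            "n_boundary_flags": int(np.nansum(art.boundary_flags)),
            "sticking_score": art.sticking_score,
            "train_sticking_score": art.train_sticking_score,
            "background_fraction_mean": float(np.nanmean(art.background_fraction)),
            "n_failures": len(art.failures),
        }
        report["diagnostics"] = diag
    except Exception as exc:  # noqa: BLE001
        log.exception("diagnostics failed")
        report["errors"]["diagnostics"] = repr(exc)

    report = _jsonable(report)
    if config.out_path:
        with open(config.out_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
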