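"""Shared fixtures: small seeded ensembles generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from phantombench.features import default_registry, extract_table
from phantombench.phantom import GeneratorConfig, iter_ensemble


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_records():
    """24 slices at 128 px with ground-truth layouts attached."""
    cfg = GeneratorConfig(image_size=128, n_images=24, seed=42)
    return list(iter_ensemble(cfg, with_layouts=True))


@pytest.fixture(scope="session")
def small_table(small_records, registry):
    return extract_table(
        ((r["filename"], r["image"]) for r in small_records), registry)


@pytest.fixture(scope="session")
def medium_records():
    """240 slices at 192 px — shared by ranking/diagnostics acceptance checks."""
    cfg = GeneratorConfig(image_size=192, n_images=240, seed=7)
    return list(iter_ensemble(cfg))


@pytest.fixture(scope="session")
def medium_table(medium_records, registry):
    return extract_table(
        ((r["filename"], r["image"]) for r in medium_records), registry)


@pytest.fixture(scope="session")
def marginal_records():
    """100 slices at 256 px with layouts, for intensity-marginal checks."""
    cfg = GeneratorConfig(image_size=256, n_images=100, seed=20)
    return list(iter_ensemble(cfg, with_layouts=True))


@pytest.fixture(scope="session")
def disk_mask():
    yy, xx = np.mgrid[0:100, 0:100]
    return (yy - 50) ** 2 + (xx - 50) ** 2 <= 40 ** 2
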