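"""Shared fixtures: pipeline configuration and pre-analysed synthetic suites."""

from __future__ import annotations

import numpy as np
import pytest

from maizecfi.imaging_io import Calibration, PipelineConfig
from maizecfi.pipeline import analyze_image
from maizecfi.synthetic_plants import default_suite

#: fixed seed for every suite-based test; the generator is seed-robust, this
#: just pins the exact plants the assertions run on
SUITE_SEED = 11


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def cal() -> Calibration:
    return Calibration(cm_per_px=0.05)


@pytest.fixture(scope="session")
def suite30():
    """The 30-plant graded benchmark suite (all tiers, incl. overlap)."""
    return default_suite(30, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def suite30_records(suite30, config):
    """Full-pipeline records for every suite plant, computed once."""
    return [
        analyze_image(img, config, plant_id=f"synth_{i:03d}")
        for i, (_, img, _) in enumerate(suite30)
    ]


@pytest.fixture(scope="session")
def nonoverlap(suite30, suite30_records):
    """(spec, image, truth, record) tuples for the non-overlapping tiers."""
    return [
        (spec, img, truth, rec)
        for (spec, img, truth), rec in zip(suite30, suite30_records)
        if truth.n_expanded_leaves < 8
    ]


@pytest.fixture(scope="session")
def overlap(suite30, suite30_records):
    """(spec, image, truth, record) tuples for the deliberate-overlap tier."""
    return [
        (spec, img, truth, rec)
        for (spec, img, truth), rec in zip(suite30, suite30_records)
        if truth.n_expanded_leaves == 8
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
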