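"""Shared fixtures: expensive simulated studies are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ibpforecast import learnable_study_config, simulate
from ibpforecast.classifier import SampleTable
from ibpforecast.pipeline import featurize_recordings
from ibpforecast.sampler import SamplerConfig


def _study_table(n_patients: int, seed: int, precursor_drop: float) -> SampleTable:
    cfgs = learnable_study_config(n_patients, seed=seed, precursor_drop=precursor_drop)
    recs = [simulate(c) for c in cfgs]
    table, _ = featurize_recordings(recs, SamplerConfig())
    return table


@pytest.fixture(scope="session")
def precursor_table() -> SampleTable:
    """Study with a 12 mmHg pre-episode MAP dip inside the observation window."""
    return _study_table(20, seed=1, precursor_drop=12.0)


@pytest.fixture(scope="session")
def null_table() -> SampleTable:
    """Signal-free study: episodes occur but nothing precedes them."""
    return _study_table(40, seed=1, precursor_drop=0.0)


@pytest.fixture(scope="session")
def boundary_table() -> SampleTable:
    """Study at the 8 mmHg detectability boundary (imperfect-classifier regime)."""
    return _study_table(40, seed=11, precursor_drop=8.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
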