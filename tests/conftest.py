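"""Shared fixtures: small synthetic montages, subjects and tabular data.

Everything is generated programmatically at collection time; no data files.
The reduced montage (27 channels, 128 Hz, 108 trials) keeps model fits cheap
while preserving the full structure of the design: 9 ROIs, 3 balanced loads,
3 s epochs, 1-40 Hz spectra.
"""

from __future__ import annotations

import numpy as np
import pytest

import grouprely as g

#: Reduced-montage study conditions used throughout the suite.
SMALL = dict(
    n_channels=27, srate=128.0, sessions=1, blocks_per_session=2
)


def small_config(seed: int = 0, **overrides) -> g.SimulationConfig:
    return g.SimulationConfig(**{**SMALL, **overrides, "seed": seed})


@pytest.fixture(scope="session")
def layout27() -> g.ChannelLayout:
    return g.hex_layout(27)


@pytest.fixture(scope="session")
def small_subject(layout27) -> g.TrialEpochs:
    """One reduced-montage subject with the default planted alpha effect."""
    return g.simulate_subject(small_config(seed=3), 0, layout=layout27)


@pytest.fixture(scope="session")
def small_features(small_subject) -> g.FeatureMatrix:
    return g.power_spectrum(small_subject, range(1, 41))


@pytest.fixture(scope="session")
def small_groups(small_features, layout27) -> g.GroupSpec:
    bands = g.band_groups(small_features.meta)
    rois = g.roi_groups(small_features.meta, layout27)
    return g.GroupSpec(
        groups={**bands.groups, **rois.groups},
        kinds={**bands.kinds, **rois.kinds},
        n_predictors=small_features.n_predictors,
    )


@pytest.fixture(scope="session")
def planted_tabular() -> tuple[g.FeatureMatrix, g.GroupSpec]:
    """300 trials, four 5-column groups, one informative (g1), effect 2."""
    return g.simulate_grouped_tabular(
        n=300, group_sizes=[5, 5, 5, 5], informative={"g1"}, effect=2.0,
        within_group_corr=0.3, n_classes=3, seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_rf():
    """A small, seeded tree ensemble; the production default is 5000 trees."""
    return g.random_forest_factory(n_trees=100, random_state=0)
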