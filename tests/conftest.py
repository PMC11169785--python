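"""Shared fixtures: small synthetic recordings and feature tables.

Everything is generated programmatically and seeded; session scope is
used for the expensive signal-level fixtures so multiple tests can
share them.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from ecogdecode.containers import BandTable, DEFAULT_BANDS, FeatureTable
from ecogdecode.synth import (BehaviorLabels, EffectMap, NoiseSpec,
                              make_labels, make_layout, synthesize_recording)

# fold-skip and degenerate-feature warnings are expected in edge-case
# tests; keep the output readable
logging.getLogger("ecogdecode").setLevel(logging.ERROR)


TWO_ROI_CENTROIDS = {"roiA": (0.0, 0.0, 0.0), "roiB": (40.0, 0.0, 0.0)}


@pytest.fixture(scope="session")
def two_roi_layout():
    return make_layout(3, TWO_ROI_CENTROIDS, jitter_sd=3.0, seed=11)


@pytest.fixture(scope="session")
def alternating_labels():
    """Deterministically alternating two-state block labels."""
    return make_labels(8, ("Talking", "WatchingTV"), persistence=0.0, seed=5)


@pytest.fixture(scope="session")
def clean_recording(two_roi_layout, alternating_labels):
    """16-minute, 6-channel recording with an alpha effect in roiA."""
    effects = EffectMap({("roiA", "alpha", "Talking"): 1.6})
    return synthesize_recording(
        two_roi_layout, alternating_labels, DEFAULT_BANDS, effects,
        NoiseSpec(noise_sd=5.0, drift_amplitude=10.0, seed=21), fs=500.0)


@pytest.fixture()
def feature_rng():
    return np.random.default_rng(2024)


def make_feature_table(n_bins: int, n_channels: int, rng,
                       effect_channels=(), effect_band: str = "alpha",
                       effect_size: float = 1.0, labels=None,
                       bands: BandTable = DEFAULT_BANDS) -> FeatureTable:
    """Feature-level synthetic table: lognormal-ish envelope means with
    an optional additive state effect on chosen channels/band."""
    values = rng.lognormal(mean=1.0, sigma=0.25,
                           size=(n_bins, n_channels, len(bands)))
    if labels is None:
        labels = np.array(["Talking" if (b // 12) % 2 == 0 else "WatchingTV"
                           for b in range(n_bins)], dtype=object)
    labels = np.asarray(labels, dtype=object)
    if effect_channels:
        k = bands.index(effect_band)
        talk = labels == "Talking"
        for c in effect_channels:
            values[talk, c, k] += effect_size
    positions = rng.normal(size=(n_channels, 3))
    return FeatureTable(values=values, bin_s=10.0, band_table=bands,
                        positions=positions, labels=labels)
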