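"""Shared fixtures: synthetic loci and simple layouts.

Everything is generated programmatically; no fixture files ship with the
package.
"""

from __future__ import annotations

import numpy as np
import pytest

import metalocus as ml
from metalocus.layout import GaudiLayout

HUB_BINS = tuple(range(60, 68))  # 8-bin planted hub
HUB_SEED = 3


@pytest.fixture(scope="session")
def hub_locus():
    """101-bin locus with one strong 8-bin hub (contacts x5, signal 50 vs 5)."""
    cm, sig, truth = ml.make_locus(
        seed=HUB_SEED, hubs=[ml.HubSpec(member_bins=HUB_BINS)])
    return cm, sig, truth


@pytest.fixture(scope="session")
def analyzed_hub(hub_locus):
    cm, sig, _ = hub_locus
    return ml.analyze_locus(cm, sig, ml.PipelineConfig(n_perm=999, seed=1))


@pytest.fixture(scope="session")
def null_locus():
    """Locus with no hub: decaying contacts, flat noisy signal."""
    cm, sig, truth = ml.make_locus(seed=11)
    return cm, sig, truth


def chain_layout(n: int, step: float = 1.0, bins=None) -> GaudiLayout:
    """A straight equally spaced chain layout (weights/statistics only)."""
    coords = np.column_stack([step * np.arange(n, dtype=float), np.zeros(n)])
    if bins is None:
        bins = np.arange(n)
    return GaudiLayout(region=None, bins=np.asarray(bins), coords=coords,
                       polygons=[], buffer_distance=1.5 * step, mean_step=step)


def random_layout(n: int, seed: int) -> GaudiLayout:
    """Random-walk chain layout: consecutive bins ~1 apart, so the
    3x-mean-step band stays local (as in a real embedded locus)."""
    rng = np.random.default_rng(seed)
    theta = np.cumsum(rng.normal(0.0, 0.9, size=n - 1))
    steps = (1.0 + 0.2 * rng.random(n - 1))[:, None] * \
        np.column_stack([np.cos(theta), np.sin(theta)])
    coords = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    mean_step = float(np.linalg.norm(np.diff(coords, axis=0), axis=1).mean())
    return GaudiLayout(region=None, bins=np.arange(n), coords=coords,
                       polygons=[], buffer_distance=1.5 * mean_step,
                       mean_step=mean_step)
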