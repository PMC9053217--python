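"""Shared fixtures: toy standardized grids and seeded phantom cohorts.

Experiments run on a scaled-down standardized grid (64 x 80 x 64 voxels at
3 x 2.8 x 3 mm) with the same world extent and stride structure as the full
192 x 224 x 192 / 1 mm grid, keeping every pipeline mechanism intact while
staying cheap on one CPU.  Expensive artifacts (cohorts, trained networks)
are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from ischeseg import netzoo
from ischeseg.phantomgen import PhantomSpec, generate_cohort, generate_subject
from ischeseg.pipeline import cohort_to_samples
from ischeseg.trainloop import TrainConfig, train
from ischeseg.volspace import GridSpec, Space

#: scaled-down standardized grid used throughout the suite
TOY_GRID = GridSpec(shape=(64, 80, 64), spacing=(3.0, 2.8, 3.0))


@pytest.fixture(scope="session")
def toy_grid() -> GridSpec:
    return TOY_GRID


@pytest.fixture(scope="session")
def toy_spec() -> PhantomSpec:
    """Base spec for phantoms generated directly on the standardized grid."""
    return PhantomSpec(shape=TOY_GRID.shape, spacing=TOY_GRID.spacing,
                       space=Space.IPMNI)


@pytest.fixture(scope="session")
def easy_subject(toy_spec):
    """One easy lesioned phantom: 10 ml, kappa_DWI 4, no artifacts."""
    spec = PhantomSpec(shape=toy_spec.shape, spacing=toy_spec.spacing,
                       space=toy_spec.space, lesion_volume_ml=10.0,
                       kappa_dwi=4.0, kappa_adc=0.5, seed=7)
    return generate_subject(spec)


@pytest.fixture(scope="session")
def control_cohort(toy_spec):
    """Ten lesion-free controls for template building."""
    return generate_cohort(10, 0, seed=11, base_spec=toy_spec)


@pytest.fixture(scope="session")
def training_cohort(toy_spec):
    """Twenty phantoms (6 controls + 14 lesioned, large/high-contrast)."""
    return generate_cohort(6, 14, seed=5, base_spec=toy_spec,
                           volume_range_ml=(8.0, 40.0),
                           kappa_dwi_range=(3.0, 5.0))


@pytest.fixture(scope="session")
def training_samples(training_cohort):
    """Preprocessed 3-channel training samples plus population templates."""
    samples, templates = cohort_to_samples(training_cohort, in_channels=3)
    return samples, templates


@pytest.fixture(scope="session")
def trained_dagmnet(training_samples):
    """A small DAGMNet trained for 30 epochs on the 20-phantom cohort."""
    samples, _ = training_samples
    net = netzoo.build_dagmnet(
        netzoo.NetworkConfig(nf=4, in_channels=3), seed=1)
    # lr 3e-3 for the reduced regime: ~150 Adam steps total, ~100x fewer
    # than full-scale training (see docs/methods.md)
    cfg = TrainConfig(lr=3e-3, max_epochs=30, early_stop_epoch=30,
                      snapshot_every=10, seed=3)
    result = train(net, samples, cfg)
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
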