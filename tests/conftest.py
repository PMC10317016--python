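"""Shared fixtures.

The expensive fixtures (trained detectors on the Lorenz63 study
conditions) are session-scoped and shared between the property tests and
the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import rctip
from rctip.readout import RidgeSpec
from rctip.systems import BenchmarkSpec, make_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_reservoir():
    return rctip.build_reservoir(rctip.ReservoirParams(n=20, seed=3), 3)


@pytest.fixture(scope="session")
def lorenz_study():
    """Trained detectors under the Lorenz63 study conditions.

    500 training runs of 1000 samples at dt=0.02 with sigma switching
    between two values drawn uniformly in [5, 15]; the regression and
    classification detectors share the reservoir, scaler and features.
    """
    spec = RidgeSpec(0.1)
    train = make_benchmark(BenchmarkSpec("lorenz63", 500, "train", 1000, seed=101))
    scaler = rctip.fit_scaler(train)
    res = rctip.build_reservoir(
        rctip.ReservoirParams(n=20, input_scaling=0.1, seed=0), 3)
    fs_reg = rctip.build_training_set(
        train, res, 300, spec, "regression", negatives_per_run=50, seed=1,
        scaler=scaler)
    fs_cls = rctip.FeatureSet(features=fs_reg.features,
                              labels=(fs_reg.labels != 0).astype(float),
                              task="classification")
    reg = rctip.train_detector(fs_reg, seed=2, T_w=300, scaler=scaler)
    cls = rctip.train_detector(fs_cls, seed=2, T_w=300, scaler=scaler)
    return {"reservoir": res, "scaler": scaler, "spec": spec,
            "regression": reg, "classification": cls, "train": train,
            "features": fs_reg}
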