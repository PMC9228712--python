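import numpy as np
import pytest

import specfuse as sf


@pytest.fixture(scope="session")
def default_blocks():
    """One default simulated dataset (seed 0), shared across tests."""
    return sf.simulate_dataset(sf.SimulationConfig())


@pytest.fixture(scope="session")
def preprocessed_blocks(default_blocks):
    pipeline = sf.PreprocessPipeline()
    mir, nir = default_blocks
    return pipeline.transform_block(mir), pipeline.transform_block(nir)


@pytest.fixture(scope="session")
def fused_default(preprocessed_blocks):
    return sf.fuse_blocks(list(preprocessed_blocks))


@pytest.fixture(scope="session")
def default_plan(fused_default):
    return sf.split_dataset(fused_default)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fit_variant(fused, plan, method="PLS", n_components=10):
    """Center on the calibration rows and fit; returns the ready model."""
    cal = plan.calibration_mask(fused.sample_id)
    X_cal, y_cal = fused.X[cal], fused.concentration[cal]
    x_mean, y_mean = X_cal.mean(axis=0), float(y_cal.mean())
    fit = sf.fit_pls if method == "PLS" else sf.fit_pcr
    model = fit(X_cal - x_mean, y_cal - y_mean, n_components)
    model.x_mean, model.y_mean = x_mean, y_mean
    return model
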