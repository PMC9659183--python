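import warnings

import numpy as np
import pytest

from tsdea import RunConfig, SimConfig, generate, run_three_stage


@pytest.fixture(scope="session")
def default_panel_truth():
    """One default synthetic 31 x 4 panel with its ground truth."""
    return generate(SimConfig())


@pytest.fixture(scope="session")
def default_result(default_panel_truth):
    """Full three-stage run on the default panel (shared: solves ~1000 LPs)."""
    panel, _ = default_panel_truth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_three_stage(panel, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20171231)


def random_instance(rng, n_dmus=None, n_inputs=1, n_outputs=1):
    """A random positive DEA cross-section."""
    if n_dmus is None:
        n_dmus = int(rng.integers(2, 7))
    X = rng.uniform(0.5, 10.0, size=(n_dmus, n_inputs))
    Y = rng.uniform(0.5, 10.0, size=(n_dmus, n_outputs))
    return X, Y
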