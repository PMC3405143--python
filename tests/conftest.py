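import numpy as np
import pytest

from bloodmeth import pipeline, synthetic


@pytest.fixture(scope="session")
def tiny_truth():
    cfg = synthetic.GeneratorConfig(**synthetic.TINY_CONFIG)
    return synthetic.make_truth(cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_truth):
    return synthetic.simulate_samples(tiny_truth, seed=12)


@pytest.fixture(scope="session")
def default_truth():
    """Full emulated study design: 20,000 probes, 10 populations, 6 donors."""
    return synthetic.make_truth(synthetic.GeneratorConfig(), seed=101)


@pytest.fixture(scope="session")
def default_run(default_truth):
    """One full analysis of the default synthetic study, shared by the
    acceptance tests (expensive: simulation + preprocessing + 60 mixture
    fits + all pairwise contrasts)."""
    dataset = synthetic.simulate_samples(default_truth, seed=102)
    result = pipeline.run_reference_analysis(dataset)
    return dataset, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
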