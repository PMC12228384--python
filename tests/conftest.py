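import numpy as np
import pytest

from roiflow import synth


@pytest.fixture(scope="session")
def small_params():
    return synth.SimulationParams(
        n_genes=300, n_deg=20, lfc_magnitude=1.0, seed=1
    )


@pytest.fixture(scope="session")
def small_study(small_params):
    design = synth.generate_design(small_params)
    counts, truth = synth.simulate_counts(design, small_params)
    return counts, truth


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("demo")
    return synth.make_demo_dataset(outdir, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
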