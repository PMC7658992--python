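import numpy as np
import pytest

import algaetox as at


@pytest.fixture(scope="session")
def noiseless_truth() -> at.TruthModel:
    return at.TruthModel(noise_cv_density=0.0, noise_sd_yield=0.0, conc_noise_cv=0.0)


@pytest.fixture(scope="session")
def design() -> at.AssayDesign:
    return at.default_design(ec50=20.0)


@pytest.fixture(scope="session")
def noiseless_dataset(design, noiseless_truth) -> at.AssayDataset:
    return at.simulate_assay(design, noiseless_truth, seed=11, herbicide_name="diuron-like")


@pytest.fixture(scope="session")
def noisy_dataset(design) -> at.AssayDataset:
    return at.simulate_assay(design, at.TruthModel(), seed=12, herbicide_name="diuron-like")


@pytest.fixture(scope="session")
def noisy_table(noisy_dataset) -> at.EndpointTable:
    return at.endpoint_table(noisy_dataset)


@pytest.fixture(scope="session")
def flat_dataset() -> at.AssayDataset:
    # haloxyfop-like regime: no response up to a very high top concentration
    design = at.AssayDesign(concentrations=tuple(np.geomspace(4.57, 4570.0, 7)))
    return at.simulate_assay(design, at.flat_truth(), seed=13, herbicide_name="haloxyfop-like")


@pytest.fixture(scope="session")
def flat_table(flat_dataset) -> at.EndpointTable:
    return at.endpoint_table(flat_dataset)


@pytest.fixture
def fast_config() -> at.RunConfig:
    """Reduced bootstrap/MCMC sizes for pipeline plumbing tests."""
    return at.RunConfig(seed=5, n_boot=50, mcmc=at.MCMCSettings(iterations=1500, burnin=750))
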