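"""Shared fixtures: one small simulated EEG-fMRI session reused across tests."""

import numpy as np
import pytest

import eegbold as eb

MASTER_SEED = 11


@pytest.fixture(scope="session")
def seeds():
    return eb.substreams(MASTER_SEED)


@pytest.fixture(scope="session")
def protocol(seeds):
    return eb.generate_protocol(8, seed=seeds["block-order"])


@pytest.fixture(scope="session")
def recording(protocol, seeds):
    return eb.simulate_eeg(protocol, eb.EEGSimParams(seed=seeds["eeg-noise"]))


@pytest.fixture(scope="session")
def scalp(recording):
    return eb.principal_projection(recording)


@pytest.fixture(scope="session")
def tfr(scalp):
    return eb.morlet_power(scalp)


@pytest.fixture(scope="session")
def gfp(recording):
    return eb.global_field_power(recording)


@pytest.fixture(scope="session")
def basis():
    return eb.canonical_hrf_basis(0.1)


@pytest.fixture(scope="session")
def bold_and_truth(tfr, gfp, protocol, basis, seeds):
    params = eb.BOLDSimParams(seed=seeds["bold-noise"], n_voxels=100)
    return eb.simulate_bold(tfr, gfp, protocol, params, basis)


@pytest.fixture(scope="session")
def three_way_models(tfr, gfp):
    return [eb.build_regressors(l, tfr, gfp=gfp) for l in ("TP", "FR3", "RMSF")]


@pytest.fixture(scope="session")
def three_way_design(three_way_models, bold_and_truth, basis):
    bold, _ = bold_and_truth
    return eb.assemble_design(three_way_models, bold, basis)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(MASTER_SEED)
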