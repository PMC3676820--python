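import numpy as np
import pytest

from foldscale import analysis, cg_sampler, fixtures


@pytest.fixture(scope="session")
def hairpin16():
    return fixtures.make_ideal_hairpin(16)


@pytest.fixture(scope="session")
def extended16():
    return fixtures.make_extended_chain(16)


@pytest.fixture(scope="session")
def gb1_standin():
    return fixtures.make_gb1_hairpin_standin()


@pytest.fixture(scope="session")
def backbone_contacts(hairpin16):
    """Native backbone (CA, C, N, O) contact set at the 4.5 Å cutoff."""
    return analysis.native_contacts(hairpin16)


@pytest.fixture(scope="session")
def ca_contacts(hairpin16):
    """CA-only contact set matching the Gō model's 8 Å cutoff."""
    return analysis.native_contacts(hairpin16, cutoff=8.0, atom_names=("CA",))


@pytest.fixture(scope="session")
def go_model(hairpin16):
    return cg_sampler.build_go_model(hairpin16, contact_cutoff=8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
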