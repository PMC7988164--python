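import pytest

from glaquant import quant, synth

#: Mature factor IX GLA domain (residues 1-46): twelve glutamates at
#: positions 7, 8, 15, 17, 20, 21, 26, 27, 30, 33, 36 and 40.
GLA_DOMAIN = "YNSGKLEEFVQGNLERECMEEKCSFEEAREVFENTERTTEFWKQYV"


@pytest.fixture(scope="session")
def scenario():
    return synth.default_scenario(seed=0)


@pytest.fixture(scope="session")
def library(scenario):
    return synth.build_library(scenario)


@pytest.fixture(scope="session")
def annotations(scenario):
    return synth.class_table(scenario)


@pytest.fixture(scope="session")
def day13_render(scenario):
    """Day-13 supernatant + purified endpoints, sigma 0.1, 3 replicates."""
    noise = synth.NoiseModel(sigma=0.1)
    table, truth, manifest = synth.render_dataset(
        scenario, noise, n_replicates=3, seed=11, days=[13]
    )
    return table, truth, manifest


@pytest.fixture(scope="session")
def day13_quant(day13_render, library):
    table, _, _ = day13_render
    peptides, proteins, normalized = quant.quantify(
        table, library, profile=quant.GLA_METHYL_PROFILE
    )
    return peptides, proteins, normalized
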