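import numpy as np
import pytest

from soilvirome import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20170509)


@pytest.fixture(scope="session")
def small_design():
    return synth.CommunityDesign(
        depths=("0-5cm",), locations=("up",), replicates_per_cell=1, library_size_mean=20_000
    )


@pytest.fixture(scope="session")
def small_community(small_design):
    """A 20-genome community with planted truth and noiseless placements."""
    contigs, genes = synth.generate_genomes(
        20, length_range=(5000, 12000), molecule_mix=0.3, seed=11
    )
    truth = synth.plant_truth(contigs, genes, small_design, seed=12)
    placements, libraries = synth.simulate_placements(
        truth, small_design, contigs, genes, seed=13, noiseless=True
    )
    return {
        "contigs": contigs,
        "genes": genes,
        "truth": truth,
        "placements": placements,
        "libraries": libraries,
    }
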