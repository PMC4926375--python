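import warnings

import pytest

from mitocomp.genome_io import parse_genbank, partition_set
from mitocomp.synthetic_mitogenome import (SynthConfig, generate_clade,
                                           write_fixture_bundle)


@pytest.fixture(scope="session")
def small_clade():
    """Four related synthetic genomes plus ground truth (seed 42)."""
    return generate_clade(SynthConfig(seed=42, n_genomes=4))


@pytest.fixture(scope="session")
def clade_genomes(small_clade):
    return small_clade[0]


@pytest.fixture(scope="session")
def clade_truth(small_clade):
    return small_clade[1]


@pytest.fixture(scope="session")
def clade_psets(clade_genomes):
    return {g.id: partition_set(g) for g in clade_genomes}


@pytest.fixture(scope="session")
def bundle_dir(small_clade, tmp_path_factory):
    genomes, truth = small_clade
    d = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(genomes, truth, d)
    return d


@pytest.fixture(scope="session")
def reparsed_genome(bundle_dir):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return parse_genbank(bundle_dir / "SYN01.gb")
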