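import numpy as np
import pytest

from dictycomp.io import GenomeSequence
from dictycomp.simulate import SimConfig, generate_dataset


def genome_of(seq: str, scaffold_id: str = "s1") -> GenomeSequence:
    """Uppercase, unmasked scaffold from a literal string (lowercase masks)."""
    masked = np.array([c.islower() for c in seq])
    return GenomeSequence(scaffold_id, seq.upper(), masked)


SMALL_CONFIG = SimConfig(n_genes=60, n_scaffolds_a=3, n_scaffolds_b=2,
                         rearrangement_ops=4, n_ncrna_loci=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact generated dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("small_dataset")
    paths, truth = generate_dataset(SMALL_CONFIG, outdir)
    return paths, truth, SMALL_CONFIG


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """A dataset at the default study conditions (300 ortholog pairs)."""
    cfg = SimConfig(seed=101)
    outdir = tmp_path_factory.mktemp("default_dataset")
    paths, truth = generate_dataset(cfg, outdir)
    return paths, truth, cfg
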