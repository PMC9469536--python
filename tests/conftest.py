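import pytest

from mitocompare.genome_model import AnnotatedGenome, Feature
from mitocompare.synthetic_data import SyntheticSpec, diverge, generate_genome


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=42, genome_id="synA")


@pytest.fixture(scope="session")
def synthetic_genome(default_spec):
    return generate_genome(default_spec)


@pytest.fixture(scope="session")
def sister_pair(default_spec, synthetic_genome):
    genome, truth = synthetic_genome
    sister, sister_truth = diverge(genome, default_spec, new_id="synB", parent_truth=truth)
    return genome, truth, sister, sister_truth


def make_genome(sequence, features=(), gid="g", topology="circular"):
    return AnnotatedGenome(gid, sequence, topology, list(features))


def feat(name, ftype, strand, intervals, parent=None, anticodon=None):
    return Feature(name, ftype, strand, list(intervals), parent=parent, anticodon=anticodon)


@pytest.fixture
def simple_gene_genome():
    """1-kb genome with a single 300-bp plus-strand gene at 101..400."""
    import numpy as np

    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    seq = seq[:100] + "ATG" + seq[103:397] + "TAA" + seq[400:]
    g = make_genome(seq, [feat("pcg1", "PCG", "+", [(101, 400)])])
    return g
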