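import numpy as np
import pandas as pd
import pytest

from mycohic.io import Genome
from mycohic.simulate import ContactModel, GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def small_spec():
    """A compact genome for unit tests: 2 x 800 kb with scaled-down
    centromeres/subtelomeres so the heterochromatin budget still fits."""
    return GenomeSpec(
        n_chroms=2,
        chrom_length_bp=800_000,
        centromere_size=50_000,
        subtelomere_size=15_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return generate_genome(small_spec)


@pytest.fixture(scope="session")
def default_genome():
    """The default study-scale synthetic genome (3 x 2 Mb, 15.76% H3K9me3)."""
    return generate_genome(GenomeSpec(seed=1))


@pytest.fixture()
def toy_genome():
    """Tiny hand-built genome for constructed-matrix tests."""
    return Genome(
        chrom_names=["c1", "c2"],
        chrom_lengths={"c1": 5000, "c2": 3000},
    )


def random_pairs_frame(genome: Genome, n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    chroms = rng.choice(genome.chrom_names, size=(n, 2))
    pos = np.column_stack(
        [
            rng.integers(0, [genome.chrom_lengths[c] for c in chroms[:, 0]]),
            rng.integers(0, [genome.chrom_lengths[c] for c in chroms[:, 1]]),
        ]
    )
    strands = rng.choice(["+", "-"], size=(n, 2))
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(n)],
            "chrom1": chroms[:, 0],
            "pos1": pos[:, 0],
            "chrom2": chroms[:, 1],
            "pos2": pos[:, 1],
            "strand1": strands[:, 0],
            "strand2": strands[:, 1],
        }
    )
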