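from __future__ import annotations

import numpy as np
import pytest

from magcurate.formats_io import Contig
from magcurate.synthetic_community import demo_specs, simulate_community

DEMO_SEED = 12345


@pytest.fixture(scope="session")
def demo_community():
    """The seeded two-genome demo: 200-kb genomes at coverages 10 and 40,
    a 4-copy rRNA operon in the high-coverage genome, contigs 2.5-10 kb."""
    contigs, truth, loci = simulate_community(
        demo_specs(), DEMO_SEED, max_contig_len=10_000
    )
    return contigs, truth, loci


@pytest.fixture(scope="session")
def demo_depths(demo_community):
    contigs, _, _ = demo_community
    return {c.id: c.depth for c in contigs}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


def make_contig(cid: str, seq: str, depth: float = 1.0) -> Contig:
    return Contig(id=cid, seq=seq, depth=depth)
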