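import numpy as np
import pytest

from centrochip.genome import (
    ChromosomeSpec,
    MinichromosomeSpec,
    RepeatFamilySpec,
    build_genome,
)
from centrochip.mapping import GenomeIndex


@pytest.fixture(scope="session")
def small_build():
    """30 kb chromosome with a 3 kb repeat array (30 x 100 bp, 3% diverged)."""
    cen = RepeatFamilySpec(unit_length=100, unit_at_fraction=0.6,
                           copy_count=30, per_copy_divergence=0.03)
    chrom = ChromosomeSpec("chr1", 30_000, cen, 10_000)
    return build_genome([chrom], None, rng_seed=42)


@pytest.fixture(scope="session")
def small_index(small_build):
    return GenomeIndex(small_build, 49)


@pytest.fixture(scope="session")
def mini_build():
    """Default palindromic minichromosome plus one small chromosome."""
    cen = RepeatFamilySpec(unit_length=50, unit_at_fraction=0.6,
                           copy_count=10, per_copy_divergence=0.0)
    chrom = ChromosomeSpec("chr1", 10_000, cen, 4_000)
    return build_genome([chrom], MinichromosomeSpec(), rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
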