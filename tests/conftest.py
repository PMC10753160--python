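import numpy as np
import pytest

from t2tkit.simulate import (ChromosomeSpec, CentromereSpec, FamilyConfig,
                             FamilyMemberSpec, GenomeConfig, simulate_genome)


@pytest.fixture(scope="session")
def small_bundle():
    """Two small chromosomes with telomeres and one centromere."""
    cfg = GenomeConfig(chromosomes=[
        ChromosomeSpec("Chr1", 500_000, tel5=120, tel3=200,
                       centromeres=[CentromereSpec(monomer_len=171, copies=300,
                                                   divergence=0.02)]),
        ChromosomeSpec("Chr2", 400_000, tel5=50, tel3=300),
    ])
    return simulate_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def family_cfg():
    return FamilyConfig(members=[
        FamilyMemberSpec("memA", residue="T", identity=0.92, chrom="Chr1", rank=3),
        FamilyMemberSpec("memB", residue="S", identity=0.85, chrom="Chr1", rank=8),
        FamilyMemberSpec("memC", residue="A", identity=0.80, chrom="Chr2", rank=2),
        FamilyMemberSpec("shorty", residue="G", identity=0.70, length=399),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
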