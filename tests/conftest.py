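from pathlib import Path

import numpy as np
import pytest

import clonehet as ch
from clonehet import genotypes as gt
from clonehet.matrix import GenotypeMatrix

DATA = Path(__file__).parent / "data"

#: grove membership of the GRAS-Di fixture samples (two groves of four)
GRASDI_GROVES = {s: "G1" for s in "ABCD"} | {s: "G2" for s in "EFGH"}

#: loci flagged by the reference-read control in the WGS fixture
WGS_REF_CONTROL = frozenset({("s1", 1300), ("s1", 1400)})


@pytest.fixture(scope="session")
def wgs_fixture():
    """Hand-crafted 20-locus WGS VCF with pre-registered survivor counts."""
    return ch.load_vcf(DATA / "wgs_fixture.vcf")


@pytest.fixture(scope="session")
def grasdi_fixture():
    """Hand-crafted 15-locus GRAS-Di VCF with pre-registered survivor counts."""
    return ch.load_vcf(DATA / "grasdi_fixture.vcf")


def matrix_from_classes(rows, samples, scaffold="s1"):
    """Build a GenotypeMatrix from a list of per-locus class lists."""
    codes = np.array([[gt.CODE[c] for c in row] for row in rows], dtype=np.int8)
    loci = [(scaffold, 100 * (i + 1)) for i in range(len(rows))]
    return GenotypeMatrix(codes, loci, list(samples))


@pytest.fixture(scope="session")
def caterpillar_truth():
    """One seeded caterpillar simulation with strong per-branch signal."""
    cfg = ch.SimConfig(genome_length=200_000, somatic_rate=2.5e-6,
                       depth_mean=60, seed=11)
    tree = ch.CloneTree.caterpillar(list("ABCDEFGH"), 50.0)
    truth = ch.propagate_clones(ch.generate_founder(cfg), tree, cfg)
    return cfg, tree, truth
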