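import numpy as np
import pytest

from domainscape.simulate import SimulationConfig, simulate_codon_genes, simulate_region


@pytest.fixture(scope="session")
def sim_region():
    """A small repeat-dense region with genes and signal tracks."""
    cfg = SimulationConfig(seed=42, region_length=120_000, gene_count=10,
                           class_densities={"LTR": 0.40, "LINE": 0.20, "DNA": 0.05})
    return simulate_region(cfg)


@pytest.fixture(scope="session")
def codon_geneset():
    """CDS sets under uniform / mutational / selected codon regimes."""
    seqs, truth, reference, optimal = simulate_codon_genes(
        seed=7, genes_per_group=6, codons_per_gene=2000)
    return {"seqs": seqs, "truth": truth, "reference": reference, "optimal": optimal}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def classes_per_base(features, length):
    """Per-base oracle: the set of canonical classes covering each base."""
    cover = [set() for _ in range(length)]
    for f in features:
        for b in range(f.start, min(f.end, length)):
            cover[b].add(f.canonical_class)
    return cover
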